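"""Low-level image representation, Bernsen local thresholding, and particle analysis.

The two image operators here mirror the Fiji/ImageJ workflow commonly used for
single-cell fluorescence quantification: an Auto-Local-Threshold (Bernsen)
binarization followed by Analyze-Particles-style connected-component
measurement.  Both are deterministic, integer-exact where the definition
permits, and validated in the test suite against brute-force oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

Role = Literal["DNA", "MEMBRANE", "PHA"]

__all__ = [
    "ChannelImage",
    "BernsenParams",
    "BinaryMask",
    "Particle",
    "ParticleFilter",
    "ParticleSet",
    "bernsen_threshold",
    "label_particles",
    "overlap_assign",
    "circular_footprint",
]


@dataclass(frozen=True)
class ChannelImage:
    """One co-registered grayscale fluorescence channel.

    Parameters
    ----------
    pixels : ndarray of unsigned integers, shape (rows, cols)
        Raw intensities.
    bit_depth : {8, 16}
        Declared camera bit depth; all intensities must lie in
        ``[0, 2**bit_depth - 1]``.
    role : {"DNA", "MEMBRANE", "PHA"}
        Biological role of the stain imaged in this channel: nucleic-acid
        stain for cell counting, membrane stain for whole-cell outlines, or
        the PHA-granule stain.
    pixel_size : float, optional
        Physical pixel edge length in µm/px, if known.
    """

    pixels: np.ndarray
    bit_depth: int
    role: Role
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixel intensities must be integers")
        vmax = (1 << self.bit_depth) - 1
        if px.min() < 0 or px.max() > vmax:
            raise ValueError(f"intensities must lie in [0, {vmax}]")
        if self.role not in ("DNA", "MEMBRANE", "PHA"):
            raise ValueError(f"unknown channel role {self.role!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BernsenParams:
    """Parameters of the Bernsen auto local threshold.

    Defaults follow the ImageJ Auto Local Threshold plugin: radius 15 px,
    contrast threshold 15 and a low-contrast cut of 128 on the 8-bit scale.
    """

    radius: int = 15
    contrast_threshold: int = 15
    low_contrast_cut: int = 128

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.contrast_threshold < 0:
            raise ValueError("contrast_threshold must be >= 0")
        if not (0 <= self.low_contrast_cut <= 255):
            raise ValueError("low_contrast_cut must lie in the 8-bit range")


@dataclass(frozen=True)
class BinaryMask:
    """Object/background mask plus provenance of how it was produced."""

    pixels: np.ndarray  # boolean, True = object
    source_role: Optional[Role] = None
    params: Optional[BernsenParams] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a nonempty 2-D array")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Particle:
    """One labeled connected component of a binary mask."""

    label: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    touches_border: bool


@dataclass(frozen=True)
class ParticleFilter:
    """Size and border filters applied during particle analysis."""

    min_area_px: int = 0
    max_area_px: Optional[int] = None
    exclude_border: bool = False

    def __post_init__(self) -> None:
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")
        if self.max_area_px is not None and self.max_area_px < self.min_area_px:
            raise ValueError("min_area_px must not exceed max_area_px")


@dataclass
class ParticleSet:
    """Surviving particles with their label image (0 = background)."""

    particles: list[Particle]
    label_image: np.ndarray
    source_role: Optional[Role] = None

    def __len__(self) -> int:
        return len(self.particles)

    def by_label(self) -> Mapping[int, Particle]:
        return {p.label: p for p in self.particles}


def circular_footprint(radius: int) -> np.ndarray:
    """Boolean disk of pixels whose center distance is <= radius."""
    r = int(radius)
    yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def _to_8bit(img: ChannelImage) -> np.ndarray:
    """Linearly rescale a channel to the 8-bit scale if needed (min-max per image)."""
    px = img.pixels
    if img.bit_depth == 8:
        return px.astype(np.int64)
    lo = int(px.min())
    hi = int(px.max())
    if hi == lo:
        return np.zeros_like(px, dtype=np.int64)
    scaled = (px.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.int64)


def bernsen_threshold(img: ChannelImage, params: BernsenParams = BernsenParams()) -> BinaryMask:
    """Binarize a channel with the Bernsen auto local threshold.

    For every pixel the intensity extrema over a circular window of the given
    radius (clipped at image borders) define ``contrast = max - min`` and
    ``midgray = (max + min)/2``.  High-contrast pixels
    (``contrast >= contrast_threshold``) are object when strictly brighter
    than the midgray; low-contrast pixels are routed wholesale to object or
    background by comparing the midgray with ``low_contrast_cut``.

    All comparisons are carried out on doubled integer intensities so the
    half-integer midgray is handled exactly.  16-bit inputs are min-max
    rescaled to the 8-bit range first, since the low-contrast cut is defined
    on that scale.
    """
    px = _to_8bit(img)
    foot = circular_footprint(params.radius)
    # mode="nearest" replicates edge values, which is equivalent to taking
    # extrema over the window clipped at the image border.
    local_max = ndimage.maximum_filter(px, footprint=foot, mode="nearest")
    local_min = ndimage.minimum_filter(px, footprint=foot, mode="nearest")
    contrast = local_max - local_min
    two_midgray = local_max + local_min  # 2 * midgray, exact
    low = contrast < params.contrast_threshold
    obj_low = two_midgray >= 2 * params.low_contrast_cut
    obj_high = 2 * px > two_midgray
    mask = np.where(low, obj_low, obj_high)
    return BinaryMask(pixels=mask, source_role=img.role, params=params)


def label_particles(mask: BinaryMask, filt: ParticleFilter = ParticleFilter()) -> ParticleSet:
    """Enumerate 8-connected components of a mask, Analyze-Particles style.

    Components outside ``[min_area_px, max_area_px]`` are dropped, as are
    components touching any image edge when ``exclude_border`` is set.
    Survivors are relabeled ``1..n`` in raster order of their first pixel.
    """
    px = mask.pixels
    raw = measure.label(px, connectivity=2)
    nrows, ncols = px.shape
    props = measure.regionprops(raw)

    # raster order of the first pixel of each component
    flat = raw.ravel()
    labels_present, first_idx = np.unique(flat, return_index=True)
    order = {
        int(lab): int(idx) for lab, idx in zip(labels_present, first_idx) if lab != 0
    }

    survivors = []
    for rp in props:
        area = int(rp.area)
        if area < filt.min_area_px:
            continue
        if filt.max_area_px is not None and area > filt.max_area_px:
            continue
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == nrows or maxc == ncols
        if filt.exclude_border and touches:
            continue
        survivors.append((order[rp.label], rp, touches))
    survivors.sort(key=lambda t: t[0])

    label_image = np.zeros_like(raw)
    particles: list[Particle] = []
    for new_label, (_, rp, touches) in enumerate(survivors, start=1):
        label_image[raw == rp.label] = new_label
        cr, cc = rp.centroid
        particles.append(
            Particle(
                label=new_label,
                area_px=int(rp.area),
                centroid=(float(cr), float(cc)),
                bbox=tuple(int(b) for b in rp.bbox),
                touches_border=bool(touches),
            )
        )
    return ParticleSet(particles=particles, label_image=label_image, source_role=mask.source_role)


def overlap_assign(children: ParticleSet, parents: ParticleSet) -> dict[int, Optional[int]]:
    """Assign each child particle to a parent particle by spatial containment.

    A child is assigned to the parent whose region contains the child's
    centroid (nearest pixel); if that pixel is parent background, to the
    parent with maximal pixel overlap, ties broken by lowest parent label.
    Children with zero overlap map to ``None``.
    """
    if children.label_image.shape != parents.label_image.shape:
        raise ValueError("child and parent label images must have identical dimensions")
    plab = parents.label_image
    nrows, ncols = plab.shape
    out: dict[int, Optional[int]] = {}
    for child in children.particles:
        cr = min(max(int(np.floor(child.centroid[0] + 0.5)), 0), nrows - 1)
        cc = min(max(int(np.floor(child.centroid[1] + 0.5)), 0), ncols - 1)
        hit = int(plab[cr, cc])
        if hit != 0:
            out[child.label] = hit
            continue
        region = plab[children.label_image == child.label]
        region = region[region != 0]
        if region.size == 0:
            out[child.label] = None
            continue
        labs, counts = np.unique(region, return_counts=True)
        # maximal overlap; np.unique sorts labels, argmax takes first (lowest) on ties
        out[child.label] = int(labs[np.argmax(counts)])
    return out
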
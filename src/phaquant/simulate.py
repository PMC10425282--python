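"""Synthetic multi-channel epifluorescence fields with known ground truth.

Generates fields of coccoid (spherical) cells carrying 0-2 polar PHA
granules, rendered as 2-D equatorial projections into three co-registered
channels (DNA, membrane, PHA) with Gaussian PSF blur, additive background
and optional noise.  Ground truth records 3-D volume fractions
(v = Σ r_granule³ / R_cell³) so the pipeline's sphere-assumption conversion
can be assessed against geometric truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .imaging import ChannelImage
from .quantify import ConversionParams, volume_to_mass_fraction

__all__ = [
    "NoiseModel",
    "SceneConfig",
    "CellTruth",
    "GroundTruth",
    "TruthSummary",
    "generate_scene",
    "truth_summary",
]


@dataclass(frozen=True)
class NoiseModel:
    """Per-channel noise applied after PSF blur.

    kind "none": noiseless; "gaussian": additive zero-mean noise of the
    given sigma (8-bit intensity units); "shot": Poisson resampling of each
    blurred pixel value, emulating photon shot noise.
    """

    kind: Literal["none", "gaussian", "shot"] = "gaussian"
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "shot"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class SceneConfig:
    """Generative description of one field of view.

    Defaults emulate the morphology seen in epifluorescence micrographs of
    PHA-accumulating methanotroph enrichments: non-touching coccoid cells,
    most granule-bearing cells with two distinct polar granules, 8-bit
    intensities with cell interiors near 180 over a background near 20.
    Cell and granule radii are drawn uniformly from mean ± spread.
    """

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 50
    cell_radius_px: float = 18.0
    cell_radius_spread_px: float = 2.0
    granules_per_cell_probs: tuple[float, float, float] = (0.6, 0.1, 0.3)  # P(0), P(1), P(2)
    granule_radius_px: float = 7.2
    granule_radius_spread_px: float = 0.5
    polar_offset_frac: float = 0.6  # granule centers at ±frac·R along the cell axis
    channel_gains: dict[str, float] = field(
        default_factory=lambda: {"DNA": 180.0, "MEMBRANE": 180.0, "PHA": 180.0}
    )
    background_level: float = 20.0
    psf_sigma_px: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if min(self.image_size) < 1:
            raise ValueError("image_size must be >= 1x1")
        probs = self.granules_per_cell_probs
        if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("granules_per_cell_probs must be 3 non-negative values summing to 1")
        if self.granule_radius_px + self.granule_radius_spread_px > self.cell_radius_px - self.cell_radius_spread_px:
            raise ValueError("granules must fit inside the smallest cell")
        if not 0.0 <= self.polar_offset_frac <= 1.0:
            raise ValueError("polar_offset_frac must lie in [0, 1]")


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one cell."""

    cell_id: int
    center: tuple[float, float]  # (row, col)
    radius_px: float
    granule_centers: tuple[tuple[float, float], ...]
    granule_radii: tuple[float, ...]
    true_area_fraction: float  # 2-D equatorial: Σ r² / R²
    true_volume_fraction: float  # 3-D: Σ r³ / R³
    true_mass_fraction: float

    @property
    def has_granules(self) -> bool:
        return len(self.granule_radii) > 0


@dataclass
class GroundTruth:
    """All per-cell truths plus per-channel label masks."""

    cells: list[CellTruth]
    cell_label_mask: np.ndarray  # DNA/membrane channels (cells labeled 1..n)
    granule_label_mask: np.ndarray  # PHA channel (granules labeled 1..m)
    config: SceneConfig


@dataclass(frozen=True)
class TruthSummary:
    n_cells: int
    n_cells_with_granules: int
    percent_cells_with_pha: float
    mean_mass_fraction_pct: float  # over granule-bearing cells; NaN if none
    all_cells_mean_mass_fraction_pct: float


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _place_cells(
    cfg: SceneConfig, rng: np.random.Generator
) -> list[tuple[tuple[float, float], float]]:
    """Random sequential placement of non-overlapping cells away from borders."""
    nrows, ncols = cfg.image_size
    margin_pad = 3.0 * cfg.psf_sigma_px + 2.0
    placed: list[tuple[tuple[float, float], float]] = []
    max_attempts = 200 * max(cfg.n_cells, 1)
    attempts = 0
    while len(placed) < cfg.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_cells} non-overlapping cells in a "
                f"{nrows}x{ncols} field after {max_attempts} attempts"
            )
        attempts += 1
        radius = rng.uniform(
            cfg.cell_radius_px - cfg.cell_radius_spread_px,
            cfg.cell_radius_px + cfg.cell_radius_spread_px,
        )
        margin = radius + margin_pad
        if 2 * margin >= min(nrows, ncols):
            raise RuntimeError("field too small for the configured cell radius")
        center = (rng.uniform(margin, nrows - margin), rng.uniform(margin, ncols - margin))
        gap = 2.0  # minimum clearance between cell rims, px
        ok = all(
            np.hypot(center[0] - c[0], center[1] - c[1]) >= radius + r + gap
            for c, r in placed
        )
        if ok:
            placed.append((center, radius))
    return placed


def _apply_noise(img: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.kind == "none":
        return img
    if noise.kind == "gaussian":
        return img + rng.normal(0.0, noise.sigma, size=img.shape)
    return rng.poisson(np.clip(img, 0.0, None)).astype(float)


def _render_channel(
    ideal: np.ndarray, cfg: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    blurred = ndimage.gaussian_filter(ideal, cfg.psf_sigma_px) if cfg.psf_sigma_px > 0 else ideal
    noisy = _apply_noise(blurred, cfg.noise, rng)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def generate_scene(
    cfg: SceneConfig, conversion: ConversionParams = ConversionParams()
) -> tuple[ChannelImage, ChannelImage, ChannelImage, GroundTruth]:
    """Render one synthetic field and its ground truth.

    DNA and membrane channels show whole-cell disks; the PHA channel shows
    the polar granule disks.  Identical config (including seed) gives
    identical pixel arrays.  True mass fractions use the given conversion
    parameters on the 3-D volume fraction.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.image_size
    cells = _place_cells(cfg, rng)

    cell_label = np.zeros(shape, dtype=np.int32)
    gran_label = np.zeros(shape, dtype=np.int32)
    dna_ideal = np.full(shape, cfg.background_level, dtype=float)
    mem_ideal = np.full(shape, cfg.background_level, dtype=float)
    pha_ideal = np.full(shape, cfg.background_level, dtype=float)

    truths: list[CellTruth] = []
    granule_counter = 0
    for cell_id, (center, radius) in enumerate(cells, start=1):
        n_gran = int(rng.choice(3, p=cfg.granules_per_cell_probs))
        axis = rng.uniform(0.0, 2.0 * np.pi)
        poles = [axis, axis + np.pi]
        if n_gran == 1:
            poles = [poles[int(rng.integers(2))]]

        g_centers: list[tuple[float, float]] = []
        g_radii: list[float] = []
        for pole in poles[:n_gran]:
            g_r = rng.uniform(
                cfg.granule_radius_px - cfg.granule_radius_spread_px,
                cfg.granule_radius_px + cfg.granule_radius_spread_px,
            )
            # keep the granule fully inside the cell
            offset = min(cfg.polar_offset_frac * radius, radius - g_r)
            g_c = (center[0] + offset * np.sin(pole), center[1] + offset * np.cos(pole))
            g_centers.append(g_c)
            g_radii.append(g_r)

        disk = _disk_mask(shape, center, radius)
        cell_label[disk] = cell_id
        dna_ideal[disk] = cfg.channel_gains["DNA"]
        mem_ideal[disk] = cfg.channel_gains["MEMBRANE"]
        for g_c, g_r in zip(g_centers, g_radii):
            granule_counter += 1
            gdisk = _disk_mask(shape, g_c, g_r)
            gran_label[gdisk] = granule_counter
            pha_ideal[gdisk] = cfg.channel_gains["PHA"]

        f_true = min(1.0, sum(r ** 2 for r in g_radii) / radius ** 2)
        v_true = min(1.0, sum(r ** 3 for r in g_radii) / radius ** 3)
        truths.append(
            CellTruth(
                cell_id=cell_id,
                center=center,
                radius_px=radius,
                granule_centers=tuple(g_centers),
                granule_radii=tuple(g_radii),
                true_area_fraction=f_true,
                true_volume_fraction=v_true,
                true_mass_fraction=volume_to_mass_fraction(v_true, conversion),
            )
        )

    channels = []
    for ideal, role in ((dna_ideal, "DNA"), (mem_ideal, "MEMBRANE"), (pha_ideal, "PHA")):
        rendered = _render_channel(ideal, cfg, rng)
        channels.append(ChannelImage(pixels=rendered, bit_depth=8, role=role))

    truth = GroundTruth(
        cells=truths, cell_label_mask=cell_label, granule_label_mask=gran_label, config=cfg
    )
    return channels[0], channels[1], channels[2], truth


def truth_summary(truth: GroundTruth) -> TruthSummary:
    """Aggregate ground truth the way the pipeline summarizes a sample."""
    n = len(truth.cells)
    bearing = [c for c in truth.cells if c.has_granules]
    w_pos = np.array([c.true_mass_fraction for c in bearing], dtype=float)
    w_all = np.array([c.true_mass_fraction for c in truth.cells], dtype=float)
    return TruthSummary(
        n_cells=n,
        n_cells_with_granules=len(bearing),
        percent_cells_with_pha=100.0 * len(bearing) / n if n else 0.0,
        mean_mass_fraction_pct=float(100.0 * w_pos.mean()) if w_pos.size else float("nan"),
        all_cells_mean_mass_fraction_pct=float(100.0 * w_all.mean()) if w_all.size else float("nan"),
    )
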
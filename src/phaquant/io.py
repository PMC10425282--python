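"""TIFF/CSV/YAML input-output and configuration parsing."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import BernsenParams, BinaryMask, ChannelImage, ParticleFilter, ParticleSet, Role
from .quantify import (
    ChannelConfig,
    ConversionParams,
    FieldResult,
    QuantConfig,
    SampleSummary,
)
from .simulate import GroundTruth, NoiseModel, SceneConfig

__all__ = [
    "read_channel",
    "write_channel",
    "write_mask",
    "write_labels",
    "particles_to_frame",
    "cells_to_frame",
    "fields_to_frame",
    "summary_to_frame",
    "truth_to_frame",
    "quant_config_from_yaml",
    "scene_config_from_yaml",
    "write_provenance",
]


def read_channel(
    path: str | Path,
    role: Role,
    bit_depth: Optional[int] = None,
    page: Optional[int] = None,
    pixel_size: Optional[float] = None,
) -> ChannelImage:
    """Read a single-channel grayscale TIFF (optionally one page of a stack)."""
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.pages[page].asarray() if page is not None else tf.asarray()
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: expected integer pixel data, got {arr.dtype}")
    if bit_depth is None:
        bit_depth = 8 if arr.dtype.itemsize == 1 else 16
    return ChannelImage(pixels=arr.astype(np.int64), bit_depth=bit_depth, role=role, pixel_size=pixel_size)


def write_channel(path: str | Path, img: ChannelImage) -> None:
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    tifffile.imwrite(str(path), img.pixels.astype(dtype))


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(str(path), (mask.pixels.astype(np.uint8) * 255))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def particles_to_frame(pset: ParticleSet) -> pd.DataFrame:
    rows = [
        {
            "label": p.label,
            "area_px": p.area_px,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
            "bbox": "|".join(str(b) for b in p.bbox),
            "touches_border": p.touches_border,
        }
        for p in pset.particles
    ]
    return pd.DataFrame(
        rows,
        columns=["label", "area_px", "centroid_row", "centroid_col", "bbox", "touches_border"],
    )


def cells_to_frame(fields: list[FieldResult]) -> pd.DataFrame:
    rows = []
    for i, fr in enumerate(fields):
        for c in fr.cells:
            rows.append(
                {
                    "field": i,
                    "cell_label": c.cell_label,
                    "membrane_area_px": c.membrane_area_px,
                    "n_pha_particles": len(c.pha_particle_labels),
                    "pha_area_px": c.pha_area_px,
                    "has_pha": c.has_pha,
                    "area_fraction": c.area_fraction,
                    "volume_fraction": c.volume_fraction,
                    "mass_fraction": c.mass_fraction,
                    "area_pct": 100.0 * c.area_fraction,
                    "volume_pct": 100.0 * c.volume_fraction,
                    "mass_pct": 100.0 * c.mass_fraction,
                }
            )
    cols = [
        "field", "cell_label", "membrane_area_px", "n_pha_particles", "pha_area_px",
        "has_pha", "area_fraction", "volume_fraction", "mass_fraction",
        "area_pct", "volume_pct", "mass_pct",
    ]
    return pd.DataFrame(rows, columns=cols)


def fields_to_frame(fields: list[FieldResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "field": i,
                "dna_cell_count": fr.dna_cell_count,
                "n_membrane_cells": fr.n_membrane_cells,
                "n_cells_with_pha": fr.n_cells_with_pha,
                "n_unassigned_pha": fr.n_unassigned_pha,
            }
            for i, fr in enumerate(fields)
        ]
    )


def summary_to_frame(summary: SampleSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "n_images": summary.n_images,
                "dna_cell_count": summary.dna_cell_count,
                "n_membrane_cells": summary.n_membrane_cells,
                "n_cells_with_pha": summary.n_cells_with_pha,
                "percent_cells_with_pha": summary.percent_cells_with_pha,
                "mean_mass_fraction_pct": summary.mean_mass_fraction_pct,
                "mean_mass_fraction_all_cells_pct": summary.mean_mass_fraction_all_cells_pct,
            }
        ]
    )


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for c in truth.cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "center_row": c.center[0],
                "center_col": c.center[1],
                "radius_px": c.radius_px,
                "n_granules": len(c.granule_radii),
                "granule_radii_px": "|".join(f"{r:.4f}" for r in c.granule_radii),
                "true_area_fraction": c.true_area_fraction,
                "true_volume_fraction": c.true_volume_fraction,
                "true_mass_fraction": c.true_mass_fraction,
            }
        )
    return pd.DataFrame(rows)


def _bernsen_from_dict(d: dict[str, Any]) -> BernsenParams:
    return BernsenParams(
        radius=int(d.get("radius", 15)),
        contrast_threshold=int(d.get("contrast", d.get("contrast_threshold", 15))),
        low_contrast_cut=int(d.get("low_contrast_cut", 128)),
    )


def _filter_from_dict(d: dict[str, Any]) -> ParticleFilter:
    max_area = d.get("max_area_px")
    return ParticleFilter(
        min_area_px=int(d.get("min_area_px", 0)),
        max_area_px=None if max_area in (None, "none") else int(max_area),
        exclude_border=bool(d.get("exclude_border", False)),
    )


def _channel_from_dict(d: dict[str, Any], default: ChannelConfig) -> ChannelConfig:
    if not d:
        return default
    bern = _bernsen_from_dict(d.get("bernsen", {})) if "bernsen" in d else default.bernsen
    filt = _filter_from_dict(d.get("filter", {})) if "filter" in d else default.filter
    return ChannelConfig(bernsen=bern, filter=filt)


def quant_config_from_yaml(path: Optional[str | Path]) -> QuantConfig:
    """Build a QuantConfig from a YAML file; missing keys keep defaults.

    Recognized keys: per-channel blocks ``dna``/``membrane``/``pha`` each
    with ``bernsen: {radius, contrast, low_contrast_cut}`` and ``filter:
    {min_area_px, max_area_px, exclude_border}``; and ``conversion:
    {density_ratio, volume_model, mass_model}``.
    """
    base = QuantConfig()
    if path is None:
        return base
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    conv_d = data.get("conversion", {})
    conversion = ConversionParams(
        density_ratio=float(conv_d.get("density_ratio", 1.099)),
        volume_model=conv_d.get("volume_model", "aggregate"),
        mass_model=conv_d.get("mass_model", "mixture"),
    )
    return QuantConfig(
        dna=_channel_from_dict(data.get("dna", {}), base.dna),
        membrane=_channel_from_dict(data.get("membrane", {}), base.membrane),
        pha=_channel_from_dict(data.get("pha", {}), base.pha),
        conversion=conversion,
    )


def scene_config_from_yaml(path: Optional[str | Path], seed: Optional[int] = None) -> SceneConfig:
    """Build a SceneConfig from YAML; missing keys keep the defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {}
    simple = [
        "n_cells", "cell_radius_px", "cell_radius_spread_px", "granule_radius_px",
        "granule_radius_spread_px", "polar_offset_frac", "background_level",
        "psf_sigma_px", "seed",
    ]
    for key in simple:
        if key in data:
            kwargs[key] = data[key]
    if "image_size" in data:
        kwargs["image_size"] = tuple(int(x) for x in data["image_size"])
    if "granules_per_cell_probs" in data:
        kwargs["granules_per_cell_probs"] = tuple(float(x) for x in data["granules_per_cell_probs"])
    if "channel_gains" in data:
        kwargs["channel_gains"] = {str(k): float(v) for k, v in data["channel_gains"].items()}
    if "noise" in data:
        nd = data["noise"] or {}
        kwargs["noise"] = NoiseModel(kind=nd.get("kind", "gaussian"), sigma=float(nd.get("sigma", 1.5)))
    if seed is not None:
        kwargs["seed"] = int(seed)
    return SceneConfig(**kwargs)


def write_provenance(path: str | Path, payload: dict[str, Any]) -> None:
    """Record the run configuration (JSON) so a run can be reproduced."""
    from . import __version__

    payload = dict(payload)
    payload["phaquant_version"] = __version__

    def _default(o: Any):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
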
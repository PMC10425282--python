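"""Per-cell PHA scoring from three co-registered fluorescence channels.

Pipeline: Bernsen-threshold each channel, label particles, attribute PHA
granule particles to membrane-defined cells, then convert each cell's PHA
cross-sectional area fraction to a volume fraction (sphere assumption) and a
mass fraction (PHA-to-biomass density ratio 1.099).  The fraction of cells
with detectable PHA uses the DNA-channel cell count as denominator, because
the membrane stain does not label every cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .imaging import (
    BernsenParams,
    ChannelImage,
    ParticleFilter,
    ParticleSet,
    bernsen_threshold,
    label_particles,
    overlap_assign,
)

__all__ = [
    "ConversionParams",
    "ChannelConfig",
    "QuantConfig",
    "CellRecord",
    "FieldResult",
    "SampleSummary",
    "cell_area_fraction",
    "area_to_volume_fraction",
    "volume_to_mass_fraction",
    "count_cells_dna",
    "percent_cells_with_pha",
    "quantify_field",
    "summarize_sample",
]

DENSITY_RATIO_PHA_BIOMASS = 1.099  # dimensionless, PHA vs non-PHA biomass


@dataclass(frozen=True)
class ConversionParams:
    """Area→volume→mass conversion settings.

    volume_model
        "aggregate": the sphere assumption is applied to the summed granule
        cross-section, v = f^{3/2}.
        "per_granule": each granule is converted separately,
        v = Σ A_i^{3/2} / A_cell^{3/2} — consistent with discrete spherical
        granules.
    mass_model
        "mixture": w = ρv / (ρv + (1 − v)), the two-component mixture with
        density ratio ρ (satisfies w(1) = 1).
        "linear": w = ρ·v, the small-v approximation.
    """

    density_ratio: float = DENSITY_RATIO_PHA_BIOMASS
    volume_model: Literal["aggregate", "per_granule"] = "aggregate"
    mass_model: Literal["mixture", "linear"] = "mixture"

    def __post_init__(self) -> None:
        if self.density_ratio <= 0:
            raise ValueError("density_ratio must be > 0")
        if self.volume_model not in ("aggregate", "per_granule"):
            raise ValueError(f"unknown volume_model {self.volume_model!r}")
        if self.mass_model not in ("mixture", "linear"):
            raise ValueError(f"unknown mass_model {self.mass_model!r}")


@dataclass(frozen=True)
class ChannelConfig:
    """Threshold and particle-filter settings for one channel."""

    bernsen: BernsenParams = field(default_factory=BernsenParams)
    filter: ParticleFilter = field(default_factory=ParticleFilter)


def _default_cell_channel() -> ChannelConfig:
    return ChannelConfig(filter=ParticleFilter(min_area_px=20, exclude_border=True))


def _default_pha_channel() -> ChannelConfig:
    return ChannelConfig(filter=ParticleFilter(min_area_px=4, exclude_border=False))


@dataclass(frozen=True)
class QuantConfig:
    """Full configuration of the quantification pipeline."""

    dna: ChannelConfig = field(default_factory=_default_cell_channel)
    membrane: ChannelConfig = field(default_factory=_default_cell_channel)
    pha: ChannelConfig = field(default_factory=_default_pha_channel)
    conversion: ConversionParams = field(default_factory=ConversionParams)


@dataclass(frozen=True)
class CellRecord:
    """One membrane-defined cell and its PHA content."""

    cell_label: int
    membrane_area_px: int
    pha_particle_labels: tuple[int, ...]
    pha_area_px: int
    area_fraction: float
    volume_fraction: float
    mass_fraction: float

    @property
    def has_pha(self) -> bool:
        return len(self.pha_particle_labels) > 0


@dataclass
class FieldResult:
    """Per-field (per-image) quantification output."""

    cells: list[CellRecord]
    dna_cell_count: int
    n_membrane_cells: int
    n_unassigned_pha: int = 0

    @property
    def n_cells_with_pha(self) -> int:
        return sum(1 for c in self.cells if c.has_pha)


@dataclass
class SampleSummary:
    """Sample-level summary pooled over fields (typically 15 images/sample)."""

    n_images: int
    dna_cell_count: int
    n_membrane_cells: int
    n_cells_with_pha: int
    percent_cells_with_pha: float
    per_cell_mass_fractions: np.ndarray  # PHA-positive cells only
    mean_mass_fraction_pct: float  # mean over PHA-positive cells, % m/m
    mean_mass_fraction_all_cells_pct: float  # mean over all membrane cells


def cell_area_fraction(membrane_area_px: int, pha_areas_px: Sequence[int]) -> float:
    """Fraction of the cell cross-section occupied by PHA granules, clipped at 1."""
    if membrane_area_px < 1:
        raise ValueError("membrane_area_px must be >= 1 (degenerate cell)")
    if any(a < 0 for a in pha_areas_px):
        raise ValueError("granule areas must be >= 0")
    return min(1.0, sum(pha_areas_px) / membrane_area_px)


def area_to_volume_fraction(f: float) -> float:
    """Sphere-assumption conversion of an area fraction to a volume fraction.

    Both the cell and the aggregate PHA cross-section are treated as
    equatorial sections of spheres, V = (4/3)π(A/π)^{3/2}; the volume ratio
    then reduces to f^{3/2}.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"area fraction must lie in [0, 1], got {f}")
    return f ** 1.5


def volume_to_mass_fraction(v: float, params: ConversionParams = ConversionParams()) -> float:
    """Convert a volume fraction to a mass fraction via the density ratio.

    Mixture form: w = ρv / (ρv + (1 − v)); strictly increasing with
    w(0) = 0 and w(1) = 1.  The linear form w = ρ·v is available for
    sensitivity analysis.
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"volume fraction must lie in [0, 1], got {v}")
    rho = params.density_ratio
    if params.mass_model == "linear":
        return min(1.0, rho * v)
    return (rho * v) / (rho * v + (1.0 - v))


def _cell_volume_fraction(
    membrane_area_px: int, pha_areas_px: Sequence[int], params: ConversionParams
) -> float:
    if params.volume_model == "per_granule":
        v = sum(a ** 1.5 for a in pha_areas_px) / membrane_area_px ** 1.5
        return min(1.0, v)
    return area_to_volume_fraction(cell_area_fraction(membrane_area_px, pha_areas_px))


def count_cells_dna(dna_particles: ParticleSet) -> int:
    """Cell count from the DNA channel: each surviving particle is one cell."""
    return len(dna_particles)


def percent_cells_with_pha(n_cells_with_pha: int, dna_cell_count: int) -> float:
    """Percent of cells with detectable PHA, DNA-stain count as denominator.

    May exceed 100 when the membrane and DNA channels disagree; flagged with
    a warning rather than clipped.
    """
    if dna_cell_count < 1:
        raise ValueError("dna_cell_count must be >= 1")
    pct = 100.0 * n_cells_with_pha / dna_cell_count
    if pct > 100.0:
        warnings.warn(
            f"percent of cells with PHA exceeds 100% ({pct:.1f}%): "
            "membrane and DNA channels disagree",
            stacklevel=2,
        )
    return pct


def quantify_field(
    dna: ChannelImage,
    membrane: ChannelImage,
    pha: ChannelImage,
    config: QuantConfig = QuantConfig(),
) -> FieldResult:
    """Quantify one field of view: per-cell PHA fractions and cell counts.

    Deterministic for fixed inputs and configuration.
    """
    if not (dna.shape == membrane.shape == pha.shape):
        raise ValueError("the three channels must have identical dimensions")

    dna_parts = label_particles(bernsen_threshold(dna, config.dna.bernsen), config.dna.filter)
    mem_parts = label_particles(
        bernsen_threshold(membrane, config.membrane.bernsen), config.membrane.filter
    )
    pha_parts = label_particles(bernsen_threshold(pha, config.pha.bernsen), config.pha.filter)

    assignment = overlap_assign(pha_parts, mem_parts)
    pha_by_label = pha_parts.by_label()

    granules_per_cell: dict[int, list[int]] = {p.label: [] for p in mem_parts.particles}
    n_unassigned = 0
    for child_label, parent_label in assignment.items():
        if parent_label is None:
            n_unassigned += 1
        else:
            granules_per_cell[parent_label].append(child_label)

    conv = config.conversion
    cells: list[CellRecord] = []
    for mem_particle in mem_parts.particles:
        if mem_particle.area_px < 1:  # pragma: no cover - filtered upstream
            warnings.warn(f"dropping zero-area cell {mem_particle.label}", stacklevel=2)
            continue
        labels = tuple(sorted(granules_per_cell[mem_particle.label]))
        areas = [pha_by_label[lab].area_px for lab in labels]
        f = cell_area_fraction(mem_particle.area_px, areas)
        v = _cell_volume_fraction(mem_particle.area_px, areas, conv)
        w = volume_to_mass_fraction(v, conv)
        cells.append(
            CellRecord(
                cell_label=mem_particle.label,
                membrane_area_px=mem_particle.area_px,
                pha_particle_labels=labels,
                pha_area_px=int(sum(areas)),
                area_fraction=f,
                volume_fraction=v,
                mass_fraction=w,
            )
        )

    return FieldResult(
        cells=cells,
        dna_cell_count=count_cells_dna(dna_parts),
        n_membrane_cells=len(mem_parts),
        n_unassigned_pha=n_unassigned,
    )


def summarize_sample(fields: Sequence[FieldResult]) -> SampleSummary:
    """Pool cells over fields and report sample-level PHA statistics.

    ``percent_cells_with_pha`` uses pooled counts; the mean single-cell mass
    fraction is reported over PHA-positive cells (% m/m), with an all-cells
    mean alongside.
    """
    if len(fields) == 0:
        raise ValueError("need at least one field")
    dna_total = sum(fr.dna_cell_count for fr in fields)
    if dna_total == 0:
        raise ValueError("zero pooled DNA cell count")
    n_membrane = sum(fr.n_membrane_cells for fr in fields)
    n_with = sum(fr.n_cells_with_pha for fr in fields)
    w_pos = np.array(
        [c.mass_fraction for fr in fields for c in fr.cells if c.has_pha], dtype=float
    )
    w_all = np.array([c.mass_fraction for fr in fields for c in fr.cells], dtype=float)
    return SampleSummary(
        n_images=len(fields),
        dna_cell_count=dna_total,
        n_membrane_cells=n_membrane,
        n_cells_with_pha=n_with,
        percent_cells_with_pha=percent_cells_with_pha(n_with, dna_total),
        per_cell_mass_fractions=w_pos,
        mean_mass_fraction_pct=float(100.0 * w_pos.mean()) if w_pos.size else float("nan"),
        mean_mass_fraction_all_cells_pct=float(100.0 * w_all.mean()) if w_all.size else float("nan"),
    )
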
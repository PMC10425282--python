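"""Growth-cycle arithmetic for batch methanotroph enrichments.

Headspace CH₄ accounting via the ideal gas law, substrate consumption
fractions, carbon- and nitrogen-based cell yields, mean ± SD reporting, and
relative-abundance-normalized PHA content.  Defaults correspond to crimp-
sealed 160 mL serum bottles with 50 mL medium incubated at 30 °C and 1 atm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GrowthCycle",
    "YieldResult",
    "headspace_gas_mass_C",
    "consumption_fraction",
    "cell_yield",
    "yield_ratio",
    "mean_sd",
    "normalized_pha_content",
    "analyze_cycle",
    "GAS_CONSTANT_L_ATM",
    "MOLAR_MASS_C",
    "MOLAR_MASS_N",
]

GAS_CONSTANT_L_ATM = 0.082057  # L·atm·mol⁻¹·K⁻¹
MOLAR_MASS_C = 12.011  # g·mol⁻¹
MOLAR_MASS_N = 14.007  # g·mol⁻¹


@dataclass
class GrowthCycle:
    """Time series of one enrichment bottle over a growth cycle.

    times are hours; ch4_headspace_pct is headspace CH₄ in % v/v; nh4_mM is
    liquid-phase ammonium; cells_per_mL from flow cytometry.  Bottle
    geometry defaults: 160 mL serum bottle with 50 mL medium (110 mL
    headspace), 30 °C, 1 atm.
    """

    times: np.ndarray
    ch4_headspace_pct: np.ndarray
    nh4_mM: np.ndarray
    cells_per_mL: np.ndarray
    liquid_volume_mL: float = 50.0
    headspace_volume_mL: float = 110.0
    temperature_K: float = 303.15
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ch4_headspace_pct = np.asarray(self.ch4_headspace_pct, dtype=float)
        self.nh4_mM = np.asarray(self.nh4_mM, dtype=float)
        self.cells_per_mL = np.asarray(self.cells_per_mL, dtype=float)
        n = self.times.size
        if n == 0:
            raise ValueError("empty time series")
        for name in ("ch4_headspace_pct", "nh4_mM", "cells_per_mL"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if (
            np.any(self.ch4_headspace_pct < 0)
            or np.any(self.nh4_mM < 0)
            or np.any(self.cells_per_mL < 0)
        ):
            raise ValueError("concentrations must be >= 0")
        if min(self.liquid_volume_mL, self.headspace_volume_mL) <= 0:
            raise ValueError("volumes must be > 0")
        if self.temperature_K <= 0 or self.pressure_atm <= 0:
            raise ValueError("temperature and pressure must be > 0")


@dataclass(frozen=True)
class YieldResult:
    yield_C: float  # cells per g CH₄-C consumed
    yield_N: float  # cells per g NH₄⁺-N consumed
    ch4_consumed_fraction: float
    nh4_consumed_fraction: float


def headspace_gas_mass_C(pct: float, cycle: GrowthCycle) -> float:
    """Grams of CH₄-carbon in the headspace at the given % v/v.

    Ideal gas law: n = (pct/100)·P·V/(R·T); mass of carbon = n·12.011 g/mol.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError("pct must lie in [0, 100]")
    v_L = cycle.headspace_volume_mL / 1000.0
    n_mol = (pct / 100.0) * cycle.pressure_atm * v_L / (GAS_CONSTANT_L_ATM * cycle.temperature_K)
    return n_mol * MOLAR_MASS_C


def consumption_fraction(series: Sequence[float]) -> float:
    """(initial − final)/initial over a per-timepoint amount series.

    Negative apparent consumption (measurement fluctuation) is clipped to 0
    with a warning; values above 1 cannot occur for non-negative series.
    """
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    initial, final = s[0], s[-1]
    if initial <= 0:
        raise ValueError("initial amount must be > 0")
    frac = (initial - final) / initial
    if frac < 0:
        warnings.warn(
            f"negative apparent consumption ({frac:.3g}); clipping to 0", stacklevel=2
        )
        return 0.0
    return min(1.0, frac)


def cell_yield(delta_cells_total: float, substrate_consumed_g: float) -> float:
    """Cells gained per gram of substrate consumed over the cycle."""
    if substrate_consumed_g <= 0:
        raise ValueError("substrate_consumed_g must be > 0")
    return max(0.0, delta_cells_total) / substrate_consumed_g


def yield_ratio(a: float, b: float) -> float:
    """Ratio of two yields (dimensionless)."""
    if b == 0:
        raise ValueError("denominator yield must be nonzero")
    return a / b


def mean_sd(
    values: Sequence[float], mode: Literal["population", "sample"] = "population"
) -> tuple[float, float]:
    """Arithmetic mean and standard deviation.

    Population mode divides by n (default reporting mode here); sample mode
    divides by n − 1 and requires at least two values.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty list")
    if mode == "sample":
        if v.size < 2:
            raise ValueError("sample SD requires at least two values")
        return float(v.mean()), float(v.std(ddof=1))
    if mode != "population":
        raise ValueError(f"unknown mode {mode!r}")
    return float(v.mean()), float(v.std(ddof=0))


def normalized_pha_content(mean_pha_pct: float, methanotroph_rel_abundance_pct: float) -> float:
    """Community PHA content rescaled to the methanotroph population.

    Divides the whole-community mass percentage by the methanotrophs'
    relative abundance, giving the content the PHA-accumulating fraction
    alone would have.
    """
    if not 0.0 < methanotroph_rel_abundance_pct <= 100.0:
        raise ValueError("relative abundance must lie in (0, 100]")
    return 100.0 * mean_pha_pct / methanotroph_rel_abundance_pct


def analyze_cycle(cycle: GrowthCycle) -> YieldResult:
    """Consumption fractions and C/N cell yields for one growth cycle.

    CH₄ amounts come from headspace % via the ideal gas law; NH₄⁺-N from
    liquid molarity × volume; cell gains use total-bottle counts
    (cells·mL⁻¹ × liquid volume).
    """
    g_C = np.array([headspace_gas_mass_C(p, cycle) for p in cycle.ch4_headspace_pct])
    g_N = cycle.nh4_mM * 1e-3 * (cycle.liquid_volume_mL / 1000.0) * MOLAR_MASS_N
    ch4_frac = consumption_fraction(g_C)
    nh4_frac = consumption_fraction(g_N)
    delta_cells = (cycle.cells_per_mL[-1] - cycle.cells_per_mL[0]) * cycle.liquid_volume_mL
    c_consumed = g_C[0] - g_C[-1]
    n_consumed = g_N[0] - g_N[-1]
    y_C = cell_yield(delta_cells, c_consumed) if c_consumed > 0 else float("nan")
    y_N = cell_yield(delta_cells, n_consumed) if n_consumed > 0 else float("nan")
    return YieldResult(
        yield_C=y_C, yield_N=y_N, ch4_consumed_fraction=ch4_frac, nh4_consumed_fraction=nh4_frac
    )
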
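"""Growth rates, replicate summaries, yields and carbon balances.

Operates on :class:`ProcessTimeSeries` objects, the package's container for
one batch cultivation: timestamped concentrations of cell dry mass (CDM),
glucose and organic-acid by-products plus the off-gas CO2 carbon evolution
rate.  All functions return full-precision values; rounding to the 2-decimal
convention of process reports happens only in the reporting layer
(:func:`fermscope.pipeline` and the CLI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import elements
from .elements import ElementalComposition, carbon_fraction
from .errors import DomainError, InsufficientDataError, MissingDataError

#: Canonical column order of the process TSV dialect.
PROCESS_COLUMNS = [
    "time_h",
    "cdm_g_per_L",
    "glucose_g_per_L",
    "acetate_g_per_L",
    "formate_g_per_L",
    "pyruvate_g_per_L",
    "lactate_g_per_L",
    "co2_rate_gC_per_L_h",
]

_CONC_COLUMNS = PROCESS_COLUMNS[1:7]


@dataclass
class ProcessTimeSeries:
    """One cultivation's measured (or simulated) trajectory.

    Parameters
    ----------
    data
        Frame with the :data:`PROCESS_COLUMNS` columns.  ``time_h`` must be
        strictly increasing and concentrations non-negative.
    volume
        Batch working volume in litres (4 L reactor scale by default).
    co2_cumulative
        If True the CO2 column holds cumulative g C/L instead of a rate.
    """

    data: pd.DataFrame
    volume: float = 4.0
    co2_cumulative: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in PROCESS_COLUMNS[:-1] if c not in self.data.columns]
        if missing:
            raise MissingDataError(f"missing columns: {missing}")
        t = self.data["time_h"].to_numpy(float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise DomainError("time_h must be strictly increasing")
        conc = self.data[_CONC_COLUMNS].to_numpy(float)
        if np.any(conc < 0):
            raise DomainError("concentrations must be non-negative")
        if self.volume <= 0:
            raise DomainError("volume must be positive")

    # Convenience accessors -------------------------------------------------
    @property
    def time(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(float)

    @property
    def cdm(self) -> np.ndarray:
        return self.data["cdm_g_per_L"].to_numpy(float)

    def concentration(self, pool: str) -> np.ndarray:
        return self.data[f"{pool}_g_per_L"].to_numpy(float)

    # I/O -------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, volume: float = 4.0, co2_cumulative: bool = False) -> "ProcessTimeSeries":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame, volume=volume, co2_cumulative=co2_cumulative)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and standard error of the mean over replicate cultivations."""

    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class GrowthRateFit:
    """Log-linear growth-rate estimate with its OLS standard error."""

    rate: float
    stderr: float
    n: int
    window: tuple[float, float]


@dataclass(frozen=True)
class YieldResult:
    """Raw and by-product-corrected substrate yield coefficients, g CDM / g glucose."""

    yxs_raw: float
    yxs_corrected: float
    glucose_equivalent_of_byproduct: float
    available_substrate: float


@dataclass
class CarbonBalance:
    """Per-pool carbon masses (g) and percentages of the total input carbon."""

    pools_g: dict[str, float]
    total_input_carbon: float
    percentages: dict[str, float] = field(init=False)
    recovery: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total_input_carbon <= 0:
            raise DomainError("total input carbon must be positive")
        self.percentages = {
            k: 100.0 * v / self.total_input_carbon for k, v in self.pools_g.items()
        }
        self.recovery = float(sum(self.percentages.values()))


def fit_growth_rate(
    series: ProcessTimeSeries,
    window: tuple[float, float] | None = None,
) -> GrowthRateFit:
    """Specific growth rate from an OLS fit of ln(CDM) on time.

    ``window`` restricts the fit to ``t0 <= time <= t1`` (typically the
    exponential phase); by default all samples are used.  Requires at least
    three points with positive CDM inside the window.
    """
    t = series.time
    x = series.cdm
    if window is not None:
        t0, t1 = window
        mask = (t >= t0) & (t <= t1)
    else:
        mask = np.ones_like(t, dtype=bool)
    t, x = t[mask], x[mask]
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 samples in window for rate fit")
    if np.any(x <= 0):
        raise DomainError("CDM must be positive inside the fit window")
    res = stats.linregress(t, np.log(x))
    return GrowthRateFit(
        rate=float(res.slope),
        stderr=float(res.stderr),
        n=len(t),
        window=(float(t[0]), float(t[-1])),
    )


def average_growth_rate(series: ProcessTimeSeries) -> float:
    """Endpoint 'average' rate ln(x_end / x_start) / (t_end - t_start).

    The whole-batch average reported alongside the log-linear fit; both are
    exposed because 'average growth rate' is ambiguous between them.
    """
    t, x = series.time, series.cdm
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 samples")
    if x[0] <= 0 or x[-1] <= 0:
        raise DomainError("CDM must be positive at the endpoints")
    return float(math.log(x[-1] / x[0]) / (t[-1] - t[0]))


def summarize_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Mean and SEM (sample sd / sqrt(n)) over replicate measurements."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("no replicate values")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size >= 2 else 0.0
    return ReplicateSummary(mean=mean, sem=sem, n=int(vals.size))


def glucose_equivalent(acetate_mass: float) -> float:
    """Glucose mass diverted to a given acetate mass.

    Homoacetate stoichiometry (1 glucose -> 2 acetate) gives a molar-mass
    factor M_glc / (2 M_ac) ~= 1.5, so 6 g acetate correspond to ~9 g glucose.
    """
    if acetate_mass < 0:
        raise DomainError("acetate mass must be non-negative")
    return acetate_mass * elements.GLUCOSE_PER_ACETATE


def yield_coefficients(
    final_cdm: float, substrate0: float, byproduct_acetate: float
) -> YieldResult:
    """Raw and acetate-corrected substrate yield coefficients.

    The corrected yield divides by the substrate actually available for
    biomass formation, i.e. the initial glucose minus the glucose equivalent
    of the accumulated acetate.
    """
    if substrate0 <= 0:
        raise DomainError("initial substrate must be positive")
    equiv = glucose_equivalent(byproduct_acetate)
    available = substrate0 - equiv
    if available <= 0:
        raise DomainError("by-product exceeds the available substrate")
    return YieldResult(
        yxs_raw=final_cdm / substrate0,
        yxs_corrected=final_cdm / available,
        glucose_equivalent_of_byproduct=equiv,
        available_substrate=available,
    )


def integrate_offgas(series: ProcessTimeSeries) -> float:
    """Cumulative CO2 carbon in g over the whole run, scaled by volume.

    Trapezoidal integration of the off-gas carbon evolution rate; if the
    series carries a cumulative column the last value is used directly.
    """
    col = "co2_rate_gC_per_L_h"
    if col not in series.data.columns or series.data[col].isna().all():
        raise MissingDataError("no CO2 off-gas channel")
    vals = series.data[col].to_numpy(float)
    if len(vals) == 0:
        raise MissingDataError("empty CO2 off-gas channel")
    if series.co2_cumulative:
        per_litre = float(vals[-1])
    else:
        per_litre = float(np.trapezoid(vals, series.time))
    return max(per_litre, 0.0) * series.volume


def carbon_balance(
    series: ProcessTimeSeries,
    total_input_carbon: float,
    compositions: Mapping[str, ElementalComposition] = elements.POOL_COMPOSITIONS,
) -> CarbonBalance:
    """End-of-run carbon balance over biomass, by-product and CO2 pools.

    Each dissolved pool contributes ``end concentration x volume x carbon
    fraction`` grams of carbon; the CO2 pool comes from
    :func:`integrate_offgas`.  ``total_input_carbon`` is a caller input (g):
    the balance denominator depends on the consumed glucose and any
    complex-media carbon, which are not derivable from the series itself.
    """
    if total_input_carbon <= 0:
        raise DomainError("total input carbon must be positive")
    pools: dict[str, float] = {}
    end = series.data.iloc[-1]
    pools["biomass"] = (
        float(end["cdm_g_per_L"]) * series.volume * carbon_fraction(compositions["biomass"])
    )
    for pool in ("acetate", "formate", "pyruvate", "lactate"):
        pools[pool] = (
            float(end[f"{pool}_g_per_L"])
            * series.volume
            * carbon_fraction(compositions[pool])
        )
    pools["co2"] = integrate_offgas(series)
    return CarbonBalance(pools_g=pools, total_input_carbon=total_input_carbon)
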
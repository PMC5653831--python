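"""Abiotic aragonite precipitation kinetics and the seasonal rate scenarios.

The internal-pH-regulation abiotic calcification (IpHRAC) picture treats the
coral skeleton as inorganic aragonite precipitating from the calcifying fluid
at the empirical rate

    G = k(T) · (Ω_cf − 1)^n(T)        [µmol m⁻² h⁻¹]

with temperature-dependent rate constant k and reaction order n from abiotic
seawater precipitation experiments.  Because measured coral calcification is
in different units (mg cm⁻² d⁻¹) and the absolute scale of k is uncertain,
all model/data comparisons are made on the percent-of-mean scale, where each
series is normalised to its own mean (≡ 100 %).

Three seasonal scenarios are compared against measured rates:

1. temperature and Ω_cf both vary with season (full proxy reconstruction);
2. temperature and DIC_cf vary with season but pH_cf follows the muted
   aquaria response to seawater pH (pH_cf = 0.51·pH_sw + 4.28), with Ω_cf
   recomputed from that pH and the seasonal DIC_cf;
3. Ω_cf varies with season but temperature is held at its annual average
   (21.7 °C), removing the kinetic temperature response entirely.

Fit quality is the RMSE between modelled and measured percent-of-mean series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    DomainError,
    SeawaterConditions,
    co3_from_ph_dic,
    constants_for,
)
from .boron import omega as omega_of

__all__ = [
    "KineticParams",
    "ScenarioResult",
    "kinetic_params",
    "precip_rate",
    "aquaria_phcf",
    "percent_of_mean",
    "rmse_percent",
    "scenario_series",
]

#: anchor points of the abiotic aragonite calibration: T °C, k µmol m-2 h-1, n
_ANCHOR_T = np.array([5.0, 25.0, 37.0])
_ANCHOR_K = np.array([21.8, 45.2, 64.9])
_ANCHOR_N = np.array([0.9, 1.9, 2.4])

# smooth default scheme: n linear in T, ln k linear in 1/T (Arrhenius)
_N_SLOPE, _N_INTERCEPT = np.polyfit(_ANCHOR_T, _ANCHOR_N, 1)
_ARR_B, _ARR_A = np.polyfit(1.0 / (_ANCHOR_T + 273.15), np.log(_ANCHOR_K), 1)

#: published annual-average temperature used by scenario 3
DEFAULT_FIXED_T = 21.7

#: aquaria pH_cf response to seawater pH: slope, intercept
DEFAULT_AQUARIA = (0.51, 4.28)


@dataclass(frozen=True)
class KineticParams:
    """Rate constant k (µmol m⁻² h⁻¹) and reaction order n at temperature T."""

    k: float
    n: float
    T: float  # °C
    parameterisation: str = "arrhenius"

    def __post_init__(self) -> None:
        if self.k <= 0 or self.n <= 0:
            raise DomainError("k and n must be positive")


@dataclass(frozen=True)
class ScenarioResult:
    """Modelled precipitation for one scenario, aligned to measured rates."""

    scenario: int
    periods: tuple
    G: np.ndarray  # µmol m-2 h-1
    percent_of_mean: np.ndarray  # %
    rmse_vs_measured: float  # % (percent-of-mean scale)
    dissolution: np.ndarray  # per-period Ω<1 flags
    provenance: dict = field(default_factory=dict, compare=False)


def kinetic_params(T: float, parameterisation: str = "arrhenius") -> KineticParams:
    """Temperature-dependent kinetic constants k(T), n(T).

    ``arrhenius`` (default): n linear in T, ln k linear in 1/T, both fit
    through the abiotic aragonite anchor points (5, 25, 37 °C).  ``linear``:
    piecewise-linear interpolation of the same anchors.  Both are continuous
    in T; valid for T in [5, 40] °C.
    """
    if not 5.0 <= T <= 40.0:
        raise DomainError(f"temperature {T} °C outside [5, 40]")
    if parameterisation == "arrhenius":
        n = _N_SLOPE * T + _N_INTERCEPT
        k = math.exp(_ARR_A + _ARR_B / (T + 273.15))
    elif parameterisation == "linear":
        n = float(np.interp(T, _ANCHOR_T, _ANCHOR_N))
        k = float(np.interp(T, _ANCHOR_T, _ANCHOR_K))
    else:
        raise ValueError(f"unknown parameterisation {parameterisation!r}")
    return KineticParams(k=float(k), n=float(n), T=T, parameterisation=parameterisation)


def precip_rate(
    omega_cf: float, T: float, params: KineticParams | None = None
) -> tuple[float, bool]:
    """Aragonite precipitation rate G = k(Ω−1)ⁿ, µmol m⁻² h⁻¹.

    Undersaturated fluid (Ω < 1) returns G = 0 with the dissolution flag
    set: the power law is undefined for a negative base with fractional n,
    and no dissolution kinetics are modelled.

    Returns ``(G, dissolution_flag)``.
    """
    if params is None:
        params = kinetic_params(T)
    if omega_cf < 1.0:
        return 0.0, True
    return params.k * (omega_cf - 1.0) ** params.n, False


def aquaria_phcf(pH_sw: float, slope: float = DEFAULT_AQUARIA[0],
                 intercept: float = DEFAULT_AQUARIA[1]) -> float:
    """Calcifying-fluid pH inferred from seawater pH via the muted linear
    response observed in fixed-condition aquaria: pH_cf = 0.51·pH_sw + 4.28."""
    if not 7.0 <= pH_sw <= 9.0:
        raise DomainError(f"pH_sw {pH_sw} outside [7, 9]")
    return slope * pH_sw + intercept


def percent_of_mean(series: Sequence[float]) -> np.ndarray:
    """Normalise a positive series to its own mean (mean ≡ 100 %)."""
    x = np.asarray(series, dtype=float)
    m = x.mean()
    if m <= 0:
        raise DomainError("series mean must be positive")
    return 100.0 * x / m


def rmse_percent(modelled_pct: Sequence[float], measured_pct: Sequence[float]) -> float:
    """Root-mean-square difference between two percent-of-mean series."""
    a = np.asarray(modelled_pct, dtype=float)
    b = np.asarray(measured_pct, dtype=float)
    if a.shape != b.shape:
        raise DomainError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _check_alignment(*frames: pd.DataFrame | pd.Series) -> pd.Index:
    ref = frames[0].index
    for f in frames[1:]:
        missing = ref.symmetric_difference(f.index)
        if len(missing):
            raise DomainError(
                f"misaligned periods: {sorted(map(str, missing))}"
            )
    return ref


def scenario_series(
    cf: pd.DataFrame,
    env: pd.DataFrame,
    measured: pd.Series,
    scenario: int,
    *,
    fixed_T: float = DEFAULT_FIXED_T,
    aquaria: tuple[float, float] = DEFAULT_AQUARIA,
    parameterisation: str = "arrhenius",
    k1k2: str = "lueker2000",
    boron: str = "uppstrom",
) -> ScenarioResult:
    """Run one seasonal calcification scenario against measured rates.

    Parameters
    ----------
    cf : DataFrame indexed by period with columns ``omega_cf`` and
        ``dic_cf`` (proxy-reconstructed period means).
    env : DataFrame indexed by period with columns ``temperature``,
        ``salinity`` and ``pH_sw`` (period-mean ambient state).
    measured : Series of measured calcification rates (any positive unit;
        only its percent-of-mean shape enters the comparison).
    scenario : 1, 2 or 3 (see module docstring).
    """
    if scenario not in (1, 2, 3):
        raise ValueError("scenario must be 1, 2 or 3")
    idx = _check_alignment(cf, env, measured)

    G = np.empty(len(idx))
    diss = np.zeros(len(idx), dtype=bool)
    for i, period in enumerate(idx):
        T_amb = float(env.loc[period, "temperature"])
        if scenario == 1:
            om, T_kin = float(cf.loc[period, "omega_cf"]), T_amb
        elif scenario == 2:
            cond = SeawaterConditions(T_amb, float(env.loc[period, "salinity"]))
            consts = constants_for(cond, k1k2=k1k2, boron=boron)
            ph2 = aquaria_phcf(float(env.loc[period, "pH_sw"]), *aquaria)
            co3 = co3_from_ph_dic(ph2, float(cf.loc[period, "dic_cf"]), consts)
            om, T_kin = omega_of(co3, consts.Ca, consts.Ksp_arag), T_amb
        else:  # scenario 3: seasonal Ω, constant annual-mean temperature
            om, T_kin = float(cf.loc[period, "omega_cf"]), fixed_T
        G[i], diss[i] = precip_rate(om, T_kin, kinetic_params(T_kin, parameterisation))

    pct = percent_of_mean(G)
    rmse = rmse_percent(pct, percent_of_mean(measured.to_numpy()))
    return ScenarioResult(
        scenario=scenario,
        periods=tuple(idx),
        G=G,
        percent_of_mean=pct,
        rmse_vs_measured=rmse,
        dissolution=diss,
        provenance={
            "parameterisation": parameterisation,
            "fixed_T": fixed_T if scenario == 3 else None,
            "aquaria": aquaria if scenario == 2 else None,
        },
    )
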
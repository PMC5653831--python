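"""Synthetic seasonal coral-geochemistry studies with known ground truth.

The generator emulates the statistical structure of a sub-tropical reef
monitoring study: a sinusoidal seasonal environment (temperature between
monthly-mean extremes of 19.3 and 23.7 °C peaking in February, light 15–48
mol m⁻² d⁻¹ in phase, near-constant seawater pH 8.03–8.10), a prescribed
counter-cyclical calcifying-fluid regulation (pH_cf high in winter, DIC_cf
high in summer), forward-modelled skeletal geochemistry for a handful of
colonies with analytical and between-colony noise, and buoyant-weight style
calcification-rate observations driven by the temperature-independent
kinetics scenario.

Carbonate-ion concentration and aragonite saturation state of the truth are
always *derived* from the prescribed pH_cf and DIC_cf through the same
equilibrium-constant module the analysis pipeline uses — they are never set
freely, so every synthetic study is internally consistent and exactly
recoverable at zero noise.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import boron, kinetics
from .constants import (
    DomainError,
    SeawaterConditions,
    co3_from_ph_dic,
    constants_for,
)
from .records import SPECIES
from .thermometry import DEFAULT_CALIBRATIONS

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "gen_environment",
    "gen_cf_cycles",
    "forward_geochem",
    "gen_calcification",
    "generate_study",
    "noise_sigma_for_r2",
]

#: length of the monthly averaging window, days (phase-mean damping)
_MONTH_DAYS = 30.44
_YEAR_DAYS = 365.25
#: day-of-year of the austral temperature maximum (mid-February)
_PEAK_DOY = 46


def _monthly_mean_damping() -> float:
    """Amplitude attenuation of a one-month boxcar mean of an annual sinusoid."""
    x = np.pi * _MONTH_DAYS / _YEAR_DAYS
    return float(np.sin(x) / x)


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the synthetic generator.

    Defaults are the published seasonal extremes of the Rottnest Island
    system; noise magnitudes are tuned once so that the emergent
    calibration r² levels sit near the observed ones (≈0.8 for Li/Mg–T,
    ≈0.4 for DIC_cf–T).
    """

    seed: int  # mandatory; no default randomness
    species: str = "A_yongei"
    T_min: float = 19.3  # °C, monthly-mean winter minimum
    T_max: float = 23.7  # °C, monthly-mean summer maximum
    PAR_min: float = 15.0  # mol m-2 d-1
    PAR_max: float = 48.0
    pHsw_min: float = 8.03
    pHsw_max: float = 8.10
    pHcf_summer: float = 8.38
    pHcf_winter: float = 8.60
    DICcf_summer: float = 4520.0  # µmol/kg
    DICcf_winter: float = 3620.0
    salinity: float = 35.5
    n_colonies: int = 4
    n_periods: int = 10
    period_days: int = 45
    start: _dt.date = _dt.date(2013, 2, 1)
    base_rate: float = 1.6  # mg cm-2 d-1, long-term mean calcification
    rate_n: int = 16  # colonies in the buoyant-weight record
    # observation noise (per colony per period, Gaussian sd)
    sigma_d11B: float = 0.15  # ‰
    sigma_BCa: float = 0.012  # mmol/mol
    sigma_LiMg: float = 0.058  # mmol/mol
    sigma_SrCa: float = 0.053  # mmol/mol
    sigma_rate_pct: float = 8.0  # % of the base rate
    # between-colony offsets (constant per colony, Gaussian sd)
    colony_sigma_d11B: float = 0.10
    colony_sigma_BCa: float = 0.008
    # period-scale regulation noise on the true cycles: a DIC supply anomaly
    # partially compensated by pH (the counter-regulation mechanism), plus an
    # independent pH residual
    sigma_DIC_period: float = 450.0  # µmol/kg
    pH_compensation: float = 0.5  # fraction of the seasonal dpH/dDIC slope
    sigma_pHcf_period: float = 0.015
    counter_cyclical: bool = True

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DomainError(f"species {self.species!r} not one of {SPECIES}")
        if self.T_min >= self.T_max:
            raise DomainError("T_min must be below T_max")
        if self.counter_cyclical:
            if not (self.pHcf_winter > self.pHcf_summer
                    and self.DICcf_summer > self.DICcf_winter):
                raise DomainError(
                    "counter-cyclical regulation requires winter pH_cf > "
                    "summer pH_cf and summer DIC_cf > winter DIC_cf"
                )
        for name in ("sigma_d11B", "sigma_BCa", "sigma_LiMg", "sigma_SrCa",
                     "sigma_rate_pct", "colony_sigma_d11B", "colony_sigma_BCa",
                     "sigma_pHcf_period", "sigma_DIC_period"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.base_rate <= 0:
            raise DomainError("base_rate must be positive")

    def zero_noise(self) -> "GeneratorParams":
        """A copy with every noise term switched off (exact-recovery tests)."""
        return replace(
            self,
            sigma_d11B=0.0, sigma_BCa=0.0, sigma_LiMg=0.0, sigma_SrCa=0.0,
            sigma_rate_pct=0.0, colony_sigma_d11B=0.0, colony_sigma_BCa=0.0,
            sigma_pHcf_period=0.0, sigma_DIC_period=0.0,
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth per-period calcifying-fluid state behind one study."""

    periods: tuple[str, ...]
    dates: tuple[_dt.date, ...]
    temperature: np.ndarray  # period-mean °C
    pH_cf: np.ndarray
    dic_cf: np.ndarray  # µmol/kg
    co3_cf: np.ndarray  # µmol/kg, derived
    omega_cf: np.ndarray  # derived
    salinity: float
    calibrations: dict = field(default_factory=dict, compare=False)
    seed: int = 0


def _annual_cycle(dates: pd.DatetimeIndex, lo: float, hi: float,
                  inflate: float = 1.0) -> np.ndarray:
    """Sinusoid peaking mid-February, between lo and hi (optionally inflated
    about the midpoint so one-month means span exactly [lo, hi])."""
    mid, amp = 0.5 * (hi + lo), 0.5 * (hi - lo) * inflate
    phase = 2.0 * np.pi * (dates.dayofyear.to_numpy() - _PEAK_DOY) / _YEAR_DAYS
    return mid + amp * np.cos(phase)


def gen_environment(params: GeneratorParams) -> pd.DataFrame:
    """Daily environmental series over the study span.

    Temperature extremes are monthly-mean facts, so the daily sinusoid is
    inflated by the one-month averaging factor to make calendar-month means
    span [T_min, T_max]; PAR and pH_sw extremes bound the daily series
    directly.  Deterministic given the parameters.
    """
    n_days = params.n_periods * params.period_days
    dates = pd.date_range(params.start, periods=n_days, freq="D")
    inflate = 1.0 / _monthly_mean_damping()
    return pd.DataFrame(
        {
            "date": dates,
            "temperature": _annual_cycle(dates, params.T_min, params.T_max, inflate),
            "salinity": params.salinity,
            "pH_sw": _annual_cycle(dates, params.pHsw_min, params.pHsw_max),
            "PAR": _annual_cycle(dates, params.PAR_min, params.PAR_max),
        }
    )


def _period_windows(params: GeneratorParams, env: pd.DataFrame):
    """Collection periods: labels, midpoint dates and period-mean
    temperatures computed through the same growth-window convention the
    analysis pipeline applies (so a zero-noise study round-trips exactly)."""
    from .pipeline import env_period_means

    labels, dates = [], []
    for i in range(params.n_periods):
        chunk = env.iloc[i * params.period_days:(i + 1) * params.period_days]
        labels.append(f"P{i + 1:02d}")
        dates.append(chunk["date"].iloc[len(chunk) // 2].date())
    env_p = env_period_means(env, dict(zip(labels, dates)))
    temps = env_p.loc[labels, "temperature"].to_numpy(dtype=float)
    return labels, dates, temps


def gen_cf_cycles(
    params: GeneratorParams, env: pd.DataFrame, rng: np.random.Generator | None = None
) -> SyntheticTruth:
    """Prescribe the true calcifying-fluid cycles and derive CO₃/Ω.

    pH_cf is anti-phased with temperature (winter maximum) and DIC_cf
    in-phase (summer maximum), each linear in the period-mean temperature
    between the configured seasonal endpoints.  Period-scale regulation
    noise enters as a DIC supply anomaly that pH partially compensates
    along the seasonal dpH/dDIC slope (``pH_compensation`` is the
    compensated fraction) — deviations therefore move the fluid largely
    *along* the counter-regulation line, which is what keeps Ω_cf
    seasonality intact while leaving DIC_cf only weakly coupled to
    temperature, as observed.  An independent Gaussian pH residual is
    added on top.  [CO₃²⁻]_cf and Ω_cf are then derived through the
    carbonate-system constants at ambient (T, S) — never set freely.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    labels, dates, temps = _period_windows(params, env)
    frac = (temps - params.T_min) / (params.T_max - params.T_min)
    frac = np.clip(frac, 0.0, 1.0)
    ph = params.pHcf_winter + (params.pHcf_summer - params.pHcf_winter) * frac
    dic = params.DICcf_winter + (params.DICcf_summer - params.DICcf_winter) * frac
    # seasonal counter-regulation slope, pH units per µmol/kg (< 0);
    # degenerate (flat-DIC) configurations have no line to compensate along
    ddic = params.DICcf_summer - params.DICcf_winter
    dph_ddic = (params.pHcf_summer - params.pHcf_winter) / ddic if ddic else 0.0
    supply = rng.normal(0.0, params.sigma_DIC_period, size=dic.shape)
    dic = np.maximum(dic + supply, 500.0)
    ph = (
        ph
        + params.pH_compensation * dph_ddic * supply
        + rng.normal(0.0, params.sigma_pHcf_period, size=ph.shape)
    )

    co3 = np.empty_like(dic)
    om = np.empty_like(dic)
    for i, T in enumerate(temps):
        consts = constants_for(SeawaterConditions(float(T), params.salinity))
        co3[i] = co3_from_ph_dic(float(ph[i]), float(dic[i]), consts)
        om[i] = boron.omega(co3[i], consts.Ca, consts.Ksp_arag)

    cals = {
        "Li/Mg": DEFAULT_CALIBRATIONS[(params.species, "Li/Mg")],
        "Sr/Ca": DEFAULT_CALIBRATIONS[(params.species, "Sr/Ca")],
    }
    return SyntheticTruth(
        periods=tuple(labels), dates=tuple(dates), temperature=temps,
        pH_cf=ph, dic_cf=dic, co3_cf=co3, omega_cf=om,
        salinity=params.salinity, calibrations=cals, seed=params.seed,
    )


def forward_geochem(
    truth: SyntheticTruth,
    env: pd.DataFrame,
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-model skeletal geochemistry per colony per period.

    δ¹¹B is the exact inverse of the pH proxy at the true pH_cf; B/Ca is the
    exact inversion of the distribution-coefficient relation at the true
    [CO₃²⁻]_cf; Li/Mg and Sr/Ca follow the species' calibration lines at
    period-mean temperature.  Independent Gaussian noise per observable per
    colony, plus constant per-colony offsets on the boron observables.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    colony_ids = [f"C{j + 1}" for j in range(params.n_colonies)]
    off_d11b = rng.normal(0.0, params.colony_sigma_d11B, params.n_colonies)
    off_bca = rng.normal(0.0, params.colony_sigma_BCa, params.n_colonies)
    limg_sl, limg_ic = truth.calibrations["Li/Mg"]
    srca_sl, srca_ic = truth.calibrations["Sr/Ca"]

    rows = []
    for i, period in enumerate(truth.periods):
        consts = constants_for(
            SeawaterConditions(float(truth.temperature[i]), truth.salinity)
        )
        d11b_true = boron.d11b_from_ph(float(truth.pH_cf[i]), consts.pK_B)
        h_nmol = 10.0 ** (-truth.pH_cf[i]) * 1e9
        borate = boron.borate_cf(float(truth.pH_cf[i]), consts.B_T, consts.pK_B)
        bca_true = boron.bca_from_co3(
            float(truth.co3_cf[i]), borate, boron.kd_boron(float(h_nmol))
        )
        T = float(truth.temperature[i])
        for j, colony in enumerate(colony_ids):
            rows.append(
                {
                    "species": params.species,
                    "colony": colony,
                    "period": period,
                    "date": truth.dates[i].isoformat(),
                    "d11B": d11b_true + off_d11b[j]
                    + rng.normal(0.0, params.sigma_d11B),
                    "BCa": max(
                        bca_true + off_bca[j] + rng.normal(0.0, params.sigma_BCa),
                        0.05,
                    ),
                    "LiMg": limg_sl * T + limg_ic + rng.normal(0.0, params.sigma_LiMg),
                    "SrCa": srca_sl * T + srca_ic + rng.normal(0.0, params.sigma_SrCa),
                }
            )
    return pd.DataFrame(rows)


def gen_calcification(
    truth: SyntheticTruth,
    env: pd.DataFrame,
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Measured-rate table generated from the temperature-independent
    kinetics scenario.

    Per-period rate = base_rate × percent-of-mean of G(Ω_true, T̄ const) plus
    Gaussian observation noise; emitted in the same schema as a transcribed
    calcification-rate table (mean, SE, n per period).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    G = np.array(
        [kinetics.precip_rate(float(om), kinetics.DEFAULT_FIXED_T)[0]
         for om in truth.omega_cf]
    )
    pct = kinetics.percent_of_mean(G)
    sigma = params.base_rate * params.sigma_rate_pct / 100.0
    rates = params.base_rate * pct / 100.0 + rng.normal(0.0, sigma, size=pct.shape)
    rates = np.maximum(rates, 0.01)
    return pd.DataFrame(
        {
            "species": params.species,
            "period": truth.periods,
            "date": [d.isoformat() for d in truth.dates],
            "rate": rates,
            "se": sigma / np.sqrt(params.rate_n),
            "n": params.rate_n,
        }
    )


def generate_study(
    params: GeneratorParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a complete synthetic study: (samples, environment, rates, truth).

    All randomness flows from ``params.seed``; identical parameters give
    byte-identical tables.
    """
    rng = np.random.default_rng(params.seed)
    env = gen_environment(params)
    truth = gen_cf_cycles(params, env, rng)
    samples = forward_geochem(truth, env, params, rng)
    rates = gen_calcification(truth, env, params, rng)
    return samples, env, rates, truth


def noise_sigma_for_r2(slope: float, var_x: float, r2: float) -> float:
    """Gaussian noise sd giving population r² for a linear signal.

    With signal variance slope²·var_x, r² = signal/(signal+noise), so
    σ = |slope|·√(var_x·(1−r²)/r²).
    """
    if not 0.0 < r2 < 1.0:
        raise DomainError("r2 must lie strictly between 0 and 1")
    return abs(slope) * float(np.sqrt(var_x * (1.0 - r2) / r2))
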
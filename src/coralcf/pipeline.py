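"""End-to-end seasonal analysis pipeline.

Reads the three long-format CSV inputs (skeletal geochemistry per colony per
collection period, daily environmental series, measured calcification
rates), runs the boron proxy chain per colony, aggregates to period means ±
SE, computes seasonal statistics and cross-correlations, runs the
trace-element chronology check and the three kinetics scenarios, and emits
tidy CSV/JSON outputs.

Reconstruction is done per colony and aggregated afterwards — the proxy
chain is nonlinear, so aggregating δ¹¹B first and reconstructing the mean
would not give the mean of the reconstructions.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import boron as _boron
from . import kinetics as _kinetics
from .config import DEFAULTS, load_config
from .constants import DomainError
from .records import EnvRecord, SkeletalSample
from .thermometry import chronology_check

__all__ = [
    "InputError",
    "read_inputs",
    "assign_season",
    "aggregate_colonies",
    "seasonal_stats",
    "correlate",
    "run",
]

log = logging.getLogger("coralcf")

#: variables carried through aggregation and seasonal statistics
CF_VARIABLES = ("d11B", "BCa", "pH_cf", "dic_cf", "co3_cf", "omega_cf")

_GEOCHEM_MANDATORY = ("species", "colony", "period", "date")
_ENV_MANDATORY = ("date", "temperature", "pH_sw")
_RATES_MANDATORY = ("species", "period", "date", "rate")


class InputError(ValueError):
    """Invalid or unparseable pipeline input."""


def _require_columns(df: pd.DataFrame, mandatory: Sequence[str], what: str) -> None:
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise InputError(f"{what}: missing mandatory column(s) {missing}")


def _parse_date(value, row: int, errors: list[str]) -> _dt.date | None:
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError:
        errors.append(f"row {row}: unparseable ISO-8601 date {value!r}")
        return None


def read_inputs(
    geochem_path: str | Path | None = None,
    env_path: str | Path | None = None,
    rates_path: str | Path | None = None,
    config: dict | None = None,
) -> tuple[list[SkeletalSample], pd.DataFrame | None, pd.DataFrame | None]:
    """Read and validate the pipeline's CSV inputs.

    Row-level failures are collected and reported together with line
    numbers (header = line 1).  Missing optional environment columns
    (salinity, PAR) are filled from the configuration defaults.
    """
    cfg = config or load_config()
    samples: list[SkeletalSample] = []
    env = rates = None
    errors: list[str] = []

    if geochem_path is not None:
        df = pd.read_csv(geochem_path)
        if df.empty:
            raise InputError(f"{geochem_path}: no records")
        _require_columns(df, _GEOCHEM_MANDATORY, str(geochem_path))
        for i, row in df.iterrows():
            line = i + 2  # header line + 1-based
            date = _parse_date(row["date"], line, errors)
            if date is None:
                continue
            try:
                samples.append(
                    SkeletalSample(
                        species=str(row["species"]),
                        colony=str(row["colony"]),
                        period=str(row["period"]),
                        date=date,
                        **{
                            k: (float(row[k]) if k in df.columns
                                and pd.notna(row[k]) else None)
                            for k in ("d11B", "BCa", "LiMg", "SrCa")
                        },
                    )
                )
            except (DomainError, ValueError) as err:
                errors.append(f"row {line}: {err}")
        if errors:
            raise InputError(
                f"{geochem_path}: {len(errors)} invalid row(s):\n  "
                + "\n  ".join(errors)
            )

    if env_path is not None:
        env = pd.read_csv(env_path)
        if env.empty:
            raise InputError(f"{env_path}: no records")
        _require_columns(env, _ENV_MANDATORY, str(env_path))
        env["date"] = pd.to_datetime(env["date"])
        if "salinity" not in env.columns:
            default_s = cfg["seawater"]["default_salinity"]
            log.warning("environment table lacks salinity; using default %s", default_s)
            env["salinity"] = default_s
        if "PAR" not in env.columns:
            env["PAR"] = np.nan

    if rates_path is not None:
        rates = pd.read_csv(rates_path)
        if rates.empty:
            raise InputError(f"{rates_path}: no records")
        _require_columns(rates, _RATES_MANDATORY, str(rates_path))
        bad = rates.index[rates["rate"] <= 0].tolist()
        if bad:
            raise InputError(
                f"{rates_path}: non-positive rate at row(s) "
                f"{[i + 2 for i in bad]}"
            )

    return samples, env, rates


def assign_season(date: _dt.date) -> str:
    """Austral season of a date.

    Winter runs mid-April through mid-October (Apr 16 – Oct 15), summer
    mid-November through mid-April (Nov 16 – Apr 15).  Dates in the
    unassigned mid-October–mid-November gap go to the nearer season's
    boundary (Oct 16–31 → winter, Nov 1–15 → summer).
    """
    m, d = date.month, date.day
    if (m == 4 and d >= 16) or m in (5, 6, 7, 8, 9) or (m == 10 and d <= 15):
        return "winter"
    if m == 10 or (m == 11 and d <= 15):  # gap: nearest boundary
        season = "winter" if m == 10 else "summer"
        log.info("date %s falls in the season gap; assigned %s", date, season)
        return season
    return "summer"


def aggregate_colonies(
    values: Iterable[float],
) -> dict[str, float]:
    """Mean, standard error (sd/√n) and n across colonies for one variable.

    A single colony yields a mean with SE flagged undefined (NaN).
    Missing values (NaN) reduce n.
    """
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)],
                     dtype=float)
    n = arr.size
    if n == 0:
        return {"mean": np.nan, "se": np.nan, "n": 0}
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
    return {"mean": mean, "se": se, "n": n}


def _growth_windows(dates: Sequence[_dt.date]) -> list[tuple[_dt.date, _dt.date]]:
    """Growth window per period: the period midpoint date ± half the
    sampling interval (window boundaries halfway to the neighbouring
    periods; the first/last extend by half the median interval)."""
    ds = sorted(set(dates))
    ords = [d.toordinal() for d in ds]
    if len(ds) >= 2:
        half = float(np.median(np.diff(ords))) / 2.0
    else:
        half = 15.0
    bounds = [ords[0] - half]
    bounds += [(a + b) / 2.0 for a, b in zip(ords, ords[1:])]
    bounds += [ords[-1] + half]
    return [
        (
            _dt.date.fromordinal(int(np.ceil(lo))),
            _dt.date.fromordinal(int(np.floor(hi))),
        )
        for lo, hi in zip(bounds, bounds[1:])
    ]


def env_period_means(
    env: pd.DataFrame, period_dates: dict[str, _dt.date], config: dict | None = None
) -> pd.DataFrame:
    """Environmental means over each collection period's growth window."""
    cfg = config or load_config()
    ds = sorted(period_dates.items(), key=lambda kv: kv[1])
    windows = _growth_windows([d for _, d in ds])
    rows = []
    for (period, date), (lo, hi) in zip(ds, windows):
        mask = (env["date"] >= pd.Timestamp(lo)) & (env["date"] <= pd.Timestamp(hi))
        chunk = env.loc[mask]
        if chunk.empty:
            log.warning(
                "no environment rows in growth window %s..%s for period %s; "
                "using whole-series means", lo, hi, period,
            )
            chunk = env
        phsw = chunk["pH_sw"].mean()
        rows.append(
            {
                "period": period,
                "date": date,
                "season": assign_season(date),
                "temperature": float(chunk["temperature"].mean()),
                "salinity": float(chunk["salinity"].mean())
                if chunk["salinity"].notna().any()
                else cfg["seawater"]["default_salinity"],
                "pH_sw": float(phsw) if pd.notna(phsw)
                else cfg["seawater"]["default_pH_sw"],
                "PAR": float(chunk["PAR"].mean())
                if "PAR" in chunk and chunk["PAR"].notna().any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("period")


def reconstruct_samples(
    samples: Sequence[SkeletalSample],
    env_periods: pd.DataFrame,
    config: dict | None = None,
) -> pd.DataFrame:
    """Run the boron proxy chain per colony; returns a tidy per-sample table."""
    cfg = config or load_config()
    bcfg = _boron.BoronConfig(
        d11B_sw=cfg["boron"]["d11B_sw"], alpha_B=cfg["boron"]["alpha_B"]
    )
    rows = []
    for s in samples:
        if s.period not in env_periods.index:
            raise DomainError(
                f"sample {s.colony}/{s.period}: no matching environment period"
            )
        ep = env_periods.loc[s.period]
        rec = {
            "species": s.species, "colony": s.colony, "period": s.period,
            "date": s.date, "season": str(ep["season"]),
            "temperature": float(ep["temperature"]),
            "d11B": s.d11B, "BCa": s.BCa, "LiMg": s.LiMg, "SrCa": s.SrCa,
        }
        if s.d11B is not None and s.BCa is not None:
            st = _boron.reconstruct(
                s,
                EnvRecord(
                    date=s.date,
                    temperature=float(ep["temperature"]),
                    salinity=float(ep["salinity"]),
                    pH_sw=float(ep["pH_sw"]),
                ),
                bcfg,
                k1k2=cfg["constants"]["k1k2"],
                boron_formulation=cfg["constants"]["boron"],
            )
            rec.update(
                pH_cf=st.pH_cf, dic_cf=st.dic_cf, co3_cf=st.co3_cf,
                omega_cf=st.omega_cf, KD=st.KD, borate_cf=st.borate_cf,
                flagged=st.flagged,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def period_summaries(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-colony reconstructions to period mean ± SE (n colonies)."""
    rows = []
    for (period, ), group in per_sample.groupby(["period"]):
        rec: dict = {
            "period": period,
            "date": group["date"].iloc[0],
            "season": group["season"].iloc[0],
            "temperature": group["temperature"].iloc[0],
        }
        for var in CF_VARIABLES + ("LiMg", "SrCa"):
            if var in group:
                agg = aggregate_colonies(group[var])
                rec[f"{var}_mean"] = agg["mean"]
                rec[f"{var}_se"] = agg["se"]
                rec[f"{var}_n"] = agg["n"]
        rows.append(rec)
    return (
        pd.DataFrame(rows)
        .sort_values("date")
        .set_index("period")
    )


def seasonal_stats(
    summaries: pd.DataFrame, variables: Sequence[str] = CF_VARIABLES
) -> dict[str, dict]:
    """Seasonal means, amplitudes and percent differences per variable.

    Percent difference uses the smaller season as denominator,
    100·(high − low)/low; reported both on season means and on the extreme
    period means (the two conventions differ, so both are emitted).
    Amplitude is max − min of the period means.
    """
    if set(summaries["season"].unique()) != {"summer", "winter"}:
        raise DomainError("both seasons must be represented")
    out: dict[str, dict] = {}
    for var in variables:
        col = f"{var}_mean"
        if col not in summaries or summaries[col].isna().all():
            continue
        means = summaries[col].astype(float)
        summer = float(means[summaries["season"] == "summer"].mean())
        winter = float(means[summaries["season"] == "winter"].mean())
        hi, lo = max(summer, winter), min(summer, winter)
        p_hi, p_lo = float(means.max()), float(means.min())
        out[var] = {
            "summer_mean": summer,
            "winter_mean": winter,
            "higher_season": "summer" if summer >= winter else "winter",
            "amplitude": p_hi - p_lo,
            "percent_diff_season_means": 100.0 * (hi - lo) / lo,
            "percent_diff_period_means": 100.0 * (p_hi - p_lo) / p_lo,
        }
    return out


def correlate(
    x: Sequence[float], y: Sequence[float]
) -> dict[str, float]:
    """OLS regression of y on x over aligned period means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError(f"misaligned series: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DomainError("need at least 3 aligned period means")
    if np.ptp(x) == 0:
        raise DomainError("x series is constant")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
    }


def _rate_summary(rates: pd.DataFrame) -> dict:
    """Long-term mean and percent deviations of a measured-rate series."""
    r = rates["rate"].astype(float).to_numpy()
    mean = float(r.mean())
    dev_pct = 100.0 * (r - mean) / mean
    return {
        "long_term_mean": mean,
        "max_abs_deviation_pct": float(np.max(np.abs(dev_pct))),
        "percent_of_mean": _kinetics.percent_of_mean(r).tolist(),
    }


def run(
    geochem_path: str | Path | None = None,
    env_path: str | Path | None = None,
    rates_path: str | Path | None = None,
    *,
    config: dict | None = None,
    species: str | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Full pipeline run; returns (and optionally writes) the report bundle.

    With geochemistry + environment inputs the full proxy chain, seasonal
    statistics, correlations, chronology check and (given measured rates)
    the three kinetics scenarios are produced.  With only a rates table the
    growth-rate summary subset is produced and the proxy stages are skipped
    with a notice.  Deterministic given identical inputs and configuration.
    """
    cfg = config or load_config()
    samples, env, rates = read_inputs(geochem_path, env_path, rates_path, cfg)
    if species is not None:
        samples = [s for s in samples if s.species == species]
        if rates is not None:
            rates = rates[rates["species"] == species]
    report: dict = {"config": cfg, "notices": []}
    per_sample = summaries = env_periods = None

    if samples and env is not None:
        period_dates = {s.period: s.date for s in samples}
        env_periods = env_period_means(env, period_dates, cfg)
        per_sample = reconstruct_samples(samples, env_periods, cfg)
        summaries = period_summaries(per_sample)
        report["seasonal_stats"] = seasonal_stats(summaries)
        T = summaries["temperature"].to_numpy(dtype=float)
        report["correlations"] = {
            "dic_cf_vs_T": correlate(T, summaries["dic_cf_mean"]),
            "pH_cf_vs_T": correlate(T, summaries["pH_cf_mean"]),
            "omega_cf_vs_T": correlate(T, summaries["omega_cf_mean"]),
            "dic_cf_vs_pH_cf": correlate(
                summaries["pH_cf_mean"], summaries["dic_cf_mean"]
            ),
        }
        proxy_series = {}
        for proxy, col in (("Li/Mg", "LiMg_mean"), ("Sr/Ca", "SrCa_mean")):
            if col in summaries and summaries[col].notna().all():
                proxy_series[proxy] = summaries[col].to_numpy(dtype=float)
        if proxy_series:
            report["chronology"] = chronology_check(
                proxy_series, T, cfg["thermometry"]["chronology_r2"]
            )
    else:
        report["notices"].append(
            "proxy stages skipped: geochemistry and/or environment input missing"
        )

    if rates is not None and len(rates):
        report["rates"] = _rate_summary(rates)
        if summaries is not None and env_periods is not None:
            measured = rates.set_index("period")["rate"].astype(float)
            common = summaries.index.intersection(measured.index)
            if len(common) >= 3:
                cf = summaries.loc[
                    common, ["omega_cf_mean", "dic_cf_mean"]
                ].rename(
                    columns={"omega_cf_mean": "omega_cf", "dic_cf_mean": "dic_cf"}
                )
                env_p = env_periods.loc[common]
                rm = cfg["rate_model"]
                scen = {}
                for s in (1, 2, 3):
                    res = _kinetics.scenario_series(
                        cf, env_p, measured.loc[common], s,
                        fixed_T=rm["fixed_T"],
                        aquaria=(rm["aquaria"]["slope"], rm["aquaria"]["intercept"]),
                        parameterisation=rm["parameterisation"],
                        k1k2=cfg["constants"]["k1k2"],
                        boron=cfg["constants"]["boron"],
                    )
                    scen[f"scenario_{s}"] = {
                        "rmse_pct": res.rmse_vs_measured,
                        "percent_of_mean": res.percent_of_mean.tolist(),
                    }
                report["scenarios"] = scen

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if per_sample is not None:
            per_sample.to_csv(out / "cf_states.csv", index=False)
        if summaries is not None:
            summaries.to_csv(out / "period_summaries.csv")
        serialisable = {k: v for k, v in report.items()}
        (out / "summary.json").write_text(
            json.dumps(serialisable, indent=2, default=str) + "\n"
        )
    return report
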
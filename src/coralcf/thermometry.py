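"""Trace-element palaeothermometry and the skeletal chronology check.

Skeletal Li/Mg and Sr/Ca both decrease linearly with the temperature of the
water the coral grew in, so a regression of either ratio against ambient
temperature (i) calibrates a thermometer that can be inverted, and (ii)
verifies that the sampled skeletal increment was deposited during the period
the environmental record covers — if the apical tip integrated a different
window, the correlation collapses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .constants import DomainError

__all__ = [
    "TECalibration",
    "fit_calibration",
    "invert_temperature",
    "chronology_check",
    "DEFAULT_CALIBRATIONS",
]


@dataclass(frozen=True)
class TECalibration:
    """A linear ratio-vs-temperature calibration: ratio = slope·T + intercept."""

    proxy: str  # "Li/Mg" or "Sr/Ca"
    slope: float  # mmol/mol per °C
    intercept: float  # mmol/mol
    r2: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.proxy not in ("Li/Mg", "Sr/Ca"):
            raise ValueError(f"unknown proxy {self.proxy!r}")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("calibration needs at least 3 pairs")


#: Rottnest Island A. yongei / P. damicornis calibration lines
DEFAULT_CALIBRATIONS = {
    ("A_yongei", "Li/Mg"): (-0.08, 3.63),
    ("A_yongei", "Sr/Ca"): (-0.061, 10.92),
    ("P_damicornis", "Li/Mg"): (-0.05, 2.99),
    ("P_damicornis", "Sr/Ca"): (-0.053, 10.57),
}


def fit_calibration(
    pairs: Iterable[tuple[float, float]], proxy: str = "Li/Mg"
) -> TECalibration:
    """Ordinary-least-squares fit of ratio on temperature.

    ``pairs`` are (temperature °C, ratio mmol/mol).  Returns the slope,
    intercept, r² and the two-sided p-value of the slope from the standard
    t distribution.  Order of the pairs does not matter.
    """
    arr = np.asarray(sorted(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise DomainError("need at least 3 (T, ratio) pairs")
    T, y = arr[:, 0], arr[:, 1]
    if np.ptp(T) == 0:
        raise DomainError("no temperature variance in calibration data")
    res = stats.linregress(T, y)
    return TECalibration(
        proxy=proxy,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(T),
    )


def invert_temperature(ratio: float, cal: TECalibration) -> float:
    """Temperature (°C) from a measured ratio: T = (ratio − intercept)/slope."""
    if cal.slope == 0:
        raise DomainError("cannot invert a zero-slope calibration")
    return (ratio - cal.intercept) / cal.slope


def predict_ratio(T: float, cal: TECalibration) -> float:
    """Forward calibration line: ratio = slope·T + intercept."""
    return cal.slope * T + cal.intercept


def chronology_check(
    proxy_series: dict[str, Sequence[float]],
    temperatures: Sequence[float],
    threshold_r2: float = 0.5,
) -> dict[str, dict]:
    """Verify that skeletal samples record ambient conditions.

    For each proxy series (matched 1:1 to period-mean temperatures),
    regress the ratio on temperature and pass when r² ≥ ``threshold_r2``
    with a negative slope — both proxies decrease with temperature in this
    system, so a positive slope means the chronology is broken regardless
    of r².

    Returns per-proxy ``{"r2", "p", "slope", "passed"}``.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size < 4:
        raise DomainError("need at least 4 matched sample/environment periods")
    out: dict[str, dict] = {}
    for proxy, values in proxy_series.items():
        values = np.asarray(values, dtype=float)
        if values.size != temperatures.size:
            raise DomainError(
                f"{proxy}: {values.size} samples vs "
                f"{temperatures.size} environment periods"
            )
        res = stats.linregress(temperatures, values)
        r2 = float(res.rvalue**2)
        out[proxy] = {
            "r2": r2,
            "p": float(res.pvalue),
            "slope": float(res.slope),
            "passed": bool(r2 >= threshold_r2 and res.slope < 0),
        }
    return out
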
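"""Core record types shared across the pipeline stages."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

from .constants import DomainError

__all__ = ["SkeletalSample", "EnvRecord", "SPECIES"]

SPECIES = ("A_yongei", "P_damicornis")


@dataclass(frozen=True)
class SkeletalSample:
    """One colony × collection-period skeletal geochemistry measurement set.

    Any proxy may be missing (None); δ¹¹B must fall in (10, 35) ‰ when
    present and elemental ratios must be positive.
    """

    species: str
    colony: str
    period: str
    date: _dt.date
    d11B: float | None = None  # ‰
    BCa: float | None = None  # mmol/mol
    LiMg: float | None = None  # mmol/mol
    SrCa: float | None = None  # mmol/mol

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DomainError(
                f"species {self.species!r} not one of {SPECIES}"
            )
        if self.d11B is not None and not 10.0 < self.d11B < 35.0:
            raise DomainError(
                f"d11B {self.d11B} ‰ outside (10, 35) for "
                f"{self.colony}/{self.period}"
            )
        for name in ("BCa", "LiMg", "SrCa"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(
                    f"{name} must be positive for {self.colony}/{self.period}"
                )


@dataclass(frozen=True)
class EnvRecord:
    """Dated ambient seawater state driving constants and scenarios."""

    date: _dt.date
    temperature: float  # °C
    salinity: float
    pH_sw: float  # total scale
    PAR: float | None = None  # mol m-2 d-1

    def __post_init__(self) -> None:
        if not 7.5 < self.pH_sw < 8.5:
            raise DomainError(f"pH_sw {self.pH_sw} outside (7.5, 8.5)")
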
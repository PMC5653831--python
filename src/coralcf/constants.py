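"""Seawater equilibrium constants and carbonate-system speciation.

Everything downstream of the boron proxies needs temperature- and
salinity-dependent equilibrium constants on the total hydrogen-ion pH scale:
the boric-acid dissociation exponent pK_B, the carbonic-acid constants K1 and
K2, the stoichiometric aragonite solubility product K*sp, and the conservative
concentrations of total boron and calcium.  This module provides them from
named literature formulations, together with the closed-form two-parameter
(pH, [CO3--]) <-> DIC speciation solver used throughout the proxy chain.

All constants are evaluated at surface pressure (0 dbar); the study system is
a shallow subtidal reef and no pressure corrections are offered.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "SeawaterConditions",
    "ConstantsSet",
    "boron_pKB",
    "total_boron",
    "carbonic_constants",
    "aragonite_ksp",
    "calcium_conc",
    "constants_for",
    "dic_from_ph_co3",
    "co3_from_ph_dic",
]

#: molar mass of boron, g/mol
_M_BORON = 10.811

#: Uppström (1974): total boron 0.1284 mg kg-1 per salinity unit
_BORON_MG_PER_PSU = {"uppstrom": 0.1284, "lee": 0.1336}

#: mean-seawater calcium at S=35, µmol/kg (Riley & Tongudai proportionality)
_CA_S35 = 10280.0


class DomainError(ValueError):
    """An input lies outside the physically admissible domain."""


@dataclass(frozen=True)
class SeawaterConditions:
    """Ambient seawater state at which constants are evaluated.

    Parameters
    ----------
    temperature : float
        In-situ temperature, °C. Must lie in (0, 40).
    salinity : float
        Practical salinity (dimensionless). Must lie in (20, 42).
    """

    temperature: float
    salinity: float
    pressure: float = 0.0  # dbar; fixed at surface

    def __post_init__(self) -> None:
        if not 0.0 < self.temperature < 40.0:
            raise DomainError(
                f"temperature {self.temperature} °C outside (0, 40)"
            )
        if not 20.0 < self.salinity < 42.0:
            raise DomainError(f"salinity {self.salinity} outside (20, 42)")
        if self.pressure != 0.0:
            raise DomainError("only surface pressure (0 dbar) is supported")

    @property
    def kelvin(self) -> float:
        return self.temperature + 273.15


@dataclass(frozen=True)
class ConstantsSet:
    """Bundle of equilibrium constants evaluated at one seawater state.

    Attributes
    ----------
    pK_B : float
        Boric-acid dissociation exponent, total scale.
    K1, K2 : float
        First and second carbonic-acid dissociation constants, mol/kg,
        total scale.
    Ksp_arag : float
        Aragonite stoichiometric solubility product, mol²/kg².
    B_T : float
        Total inorganic boron, µmol/kg.
    Ca : float
        Calcium concentration, µmol/kg.
    provenance : dict
        Formulation names and the conditions used.
    """

    pK_B: float
    K1: float
    K2: float
    Ksp_arag: float
    B_T: float
    Ca: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if min(self.K1, self.K2, self.Ksp_arag, self.B_T, self.Ca) <= 0:
            raise DomainError("all constants must be strictly positive")
        if self.K1 <= self.K2:
            raise DomainError("K1 must exceed K2")

    @property
    def K_B(self) -> float:
        """Boric-acid dissociation constant, mol/kg, total scale."""
        return 10.0 ** (-self.pK_B)


def boron_pKB(cond: SeawaterConditions) -> float:
    """Boric-acid dissociation exponent pK_B, total scale (Dickson 1990).

    Decreasing in temperature; ~8.60 at 25 °C, S=35.
    """
    T = cond.kelvin
    S = cond.salinity
    sqS = math.sqrt(S)
    lnK = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S ** 1.5 - 0.0996 * S ** 2)
        / T
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * math.log(T)
        + 0.053105 * sqS * T
    )
    return -math.log10(math.exp(lnK))


def total_boron(salinity: float, formulation: str = "uppstrom") -> float:
    """Total inorganic boron B_T in µmol/kg; linear in salinity.

    The two selectable proportionalities differ by ~4 %:
    Uppström (1974) 0.1284 and Lee et al. (2010) 0.1336 mg kg⁻¹ psu⁻¹.
    """
    if salinity <= 0:
        raise DomainError("salinity must be positive")
    try:
        mg_per_psu = _BORON_MG_PER_PSU[formulation]
    except KeyError:
        raise ValueError(f"unknown boron formulation {formulation!r}") from None
    return mg_per_psu * salinity / _M_BORON * 1e3


def carbonic_constants(
    cond: SeawaterConditions, formulation: str = "lueker2000"
) -> tuple[float, float]:
    """Carbonic-acid dissociation constants (K1, K2), mol/kg, total scale.

    Default is the Lueker et al. (2000) refit of the Mehrbach constants,
    the community-standard choice for open-ocean surface waters.  The
    Dickson & Millero (1987) refit is selectable; it was calibrated on the
    seawater scale, which differs from the total scale by well under 1 %
    in K at these conditions.
    """
    T = cond.kelvin
    S = cond.salinity
    if formulation == "lueker2000":
        pK1 = 3633.86 / T - 61.2172 + 9.67770 * math.log(T) - 0.011555 * S + 0.0001152 * S ** 2
        pK2 = 471.78 / T + 25.9290 - 3.16967 * math.log(T) - 0.01781 * S + 0.0001122 * S ** 2
        if not (2.0 < cond.temperature < 35.0 and 19.0 < S < 43.0):
            warnings.warn(
                "conditions outside the Lueker et al. (2000) calibration range",
                stacklevel=2,
            )
    elif formulation == "dickson_millero":
        pK1 = 3670.7 / T - 62.008 + 9.7944 * math.log(T) - 0.0118 * S + 0.000116 * S ** 2
        pK2 = 1394.7 / T + 4.777 - 0.0184 * S + 0.000118 * S ** 2
        if not (1.0 < cond.temperature < 36.0 and 19.0 < S < 41.0):
            warnings.warn(
                "conditions outside the Dickson & Millero (1987) calibration range",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown K1/K2 formulation {formulation!r}")
    return 10.0 ** (-pK1), 10.0 ** (-pK2)


def aragonite_ksp(cond: SeawaterConditions) -> float:
    """Aragonite stoichiometric solubility product, mol²/kg² (Mucci 1983)."""
    T = cond.kelvin
    S = cond.salinity
    log10_ksp = (
        -171.945
        - 0.077993 * T
        + 2903.293 / T
        + 71.595 * math.log10(T)
        + (-0.068393 + 0.0017276 * T + 88.135 / T) * math.sqrt(S)
        - 0.10018 * S
        + 0.0059415 * S ** 1.5
    )
    return 10.0 ** log10_ksp


def calcium_conc(salinity: float) -> float:
    """Calcium concentration, µmol/kg, conservative with salinity.

    Ca = 10280 × S/35; the calcifying fluid is assumed to carry the ambient
    seawater calcium concentration.
    """
    if salinity <= 0:
        raise DomainError("salinity must be positive")
    return _CA_S35 * salinity / 35.0


def constants_for(
    cond: SeawaterConditions,
    *,
    k1k2: str = "lueker2000",
    boron: str = "uppstrom",
) -> ConstantsSet:
    """Evaluate the full :class:`ConstantsSet` at one seawater state.

    Constants are recomputed on every call; nothing is cached across
    conditions.
    """
    K1, K2 = carbonic_constants(cond, k1k2)
    return ConstantsSet(
        pK_B=boron_pKB(cond),
        K1=K1,
        K2=K2,
        Ksp_arag=aragonite_ksp(cond),
        B_T=total_boron(cond.salinity, boron),
        Ca=calcium_conc(cond.salinity),
        provenance={
            "pK_B": "dickson1990",
            "k1k2": k1k2,
            "ksp": "mucci1983",
            "boron": boron,
            "temperature": cond.temperature,
            "salinity": cond.salinity,
        },
    )


def dic_from_ph_co3(pH: float, co3: float, constants: ConstantsSet) -> float:
    """Dissolved inorganic carbon (µmol/kg) from pH and [CO3--].

    DIC = [CO3--] × (1 + [H+]/K2 + [H+]²/(K1·K2)); the three terms are the
    carbonate, bicarbonate and aqueous-CO2 fractions.  Always ≥ [CO3--].
    """
    if not 0.0 < pH < 14.0:
        raise DomainError(f"pH {pH} outside (0, 14)")
    if co3 < 0:
        raise DomainError("carbonate-ion concentration must be non-negative")
    h = 10.0 ** (-pH)
    return co3 * (1.0 + h / constants.K2 + h * h / (constants.K1 * constants.K2))


def co3_from_ph_dic(pH: float, dic: float, constants: ConstantsSet) -> float:
    """[CO3--] (µmol/kg) from pH and DIC; exact inverse of
    :func:`dic_from_ph_co3` at fixed pH."""
    if not 0.0 < pH < 14.0:
        raise DomainError(f"pH {pH} outside (0, 14)")
    if dic < 0:
        raise DomainError("DIC must be non-negative")
    h = 10.0 ** (-pH)
    return dic / (1.0 + h / constants.K2 + h * h / (constants.K1 * constants.K2))
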
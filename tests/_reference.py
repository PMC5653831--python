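"""Independent reference values and routes for cross-checking.

The constants checks anchor on published check values (boric-acid constant
at 25 °C / S=35, the Mehrbach-refit carbonic-acid constants, the aragonite
solubility product) transcribed here directly from the primary literature,
plus an independently coded speciation route for the two-parameter
(pH, CO3) -> DIC solver.  Nothing here imports the package under test.
"""

import math

# -- published check values, total pH scale, 25 °C, S = 35 ------------------
# boric acid (Dickson 1990): ln K_B = -19.7964 -> pK_B = 8.5975
PKB_CHECK_25_35 = -math.log10(math.exp(-19.7964))

# Lueker et al. (2000) refit of Mehrbach: pK1 = 5.8472, pK2 = 8.9660
PK1_CHECK_25_35 = 5.8472
PK2_CHECK_25_35 = 8.9660

# Mucci (1983) aragonite stoichiometric solubility product: log10 = -6.1883
KSP_ARAG_CHECK_25_35 = 10.0 ** (-6.1883)

# total boron proportionalities, mg kg-1 per salinity unit / M_B
BT_UPPSTROM_S35 = 0.1284 * 35 / 10.811 * 1e3  # 415.7 µmol/kg
BT_LEE_S35 = 0.1336 * 35 / 10.811 * 1e3  # 432.6 µmol/kg


def lueker_pk1_pk2(T_celsius: float, S: float) -> tuple[float, float]:
    """Independent transcription of the Lueker et al. (2000) coefficients."""
    T = T_celsius + 273.15
    pk1 = 3633.86 / T - 61.2172 + 9.6777 * math.log(T) - 0.011555 * S + 0.0001152 * S * S
    pk2 = 471.78 / T + 25.929 - 3.16967 * math.log(T) - 0.01781 * S + 0.0001122 * S * S
    return pk1, pk2


def dic_speciation_route(pH: float, co3: float, K1: float, K2: float) -> float:
    """DIC from (pH, CO3) via the carbonate-fraction formula.

    CO3/DIC = K1·K2 / (H² + K1·H + K1·K2), so
    DIC = CO3 · (H² + K1·H + K1·K2) / (K1·K2) — a different algebraic route
    than the per-species ratio sum used by the implementation.
    """
    h = 10.0 ** (-pH)
    return co3 * (h * h + K1 * h + K1 * K2) / (K1 * K2)
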
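"""Physical constants and unit conversions.

Internal energy unit is kcal/mol, length is the angstrom.  Umbrella spring
constants are accepted in kJ mol^-1 nm^-2 (the unit restraint forces are
commonly reported in) and converted on ingestion.
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

#: kJ per kcal
KJ_PER_KCAL = 4.184

#: Default analysis temperature, K
DEFAULT_TEMPERATURE = 298.0


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy in kcal/mol at the given temperature (K)."""
    return KB_KCAL * temperature


def spring_kj_nm2_to_kcal_A2(k: float) -> float:
    """Convert a harmonic spring constant from kJ mol^-1 nm^-2 to kcal mol^-1 A^-2."""
    return k / KJ_PER_KCAL / 100.0
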
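"""Physical constants and unit conversions used across the package.

Internal unit system: lengths in Å, time in ps, energies in kJ/mol,
temperatures in K.  Free-energy surfaces are reported in kcal/mol to
match the conventional presentation of torsion-space landscapes.
"""

#: Boltzmann constant in kJ/(mol·K)
KB_KJ = 8.3144621e-3

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL = 1.9872041e-3

#: kJ per kcal
KJ_PER_KCAL = 4.184


def kt_kj(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol."""
    return KB_KJ * temperature


def kt_kcal(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol."""
    return KB_KCAL * temperature
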
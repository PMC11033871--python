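"""Physical constants and unit conventions.

Internal units throughout the package:

* length      nm
* time        ps
* temperature K
* energy      kJ/mol
* mass        g/mol  (so that g/mol * nm^2 / ps^2 == kJ/mol)

Free energies reported to users are converted to kcal/mol where noted.
"""

#: Boltzmann constant in kJ/(mol K).
KB = 0.0083144621

#: Gas constant in kcal/(mol K).
R_KCAL = 1.98720425864e-3

#: kJ per kcal.
KJ_PER_KCAL = 4.184

#: Standard-state volume per molecule at 1 M, in nm^3.
STANDARD_VOLUME = 1.661


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    return KB * temperature
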
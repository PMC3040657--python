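"""Physical constants and unit conversions.

Internal units throughout the package: length in Å, time in ns, force in
pN, energy in pN·Å, temperature in K.  Config files may state spring
constants in kcal mol⁻¹ Å⁻² and speeds in nm ns⁻¹; the conversions below
are applied at load time.
"""

#: Boltzmann constant, pN·Å/K.
KB_PN_A_PER_K = 0.138065

#: kB·T at 300 K, pN·Å.
KBT_300K = 41.4195

#: 1 kcal mol⁻¹ Å⁻¹ expressed in pN.
KCAL_PER_MOL_A_TO_PN = 69.479

#: 1 nm ns⁻¹ in Å ns⁻¹.
NM_PER_NS_TO_A_PER_NS = 10.0


def kbt(temperature_k: float) -> float:
    """Thermal energy kB·T in pN·Å at the given temperature in K."""
    return KB_PN_A_PER_K * temperature_k


def spring_kcal_to_pn_per_a(k_kcal_mol_a2: float) -> float:
    """Convert a spring constant from kcal mol⁻¹ Å⁻² to pN/Å."""
    return k_kcal_mol_a2 * KCAL_PER_MOL_A_TO_PN
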
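"""Physical constants and unit conversions.

Internal conventions: lengths in nm, times in ps, energies in kJ/mol.
Free energies are reported in kcal/mol, lateral diffusion in cm^2/s.
"""

#: Molar gas constant, kJ mol^-1 K^-1 (CODATA).
R_KJ_PER_MOL_K = 8.31446261815324e-3

#: kcal per kJ.
KCAL_PER_KJ = 1.0 / 4.184

#: kJ per kcal.
KJ_PER_KCAL = 4.184

# 1 nm^2 = 1e-14 cm^2 and 1 ps = 1e-12 s, hence 1 nm^2/ps = 1e-2 cm^2/s.
#: Multiply a diffusion coefficient in nm^2/ps by this to get cm^2/s.
CM2_PER_S_PER_NM2_PER_PS = 1e-2

#: Atomic mass unit in kg.
KG_PER_AMU = 1.66053906892e-27


def kT_kj(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    return R_KJ_PER_MOL_K * temperature
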
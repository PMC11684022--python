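"""Physical constants shared across the package.

Units follow molecular-mechanics convention: lengths in Å, energies in
kcal/mol, charges in elementary charge units e, temperatures in K.
"""

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_K = 332.0636

#: Boltzmann constant, kcal/(mol·K).
KB = 0.0019872

#: ALPB interpolation constant (dimensionless).
ALPB_ALPHA = 0.571412

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: Debye screening convention for monovalent salt in water near 298 K:
#: kappa² (Å⁻²) = DEBYE_KAPPA_COEFF · c (mol/L).
DEBYE_KAPPA_COEFF = 0.10806

#: Conventional standard-state volume per molecule at 1 mol/L, ų.
STANDARD_VOLUME_A3 = 1660.0


def standard_state_volume(concentration_molar: float = 1.0) -> float:
    """Per-molecule volume in ų at the given molar concentration.

    At 1 mol/L this evaluates to 1660.5 ų, the familiar 1 M standard-state
    volume (rounded to 1660 ų in most of the binding literature).
    """
    if concentration_molar <= 0:
        raise ValueError("concentration must be positive")
    return 1.0e27 / (AVOGADRO * concentration_molar)
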
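"""Physical constants and unit conventions.

The package works in Å, ps, amu, K and kcal/mol throughout.  Forces are
kcal/mol/Å; the single conversion factor below turns them into
accelerations in Å/ps² (1 kcal/mol = 418.4 amu·Å²/ps², exact given
N_A·amu = 1 g/mol).
"""

KB_KCAL_MOL_K = 0.0019872041
"""Boltzmann constant in kcal/mol/K."""

KCAL_PER_AMU_A2_PS2 = 418.4
"""kcal/mol expressed in amu·Å²/ps² (divide a force in kcal/mol/Å by the
mass in amu and multiply by this to get Å/ps²)."""

STANDARD_STATE_VOLUME_A3 = 1660.0
"""Volume per molecule at 1 M standard concentration, ų."""


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol at ``temperature`` kelvin."""
    return KB_KCAL_MOL_K * temperature
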
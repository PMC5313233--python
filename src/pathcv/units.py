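"""Unit system and physical constants.

The package works in the AKMA-style unit set common to biomolecular
simulation codes: lengths in Å, time in ps, energies in kcal/mol, masses
in amu, temperatures in K.  Because kcal/mol is not amu·Å²/ps², every
conversion between energy-derived forces and kinematic quantities
(accelerations, thermal velocities) goes through :data:`KCAL_PER_AKMA`.
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: 1 kcal/mol expressed in amu·Å²/ps².
KCAL_PER_AKMA = 418.4


def kt(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol."""
    return KB * temperature
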
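"""Physical constants used throughout the package (kcal/mol, Å, ps units)."""

#: Boltzmann constant in kcal/mol/K.
BOLTZMANN_KCAL_PER_MOL_K = 0.0019872041

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 300.0


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Return kT in kcal/mol. kT(300 K) ≈ 0.596 kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_KCAL_PER_MOL_K * temperature
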
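"""Physical constants and unit helpers.

Unit convention used throughout the package: lengths in nm, forces in pN,
times in ms, energies in kBT (reference temperature 298 K unless stated).
"""

#: Boltzmann constant in pN·nm/K.
KB_PN_NM = 0.0138064852

#: Default experimental temperature (room temperature), K.
ROOM_TEMPERATURE_K = 298.0


def kbt(temperature: float = ROOM_TEMPERATURE_K) -> float:
    """Thermal energy kB*T in pN·nm at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_PN_NM * temperature


def kbt_to_kj_per_mol(energy_kbt: float, temperature: float = ROOM_TEMPERATURE_K) -> float:
    """Convert an energy in kBT units to kJ/mol at the given temperature."""
    # R = NA * kB = 8.31446 J/(mol K)
    return energy_kbt * 8.31446e-3 * temperature
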
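"""Physical constants and unit conventions.

All spatial coordinates are in Å, charges in units of the elementary
charge e, potentials in V, energies in meV, times in fs (electronic
dynamics) or ps (nuclear trajectories), rates in s^-1.
"""

#: Coulomb constant e/(4 pi eps0) in V*Angstrom per elementary charge.
COULOMB_K = 14.3996

#: Boltzmann constant in meV/K (CODATA).
KB_MEV = 8.617333262e-2

#: Reduced Planck constant in meV*s.
HBAR_MEV_S = 6.582119569e-13

#: Reduced Planck constant in meV*fs.
HBAR_MEV_FS = 658.2119569

#: Bulk water number density at 298 K, molecules/Angstrom^3.
RHO_BULK_WATER = 0.0334

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 298.0

#: Default reorganization energy for the quadruplex hopping analysis, meV.
DEFAULT_LAMBDA_MEV = 800.0


def kt_mev(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in meV."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_MEV * temperature
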
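"""Small unit conversions used across the package."""

import math

PLANCK = 6.62607015e-34      # J s
SPEED_OF_LIGHT = 2.99792458e8  # m/s


def photon_energy_J(wavelength_nm: float) -> float:
    """Energy of one photon, joules."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return PLANCK * SPEED_OF_LIGHT / (wavelength_nm * 1e-9)


def photon_flux(power_density_mw_per_um2: float, wavelength_nm: float) -> float:
    """Photon flux (photons s^-1 m^-2) for a given power density.

    E.g. 1.33 mW/um^2 at 940 nm is 6.29e27 photons s^-1 m^-2.
    """
    power_w_per_m2 = power_density_mw_per_um2 * 1e-3 / 1e-12
    return power_w_per_m2 / photon_energy_J(wavelength_nm)
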
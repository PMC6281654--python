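"""Unit conventions and conversions used throughout the package.

All energies are wavenumbers (cm^-1), all times are picoseconds, and all
wavelengths are vacuum nanometres.  The single constant coupling the
energy and time axes is the speed of light expressed in cm/ps: a level
spacing ``de`` (cm^-1) beats with period ``1 / (C_CM_PS * de)`` ps, and a
beat frequency ``f`` (cycles/ps) corresponds to ``f / C_CM_PS`` cm^-1.
"""

from __future__ import annotations

import math

#: Speed of light in cm per picosecond.
C_CM_PS: float = 2.99792458e-2

#: Conversion factor from a Gaussian FWHM to its standard deviation.
FWHM_TO_SIGMA: float = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Standard deviation of a Gaussian with the given full width at half maximum."""
    return fwhm * FWHM_TO_SIGMA


def nm_to_cm1(lambda_nm: float) -> float:
    """Absolute photon energy (cm^-1) of a vacuum wavelength (nm)."""
    if lambda_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {lambda_nm} nm")
    return 1.0e7 / lambda_nm


def wavelength_to_relative_energy(lambda_nm: float, origin_cm1: float) -> float:
    """Photon energy relative to an electronic origin.

    Parameters
    ----------
    lambda_nm
        Vacuum wavelength in nm.
    origin_cm1
        Absolute energy of the electronic origin in cm^-1.

    Returns
    -------
    float
        ``1e7 / lambda_nm - origin_cm1``; negative values mean the photon
        is red of the origin.
    """
    return nm_to_cm1(lambda_nm) - origin_cm1


def beat_period_ps(gap_cm1: float) -> float:
    """Oscillation period (ps) of a quantum beat between levels ``gap_cm1`` apart."""
    if gap_cm1 <= 0:
        raise ValueError("level gap must be positive")
    return 1.0 / (C_CM_PS * gap_cm1)
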
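"""Physical constants, unit conversions and solvent property tables.

All unit bookkeeping for the package is centralized here.  Working units
throughout the package are: concentrations in μM (monomer units unless
stated otherwise), particle masses in kDa, radii in nm, sedimentation
coefficients in Svedbergs (1 S = 1e-13 s), viscosities in mPa·s,
densities in g/ml, activation energies in kJ/mol, time in seconds.
"""

from __future__ import annotations

import numpy as np

# --- fundamental constants (SI) ---
R_GAS = 8.314          # J mol^-1 K^-1
K_BOLTZMANN = 1.380649e-23   # J K^-1
N_AVOGADRO = 6.02214076e23   # mol^-1
E_CHARGE = 1.602176634e-19   # C
EPSILON_0 = 8.8541878128e-12  # F m^-1

# --- unit conversions ---
KDA_TO_G = 1.66054e-21   # grams per kDa (one molecule)
KDA_TO_KG = 1.66054e-24  # kilograms per kDa
SVEDBERG = 1e-13         # seconds per Svedberg
NM_TO_M = 1e-9
NM_TO_CM = 1e-7
MPAS_TO_PAS = 1e-3

FWHM_PER_SIGMA = 2.355   # conventional Gaussian FWHM/σ (2·sqrt(2 ln 2) ≈ 2.3548)

# Dynamic viscosity of pure water, mPa·s (CRC handbook values).
_WATER_VISCOSITY_TABLE = {
    0.0: 1.792,
    5.0: 1.519,
    10.0: 1.307,
    15.0: 1.139,
    20.0: 1.002,
    25.0: 0.8900,
    30.0: 0.7972,
    35.0: 0.7190,
    37.0: 0.6913,
    40.0: 0.6527,
}

# Density of pure water, g/ml (CRC handbook values).
_WATER_DENSITY_TABLE = {
    0.0: 0.99984,
    5.0: 0.99997,
    10.0: 0.99970,
    15.0: 0.99910,
    20.0: 0.99821,
    25.0: 0.99705,
    30.0: 0.99565,
    35.0: 0.99403,
    37.0: 0.99330,
    40.0: 0.99222,
}

_VISC_T = np.array(sorted(_WATER_VISCOSITY_TABLE))
_VISC_V = np.array([_WATER_VISCOSITY_TABLE[t] for t in _VISC_T])
_DENS_T = np.array(sorted(_WATER_DENSITY_TABLE))
_DENS_V = np.array([_WATER_DENSITY_TABLE[t] for t in _DENS_T])


def water_viscosity(temperature_c: float) -> float:
    """Viscosity of water in mPa·s, linearly interpolated between table entries.

    Valid over 0-40 °C, the operating span of the instruments modelled here.
    """
    t = float(temperature_c)
    if not (_VISC_T[0] <= t <= _VISC_T[-1]):
        raise ValueError(f"temperature {t} °C outside tabulated range 0-40 °C")
    return float(np.interp(t, _VISC_T, _VISC_V))


def water_density(temperature_c: float) -> float:
    """Density of water in g/ml, linearly interpolated between table entries."""
    t = float(temperature_c)
    if not (_DENS_T[0] <= t <= _DENS_T[-1]):
        raise ValueError(f"temperature {t} °C outside tabulated range 0-40 °C")
    return float(np.interp(t, _DENS_T, _DENS_V))


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15
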
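"""Svedberg-equation hydrodynamics, s20,w correction and distribution fusion.

The sedimentation coefficient of a particle of protein mass m_p and
hydrodynamic radius R_H in a solvent of viscosity η is

    s = m_p (1 - ρ_w/ρ_p) / (6 π η R_H)

with ρ_p the density of pure protein (default 1.39 g/ml) and ρ_w the
density of water (1 g/ml).  The relation is used in both directions:
forward to predict s from a packing model, and inverted to assign an
R_H to each (mass, s) pair obtained by aligning a mass-weighted mass
histogram with a mass-weighted sedimentation-coefficient distribution.
From R_H follow the particle packing density (mass over the spherical
volume) and the mass fraction of water inside that sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .constants import (
    KDA_TO_G,
    KDA_TO_KG,
    MPAS_TO_PAS,
    NM_TO_CM,
    NM_TO_M,
    SVEDBERG,
    celsius_to_kelvin,
    kelvin_to_celsius,
    water_density,
    water_viscosity,
)
from .errors import DomainError, WeightingError

if TYPE_CHECKING:  # pragma: no cover
    from .mass_photometry import MassHistogram

PROTEIN_DENSITY = 1.39  # g/ml, mean literature value for packed protein
WATER_DENSITY_NOMINAL = 1.00  # g/ml, nominal buoyancy reference


@dataclass(frozen=True)
class SvedbergContext:
    """Solvent and particle densities entering the Svedberg equation.

    Parameters
    ----------
    eta : float
        Solvent viscosity in mPa·s.
    rho_p : float
        Density of pure (anhydrous) protein in g/ml.
    rho_w : float
        Solvent (water) density in g/ml used for buoyancy.
    temperature : float
        Temperature in K the context refers to.
    """

    eta: float = 1.002
    rho_p: float = PROTEIN_DENSITY
    rho_w: float = WATER_DENSITY_NOMINAL
    temperature: float = celsius_to_kelvin(20.0)

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise DomainError("viscosity must be positive")
        if not (self.rho_p > self.rho_w > 0):
            raise DomainError("require rho_p > rho_w > 0")

    @classmethod
    def water(cls, temperature_c: float = 20.0, rho_p: float = PROTEIN_DENSITY) -> "SvedbergContext":
        """Context for pure water at `temperature_c`, from the solvent tables."""
        return cls(
            eta=water_viscosity(temperature_c),
            rho_p=rho_p,
            rho_w=water_density(temperature_c),
            temperature=celsius_to_kelvin(temperature_c),
        )


#: Reference context matching the convention the analysis reports in:
#: water at 20 °C with nominal densities ρ_w = 1.00, ρ_p = 1.39 g/ml.
CTX_20W = SvedbergContext()


@dataclass
class SedimentationDistribution:
    """Mass-weighted distribution of sedimentation coefficients.

    Amplitudes are mass-weighted because absorbance detection reports
    total protein mass per s-value, not particle counts.
    """

    s_values: np.ndarray
    amplitudes: np.ndarray
    temperature: float = celsius_to_kelvin(20.0)  # K
    corrected_to_20C: bool = False

    def __post_init__(self) -> None:
        self.s_values = np.asarray(self.s_values, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.s_values.shape != self.amplitudes.shape:
            raise ValueError("s_values and amplitudes must have equal length")
        if np.any(np.diff(self.s_values) <= 0):
            raise ValueError("s_values must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def total_weight(self) -> float:
        return float(np.sum(self.amplitudes))


@dataclass
class FusedDistribution:
    """Per-bin output of the mass/sedimentation fusion.

    Each entry pairs a sedimentation coefficient with the particle mass
    found at the same mass-weighted quantile, the R_H implied by the
    Svedberg equation, and the derived packing density and water mass
    fraction.
    """

    mass: np.ndarray            # kDa
    s: np.ndarray               # Svedbergs
    r_h: np.ndarray             # nm
    density: np.ndarray         # g/ml
    water_fraction: np.ndarray  # mass fraction
    weight: np.ndarray          # mass-weighted amplitude per bin
    ctx: SvedbergContext = field(default_factory=lambda: CTX_20W)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mass_kDa": self.mass,
                "s_svedberg": self.s,
                "rh_nm": self.r_h,
                "density_g_ml": self.density,
                "water_fraction": self.water_fraction,
                "weight": self.weight,
            }
        )

    def weighted_mean_rh(self) -> float:
        """Amplitude-weighted mean R_H, comparable to a bulk sizing average."""
        return float(np.sum(self.r_h * self.weight) / np.sum(self.weight))


def sedimentation_coefficient(m: float, r_h: float, ctx: SvedbergContext = CTX_20W) -> float:
    """Sedimentation coefficient (Svedbergs) of a particle.

    Parameters
    ----------
    m : float
        Protein mass of the particle in kDa.
    r_h : float
        Hydrodynamic radius in nm.
    """
    if m <= 0 or r_h <= 0:
        raise DomainError("mass and radius must be positive")
    m_kg = m * KDA_TO_KG
    buoyancy = 1.0 - ctx.rho_w / ctx.rho_p
    s_si = m_kg * buoyancy / (6.0 * np.pi * ctx.eta * MPAS_TO_PAS * r_h * NM_TO_M)
    return float(s_si / SVEDBERG)


def hydrodynamic_radius(m: float, s: float, ctx: SvedbergContext = CTX_20W) -> float:
    """Invert the Svedberg equation: R_H in nm from mass (kDa) and s (S)."""
    if m <= 0 or s <= 0:
        raise DomainError("mass and sedimentation coefficient must be positive")
    m_kg = m * KDA_TO_KG
    buoyancy = 1.0 - ctx.rho_w / ctx.rho_p
    r_m = m_kg * buoyancy / (6.0 * np.pi * ctx.eta * MPAS_TO_PAS * s * SVEDBERG)
    if r_m <= 0:
        raise DomainError("inputs imply a nonpositive radius")
    return float(r_m / NM_TO_M)


def correct_s20w(
    s_obs: float | np.ndarray,
    ctx_obs: SvedbergContext,
    ctx_20w: SvedbergContext = CTX_20W,
    viscosity_only: bool = False,
) -> float | np.ndarray:
    """Correct an observed s to standard conditions (water, 20 °C).

    s20,w = s_obs · (η_obs/η_20) · (1 - ρ_w,20/ρ_p) / (1 - ρ_w,obs/ρ_p).
    With ``viscosity_only=True`` the buoyancy-density factor is omitted
    and only the viscosity ratio is applied.
    """
    factor = ctx_obs.eta / ctx_20w.eta
    if not viscosity_only:
        factor *= (1.0 - ctx_20w.rho_w / ctx_20w.rho_p) / (1.0 - ctx_obs.rho_w / ctx_obs.rho_p)
    return s_obs * factor


def correct_distribution_s20w(
    dist: SedimentationDistribution,
    ctx_20w: SvedbergContext = CTX_20W,
    viscosity_only: bool = False,
) -> SedimentationDistribution:
    """Return a copy of `dist` with s-values corrected to 20 °C water."""
    if dist.corrected_to_20C:
        return dist
    t_c = kelvin_to_celsius(dist.temperature)
    ctx_obs = SvedbergContext.water(t_c, rho_p=ctx_20w.rho_p)
    s_new = correct_s20w(dist.s_values, ctx_obs, ctx_20w, viscosity_only=viscosity_only)
    return SedimentationDistribution(
        s_values=np.asarray(s_new),
        amplitudes=dist.amplitudes.copy(),
        temperature=ctx_20w.temperature,
        corrected_to_20C=True,
    )


def packing_density(m: float | np.ndarray, r_h: float | np.ndarray) -> float | np.ndarray:
    """Particle mass (kDa) divided by the volume of the R_H sphere, in g/ml."""
    m = np.asarray(m, dtype=float)
    r_h = np.asarray(r_h, dtype=float)
    if np.any(m <= 0) or np.any(r_h <= 0):
        raise DomainError("mass and radius must be positive")
    volume_ml = (4.0 / 3.0) * np.pi * (r_h * NM_TO_CM) ** 3
    out = m * KDA_TO_G / volume_ml
    return float(out) if out.ndim == 0 else out


def water_mass_fraction(
    density: float | np.ndarray, ctx: SvedbergContext = CTX_20W
) -> float | np.ndarray:
    """Mass fraction of water in a particle of given packing density.

    The sphere of radius R_H holds the protein (at ρ_p) plus water (at
    ρ_w); the fraction follows from volume bookkeeping:
    f = ρ_w (1/d - 1/ρ_p) / (ρ_w (1/d - 1/ρ_p) + 1).
    """
    d = np.asarray(density, dtype=float)
    if np.any(d <= 0):
        raise DomainError("density must be positive")
    if np.any(d > ctx.rho_p * (1 + 1e-12)):
        raise DomainError(f"density exceeds pure-protein density {ctx.rho_p} g/ml")
    d = np.minimum(d, ctx.rho_p)
    ratio = ctx.rho_w * (1.0 / d - 1.0 / ctx.rho_p)
    out = ratio / (ratio + 1.0)
    return float(out) if out.ndim == 0 else out


def micelle_radius(m: float | np.ndarray, water_frac: float, ctx: SvedbergContext = CTX_20W):
    """Sphere-equivalent R_H (nm) of a particle from the packing model.

    Total volume = protein volume m/ρ_p plus the water volume implied by
    the water mass fraction f: m_water = m·f/(1-f), at density ρ_w.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise DomainError("mass must be positive")
    if not (0 <= water_frac < 1):
        raise DomainError("water fraction must lie in [0, 1)")
    m_g = m * KDA_TO_G
    v_ml = m_g / ctx.rho_p + (water_frac / (1.0 - water_frac)) * m_g / ctx.rho_w
    r_cm = (3.0 * v_ml / (4.0 * np.pi)) ** (1.0 / 3.0)
    out = r_cm / NM_TO_CM
    return float(out) if out.ndim == 0 else out


def _midpoint_quantiles(weights: np.ndarray) -> np.ndarray:
    """Cumulative weight evaluated at bin midpoints, normalized to (0, 1)."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise DomainError("distribution has zero total weight")
    cum = np.cumsum(w)
    return (cum - 0.5 * w) / total


def fuse_distributions(
    mass_hist: "MassHistogram",
    sed_dist: SedimentationDistribution,
    ctx: SvedbergContext = CTX_20W,
) -> FusedDistribution:
    """Pair the mass and sedimentation distributions by quantile matching.

    Both inputs must be mass-weighted and the sedimentation distribution
    corrected to 20 °C water.  Each sedimentation bin is assigned the mass
    found at the same normalized cumulative weight in the mass histogram
    (piecewise-linear interpolation between bin centers); R_H, packing
    density and water fraction follow per bin from the Svedberg inversion.
    The map is monotone by construction: larger s pairs with larger mass.
    """
    if mass_hist.weighting != "mass":
        raise WeightingError("mass histogram must be mass-weighted before fusion")
    if not sed_dist.corrected_to_20C:
        raise WeightingError("sedimentation distribution must be corrected to 20 °C water")

    centers = mass_hist.bin_centers
    counts = np.asarray(mass_hist.counts, dtype=float)
    occupied = counts > 0
    if occupied.sum() < 1:
        raise DomainError("mass histogram is empty")
    centers = centers[occupied]
    counts = counts[occupied]

    sed_occ = sed_dist.amplitudes > 0
    s_vals = sed_dist.s_values[sed_occ]
    amps = sed_dist.amplitudes[sed_occ]
    if s_vals.size < 1:
        raise DomainError("sedimentation distribution is empty")

    q_mass = _midpoint_quantiles(counts)
    q_sed = _midpoint_quantiles(amps)
    mass_at_q = np.interp(q_sed, q_mass, centers)

    r_h = np.array(
        [hydrodynamic_radius(m, s, ctx) for m, s in zip(mass_at_q, s_vals)]
    )
    dens = packing_density(mass_at_q, r_h)
    dens_clipped = np.minimum(np.asarray(dens), ctx.rho_p)
    frac = water_mass_fraction(dens_clipped, ctx)

    return FusedDistribution(
        mass=mass_at_q,
        s=s_vals,
        r_h=np.atleast_1d(r_h),
        density=np.atleast_1d(np.asarray(dens)),
        water_fraction=np.atleast_1d(np.asarray(frac)),
        weight=amps.copy(),
        ctx=ctx,
    )
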
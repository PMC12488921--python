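"""Synthetic-data generator for the micelle self-assembly measurements.

Emulates, with the statistical structure the analysis assumes, the four
measurement types the pipeline consumes:

* single-particle mass-photometry landing events drawn from a micelle
  population (broad aggregation-number distribution above a cmc of
  ~0.12 μM, coexisting with free monomers);
* mass-weighted sedimentation-coefficient distributions via the
  Svedberg forward map and a sphere packing model;
* time-resolved mean-hydrodynamic-radius dissociation series with
  Arrhenius temperature dependence of the rate constant;
* refractometry concentration series for dn/dc fits.

The population model is a discretized Gaussian in aggregation number N
(two-Gaussian mixture for the pH 4 preset), truncated below N_min = 5
because very small oligomers expose too much hydrophobic surface to be
stable.  For the near-neutral presets the mean aggregation number grows
with total concentration as a power law tuned so that the mean doubles
from ~20 to ~40 between 1 and 100 μM.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .constants import R_GAS, celsius_to_kelvin, water_viscosity
from .errors import ConfigurationError, DomainError
from .hydrodynamics import (
    SedimentationDistribution,
    SvedbergContext,
    micelle_radius,
    sedimentation_coefficient,
)
from .kinetics import SizeTimeSeries
from .mass_photometry import JB6_MONOMER_KDA

#: Hydrodynamic radius of the free monomer, nm (measured value for the
#: 26.9 kDa chaperone subunit, which is partly disordered and therefore
#: larger than a compact sphere of the same mass).
MONOMER_RH_NM = 3.3


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2^31) from a global seed.

    Hashing the stage name keeps each stage's random stream independent
    of whether other stages run.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PHPreset:
    """Shape of the aggregation-number distribution at one pH condition."""

    mode: str                   # "power" (μ from concentration) or "fixed"
    mu: float | None = None     # fixed mean N (fixed mode)
    sigma: float | None = None  # fixed σ_N (fixed mode)
    second: tuple[float, float, float] | None = None  # (weight, μ2, σ2)
    water_fraction: float = 0.65


#: Distribution presets per pH regime.  Near-neutral pH gives a broad
#: distribution whose mean grows with concentration; at pH 2-3 the
#: C-terminal domain is unfolded and the distribution is narrow around
#: N ≈ 10 with highly hydrated particles; pH 4 is the transition point
#: with a bimodal distribution.  Water fractions follow the packing
#: analysis (65% at pH 5-8 up to ~90% at pH 2).
PH_PRESETS: Mapping[str, PHPreset] = {
    "pH2": PHPreset(mode="fixed", mu=9.6, sigma=2.0, water_fraction=0.90),
    "pH3": PHPreset(mode="fixed", mu=9.6, sigma=2.0, water_fraction=0.90),
    "pH4": PHPreset(
        mode="fixed", mu=9.6, sigma=2.0, second=(0.15, 40.0, 8.0), water_fraction=0.88
    ),
    "pH5": PHPreset(mode="power", water_fraction=0.65),
    "pH7.4": PHPreset(mode="power", water_fraction=0.65),
    "pH8": PHPreset(mode="power", water_fraction=0.65),
}


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the generative micelle population model.

    Defaults describe the chaperone at near-neutral pH: cmc 0.12 μM,
    26.9 kDa monomer, number-mean aggregation number 20 at 1 μM growing
    as C^0.1505 (doubling over two decades), relative width σ_N/μ_N 0.22,
    and no stable micelles below N = 5.
    """

    cmc: float = 0.12                 # μM
    monomer_mass: float = JB6_MONOMER_KDA  # kDa
    meanN_ref: float = 20.0           # mean N at 1 μM (power-law presets)
    conc_exponent: float = 0.1505     # μ_N ∝ C^exponent
    relative_width: float = 0.22      # σ_N / μ_N
    N_min: int = 5
    presets: Mapping[str, PHPreset] = field(default_factory=lambda: PH_PRESETS)

    def __post_init__(self) -> None:
        if self.cmc <= 0 or self.monomer_mass <= 0:
            raise DomainError("cmc and monomer_mass must be positive")
        if self.N_min < 2:
            raise DomainError("N_min must be >= 2")
        if self.relative_width <= 0:
            raise DomainError("relative_width must be positive")


@dataclass
class MicellePopulation:
    """Number concentrations C_N over aggregation number N plus monomers.

    The generative truth object: C_N is the number concentration (μM of
    particles) of N-mers; monomer_conc + Σ N·C_N equals the total
    concentration in monomer units.
    """

    N_values: np.ndarray       # integer aggregation numbers
    C_N: np.ndarray            # μM of particles per N
    monomer_conc: float        # μM
    total_conc: float          # μM, monomer units
    monomer_mass: float = JB6_MONOMER_KDA
    pH_label: str = "pH8"
    water_fraction: float = 0.65

    def __post_init__(self) -> None:
        self.N_values = np.asarray(self.N_values, dtype=int)
        self.C_N = np.asarray(self.C_N, dtype=float)
        if np.any(self.C_N < 0):
            raise DomainError("concentrations must be nonnegative")
        if not (0 <= self.water_fraction < 1):
            raise DomainError("water fraction must lie in [0, 1)")
        balance = self.monomer_conc + float(np.sum(self.N_values * self.C_N))
        if not np.isclose(balance, self.total_conc, rtol=1e-9, atol=1e-15):
            raise DomainError(
                f"mass balance violated: {balance} != {self.total_conc}"
            )

    @property
    def micellar_conc(self) -> float:
        """Monomer units bound in micelles, μM."""
        return float(np.sum(self.N_values * self.C_N))

    @property
    def number_mean_n(self) -> float:
        """Number-weighted mean aggregation number of the micelles."""
        if self.C_N.sum() == 0:
            raise DomainError("no micelles in population")
        return float(np.sum(self.N_values * self.C_N) / np.sum(self.C_N))

    @property
    def mass_mean_n(self) -> float:
        """Mass-weighted mean aggregation number: Σ N²C_N / Σ N·C_N."""
        denom = np.sum(self.N_values * self.C_N)
        if denom == 0:
            raise DomainError("no micelles in population")
        return float(np.sum(self.N_values**2 * self.C_N) / denom)


def build_population(
    params: PopulationParams,
    total_conc: float,
    pH_label: str = "pH8",
) -> MicellePopulation:
    """Construct the equilibrium population at a given total concentration.

    Monomers saturate at the cmc (monomer_conc = min(total, cmc)); the
    remaining monomer units are distributed over a truncated discretized
    Gaussian in N (or a two-Gaussian mixture for the pH 4 preset).
    """
    if total_conc <= 0:
        raise DomainError("total concentration must be positive")
    try:
        preset = params.presets[pH_label]
    except KeyError:
        raise ConfigurationError(
            f"unknown pH preset {pH_label!r}; known: {sorted(params.presets)}"
        ) from None

    monomer = min(total_conc, params.cmc)
    micellar = total_conc - monomer

    if preset.mode == "power":
        mu = params.meanN_ref * (total_conc / 1.0) ** params.conc_exponent
        sigma = params.relative_width * mu
        modes = [(1.0, mu, sigma)]
    else:
        modes = [(1.0, preset.mu, preset.sigma)]
        if preset.second is not None:
            w2, mu2, s2 = preset.second
            modes = [(1.0 - w2, preset.mu, preset.sigma), (w2, mu2, s2)]

    n_max = int(np.ceil(max(mu_ + 8 * s_ for _, mu_, s_ in modes)))
    n_max = max(n_max, params.N_min + 1)
    n = np.arange(params.N_min, n_max + 1)

    weights = np.zeros_like(n, dtype=float)
    for w, mu_, s_ in modes:
        comp = np.exp(-0.5 * ((n - mu_) / s_) ** 2)
        total_comp = comp.sum()
        if total_comp > 0:
            weights += w * comp / total_comp

    if micellar > 0:
        c_n = micellar * weights / np.sum(n * weights)
    else:
        c_n = np.zeros_like(weights)

    return MicellePopulation(
        N_values=n,
        C_N=c_n,
        monomer_conc=monomer,
        total_conc=total_conc,
        monomer_mass=params.monomer_mass,
        pH_label=pH_label,
        water_fraction=preset.water_fraction,
    )


# ---------------------------------------------------------------------------
# mass photometry events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassNoiseModel:
    """Affine Gaussian mass-measurement noise σ(m) = σ0 + σ1·m.

    Defaults (σ0 = 9 kDa, σ1 = 0.02) reproduce the instrument's mass
    uncertainty at large particle mass: σ(669 kDa) ≈ 22.4 kDa, i.e. a
    full width at half-maximum of ~52 kDa on the 669 kDa standard.  The
    optional low-mass bias emulates the documented overestimation of
    masses below ~40 kDa when the calibration line is extrapolated: an
    additive offset 12·exp(-(m-20)/10) kDa for m < 40 kDa.
    """

    sigma0: float = 9.0   # kDa
    sigma1: float = 0.02  # kDa per kDa
    low_mass_bias: bool = False

    def sigma(self, m: np.ndarray) -> np.ndarray:
        return self.sigma0 + self.sigma1 * np.asarray(m, dtype=float)

    def bias(self, m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        if not self.low_mass_bias:
            return np.zeros_like(m)
        return np.where(m < 40.0, 12.0 * np.exp(-(m - 20.0) / 10.0), 0.0)


@dataclass
class MPEventSet:
    """Single-particle landing events in mass units (kDa)."""

    measured_mass: np.ndarray
    true_N: np.ndarray | None = None
    seed: int | None = None
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        self.measured_mass = np.asarray(self.measured_mass, dtype=float)
        if self.measured_mass.size == 0:
            raise DomainError("event set must be non-empty")
        if not np.all(np.isfinite(self.measured_mass)):
            raise DomainError("measured masses must be finite")


def sample_mp_events(
    pop: MicellePopulation,
    n_events: int,
    noise: MassNoiseModel | None = None,
    seed: int = 0,
) -> MPEventSet:
    """Draw landing events from a population.

    Each event's species is drawn with probability proportional to its
    number concentration (the monomer pool included); the measured mass
    is N·m1 plus Gaussian noise of width σ(m), after the optional
    low-mass bias offset.
    """
    if n_events <= 0:
        raise DomainError("n_events must be positive")
    noise = noise or MassNoiseModel()
    species_n = np.concatenate(([1], pop.N_values))
    species_c = np.concatenate(([pop.monomer_conc], pop.C_N))
    total = species_c.sum()
    if total <= 0:
        raise DomainError("population has no particles to sample")
    p = species_c / total

    rng = np.random.default_rng(seed)
    true_n = rng.choice(species_n, size=n_events, p=p)
    true_mass = true_n * pop.monomer_mass
    center = true_mass + noise.bias(true_mass)
    measured = center + rng.normal(0.0, noise.sigma(true_mass), size=n_events)
    return MPEventSet(measured_mass=measured, true_N=true_n, seed=seed)


def sample_standard_events(
    mass_kda: float,
    n_events: int,
    noise: MassNoiseModel | None = None,
    seed: int = 0,
) -> MPEventSet:
    """Events for a single calibration standard of known mass."""
    if n_events <= 0:
        raise DomainError("n_events must be positive")
    noise = noise or MassNoiseModel()
    rng = np.random.default_rng(seed)
    center = mass_kda + float(noise.bias(np.array(mass_kda)))
    measured = center + rng.normal(0.0, float(noise.sigma(np.array(mass_kda))), size=n_events)
    return MPEventSet(measured_mass=measured, true_N=None, seed=seed)


def mass_to_contrast(
    masses: np.ndarray,
    slope: float = 1e-3,
    intercept: float = 0.0,
    rel_noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Linear optical-contrast layer for calibration tests.

    Contrast = slope·mass + intercept, with optional multiplicative
    Gaussian noise of relative width `rel_noise`.
    """
    masses = np.asarray(masses, dtype=float)
    contrast = slope * masses + intercept
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        contrast = contrast * (1.0 + rng.normal(0.0, rel_noise, size=masses.shape))
    return contrast


# ---------------------------------------------------------------------------
# sedimentation forward map
# ---------------------------------------------------------------------------

def forward_auc(
    pop: MicellePopulation,
    temperature_c: float = 20.0,
    ctx: SvedbergContext | None = None,
    rel_smear: float = 0.05,
    n_grid: int = 500,
    include_monomer: bool = True,
) -> SedimentationDistribution:
    """Mass-weighted sedimentation distribution predicted for a population.

    For each N the sphere packing model (protein volume at ρ_p plus the
    water volume implied by the preset water fraction) gives R_H(N), the
    Svedberg equation gives s(N), and the amplitude is N·C_N (mass
    weighting, as for absorbance detection).  Peaks are smeared with a
    Gaussian of relative width `rel_smear` to emulate finite resolution.
    The monomer appears at its measured R_H of 3.3 nm.
    """
    if ctx is None:
        ctx = SvedbergContext(
            eta=water_viscosity(temperature_c),
            temperature=celsius_to_kelvin(temperature_c),
        )

    s_list: list[float] = []
    a_list: list[float] = []
    occupied = pop.C_N > 0
    if occupied.any():
        n_occ = pop.N_values[occupied]
        masses = n_occ * pop.monomer_mass
        radii = micelle_radius(masses, pop.water_fraction, ctx)
        for m, r, n_i, c in zip(masses, np.atleast_1d(radii), n_occ, pop.C_N[occupied]):
            s_list.append(sedimentation_coefficient(float(m), float(r), ctx))
            a_list.append(float(n_i * c))
    if include_monomer and pop.monomer_conc > 0:
        s_list.append(sedimentation_coefficient(pop.monomer_mass, MONOMER_RH_NM, ctx))
        a_list.append(pop.monomer_conc)
    if not s_list:
        raise DomainError("population is empty")

    s_peaks = np.asarray(s_list)
    amps = np.asarray(a_list)
    lo = max(1e-3, 0.5 * s_peaks.min())
    hi = 1.5 * s_peaks.max()
    grid = np.linspace(lo, hi, n_grid)
    dist = np.zeros_like(grid)
    for s0, a0 in zip(s_peaks, amps):
        width = max(rel_smear * s0, 1e-9)
        kernel = np.exp(-0.5 * ((grid - s0) / width) ** 2)
        kernel_sum = kernel.sum()
        if kernel_sum > 0:
            dist += a0 * kernel / kernel_sum
    return SedimentationDistribution(
        s_values=grid,
        amplitudes=dist,
        temperature=celsius_to_kelvin(temperature_c),
        corrected_to_20C=abs(temperature_c - 20.0) < 1e-12,
    )


# ---------------------------------------------------------------------------
# dissociation kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Arrhenius dissociation kinetics of the micelles.

    The rate constant follows k(T) = k_ref·exp(-(Ea/R)(1/T - 1/T_ref)),
    an Arrhenius law through the anchor (k_ref, T_ref).  Defaults place
    the dissociation timescale 1/k at 20 min at 37 °C with an activation
    energy of 250 kJ/mol, which puts dissociation at room temperature on
    the scale of tens of hours.  Plateau radii c(T) interpolate linearly
    between 4.5 nm at 22 °C and 3.3 nm at 40 °C (more micelles survive
    dilution at lower temperature); amplitudes a(T) are chosen so the
    initial mean radius is ~9.3 nm at every temperature.
    """

    Ea: float = 250.0                    # kJ/mol
    k_ref: float = 1.0 / 1200.0          # 1/s at T_ref
    T_ref: float = celsius_to_kelvin(37.0)  # K
    plateau_by_T: tuple = ((celsius_to_kelvin(22.0), 4.5), (celsius_to_kelvin(40.0), 3.3))
    amplitude_by_T: tuple = ((celsius_to_kelvin(22.0), 4.8), (celsius_to_kelvin(40.0), 6.0))
    noise_sd: float = 0.3                # nm

    def __post_init__(self) -> None:
        if self.Ea <= 0 or self.k_ref <= 0:
            raise DomainError("Ea and k_ref must be positive")
        if any(c <= 0 for _, c in self.plateau_by_T):
            raise DomainError("plateau radii must be positive")

    def rate(self, temperature_k: float) -> float:
        """Arrhenius rate constant at temperature T (K)."""
        exponent = -(self.Ea * 1000.0 / R_GAS) * (1.0 / temperature_k - 1.0 / self.T_ref)
        return self.k_ref * np.exp(exponent)

    def _interp(self, table: tuple, temperature_k: float) -> float:
        ts = np.array([t for t, _ in table])
        vs = np.array([v for _, v in table])
        order = np.argsort(ts)
        return float(np.interp(temperature_k, ts[order], vs[order]))

    def plateau(self, temperature_k: float) -> float:
        return self._interp(self.plateau_by_T, temperature_k)

    def amplitude(self, temperature_k: float) -> float:
        return self._interp(self.amplitude_by_T, temperature_k)


def simulate_dissociation(
    kparams: KineticParams,
    temperatures_k: Sequence[float],
    times_s: Sequence[float] | None = None,
    replicates: int = 3,
    seed: int = 0,
    n_points: int = 25,
) -> list[SizeTimeSeries]:
    """Simulate ⟨R_H⟩(t) = a·e^(-k(T)t) + c dissociation series.

    With ``times_s=None`` each temperature gets its own grid spanning
    four decay times (25 points), mirroring how slow series are followed
    for days and fast ones for minutes.  Each replicate receives
    independent additive Gaussian noise of sd `kparams.noise_sd`.
    """
    temperatures_k = list(temperatures_k)
    if not temperatures_k:
        raise DomainError("need at least one temperature")
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    if times_s is not None:
        times_arr = np.asarray(times_s, dtype=float)
        if np.any(times_arr < 0) or np.any(np.diff(times_arr) <= 0):
            raise DomainError("times must be nonnegative and strictly increasing")

    rng = np.random.default_rng(seed)
    out: list[SizeTimeSeries] = []
    for t_k in temperatures_k:
        k = kparams.rate(t_k)
        a = kparams.amplitude(t_k)
        c = kparams.plateau(t_k)
        t = (
            np.asarray(times_s, dtype=float)
            if times_s is not None
            else np.linspace(0.0, 4.0 / k, n_points)
        )
        clean = a * np.exp(-k * t) + c
        for rep in range(replicates):
            noisy = clean + rng.normal(0.0, kparams.noise_sd, size=t.shape) if kparams.noise_sd > 0 else clean.copy()
            out.append(
                SizeTimeSeries(
                    times=t.copy(),
                    values=noisy,
                    sd=np.full_like(t, kparams.noise_sd) if kparams.noise_sd > 0 else None,
                    temperature=float(t_k),
                    replicate_id=rep,
                )
            )
    return out


# ---------------------------------------------------------------------------
# refractometry
# ---------------------------------------------------------------------------

#: Default concentration series, mg/ml: a ~1.5-fold dilution ladder from
#: 12.5 mg/ml down to ~0.1 mg/ml as used for the refractive-index scans.
DEFAULT_REFRACT_CONCS = tuple(12.5 / 1.5**i for i in range(12) if 12.5 / 1.5**i >= 0.1)


@dataclass
class RefractometrySeries:
    """Refractive index versus protein mass concentration."""

    concentrations: np.ndarray  # mg/ml
    n_values: np.ndarray        # refractive index
    wavelength_nm: float = 546.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.n_values = np.asarray(self.n_values, dtype=float)
        if np.any(self.concentrations < 0):
            raise DomainError("concentrations must be nonnegative")


def simulate_refractometry(
    dndc: float = 0.17,
    n0: float = 1.3340,
    concentrations: Sequence[float] = DEFAULT_REFRACT_CONCS,
    noise_sd: float = 2e-5,
    seed: int = 0,
    wavelength_nm: float = 546.0,
) -> RefractometrySeries:
    """n(c) = n0 + (dn/dc)·c/1000 plus Gaussian read noise.

    dn/dc in ml/g, c in mg/ml (hence the factor 1000).  The default read
    noise, 2e-5 index units, is ~1% of the total index increment at the
    top of the default concentration ladder.
    """
    if dndc < 0:
        raise DomainError("dn/dc must be nonnegative")
    c = np.asarray(list(concentrations), dtype=float)
    n = n0 + dndc * c / 1000.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        n = n + rng.normal(0.0, noise_sd, size=c.shape)
    return RefractometrySeries(concentrations=c, n_values=n, wavelength_nm=wavelength_nm)
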
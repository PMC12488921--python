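# Methods

## The system and the measurement model

The package models a protein that self-assembles into finite-size
equilibrium micelles: above a critical micelle concentration (cmc) the
free-monomer pool saturates and added protein enters micelles whose
aggregation numbers N are broadly distributed. Three observables are
modelled and analysed jointly:

* **Mass photometry (MP)** counts single particles landing on a surface;
  scattering contrast is proportional to particle mass, so after linear
  calibration each event is a mass. Raw counts are number-weighted.
* **Sedimentation velocity (AUC)** yields a distribution of sedimentation
  coefficients; absorbance detection makes it mass-weighted.
* **Microfluidic diffusional sizing (MDS)** yields the average
  hydrodynamic radius ⟨R_H⟩ of everything in solution.

## Population model (synthetic generator)

The generator's job is to emulate the study conditions, not to be a
thermodynamic theory. Its choices:

* **Monomer pool**: monomer_conc = min(total, cmc) with cmc = 0.12 μM.
  Below the cmc there are no micelles at all. This is the ideal
  pseudo-phase-separation limit; the real crossover is smooth.
* **Size distribution**: a discretized Gaussian in N, truncated at
  N_min = 5 and renormalized. Truncation encodes the instability of small
  oligomers (too much exposed hydrophobic surface); the Gaussian is the
  minimal two-parameter shape reproducing a broad single maximum. The pH 4
  preset is a two-Gaussian mixture (weight 0.15 on a mode at N = 40) to
  produce the bimodal transition-region distribution.
* **Concentration dependence**: for the near-neutral presets the mean
  follows μ_N = 20·(C/1 μM)^0.1505, a power law chosen so that μ_N doubles
  (20→40) between 1 and 100 μM. The relative width σ_N/μ_N = 0.22 makes
  the mass-weighted mean of the 30 μM population ≈ 35, consistent with the
  number-mean law (for a Gaussian, mass-mean ≈ μ(1 + cv²)).
* **pH presets**: pH 5/7.4/8 share the power law and a water mass fraction
  of 0.65; pH 2/3 are fixed narrow distributions (μ_N = 9.6, σ_N = 2.0,
  mass-mean ≈ 10) with water fraction 0.90; pH 4 is bimodal with 0.88.
  These mirror the observed collapse of ⟨N⟩ and rise in hydration when the
  C-terminal domain unfolds below pH 5.
* **Mass noise**: affine σ(m) = 9 + 0.02·m kDa. Only one width anchor is
  available (σ·2.355 ≈ 52 kDa at 669 kDa); the affine form is the simplest
  extrapolation that keeps small masses from having near-zero noise. The
  optional low-mass bias (+12·e^(−(m−20)/10) kDa below 40 kDa) documents,
  qualitatively only, the overestimation of masses below the ~40 kDa
  reliable-quantification limit.
* **Dissociation kinetics**: k(T) = k_ref·exp(−(E_a/R)(1/T − 1/T_ref))
  with E_a = 250 kJ/mol and 1/k_ref = 20 min at T_ref = 310.15 K. Plateau
  radii interpolate linearly from 4.5 nm (22 °C) to 3.3 nm (40 °C);
  amplitudes are set so every series starts near 9.3 nm. Per-point noise
  sd defaults to 0.3 nm. Auto-generated time grids span four decay times
  (25 points), mirroring how slow series are followed for days and fast
  ones for minutes.
* **Refractometry**: n(c) = n0 + (dn/dc)·c/1000 on a 1.5-fold dilution
  ladder from 12.5 down to 0.1 mg/ml, read noise 2e-5 index units (~1% of
  the full increment).

What the generator does **not** emulate: landing-rate/surface kinetics and
focus drift in MP, diffusion-broadening and meniscus effects in AUC (peaks
are Gaussian-smeared with 5% relative width instead), instrument-specific
MDS binning, and any smooth monomer/micelle crossover near the cmc. Tests
passing on generator data therefore validate the analysis chain's
correctness and calibration, not robustness to those instrument artifacts.

## Hydrodynamics

The Svedberg relation s = m_p(1 − ρ_w/ρ_p)/(6πηR_H) is used with
ρ_p = 1.39 g/ml and ρ_w = 1.00 g/ml (both configurable). Particle radii in
the generator come from a sphere packing model: volume = protein volume at
ρ_p plus water volume implied by the preset water mass fraction. The same
calculus inverted (packing density → water fraction) is an exact
closed loop, which the tests exploit.

**s20,w correction** multiplies by the viscosity ratio and, by default,
the buoyancy-density ratio; a `viscosity_only` flag gives the reduced
correction since published conventions differ. Water viscosity/density are
linearly interpolated from CRC tables at 0–40 °C (5 °C spacing plus 37 °C;
interpolation error < 0.5%, well under the instrumental s uncertainty).

**Fusion** of the two mass-weighted distributions is by quantile matching:
both are normalized to cumulative weight using bin-midpoint conventions,
and each sedimentation bin takes the mass at its cumulative quantile
(piecewise-linear interpolation between mass-bin centers). This is
monotone, parameter-free and degenerate-safe (a single-species pair reduces
to direct Svedberg inversion). Because the sedimentation distribution is
instrumentally smeared while the mass histogram is not, the extreme tails
of the quantile map are unconstrained; recovery guarantees are therefore
stated over the central 90% of the fused weight.

## Kinetics fitting

Decay fits use bounded nonlinear least squares (k ≥ 0) from a fixed
three-start grid (k₀ = 1/span, 3/span, 1/(3·span); a₀ = first − last,
c₀ = last), inverse-variance weighted when per-point sd is present. A
series whose range is below three median sd is returned as degenerate
(a = 0, k = 0, c = mean) rather than fitted. The Arrhenius step is plain
OLS of ln k on 1/T — errors-in-variables are ignored, matching the
straight-line Arrhenius treatment; replicate series contribute separate
points and rates from different measurement modes (sizing vs the
single-particle oligomer-mass reporter) pool into the same regression.

## Solution chemistry

Net charge uses Henderson–Hasselbalch terms per ionizable group with a
model-compound pKa set (D 3.5, E 4.2, C 6.8, Y 10.3, H 6.6, K 10.5, R 12.0,
termini 8.0/3.3). The set is an explicit, provenance-labelled input: model
pKa values ignore structural shifts, which is exactly the intended
approximation for a charge-vs-pH overview. Phosphate speciation uses the
full triprotic fractions (pKa 2.15/7.21/12.33) with Na⁺ from
electroneutrality; only pKa2 matters near pH 8. The Debye length is
computed from fundamental constants (ε_r = 78.5, T = 295 K default); the
0.304 nm·M^½ shortcut appears only in tests as an independent oracle.

The bundled 241-residue FASTA is a **synthetic stand-in**: its length,
~26.9 kDa mass and ionizable-residue counts (14 K, 13 R, 12 H, 13 D, 13 E,
2 C, 4 Y) were designed so its charge curve matches the chaperone's
reported behaviour (≈ +40 at pH 2, weakly negative at pH 8). It is not the
real sequence and must not be used for any sequence-specific analysis
beyond exercising the charge calculators.

## Numerical and design choices

* FWHM/σ is fixed at 2.355 (the conventional rounding of 2√(2 ln 2);
  difference < 0.02%).
* Histogram bins are anchored so centers sit at integer multiples of the
  monomer mass, making N assignment exact for noiseless data; sub-40 kDa
  masses are flagged, never dropped.
* Calibration peak location fits a Gaussian to the dominant mode within
  ±20% of the modal bin (robust to dimer satellites); degenerate windows
  fall back to the windowed mean. Non-monotone peak-vs-mass orderings are
  rejected as calibration errors.
* The mean-aggregation default is mass-weighted with n_min = 3 (the N > 2
  micelle convention); both weightings are reportable and the result
  carries its weighting flag.
* All randomness flows from one global seed through SHA-256-derived
  per-stage substreams (< 2³¹), so disabling a stage never shifts another
  stage's stream and identical configurations reproduce outputs byte for
  byte.
* Problem sizes used in the shipped checks — 10⁴ landing events, 7
  temperatures × 3 replicates × 25 time points, 500-point s-grids — match
  the scale of the corresponding experiments and keep every stage
  effectively instantaneous.

## Known limitations

* The pseudo-phase cmc model makes micellar mass exactly zero below the
  cmc; real distributions cross over smoothly.
* Fusion assumes both distributions sample the same population with the
  same weighting; systematic MP/AUC discrepancies (e.g. surface selection
  in MP) would bias R_H in ways the package does not model.
* The packing model treats particles as uniform spheres; frictional-ratio
  or shape effects are out of scope.
* No mechanistic dissociation model (e.g. stepwise monomer loss) is
  provided; the single exponential is the asserted model class.
* The ionic-strength calculator ignores activity coefficients, and the
  charge model ignores pKa shifts from structure or charge regulation.
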
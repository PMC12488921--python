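"""Mass-photometry analysis: calibration, histograms and aggregation statistics.

Single-particle landing events arrive as interferometric contrasts and
are converted to masses through a linear calibration against standard
proteins of known mass.  Histograms are binned at the monomer mass so
that each bin corresponds to an aggregation number N; raw (number-
weighted) counts can be converted to mass weighting by multiplying by N,
which makes them comparable to absorbance-based sedimentation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, signal

from .constants import FWHM_PER_SIGMA
from .errors import CalibrationError, ConfigurationError, DomainError, WeightingError

#: Monomer mass of the DNAJB6b chaperone subunit, kDa.
JB6_MONOMER_KDA = 26.9

#: Lower limit of reliable single-particle mass quantification, kDa.
RELIABLE_MASS_MIN_KDA = 40.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear contrast-vs-mass calibration from standard proteins."""

    slope: float                  # contrast per kDa
    intercept: float              # contrast
    valid_mass_min: float = RELIABLE_MASS_MIN_KDA
    fit_residual_sd: float = 0.0  # contrast units
    standards: tuple = ()         # (name, nominal_mass_kDa, fitted_peak_contrast)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")
        if self.valid_mass_min < 0:
            raise CalibrationError("valid_mass_min must be nonnegative")


class CalibratedMasses(NamedTuple):
    """Masses in kDa plus a flag for events below the reliable-mass limit."""

    masses: np.ndarray
    below_limit: np.ndarray  # boolean mask; flagged, never dropped


class MeanAggregation(NamedTuple):
    value: float
    weighting: str
    n_min: int


@dataclass
class MassHistogram:
    """Binned particle-mass distribution with an explicit weighting flag."""

    bin_edges: np.ndarray        # kDa, uniform
    counts: np.ndarray
    weighting: str               # "number" or "mass"
    monomer_mass: float = JB6_MONOMER_KDA
    n_events: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.weighting not in ("number", "mass"):
            raise ValueError("weighting must be 'number' or 'mass'")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_values(self) -> np.ndarray:
        """Aggregation number assigned to each bin (nearest monomer multiple)."""
        return np.rint(self.bin_centers / self.monomer_mass).astype(int)


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_peak(values: np.ndarray, n_bins: int = 60) -> float:
    """Locate the dominant mode of an event sample by a local Gaussian fit.

    A histogram's tallest bin seeds a Gaussian fit restricted to ±20% of
    the mode location, which keeps satellite peaks (e.g. dimers of a
    standard) from biasing the fitted center.  When the windowed sample
    is too narrow to constrain a Gaussian (fewer than 5 occupied bins)
    the mean of the windowed events is used instead.
    """
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = centers[np.argmax(counts)]
    half_width = 0.2 * abs(mode) if mode != 0 else 0.2 * max(np.ptp(values), 1e-12)
    in_window = values[np.abs(values - mode) <= half_width]
    sel = (np.abs(centers - mode) <= half_width) & (counts > 0)
    if sel.sum() < 5:
        return float(np.mean(in_window))
    p0 = [counts.max(), mode, max(np.std(in_window), half_width / 10.0)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gaussian, centers[sel], counts[sel], p0=p0, maxfev=10000
            )
        fitted = float(popt[1])
    except RuntimeError:
        return float(np.mean(in_window))
    # reject a runaway fit that left the window
    if abs(fitted - mode) > half_width:
        return float(np.mean(in_window))
    return fitted


def fit_calibration(
    standards: Sequence[tuple],
    valid_mass_min: float = RELIABLE_MASS_MIN_KDA,
) -> CalibrationCurve:
    """Least-squares linear calibration from (nominal_mass, contrast_events) pairs.

    Each standard may optionally carry a name: entries are either
    ``(mass_kDa, events)`` or ``(name, mass_kDa, events)``.  The dominant
    contrast mode of each standard is located by a Gaussian fit and the
    line contrast = slope·mass + intercept is fitted through the peaks.
    """
    parsed = []
    for entry in standards:
        if len(entry) == 3:
            name, mass, events = entry
        else:
            mass, events = entry
            name = f"{mass:g}kDa"
        events = np.asarray(events, dtype=float)
        if events.size < 50:
            raise ConfigurationError(f"standard {name}: need >= 50 events, got {events.size}")
        parsed.append((str(name), float(mass), events))

    masses = np.array([p[1] for p in parsed])
    if len(np.unique(masses)) < 2:
        raise ConfigurationError("need at least 2 standards with distinct masses")

    peaks = np.array([_fit_peak(p[2]) for p in parsed])
    order = np.argsort(masses)
    if np.any(np.diff(peaks[order]) <= 0):
        raise CalibrationError("fitted peak contrasts are not monotone in mass")

    slope, intercept = np.polyfit(masses, peaks, 1)
    residuals = peaks - (slope * masses + intercept)
    dof = max(len(masses) - 2, 1)
    resid_sd = float(np.sqrt(np.sum(residuals**2) / dof))
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        valid_mass_min=valid_mass_min,
        fit_residual_sd=resid_sd,
        standards=tuple((p[0], p[1], float(pk)) for p, pk in zip(parsed, peaks)),
    )


def apply_calibration(contrast_events: np.ndarray, calib: CalibrationCurve) -> CalibratedMasses:
    """Convert contrasts to masses; sub-limit masses are flagged, not dropped."""
    contrasts = np.asarray(contrast_events, dtype=float)
    if calib.slope == 0:
        raise CalibrationError("calibration slope is zero")
    masses = (contrasts - calib.intercept) / calib.slope
    return CalibratedMasses(masses=masses, below_limit=masses < calib.valid_mass_min)


def build_histogram(
    masses: np.ndarray,
    monomer_mass: float = JB6_MONOMER_KDA,
    bin_width: float | None = None,
) -> MassHistogram:
    """Histogram of event masses with bins centered on monomer multiples.

    With the default bin width equal to the monomer mass, bin k spans
    ((k-1/2)·m1, (k+1/2)·m1] so its center is exactly k·m1 and the N
    assignment of noiseless integer-multiple data is exact.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size == 0:
        raise DomainError("cannot histogram an empty mass array")
    if bin_width is None:
        bin_width = monomer_mass
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    k_min = int(np.floor(masses.min() / bin_width + 0.5))
    k_max = int(np.floor(masses.max() / bin_width + 0.5))
    edges = (np.arange(k_min, k_max + 2) - 0.5) * bin_width
    counts, _ = np.histogram(masses, bins=edges)
    return MassHistogram(
        bin_edges=edges,
        counts=counts.astype(float),
        weighting="number",
        monomer_mass=monomer_mass,
        n_events=int(masses.size),
    )


def to_mass_weighted(hist: MassHistogram) -> MassHistogram:
    """Multiply each bin count by its aggregation number N.

    Converts a number-weighted histogram into the mass weighting used by
    absorbance-based methods; refuses to weight twice.
    """
    if hist.weighting == "mass":
        raise WeightingError("histogram is already mass-weighted")
    return MassHistogram(
        bin_edges=hist.bin_edges.copy(),
        counts=hist.counts * hist.n_values,
        weighting="mass",
        monomer_mass=hist.monomer_mass,
        n_events=hist.n_events,
    )


def mean_aggregation_number(hist: MassHistogram, n_min: int = 3) -> MeanAggregation:
    """Mean aggregation number over bins with N >= n_min.

    The mean is taken under the histogram's declared weighting (a
    mass-weighted histogram yields the mass-weighted mean).  The default
    n_min = 3 restricts the statistic to micellar species (N > 2).
    """
    if n_min < 1:
        raise DomainError("n_min must be >= 1")
    n = hist.n_values
    sel = n >= n_min
    w = hist.counts[sel]
    if w.sum() <= 0:
        raise DomainError(f"no occupied bins with N >= {n_min}")
    value = float(np.sum(n[sel] * w) / np.sum(w))
    return MeanAggregation(value=value, weighting=hist.weighting, n_min=n_min)


def oligomer_mass_total(hist: MassHistogram, n_min: int = 3) -> float:
    """Total micellar mass reporter: sum of count·bin_mass over N >= n_min.

    Expects number weighting (raw counts); the product count·mass is the
    mass-weighted contribution of each bin.
    """
    if hist.weighting != "number":
        raise WeightingError("oligomer_mass_total expects a number-weighted histogram")
    sel = hist.n_values >= n_min
    return float(np.sum(hist.counts[sel] * hist.bin_centers[sel]))


def gaussian_peak_fwhm(hist: MassHistogram, window: tuple[float, float]) -> tuple[float, float]:
    """Fit a Gaussian to the histogram within `window`; return (σ, FWHM).

    FWHM = 2.355·σ by the conventional Gaussian relation.  Emits a
    fit-quality warning when the windowed data are not unimodal.
    """
    lo, hi = window
    centers = hist.bin_centers
    sel = (centers >= lo) & (centers <= hi) & (hist.counts > 0)
    if sel.sum() < 5:
        raise DomainError("window must contain at least 5 occupied bins")
    x, y = centers[sel], hist.counts[sel]
    # a secondary mode counts only when prominent (>25% of the peak height);
    # Poisson wiggles on a single peak must not trigger the warning
    peaks, _ = signal.find_peaks(y, prominence=0.25 * y.max())
    if peaks.size > 1:
        warnings.warn("window is not unimodal; Gaussian fit may be poor", stacklevel=2)
    p0 = [y.max(), x[np.argmax(y)], 0.25 * (hi - lo)]
    popt, _ = optimize.curve_fit(_gaussian, x, y, p0=p0, maxfev=10000)
    sigma = abs(float(popt[2]))
    return sigma, FWHM_PER_SIGMA * sigma


def particle_concentration(total_conc: float, mean_n: float) -> float:
    """Particle (micelle) concentration from monomer-unit concentration.

    Works in any concentration unit; e.g. 200 nM monomer units at
    ⟨N⟩ = 20 gives 10 nM particles.
    """
    if mean_n < 1:
        raise DomainError("mean aggregation number must be >= 1")
    return total_conc / mean_n


def monomer_dimer(c_total: float, k2: float) -> tuple[float, float]:
    """Monomer-dimer equilibrium: solve c1 + 2 K2 c1^2 = c_total.

    K2 = c2/c1^2 is the dimerization association constant (1/M when
    concentrations are molar).  Returns (c1, c2) from the positive root.
    """
    if c_total < 0 or k2 < 0:
        raise DomainError("concentrations and K2 must be nonnegative")
    if k2 == 0:
        return c_total, 0.0
    c1 = (-1.0 + np.sqrt(1.0 + 8.0 * k2 * c_total)) / (4.0 * k2)
    c2 = k2 * c1**2
    return float(c1), float(c2)
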
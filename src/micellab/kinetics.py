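"""Dissociation kinetics: single-exponential decay fits and Arrhenius analysis.

Micelle dissociation after a step dilution is followed through the mean
hydrodynamic radius ⟨R_H⟩(t) (or through the total micellar mass seen by
single-particle counting) and fitted to

    ⟨R_H⟩(t) = a·exp(-k t) + c ,

a single exponential, consistent with one rate-limiting step.  Rate
constants measured at several temperatures are combined in an Arrhenius
plot, ln k versus 1/T, whose slope gives the activation energy

    k(T) = A·exp(-E_a / R T) .
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .constants import R_GAS
from .errors import DomainError, FitError


@dataclass
class SizeTimeSeries:
    """A dissociation time course at one temperature.

    values are ⟨R_H⟩ in nm by default; the unit tag allows the same
    container to carry the single-particle oligomer-mass reporter (kDa).
    """

    times: np.ndarray            # s
    values: np.ndarray
    sd: np.ndarray | None = None  # per-point standard deviation
    temperature: float = 295.15   # K
    replicate_id: int = 0
    unit: str = "nm"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("values must be finite")


@dataclass
class DecayFit:
    """Fitted single-exponential decay a·e^(-kt) + c."""

    a: float
    k: float              # 1/s
    c: float
    covariance: np.ndarray
    rms_residual: float
    degenerate: bool = False  # near-constant series, parameters not identifiable

    def __post_init__(self) -> None:
        if self.k < 0:
            raise DomainError("rate constant must be nonnegative")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.k * np.asarray(t, dtype=float)) + self.c


@dataclass
class ArrheniusFit:
    """Arrhenius regression of ln k on 1/T."""

    Ea: float             # kJ/mol
    lnA: float            # ln of 1/s
    se_Ea: float          # kJ/mol
    points: tuple         # (T_K, k_per_s, source) triples

    def rate(self, temperature_k: float) -> float:
        return float(np.exp(self.lnA - self.Ea * 1000.0 / (R_GAS * temperature_k)))


def _decay(t, a, k, c):
    return a * np.exp(-k * t) + c


def fit_decay(series: SizeTimeSeries) -> DecayFit:
    """Nonlinear least-squares fit of a single exponential decay.

    Uses inverse-variance weighting when per-point sd is available and a
    fixed three-start initialization grid (k0, 3k0, k0/3 around the
    inverse time span) to guard against local minima.  A series whose
    range is below three median standard deviations is reported as
    degenerate with a = 0, k = 0, c = mean.
    """
    t, y = series.times, series.values
    if t.size < 4:
        raise DomainError("need at least 4 time points")
    sigma = series.sd if series.sd is not None and np.all(series.sd > 0) else None

    value_range = float(np.ptp(y))
    if sigma is not None and value_range < 3.0 * float(np.median(sigma)):
        c = float(np.mean(y))
        return DecayFit(
            a=0.0, k=0.0, c=c,
            covariance=np.zeros((3, 3)),
            rms_residual=float(np.sqrt(np.mean((y - c) ** 2))),
            degenerate=True,
        )

    span = t[-1] - t[0]
    a0 = y[0] - y[-1]
    c0 = y[-1]
    best = None
    errors = []
    for k0 in (1.0 / span, 3.0 / span, 1.0 / (3.0 * span)):
        try:
            popt, pcov = optimize.curve_fit(
                _decay, t, y, p0=[a0, k0, c0], sigma=sigma,
                absolute_sigma=sigma is not None, maxfev=20000,
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            )
        except RuntimeError as exc:  # non-convergence for this start
            errors.append(str(exc))
            continue
        rms = float(np.sqrt(np.mean((y - _decay(t, *popt)) ** 2)))
        if best is None or rms < best[2]:
            best = (popt, pcov, rms)
    if best is None:
        raise FitError(f"decay fit failed from all starts: {errors}")
    popt, pcov, rms = best
    return DecayFit(
        a=float(popt[0]), k=float(popt[1]), c=float(popt[2]),
        covariance=np.asarray(pcov), rms_residual=rms,
    )


def fit_arrhenius(points: Sequence[tuple]) -> ArrheniusFit:
    """Ordinary least squares of ln k on 1/T.

    `points` are (T_K, k) or (T_K, k, source) tuples; Ea = -slope·R in
    kJ/mol, lnA is the intercept, and se_Ea follows from the regression
    standard error of the slope.
    """
    parsed = []
    for p in points:
        t_k, k = p[0], p[1]
        source = p[2] if len(p) > 2 else "unknown"
        if k <= 0:
            raise DomainError("rate constants must be positive")
        parsed.append((float(t_k), float(k), source))
    temps = np.array([p[0] for p in parsed])
    if np.unique(temps).size < 2:
        raise DomainError("need at least 2 distinct temperatures")
    x = 1.0 / temps
    y = np.log([p[1] for p in parsed])
    res = stats.linregress(x, y)
    ea_kj = -res.slope * R_GAS / 1000.0
    se_ea = (res.stderr if np.isfinite(res.stderr) else 0.0) * R_GAS / 1000.0
    return ArrheniusFit(
        Ea=float(ea_kj), lnA=float(res.intercept), se_Ea=float(se_ea),
        points=tuple(parsed),
    )


def rate_and_timescale(fit: ArrheniusFit, temperature_k: float) -> tuple[float, float]:
    """Rate constant k (1/s) and timescale 1/k (s) at a given temperature."""
    k = fit.rate(temperature_k)
    return k, 1.0 / k


def arrhenius_from_series(
    series_list: Sequence[SizeTimeSeries], source: str = "MDS"
) -> ArrheniusFit:
    """Full pipeline: fit each series to a decay, then regress ln k on 1/T.

    Every non-degenerate series contributes one (T, k) point; replicate
    series at the same temperature enter as separate points, which the
    ordinary least-squares regression averages naturally.
    """
    points = []
    for s in series_list:
        fit = fit_decay(s)
        if not fit.degenerate and fit.k > 0:
            points.append((s.temperature, fit.k, source))
    if len(points) < 2:
        raise FitError("fewer than two usable rate constants")
    return fit_arrhenius(points)
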
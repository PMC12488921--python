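"""Solution-chemistry calculators: protein net charge, buffer speciation,
ionic strength, Debye length and refractive-index-increment fits.

The net charge of a protein at a given pH is computed from the
Henderson-Hasselbalch relation with model-compound pKa values applied
to each ionizable group: basic groups (K, R, H and the N-terminus)
contribute +1/(1 + 10^(pH-pKa)) and acidic groups (D, E, C, Y and the
C-terminus) contribute -1/(1 + 10^(pKa-pH)).  The same speciation logic
applied to phosphate gives the ionic strength of sodium-phosphate
buffers, from which the Debye screening length follows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from scipy import optimize, stats

from .constants import (
    E_CHARGE,
    EPSILON_0,
    K_BOLTZMANN,
    N_AVOGADRO,
)
from .errors import DomainError, FitError
from .synthetic import RefractometrySeries

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PKaSet:
    """Model-compound pKa values for the ionizable groups of a protein.

    The default set is a standard model-compound table; it is an input,
    not a structural prediction, and can be swapped for any other
    published set via the constructor.
    """

    D: float = 3.5
    E: float = 4.2
    C: float = 6.8
    Y: float = 10.3
    H: float = 6.6
    K: float = 10.5
    R: float = 12.0
    n_term: float = 8.0
    c_term: float = 3.3
    provenance: str = "model-compound defaults"

    def __post_init__(self) -> None:
        for name in ("D", "E", "C", "Y", "H", "K", "R", "n_term", "c_term"):
            v = getattr(self, name)
            if not (0 < v < 14):
                raise DomainError(f"pKa for {name} must lie in (0, 14), got {v}")


@dataclass(frozen=True)
class IonSpecies:
    name: str
    charge: int
    concentration: float  # mM

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DomainError("concentration must be nonnegative")


@dataclass(frozen=True)
class DnDcFit:
    """Linear refractive-index-increment fit n(c) = n0 + (dn/dc)·c."""

    dndc: float        # ml/g
    n0: float
    r_squared: float
    wavelength_nm: float = 546.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.dndc):
            raise FitError("dn/dc is not finite")
        if not (0 < self.n0 < 2):
            raise FitError(f"implausible zero-concentration index {self.n0}")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    bad = set(seq) - _STANDARD_AA
    if bad:
        raise DomainError(f"unknown residue codes: {sorted(bad)}")
    if not seq:
        raise DomainError("empty sequence")
    return seq


def net_charge(sequence: str, pH: float, pkas: PKaSet | None = None) -> float:
    """Net charge (elementary charges) of a sequence at a given pH."""
    pkas = pkas or PKaSet()
    seq = _validate_sequence(sequence)
    z = 1.0 / (1.0 + 10.0 ** (pH - pkas.n_term))
    z -= 1.0 / (1.0 + 10.0 ** (pkas.c_term - pH))
    for res in _BASIC:
        z += seq.count(res) / (1.0 + 10.0 ** (pH - getattr(pkas, res)))
    for res in _ACIDIC:
        z -= seq.count(res) / (1.0 + 10.0 ** (getattr(pkas, res) - pH))
    return float(z)


def charge_curve(
    sequence: str, pH_grid: Sequence[float], pkas: PKaSet | None = None
) -> np.ndarray:
    """Net charge evaluated over a pH grid (non-increasing in pH)."""
    grid = np.asarray(pH_grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 14):
        raise DomainError("pH grid must lie within (0, 14)")
    return np.array([net_charge(sequence, ph, pkas) for ph in grid])


def isoelectric_point(sequence: str, pkas: PKaSet | None = None) -> float:
    """pH at which the net charge crosses zero (bisection on the curve)."""
    f = lambda ph: net_charge(sequence, ph, pkas)
    return float(optimize.brentq(f, 0.01, 13.99))


#: Standard phosphoric-acid pKa triplet.
PHOSPHATE_PKAS = (2.15, 7.21, 12.33)


def phosphate_speciation(
    total_phosphate: float,
    pH: float,
    pka_triplet: tuple[float, float, float] = PHOSPHATE_PKAS,
) -> list[IonSpecies]:
    """Sodium-phosphate buffer speciation at a given pH.

    Henderson-Hasselbalch fractions of H3PO4/H2PO4-/HPO4(2-)/PO4(3-)
    from the three pKa values; the sodium counter-ion concentration
    follows from electroneutrality of the buffer salt.
    Concentrations in mM.
    """
    if total_phosphate <= 0:
        raise DomainError("total phosphate must be positive")
    if not (0 < pH < 14):
        raise DomainError("pH must lie in (0, 14)")
    pk1, pk2, pk3 = pka_triplet
    h = 10.0 ** (-pH)
    k1, k2, k3 = (10.0 ** (-p) for p in (pk1, pk2, pk3))
    terms = np.array([h**3, h**2 * k1, h * k1 * k2, k1 * k2 * k3])
    alpha = terms / terms.sum()
    c = total_phosphate * alpha
    na = 1.0 * c[1] + 2.0 * c[2] + 3.0 * c[3]
    return [
        IonSpecies("H3PO4", 0, float(c[0])),
        IonSpecies("H2PO4-", -1, float(c[1])),
        IonSpecies("HPO4 2-", -2, float(c[2])),
        IonSpecies("PO4 3-", -3, float(c[3])),
        IonSpecies("Na+", +1, float(na)),
    ]


def ionic_strength(species: Sequence[IonSpecies]) -> float:
    """Ionic strength I = 1/2 Σ c_i z_i², in mM.

    Warns when the species list is not electroneutral (within 1% of the
    total charge concentration).
    """
    charge = sum(s.charge * s.concentration for s in species)
    scale = sum(abs(s.charge) * s.concentration for s in species)
    if scale > 0 and abs(charge) > 0.01 * scale:
        warnings.warn(
            f"species list is not electroneutral (net {charge:.3g} mM charge)",
            stacklevel=2,
        )
    return 0.5 * sum(s.concentration * s.charge**2 for s in species)


def debye_length(I_mM: float, temperature_k: float = 295.0, eps_r: float = 78.5) -> float:
    """Debye screening length κ⁻¹ in nm.

    κ⁻¹ = sqrt(ε_r ε₀ k_B T / (2 N_A e² I)), with I converted from mM to
    mol/m³ (numerically equal).  Computed from fundamental constants, not
    the 0.304 nm·M^1/2 shortcut.
    """
    if I_mM <= 0:
        raise DomainError("ionic strength must be positive")
    i_si = I_mM  # mM == mol/m^3
    kappa_inv_m = np.sqrt(
        eps_r * EPSILON_0 * K_BOLTZMANN * temperature_k / (2.0 * N_AVOGADRO * E_CHARGE**2 * i_si)
    )
    return float(kappa_inv_m * 1e9)


def fit_dndc(series: RefractometrySeries) -> DnDcFit:
    """Ordinary least-squares dn/dc fit to a refractometry series.

    The slope of n versus c (mg/ml) is converted to ml/g (×1000).
    """
    c = series.concentrations
    if c.size < 3 or np.ptp(c) == 0:
        raise FitError("need >= 3 concentrations spanning a nonzero range")
    res = stats.linregress(c, series.n_values)
    return DnDcFit(
        dndc=float(res.slope * 1000.0),
        n0=float(res.intercept),
        r_squared=float(res.rvalue**2),
        wavelength_nm=series.wavelength_nm,
    )


def read_fasta_sequence(path: str | Path) -> str:
    """First sequence of a FASTA file as a validated one-letter string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return _validate_sequence(str(record.seq))


def synthetic_jb6b_sequence() -> str:
    """Bundled synthetic stand-in for the 241-residue chaperone isoform.

    This is NOT the real DNAJB6b sequence (which is not distributed with
    the package); it is a synthetic sequence whose length (241), monomer
    mass (~26.9 kDa) and ionizable-residue composition are chosen to
    match the chaperone's reported charge behaviour: net charge ≈ +40 at
    pH 2 and a weak negative net charge at pH 8.  Use a real FASTA file
    (e.g. UniProt O75190-2) for work on the actual protein.
    """
    path = Path(__file__).parent / "data" / "synthetic_dnajb6b.fasta"
    return read_fasta_sequence(path)
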
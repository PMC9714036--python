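"""Mass-isotopologue distributions: validation, correction, enrichment.

A mass-isotopologue distribution (MID) is the vector of fractional
abundances ``M0..Mn`` of a metabolite's mass shifts, ``n`` being the number
of skeleton carbons. Indexing is 0-based throughout: ``fractions[0]`` is
the unlabeled species M0.

Natural 13C abundance (about 1.07% per carbon) inflates observed mass
shifts; :func:`convolve_natural_abundance` applies that effect to a true
MID and :func:`correct_natural_abundance` inverts it by solving the
binomial-convolution linear system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, ValidationError

#: Natural abundance of 13C per carbon atom.
P13_DEFAULT = 0.0107

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class MIDVector:
    """Mass-isotopologue fraction vector for one metabolite measurement.

    Parameters
    ----------
    metabolite:
        Metabolite name (free text; the registry is consulted only by
        readers that need carbon counts).
    fractions:
        Length ``n_carbons + 1`` vector of nonnegative fractions summing
        to 1, index = mass shift.
    """

    metabolite: str
    fractions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fr)
        if fr.ndim != 1 or fr.size < 1:
            raise ValidationError(f"{self.metabolite}: MID must be a 1-D vector")
        if np.any(fr < -1e-12):
            raise ValidationError(
                f"{self.metabolite}: negative isotopologue fraction {fr.min():.3g}"
            )
        if abs(fr.sum() - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"{self.metabolite}: MID sums to {fr.sum():.6f}, expected 1"
            )

    @property
    def n_carbons(self) -> int:
        return self.fractions.size - 1

    def __len__(self) -> int:
        return self.fractions.size


def isotopologue_fraction(mid: MIDVector, shift: int) -> float:
    """Return the fraction at a single mass shift (e.g. M+2 citrate)."""
    if not 0 <= shift <= mid.n_carbons:
        raise IndexError(
            f"mass shift {shift} out of range 0..{mid.n_carbons} for {mid.metabolite}"
        )
    return float(mid.fractions[shift])


def enrichment(mid: MIDVector, mode: str = "atom_fraction") -> float:
    """Summarize an MID into a scalar 13C enrichment.

    ``atom_fraction`` is the average fraction of labeled carbon atoms,
    ``sum_i (i/n) M_i``; ``labeled_fraction`` is the fraction of molecules
    carrying any label, ``1 - M0``. Atom fraction is the default because a
    pool-average label measure is what the citrate-synthase flux slope
    integrates.
    """
    n = mid.n_carbons
    if n == 0:
        raise DomainError("enrichment undefined for a 0-carbon metabolite")
    if mode == "atom_fraction":
        shifts = np.arange(n + 1)
        return float(np.dot(shifts, mid.fractions) / n)
    if mode == "labeled_fraction":
        return float(1.0 - mid.fractions[0])
    raise DomainError(f"unknown enrichment mode {mode!r}")


def natural_abundance_matrix(n_carbons: int, p13: float) -> np.ndarray:
    """Convolution matrix A with observed = A @ true.

    Column j holds the observed-shift distribution of a species with j
    labeled carbons: each of the n-j unlabeled carbons is independently
    heavy with probability ``p13``, so the extra shift is Binomial(n-j, p13).
    """
    if not 0 <= p13 < 0.5:
        raise DomainError(f"p13 must be in [0, 0.5), got {p13}")
    n = n_carbons
    a = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        extra = stats.binom.pmf(np.arange(n - j + 1), n - j, p13)
        a[j : n + 1, j] = extra
    return a


def convolve_natural_abundance(mid: MIDVector, p13: float = P13_DEFAULT) -> MIDVector:
    """Apply natural 13C abundance to a true MID, giving the observed MID."""
    a = natural_abundance_matrix(mid.n_carbons, p13)
    obs = a @ mid.fractions
    obs = obs / obs.sum()
    return MIDVector(mid.metabolite, obs)


def correct_natural_abundance(observed: MIDVector, p13: float = P13_DEFAULT) -> MIDVector:
    """Remove natural-abundance contributions from an observed MID.

    Solves ``observed = A @ true`` for ``true`` by nonnegative least
    squares, then renormalizes. Exact inverse of
    :func:`convolve_natural_abundance` on noise-free input; on noisy input
    the nonnegativity clamp keeps the result a valid MID.
    """
    a = natural_abundance_matrix(observed.n_carbons, p13)
    sol, _ = optimize.nnls(a, observed.fractions)
    total = sol.sum()
    if total <= 0:
        raise ValidationError(
            f"{observed.metabolite}: natural-abundance correction annihilated the MID"
        )
    return MIDVector(observed.metabolite, sol / total)
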
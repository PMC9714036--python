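"""Group comparisons and multiplicity control.

Thin, strictly validated wrappers over scipy/statsmodels: a pooled-variance
(Student's) two-sample t test, one-way ANOVA with Tukey's HSD, the
Benjamini-Hochberg step-up adjustment, and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DomainError, ValidationError


@dataclass(frozen=True)
class PairResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    groups: dict[str, np.ndarray]
    statistic: float
    p_value: float
    pairs: list[PairResult]


def _as_vector(x, name: str, min_len: int = 2) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size < min_len:
        raise DataError(f"{name} needs >= {min_len} values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} holds non-finite values")
    return v


def students_t_test(a, b) -> tuple[float, float]:
    """Two-tailed unpaired Student's (pooled-variance) t test.

    Zero pooled variance with equal means returns p = 1 by convention;
    with unequal means it is a degenerate-variance error.
    """
    va = _as_vector(a, "a")
    vb = _as_vector(b, "b")
    pooled = ((va.size - 1) * va.var(ddof=1) + (vb.size - 1) * vb.var(ddof=1)) / (
        va.size + vb.size - 2
    )
    if pooled == 0:
        if va.mean() == vb.mean():
            return 0.0, 1.0
        raise DataError(
            "degenerate variance: groups are constant with unequal means"
        )
    t, p = sstats.ttest_ind(va, vb, equal_var=True)
    return float(t), float(p)


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with Tukey's HSD multiple-comparisons test.

    Tukey-adjusted pairwise p values come from the studentized-range
    distribution; with k groups there are k(k-1)/2 pairs.
    """
    if len(groups) < 3:
        raise DataError("anova_tukey needs >= 3 groups; use students_t_test for 2")
    names = list(groups)
    vecs = [_as_vector(groups[n], n) for n in names]
    if np.ptp(np.concatenate(vecs)) == 0:
        # all observations identical: F = 0, nothing significant
        pairs = [
            PairResult(names[i], names[j], 0.0, 1.0, False)
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        return GroupComparison(
            {n: v for n, v in zip(names, vecs)}, 0.0, 1.0, pairs
        )
    f, p = sstats.f_oneway(*vecs)
    hsd = sstats.tukey_hsd(*vecs)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            padj = float(hsd.pvalue[i, j])
            pairs.append(
                PairResult(
                    names[i],
                    names[j],
                    float(vecs[i].mean() - vecs[j].mean()),
                    padj,
                    padj < alpha,
                )
            )
    return GroupComparison(
        {n: v for n, v in zip(names, vecs)}, float(f), float(p), pairs
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order preserved."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from the t transform."""
    vx = _as_vector(x, "x", min_len=3)
    vy = _as_vector(y, "y", min_len=3)
    if vx.size != vy.size:
        raise DataError(f"length mismatch: {vx.size} vs {vy.size}")
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise DataError("correlation undefined for a constant input")
    r, p = sstats.pearsonr(vx, vy)
    return float(r), float(p)


def spearman_r(x, y) -> tuple[float, float]:
    """Rank (Spearman) correlation, for sensitivity analysis."""
    vx = _as_vector(x, "x", min_len=3)
    vy = _as_vector(y, "y", min_len=3)
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise DataError("correlation undefined for a constant input")
    r, p = sstats.spearmanr(vx, vy)
    return float(r), float(p)
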
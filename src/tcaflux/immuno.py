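"""Immunogenomic scoring on expression matrices.

Covers the cohort-level analyses: the cytolytic-activity (CYT) score,
gene-covariate correlation screens, differential-expression gating,
prognostic survival-Z classification, PCA variance explained, and
row-z-scored hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DataError, DomainError, ValidationError
from .stats import bh_adjust, pearson_r, spearman_r


class ExpressionMatrix:
    """Nonnegative genes x samples matrix with uppercase gene symbols."""

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        df.index = df.index.astype(str).str.strip().str.upper()
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        values = df.to_numpy(dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite and >= 0")
        self._df = df.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def samples(self) -> list[str]:
        return list(self._df.columns)

    def gene(self, symbol: str) -> np.ndarray:
        key = symbol.strip().upper()
        if key not in self._df.index:
            raise KeyError(f"gene not found in matrix: {symbol}")
        return self._df.loc[key].to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape


def cyt_score(
    expr: ExpressionMatrix,
    gene_a: str = "GZMA",
    gene_b: str = "PRF1",
    pseudocount: float = 0.0,
) -> pd.Series:
    """Cytolytic activity per sample: geometric mean of GZMA and PRF1.

    CYT proxies cytotoxic-lymphocyte effector function (granzyme A and
    perforin are its key enzymes). Computed on linear-scale expression;
    zeros are an error unless a pseudocount is supplied, so that scores
    are never silently shifted.
    """
    a = expr.gene(gene_a) + pseudocount
    b = expr.gene(gene_b) + pseudocount
    if np.any(a <= 0) or np.any(b <= 0):
        raise DomainError(
            f"nonpositive expression for {gene_a}/{gene_b}; "
            "supply a pseudocount to score zeros"
        )
    return pd.Series(np.sqrt(a * b), index=expr.samples, name="CYT")


def correlate_genes(
    expr: ExpressionMatrix,
    covariate: pd.Series,
    gene_set: list[str] | None = None,
    alpha: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Screen genes for correlation with a per-sample covariate.

    Returns one row per gene with r, p and a class (positive / negative
    when p < alpha, else ns), ordered by |r| descending. The covariate
    index must match the matrix samples exactly (order-insensitive).
    """
    cov = pd.Series(covariate).astype(float)
    missing = [s for s in expr.samples if s not in cov.index]
    extra = [s for s in cov.index if s not in expr.samples]
    if missing or extra:
        raise DataError(
            f"covariate/sample mismatch; missing={missing[:5]} extra={extra[:5]}"
        )
    cov = cov.loc[expr.samples]
    genes = expr.genes if gene_set is None else [g.strip().upper() for g in gene_set]
    absent = [g for g in genes if g not in expr.frame.index]
    if absent:
        raise DataError(f"genes absent from matrix: {absent[:5]}")
    corr = pearson_r if method == "pearson" else spearman_r
    rows = []
    for g in genes:
        r, p = corr(expr.gene(g), cov.to_numpy())
        cls = "ns" if p >= alpha else ("positive" if r > 0 else "negative")
        rows.append({"gene": g, "r": r, "p": p, "class": cls})
    out = pd.DataFrame(rows, columns=["gene", "r", "p", "class"])
    if not out.empty:
        out = out.reindex(
            out["r"].abs().sort_values(ascending=False, kind="stable").index
        ).reset_index(drop=True)
    return out


def classify_de(
    table: pd.DataFrame, lfc_cut: float = 2.0, alpha: float = 0.01
) -> pd.DataFrame:
    """Gate a differential-expression table into up / down / not_significant.

    p values are Benjamini-Hochberg adjusted across the whole table, then
    a gene is ``up`` when log2fc >= lfc_cut and padj < alpha, ``down``
    when log2fc <= -lfc_cut and padj < alpha.
    """
    req = {"gene", "log2fc", "pvalue"}
    if not req <= set(table.columns):
        raise ValidationError(f"DE table needs columns {sorted(req)}")
    if table["gene"].duplicated().any():
        raise ValidationError("duplicate genes in DE table")
    out = table.loc[:, ["gene", "log2fc", "pvalue"]].copy()
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    sig = out["padj"] < alpha
    out["class"] = "not_significant"
    out.loc[sig & (out["log2fc"] >= lfc_cut), "class"] = "up"
    out.loc[sig & (out["log2fc"] <= -lfc_cut), "class"] = "down"
    return out


def z_to_p(z: float) -> float:
    """One-sided upper-tail p for a survival Z score: p = 1 - Phi(z)."""
    return float(sstats.norm.sf(z))


def p_to_z(p: float) -> float:
    """Inverse of :func:`z_to_p`: the upper-tail standard-normal quantile."""
    if not 0.0 < p < 1.0:
        raise DomainError(f"p must be in (0, 1), got {p}")
    return float(sstats.norm.isf(p))


def classify_prognostic(z_table: pd.DataFrame, z_cut: float = 3.09) -> pd.DataFrame:
    """Classify survival Z scores as detrimental / beneficial / neutral.

    Positive Z means high expression associates with worse overall
    survival; the default cut 3.09 corresponds to a one-sided p of 0.001.
    """
    req = {"gene", "zscore"}
    if not req <= set(z_table.columns):
        raise ValidationError(f"Z table needs columns {sorted(req)}")
    z = pd.to_numeric(z_table["zscore"], errors="coerce")
    if z.isna().any():
        raise ValidationError("non-numeric Z score in table")
    out = z_table.loc[:, ["gene"]].copy()
    out["zscore"] = z.astype(float)
    out["p_one_sided"] = sstats.norm.sf(out["zscore"].to_numpy())
    out["class"] = "neutral"
    out.loc[out["zscore"] > z_cut, "class"] = "detrimental"
    out.loc[out["zscore"] < -z_cut, "class"] = "beneficial"
    return out


def pca_variance_explained(expr: ExpressionMatrix) -> np.ndarray:
    """Fraction of variance per principal component (samples as points).

    Samples are the observations and genes the features; columns are
    gene-centered before the SVD. Fractions sum to 1 over the nonzero
    components.
    """
    x = expr.frame.to_numpy().T  # samples x genes
    if x.shape[0] < 2:
        raise DataError("PCA needs >= 2 samples")
    xc = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(xc, compute_uv=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise DataError("matrix has zero variance; PCA undefined")
    return var / total


def row_zscore(frame: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, sd 1 (population sd)."""
    values = frame.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise DataError("constant row; drop it before z-scoring")
    return pd.DataFrame((values - mu) / sd, index=frame.index, columns=frame.columns)


@dataclass(frozen=True)
class ClusterResult:
    row_order: list[str]
    linkage: np.ndarray
    dropped_rows: list[str]
    method: str = "average"
    metric: str = "euclidean"


def cluster_rows(frame: pd.DataFrame) -> ClusterResult:
    """Hierarchically cluster rows after per-row z-scoring.

    Euclidean distances between z-scored rows, average-linkage
    agglomeration, deterministic leaf order (scipy's distance-then-index
    ordering). Constant rows cannot be z-scored; they are dropped and
    reported.
    """
    if frame.shape[0] < 2:
        raise DataError("clustering needs >= 2 rows")
    values = frame.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    dropped = [str(i) for i in frame.index[~keep]]
    sub = frame.loc[keep]
    if sub.shape[0] < 2:
        raise DataError("fewer than 2 non-constant rows; nothing to cluster")
    z = row_zscore(sub)
    link = hierarchy.linkage(pdist(z.to_numpy(), metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(link)
    return ClusterResult(
        row_order=[str(sub.index[i]) for i in leaves],
        linkage=link,
        dropped_rows=dropped,
    )
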
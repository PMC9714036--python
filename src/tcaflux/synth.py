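"""Synthetic data with planted, recoverable structure.

Wraps the isotopomer simulator with measurement effects (natural 13C
abundance, additive MS noise) and generates the cohort-side inputs the
expression analyses consume: expression matrices with planted
gene-covariate correlations, differential-expression tables with planted
hits, survival-Z tables, and substrate-deprivation growth curves.

The generators emulate the *structure* of the study's data (sample sizes,
replicate counts, noise scales), not any particular real cohort; planted
effects are chosen so that a correct pipeline recovers them and a broken
one does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .immuno import ExpressionMatrix
from .mid import MIDVector, P13_DEFAULT, convolve_natural_abundance
from .timecourse import LabelTimeCourse

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "GrowthCondition",
    "convolve_natural_abundance",
    "add_measurement_noise",
    "observe_timecourse",
    "generate_expression_cohort",
    "generate_de_table",
    "generate_z_table",
    "generate_growth_dataset",
]


@dataclass(frozen=True)
class NoiseModel:
    """LC-MS/MS measurement model for isotopologue fractions.

    ``p13`` is the natural 13C abundance per carbon; ``sd_mid`` the
    standard deviation of additive, truncated-at-zero Gaussian noise on
    each isotopologue fraction (the pipeline consumes fractions, so noise
    is placed on fractions rather than on raw ion intensities).
    """

    p13: float = P13_DEFAULT
    sd_mid: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p13 < 0.5:
            raise ConfigurationError(f"p13 must be in [0, 0.5), got {self.p13}")
        if self.sd_mid < 0:
            raise ConfigurationError("sd_mid must be >= 0")


def add_measurement_noise(tc: LabelTimeCourse, noise: NoiseModel) -> LabelTimeCourse:
    """Perturb each MID with additive noise, clamp at 0 and renormalize."""
    rng = np.random.default_rng(noise.seed)
    records = []
    for meta, m in tc.iter_mids():
        frac = m.fractions + rng.normal(0.0, noise.sd_mid, size=len(m))
        frac = np.clip(frac, 0.0, None)
        total = frac.sum()
        if total <= 0:  # pragma: no cover - requires sd_mid >> 1
            frac = np.zeros_like(frac)
            frac[0] = 1.0
            total = 1.0
        records.append((meta, MIDVector(m.metabolite, frac / total)))
    return LabelTimeCourse.from_mids(records)


def observe_timecourse(tc: LabelTimeCourse, noise: NoiseModel) -> LabelTimeCourse:
    """Full measurement model: natural-abundance convolution, then noise."""
    with_na = tc.map_mids(lambda m: convolve_natural_abundance(m, noise.p13))
    return add_measurement_noise(with_na, noise)


# ---------------------------------------------------------------------------
# expression cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic expression cohort with planted structure.

    ``planted_positive``/``planted_negative`` map gene symbols to target
    correlation magnitudes against the leukocyte-fraction covariate.
    ``de_genes`` lists (gene, true log2 fold change) pairs for the
    companion differential-expression table.
    """

    n_genes: int = 500
    n_samples: int = 200
    planted_positive: dict[str, float] = field(default_factory=dict)
    planted_negative: dict[str, float] = field(default_factory=dict)
    de_genes: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ConfigurationError("n_samples must be >= 3")
        overlap = set(self.planted_positive) & set(self.planted_negative)
        if overlap:
            raise ConfigurationError(
                f"genes planted both positive and negative: {sorted(overlap)}"
            )
        for gene, r in {**self.planted_positive, **self.planted_negative}.items():
            if not 0 < abs(r) < 1:
                raise ConfigurationError(
                    f"target |correlation| for {gene} must be in (0, 1), got {r}"
                )


#: Latent correlation used for GZMA/PRF1 so that CYT tracks immune
#: infiltration, as cytolytic markers do in bulk tumor expression.
_CYT_GENE_R = 0.75
_LOG2_SD = 0.8  # per-gene biological spread, log2 units


def generate_expression_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log-normal expression cohort plus a leukocyte-fraction covariate.

    A latent standard-normal infiltration axis drives (i) the leukocyte
    fraction (affine, clipped to [0, 1]), (ii) the planted genes at their
    target latent correlations, and (iii) GZMA/PRF1, so the CYT score
    correlates positively with the covariate. All other genes are
    independent noise. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    latent = rng.standard_normal(n)
    leukocyte = np.clip(0.30 + 0.12 * latent + rng.normal(0, 0.015, n), 0.0, 1.0)

    targets: dict[str, float] = {g.upper(): abs(r) for g, r in spec.planted_positive.items()}
    targets.update({g.upper(): -abs(r) for g, r in spec.planted_negative.items()})
    targets.setdefault("GZMA", _CYT_GENE_R)
    targets.setdefault("PRF1", _CYT_GENE_R)

    background = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    genes = list(dict.fromkeys(list(targets) + background))[: max(spec.n_genes, len(targets))]

    rows = {}
    for gene in genes:
        r = targets.get(gene, 0.0)
        eps = rng.standard_normal(n)
        signal = r * latent + np.sqrt(1.0 - r * r) * eps
        base = rng.uniform(3.0, 9.0)
        rows[gene] = np.exp2(base + _LOG2_SD * signal)
    expr = ExpressionMatrix(pd.DataFrame(rows, index=samples).T)
    covariate = pd.DataFrame(
        {"sample_id": samples, "leukocyte_fraction": leukocyte}
    )
    return expr, covariate


def generate_de_table(spec: CohortSpec) -> pd.DataFrame:
    """Differential-expression results with planted up/down genes.

    Null genes draw p ~ Uniform(0,1) and small fold changes; planted genes
    get their stated log2 fold change and p values far below any sensible
    gate. Consumed by the DE gating stage, never refit.
    """
    rng = np.random.default_rng(spec.seed + 1)
    planted = dict(spec.de_genes)
    names = list(planted) + [
        f"NULL{i:05d}" for i in range(max(0, spec.n_genes - len(planted)))
    ]
    recs = []
    for gene in names:
        if gene in planted:
            lfc = float(planted[gene])
            p = 10.0 ** rng.uniform(-9.0, -5.0)
        else:
            lfc = float(rng.normal(0.0, 0.5))
            p = float(rng.uniform())
        recs.append({"gene": gene, "log2fc": lfc, "pvalue": p})
    df = pd.DataFrame(recs, columns=["gene", "log2fc", "pvalue"])
    if df["gene"].duplicated().any():
        raise ValidationError("duplicate genes in DE spec")
    return df


def generate_z_table(
    n_genes: int = 200,
    detrimental: list[str] | None = None,
    beneficial: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Survival Z-score table with planted prognostic genes.

    Background genes draw Z ~ N(0, 1); planted detrimental genes sit above
    +3.09 and beneficial ones below -3.09 (the one-sided p = 0.001 cut).
    """
    rng = np.random.default_rng(seed)
    detrimental = list(detrimental or [])
    beneficial = list(beneficial or [])
    recs = [{"gene": g, "zscore": 3.5 + abs(rng.standard_normal())} for g in detrimental]
    recs += [{"gene": g, "zscore": -3.5 - abs(rng.standard_normal())} for g in beneficial]
    n_null = max(0, n_genes - len(recs))
    recs += [
        {"gene": f"BG{i:05d}", "zscore": float(rng.standard_normal())}
        for i in range(n_null)
    ]
    return pd.DataFrame(recs, columns=["gene", "zscore"])


# ---------------------------------------------------------------------------
# growth curves


@dataclass(frozen=True)
class GrowthCondition:
    """One deprivation condition: logistic growth toward a plateau."""

    condition: str
    media: str
    rate_per_h: float
    plateau: float
    n0: float = 1.0e4

    def __post_init__(self) -> None:
        if self.plateau <= 0:
            raise ConfigurationError(
                f"plateau must be > 0 for condition {self.condition!r}"
            )
        if self.n0 <= 0:
            raise ConfigurationError("n0 must be > 0")


def _logistic(n0: float, k: float, r: float, t: float) -> float:
    if r == 0.0:
        return n0
    return k / (1.0 + (k / n0 - 1.0) * np.exp(-r * t))


def generate_growth_dataset(
    conditions: list[GrowthCondition],
    seed: int = 0,
    times_h: tuple[float, ...] = (24.0, 48.0, 72.0),
    n_replicates: int = 3,
    n_measurements: int = 3,
    noise_cv: float = 0.05,
) -> pd.DataFrame:
    """Trypan-blue style cell counts under deprivation conditions.

    Counts follow a logistic curve (cultures approach a plateau by the
    72-h timepoint); each replicate well is counted ``n_measurements``
    times with multiplicative log-normal noise of coefficient of
    variation ``noise_cv``.
    """
    if not conditions:
        raise ConfigurationError("no growth conditions supplied")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    recs = []
    for cond in conditions:
        for t in times_h:
            mean = _logistic(cond.n0, cond.plateau, cond.rate_per_h, t)
            for rep in range(n_replicates):
                for _ in range(n_measurements):
                    factor = np.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
                    recs.append(
                        {
                            "condition": cond.condition,
                            "media": cond.media,
                            "time_h": float(t),
                            "replicate": rep,
                            "cell_count": float(mean * factor),
                        }
                    )
    return pd.DataFrame(
        recs, columns=["condition", "media", "time_h", "replicate", "cell_count"]
    )
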
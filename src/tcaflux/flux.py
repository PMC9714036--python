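"""Flux readouts from labeled time courses.

Relative citrate-synthase flux (V_CS) is the slope of 13C citrate
enrichment versus time over the early linear window, normalized to a
reference condition. Anaplerosis is read out as the dilution of the label
between the first labeled cycle-proximal metabolite and the downstream
intermediates at isotopic steady state. The glycolysis index is the
ratio of [13C3] pyruvate to [13C6] glucose enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DataError, DomainError
from .timecourse import LabelTimeCourse

#: Cycle-proximal reference metabolite per tracer for dilution profiling:
#: the first labeled TCA-proximal metabolite (citrate for the acetyl-entry
#: tracers, glutamate for glutamine).
DILUTION_REFERENCE = {
    "glucose_U13C6": "citrate",
    "palmitate_U13C16": "citrate",
    "glutamine_U13C5": "glutamate",
}


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    stderr: float
    window: tuple[float, float]
    n_points: int
    through_origin: bool


@dataclass(frozen=True)
class FluxResult:
    condition: str
    tracer: str
    slope: float
    window: tuple[float, float]
    reference_id: str
    relative_vcs: float


@dataclass(frozen=True)
class DilutionProfile:
    condition: str
    tracer: str
    reference_metabolite: str
    enrichments: dict[str, float]
    dilution_index: dict[str, float]
    clamped: dict[str, bool]
    steady_state_checked: bool


@dataclass(frozen=True)
class SteadyStateDecision:
    steady: bool
    p_value: float
    mean_t1: float
    mean_t2: float
    t1: float
    t2: float


def fit_label_slope(
    tc: LabelTimeCourse,
    metabolite: str = "citrate",
    window: tuple[float, float] = (0.0, 30.0),
    *,
    mode: str = "atom_fraction",
    shift: int | None = None,
    through_origin: bool = True,
) -> SlopeFit:
    """Least-squares slope of enrichment vs time over a window.

    The fit is constrained through the origin by default because no label
    is present at infusion start. With a single nonzero timepoint the
    slope degenerates to the origin ratio E(t*)/t* (the in vivo mode,
    where enrichment is measured at 60 min only).

    ``shift`` switches the readout from a scalar enrichment to a single
    isotopologue fraction (e.g. ``shift=2`` tracks M+2 citrate, the
    direct product of one labeled acetyl unit under [U-13C6] glucose).
    A single-isotopologue readout is robust to baseline lifts on the
    near-empty channels because its measurement biases are
    multiplicative and cancel between conditions.
    """
    if shift is None:
        enr = tc.enrichments(mode)
    else:
        from .mid import isotopologue_fraction

        enr = pd.DataFrame(
            [
                {**meta, "enrichment": isotopologue_fraction(m, shift)}
                for meta, m in tc.iter_mids()
            ]
        )
    enr = enr[enr["metabolite"] == metabolite]
    lo, hi = window
    enr = enr[(enr["time_min"] >= lo) & (enr["time_min"] <= hi)]
    if enr.empty:
        raise DataError(f"no {metabolite} measurements in window {window}")
    t = enr["time_min"].to_numpy(dtype=float)
    y = enr["enrichment"].to_numpy(dtype=float)

    distinct = np.unique(t[t > 0])
    if distinct.size == 0:
        raise DataError("window holds only t=0 measurements; slope undefined")
    if distinct.size == 1 and not np.any(t == 0):
        # single-timepoint mode: ratio through the (0, 0) origin
        tstar = distinct[0]
        ratios = y[t == tstar] / tstar
        slope = float(ratios.mean())
        se = float(ratios.std(ddof=1) / np.sqrt(ratios.size)) if ratios.size > 1 else float("nan")
        return SlopeFit(slope, se, (lo, hi), int(ratios.size), True)

    if through_origin:
        sxx = float(np.dot(t, t))
        if sxx == 0:
            raise DataError("all times are zero; cannot fit a slope")
        slope = float(np.dot(t, y) / sxx)
        resid = y - slope * t
        dof = max(t.size - 1, 1)
        se = float(np.sqrt((resid @ resid) / dof / sxx))
    else:
        res = sstats.linregress(t, y)
        slope, se = float(res.slope), float(res.stderr)
    return SlopeFit(slope, se, (lo, hi), int(t.size), through_origin)


def relative_vcs(slope: float, reference_slope: float) -> float:
    """Slope normalized to the reference condition's slope."""
    if not reference_slope > 0:
        raise DomainError(f"reference slope must be > 0, got {reference_slope}")
    return float(slope) / float(reference_slope)


def steady_state_check(
    tc: LabelTimeCourse,
    metabolite: str = "citrate",
    t1: float = 60.0,
    t2: float = 150.0,
    alpha: float = 0.05,
    mode: str = "atom_fraction",
) -> SteadyStateDecision:
    """Test whether enrichment at ``t1`` differs from ``t2``.

    Two-tailed unpaired Student's t test on replicate enrichments; the
    pool is declared at steady state when equality is not rejected
    (p >= alpha). Note this is an absence-of-evidence criterion, not a
    formal equivalence test.
    """
    enr = tc.enrichments(mode)
    enr = enr[enr["metabolite"] == metabolite]
    a = enr.loc[enr["time_min"] == t1, "enrichment"].to_numpy()
    b = enr.loc[enr["time_min"] == t2, "enrichment"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise DataError(
            f"need >=2 replicates at both t={t1} and t={t2} "
            f"(got {a.size} and {b.size})"
        )
    from .stats import students_t_test

    _, p = students_t_test(a, b)
    return SteadyStateDecision(
        steady=bool(p >= alpha),
        p_value=float(p),
        mean_t1=float(a.mean()),
        mean_t2=float(b.mean()),
        t1=t1,
        t2=t2,
    )


def glycolysis_index(pyruvate_m3: float, glucose_m6: float) -> float:
    """[13C3] pyruvate / [13C6] glucose ratio, a glycolysis readout."""
    if not glucose_m6 > 0:
        raise DomainError(f"glucose M+6 fraction must be > 0, got {glucose_m6}")
    return float(pyruvate_m3) / float(glucose_m6)


def dilution_profile(
    tc: LabelTimeCourse,
    reference_metabolite: str | None = None,
    *,
    time_min: float | None = None,
    mode: str = "atom_fraction",
    steady_state_checked: bool = False,
    metabolites: tuple[str, ...] = ("citrate", "glutamate", "succinate", "malate"),
) -> DilutionProfile:
    """Per-metabolite steady-state enrichment and label-dilution index.

    ``dilution_index(m) = 1 - E_m / E_reference`` clamped to [0, 1] with
    clamping flagged. Higher values mean more unlabeled (anaplerotic)
    carbon entered the cycle between the reference and that metabolite.
    This index is one reasonable operationalization of "label dilution
    through the cycle"; it is not an absolute anaplerosis flux.
    """
    df = tc.frame
    tracers = df["tracer"].unique()
    conditions = df["condition"].unique()
    if len(tracers) != 1 or len(conditions) != 1:
        raise DataError("dilution_profile expects a single condition and tracer")
    tracer, condition = str(tracers[0]), str(conditions[0])
    if reference_metabolite is None:
        reference_metabolite = DILUTION_REFERENCE.get(tracer, "citrate")
    if time_min is None:
        time_min = float(tc.times[-1])

    enr = tc.enrichments(mode)
    enr = enr[enr["time_min"] == time_min]
    means = enr.groupby("metabolite")["enrichment"].mean()
    if reference_metabolite not in means.index:
        raise DataError(f"reference metabolite {reference_metabolite!r} not measured")
    e_ref = float(means[reference_metabolite])
    if e_ref <= 0:
        raise DomainError("reference enrichment is zero; dilution undefined")

    enrichments: dict[str, float] = {}
    index: dict[str, float] = {}
    clamped: dict[str, bool] = {}
    for m in metabolites:
        if m not in means.index:
            continue
        e = float(means[m])
        enrichments[m] = e
        raw = 1.0 - e / e_ref
        index[m] = float(min(1.0, max(0.0, raw)))
        clamped[m] = not (0.0 <= raw <= 1.0)
    return DilutionProfile(
        condition=condition,
        tracer=tracer,
        reference_metabolite=reference_metabolite,
        enrichments=enrichments,
        dilution_index=index,
        clamped=clamped,
        steady_state_checked=steady_state_checked,
    )


def lactate_production_rate(
    conc_start: float, conc_end: float, hours: float = 6.0, protein_mg: float = 1.0
) -> float:
    """Lactate production rate, assumed linear, per mg protein per hour."""
    if not hours > 0:
        raise DomainError("hours must be > 0")
    if not protein_mg > 0:
        raise DomainError("protein_mg must be > 0")
    return (float(conc_end) - float(conc_start)) / hours / protein_mg
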
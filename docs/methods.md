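# Methods

## The isotopomer network

The simulator tracks a single mitochondrial pool set: pyruvate (3C),
acetyl-CoA (2C), oxaloacetate (4C), citrate (6C), α-ketoglutarate (5C),
glutamate (5C), succinate (4C) and malate (4C; fumarate is lumped into
the succinate→malate step). Each c-carbon pool carries a probability
vector over its 2^c positional labeling states (bit i set = carbon i is
¹³C). Positional rather than mass-only tracking is essential: the two
oxidative decarboxylations remove specific carbons — in the first turn
both released CO₂ carbons derive from oxaloacetate — so acetyl-derived
carbons survive to succinate, and only positional bookkeeping reproduces
the tracer-fate schemes (citrate exclusively M+2 under the acetyl-entry
tracers, M+4 under glutamine). With no pool above 6 carbons the total
state is 208 numbers.

Carbon maps: pyruvate dehydrogenase releases pyruvate C1 and maps C2,C3
onto acetyl-CoA; citrate synthase condenses acetyl-CoA (citrate bits
0–1) with oxaloacetate (bits 2–5), implemented as an outer-product
convolution of the two state vectors; citrate→α-ketoglutarate drops
citrate bit 5 and α-ketoglutarate→succinate drops bit 4 (both
oxaloacetate-derived, matching the known CO₂ origins);
glutamate↔α-ketoglutarate exchange maps carbons identically. Succinate
and fumarate are symmetric molecules, so transfer distributions are
averaged with their carbon-reversed twins at succinate formation and on
the succinate→malate step.

Fluxes (concentration/min): citrate-synthase flux `v_cs`; anaplerotic
entry `v_ana` of unlabeled carbon at α-ketoglutarate, balanced by an
equal cataplerotic oxaloacetate efflux; symmetric unlabeled exchanges
`v_dil_acecoa`, `v_dil_oaa`; bidirectional glutamate↔α-ketoglutarate
exchange `v_exchange_glu`; external glutamate turnover `v_gln_in`
(labeled under the glutamine tracer); and `fao_fraction`, the share of
the acetyl-CoA supply coming from β-oxidation (labeled under palmitate,
lumped rather than tracked through eight sequential acetyl units).
`build_network` assigns a balancing efflux to any pool whose configured
inflow exceeds its configured outflow and rejects configurations that
would force a negative one (e.g. glycolysis under-supplying pyruvate).
Because anaplerosis is balanced at oxaloacetate by construction, `v_ana`
alone can never unbalance the network.

Glutamine-label routing: the tracer labels the glutamate pool, and the
glutamate↔α-ketoglutarate exchange carries label into the cycle, while
`v_ana` itself stays unlabeled. This keeps "anaplerotic dilution"
strictly a dilution phenomenon regardless of tracer identity.

## Input function and integration

A primed-continuous infusion is modeled as
`e(t) = plateau · (1 − (1 − s)·exp(−k t))` with prime step
`s = min(1, prime_multiplier · k)`: in a one-compartment plasma pool with
turnover `k`, a bolus of `prime_multiplier` times the per-minute rate
instantaneously covers that fraction of the plateau. Defaults:
prime 3×, `k = 0.09`/min, plateau enrichment 0.4 (in vivo);
`TracerSpec.constant` models in vitro tracer media held at constant
enrichment (default 0.99) from t = 0.

Integration is fixed-step classical Runge–Kutta (RK4), default step
0.05 min (0.1 allowed), so outputs are deterministic and
solver-independent. Each pool's state derivative is a sum of terms
`v·(d_in − x)/P`, which conserves probability exactly; any state
component dropping below −10⁻⁶ aborts with advice to reduce the step
(reachable only with pool turnover times comparable to the step).

`turns=1` restricts the label to one passage of the cycle by forcing the
recycling edge unlabeled — malate→oxaloacetate for the acetyl-entry
tracers, citrate→α-ketoglutarate for glutamine. This is the readout the
first-turn schemes describe; the default (`turns=None`) lets label
recycle freely and is what all kinetic analyses use.

## Default parameters

Pool sizes (pyruvate 2, acetyl-CoA 0.5, oxaloacetate 0.5, citrate 4,
α-ketoglutarate 2, glutamate 3, succinate 2, malate 2, in the same
concentration units as flux·min) and the plasma rate constant were
chosen once so the default model reproduces the two kinetic regimes the
infusion protocol is built on: citrate label accumulation approximately
linear over 0–30 min (max least-squares-line residual < 5% of the peak
enrichment for the glucose tracer) and isotopic steady state by 60 min
(60-min enrichment within 5% of the 150-min value; this holds for all
three tracers, at 0.96–0.98). The two regimes pull against each other —
a single-exponential rise cannot satisfy both — and are reconciled by
the multi-pool chain delay, which makes the rise sigmoid. A consequence
worth knowing: at these defaults the origin-constrained average slope
over 0–30 min sits ~13% below the pointwise derivative at the window
midpoint (the entry lag); the two agree only in the pre-steady-state
regime described next. The glutamine tracer's citrate rise, whose label
must traverse glutamate→α-ketoglutarate→…→oxaloacetate before reaching
citrate, is distinctly less linear early on; the linearity statement is
specific to the glucose reference condition.

## Flux readouts

`fit_label_slope` fits enrichment (atom fraction `Σᵢ (i/n)·Mᵢ` by
default, `1 − M0` or a single isotopologue fraction as alternatives)
against time, constrained through the origin because no label exists at
infusion start; an unconstrained fit is available. With a single nonzero
timepoint it returns `E(t*)/t*` — the in vivo convention where
enrichment is measured at 60 min only. Relative V_CS is the slope ratio
against a reference condition and is scale-invariant in the enrichments.

The slope readout presumes the pre-steady-state regime. The bundled
recovery experiment (`experiments.vcs_recovery_experiment`) therefore
simulates two conditions differing only in `v_cs` on a network whose
citrate pool (240 units) turns over far slower than the 30-min window,
with acetyl-CoA supplied entirely by labeled pyruvate, constant 99%
tracer media, 16 timepoints, 5 replicates and MID noise sd 0.01. The
estimator is the M+2 citrate slope: M+2 is the direct product of one
labeled acetyl unit, and its measurement distortions (renormalization
after noise truncation) are multiplicative and cancel between
conditions, whereas scalar enrichments pick up an additive baseline from
the truncated-noise lift on near-empty channels that does not cancel.
Across noise seeds the design recovers a true ratio of 2.0 with mean
1.99 and spread ±0.04 (sd); at the in vivo default pool sizes the same
estimator is biased to ~1.45 because citrate saturates inside the
window — the recovery design exists precisely to stay in the
estimator's validity regime.

`dilution_profile` reports steady-state enrichment per metabolite and
`1 − E_m/E_ref`, clamped to [0,1] with clamping flagged; the reference
is citrate for the acetyl-entry tracers and glutamate for glutamine (the
first labeled cycle-proximal metabolite). This index is one reasonable
operationalization of "label dilution through the cycle", not an
absolute anaplerosis flux. `steady_state_check` declares steady state
when a two-tailed pooled-variance t test fails to reject equality of
enrichment at 60 vs 150 min (α = 0.05) — an absence-of-evidence
criterion, not an equivalence test, and labeled as such.

## Measurement model and natural abundance

Observed MIDs are the true MIDs convolved with natural ¹³C abundance
(default 0.0107 per carbon, skeleton carbons only — no
derivatization-atom correction, since no derivatization chemistry is
modeled) followed by additive truncated-Gaussian noise on fractions
(default sd 0.01) and renormalization; noise lives on fractions rather
than raw ion intensities because the pipeline consumes fractions.
Correction solves the binomial-convolution linear system by nonnegative
least squares and renormalizes; on noise-free data the round trip is
exact to well below 10⁻⁸.

## Synthetic cohorts and growth data

Expression cohorts are log-normal (log₂ sd 0.8 per gene) over a latent
standard-normal infiltration axis: the leukocyte fraction is an affine,
[0,1]-clipped function of it; planted genes load on it at their target
latent correlation (the log-normal transform attenuates observed Pearson
r by ~8%, so a target of 0.8 lands near 0.74 at n = 200); GZMA and PRF1
load at 0.75 so CYT tracks infiltration positively; all other genes are
independent. DE tables plant their stated log₂ fold changes at p ≤ 10⁻⁵
against a Uniform(0,1) null; survival-Z tables plant tails beyond
±3.5 against N(0,1). Growth curves are logistic — cultures approach a
plateau by the 72-h timepoint — sampled at 24/48/72 h, 3 replicate wells
× 3 counts, multiplicative log-normal noise (CV 5%).

What the generators deliberately do not emulate: raw spectra, batch
effects, library-size variation, count overdispersion, dropout, or
gene–gene correlation structure beyond the single infiltration axis.
Passing tests therefore show estimator correctness under the stated
noise models, not robustness to real-data pathologies.

## Statistics

Group comparisons use the pooled-variance (Student's) two-sample t test
— named explicitly rather than Welch — with the convention p = 1 for
identical constant groups and an error for constant groups with unequal
means; three or more groups use one-way ANOVA with Tukey's HSD from the
studentized-range distribution. Note Tukey's adjusted p is bounded below
by the Fisher's-LSD unadjusted p (same pooled error, N−k df), not by the
plain two-group t test, whose smaller df can make it larger for extreme
pairs. Multiplicity control is Benjamini–Hochberg step-up, verified
against a sort/cummin/unsort oracle. Correlation screens default to
Pearson (Spearman by flag) with two-sided p from the t transform;
screen gates use raw p < 0.05 by default with BH available by flag.

DE gating reads the stated fold-change threshold as |log₂FC| ≥ 2 (the
alternative literal reading, "> 2 or ≤ 2", covers the whole real line
and is an evident typo); adjusted p < 0.01 strictly. Survival-Z
classification uses the one-sided upper-tail convention fixed by the
3.09 ↔ 0.001 anchor. CYT is computed on linear-scale expression with an
optional pseudocount (default off: zeros raise rather than silently
shifting scores). PCA treats samples as observations with gene-centered
columns and reports SVD variance fractions. Row clustering z-scores each
row (population sd), drops constant rows with a warning, and uses
Euclidean average-linkage agglomeration with scipy's deterministic leaf
ordering.

## Numerical and interface conventions

Mass shifts are 0-based (M0 = unlabeled) in all files and APIs. MIDs
must sum to 1 within 10⁻⁶ in memory; file readers renormalize drifts up
to 10⁻³ and reject anything larger, reporting the row. All CSV output is
UTF-8 with a header row, "." decimal, no index column, and a provenance
block (config hash + package version) so identical configs give
byte-identical outputs. Gene symbols are uppercased on read.

## Known limitations

One mitochondrial compartment; no CO₂ refixation, no pyruvate
carboxylase route, no genome-scale model, no gradient-based global flux
fitting — relative, not absolute, fluxes. The slope readout's accuracy
degrades as pool turnover approaches the sampling window (quantified
above). The steady-state criterion is not an equivalence test. Survival
Z scores are consumed, never recomputed, and leukocyte fractions enter
as given covariates.
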
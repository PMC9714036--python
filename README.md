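# tcaflux

Stable-isotope tracing analysis of TCA-cycle substrate preference, paired
with tumor immunogenomic scoring — built around a deterministic
positional-isotopomer simulator that generates the labeled time courses
and expression cohorts the analyses consume.

## The problem

Tumors choose among glucose, glutamine and fatty acids to feed the TCA
cycle, and that choice co-varies with how immunogenic ("hot" or "cold")
the tumor is. Infusing a uniformly labeled tracer — [U-¹³C₆] glucose,
[U-¹³C₅] glutamine or [U-¹³C₁₆] palmitate — labels the cycle
intermediates in tracer-specific patterns, and three readouts summarize
the physiology:

* **Relative citrate-synthase flux** `V_CS`: the slope of ¹³C citrate
  enrichment vs time over the early (pre-steady-state) window,
  normalized to a reference condition. Under [U-¹³C₆] glucose the direct
  product of one labeled acetyl unit is [¹³C₂] citrate, so the M+2
  isotopologue slope is the cleanest readout.
* **Anaplerotic dilution**: unlabeled carbon entering the cycle (mostly
  at α-ketoglutarate) dilutes the label between citrate and downstream
  intermediates; `dilution_index(m) = 1 − E_m / E_reference` at isotopic
  steady state quantifies it.
* **Glycolysis index**: the [¹³C₃] pyruvate / [¹³C₆] glucose ratio.

On the cohort side, the package scores cytolytic activity
`CYT = √(GZMA · PRF1)` per sample, screens genes for correlation with
immune covariates (Pearson r, p < 0.05), gates differential-expression
tables (|log₂FC| ≥ 2, Benjamini–Hochberg p < 0.01), and classifies
survival Z scores (detrimental if Z > 3.09, beneficial if Z < −3.09,
the one-sided p = 0.001 cut).

Because the raw LC-MS/MS and cohort data behind these analyses are not
publicly deposited, the package ships a first-class synthetic-data arm:
a mass-balanced isotopomer network (2^c positional states per c-carbon
pool, fixed-step RK4) with a primed-continuous-infusion input function,
natural-abundance convolution (p¹³C = 0.0107 per carbon) and additive
MS noise; expression cohorts with planted gene–covariate correlations;
and logistic deprivation growth curves. Every estimator is validated by
recovering what was planted.

## Worked example

```bash
python examples/simulate_infusion.py
```

```
citrate 13C enrichment (atom fraction):
  t =     0 min   E = 0.0000
  t =     5 min   E = 0.0141
  ...
  t =    30 min   E = 0.1295
  t =    60 min   E = 0.1696
  t =   150 min   E = 0.1750

60 vs 150 min ratio: 0.969 (close to 1 means the label has reached steady state by 60 min)
early slope (0-30 min, through origin): 0.00440 /min - the raw readout behind relative citrate-synthase flux
```

The label accumulates near-linearly over 0–30 min and is at steady state
by 60 min — the regime the slope readout assumes. Recovering a known
flux ratio through the full measurement chain:

```bash
python examples/relative_vcs_recovery.py
```

```
true V_CS ratio:       2.00
recovered ratio:       2.137
relative error:        6.9%
```

Other examples cover the first-turn labeling schemes
(`first_turn_schemes.py`: citrate exclusively M+2 under glucose and
palmitate, M+4 under glutamine), natural-abundance correction,
the anaplerosis sweep, the cohort screen and growth statistics. The same
workflow is scriptable from the shell via the `tcaflux` CLI
(`simulate`, `correct`, `vcs`, `dilution`, `steady`, `cyt`,
`correlate`, `de-filter`, `prognostic`, `pca`, `cluster`, ...).

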
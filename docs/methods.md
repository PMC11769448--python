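# Methods

## Scope and data flow

`respsens` implements the data-analysis chain of an air-liquid-interface
respiratory-sensitization assay: plate-level resazurin viability →
dose-response curves per cell compartment and their average → CV75
estimation → exposure-dose plan → flow-cytometric rMFI of CD86/CD54/TSLPr
on dendritic-like THP-1 cells → threshold calls → panel accuracy. Inputs
are plain CSV/YAML (`wells.csv`, `events.csv` or `mfi_summary.csv`,
`panel.yaml`); every stage is importable on its own and also bound into
`run_pipeline` and the `respsens` CLI.

## Viability and CV75

Relative viability is the blank-corrected sample fluorescence as a
percentage of the blank-corrected vehicle control. Values are **never
clamped**: noisy wells above 100% or below 0% participate as-is, and a
point above 100% still counts as "above 75%" in bracket selection. Blanks
and vehicle controls are matched per compartment (pooling across
compartments is not assumed); replicate viabilities are averaged per dose
before any interpolation.

The CV75 estimator is deliberately the two-point log-linear interpolation —
not a parametric Hill/log-logistic fit. Anchors follow the global
definitions: `a` is the minimum viability among points above 75% and `c`
the maximum among points below, even when the curve is non-monotone; a
warning is logged when the selected doses are not adjacent. Ties are broken
toward the crossing (largest dose attaining `a`, smallest attaining `c`).
A point at exactly 75% returns its dose directly (smallest such dose if
several). Logarithms are base 10. A curve entirely above 75% yields a
fallback result (no CV75) and the exposure plan substitutes the maximum
tested dose; a curve entirely below 75% is an error instructing a downward
dose-range extension, since no bracket exists. The low exposure dose is
exactly half the high dose at full precision; rounding is applied only at
display time (3 significant figures).

## Cytometry

Dead events (boolean flag, or raw dead-stain intensity above a single
global cutoff supplied in config) are removed from both stained and
isotype tubes with the same rule; the condition's viable fraction is taken
from the stained tube. Geometric means are `exp(mean(log x))`; non-positive
intensities — possible after instrument baseline subtraction — are dropped
with a logged count, because the geometric mean is otherwise undefined.
rMFI subtracts each tube's isotype control before forming the sample/vehicle
ratio; a non-positive denominator marks the condition non-evaluable
(`degenerate_denominator`) rather than raising, and negative rMFIs are
returned unclamped with a warning. The 75% flow-viability gate is applied
per condition and is **strict below**: exactly 75% remains evaluable. The
gate changes evaluability only; the computed value is retained for audit.

## Prediction

Threshold calls use an inclusive ≥ rule (an rMFI of exactly 120% is "+"
at the 120 criterion). Non-evaluable conditions produce "n/a" and leave
the accuracy denominator. Accuracy is rounded half away from zero to an
integer percent, the convention consistent with 11/14 → 79, 8/12 → 67,
12/14 → 86 and 11/12 → 92. Truth labels (respiratory sensitizer or not)
are supplied as panel metadata — the package hard-codes no chemical's
class; for a panel of skin sensitizers and non-sensitizers the correct
call is everywhere negative, so accuracy is the true-negative rate of the
respiratory readout. Significance of marker induction (one-sample t-test
of replicate rMFIs against 100%, two-sided; `*` p ≤ 0.05, `**` p ≤ 0.01)
is reported alongside calls but never gates them. Run-level predictions
follow the two-of-two / majority-of-three concordance rule; a discordant
pair is returned as indeterminate rather than guessed.

Two open choices were resolved conservatively: results are reported per
dose tier (no tier-combined chemical call is invented), and where a single
per-chemical value is nevertheless needed the maximum evaluable rMFI
across tiers is used.

## Synthetic data generator

The generator emulates the study conditions, not any particular dataset.

* **Viability plates.** Each compartment follows a log-logistic decay
  `v(d) = top / (1 + (d/EC50)^h)` with the EC50 re-parameterized so the
  noise-free curve crosses 75% exactly at a configured true CV75
  (`top` default 100%, hill slope default 1.2); a non-cytotoxic chemical is
  flat at `top`. Gaussian noise (default SD 1% viability, a testability
  choice — inter-replicate variance is not published for this assay) is
  added on the viability scale, truncated at 0, then mapped to fluorescence
  between the blank and vehicle levels; control wells carry the exact
  configured levels. Default 3 replicates per dose.
* **Flow conditions.** Event intensities are lognormal (the standard
  cytometry intensity model), geometric CV default 0.25. The stained-tube
  geometric mean is `isotype + m·(baseline − isotype)`, so the expected
  pipeline rMFI is exactly `100·m` — a closed-form truth emitted with every
  condition. Dead events are Bernoulli (default 5%) and carry an elevated
  dead-stain intensity (geometric means 80 vs 8000 a.u., cutoff 1000), so
  both the flag-based and intensity-based gating paths are exercised.
  Default 10,000 events per tube, the assay's acquisition count (assumed to
  be pre-gating acquisition).
* **Panels.** One master seed spawns per-chemical substreams
  (`numpy.random.SeedSequence.spawn`); the derived seeds are recorded in the
  `truth.json` sidecar, and identical configs reproduce byte-identical CSVs.
  The built-in 14-chemical benchmark panel places per-tier TSLPr targets
  centrally within the band implied by each observed call row (100 / 135 /
  300%), ≥15 percentage points from every decision boundary versus a
  Monte-Carlo error below ~2 points at 10,000 events, and simulates the two
  conditions excluded for low flow viability with a 35% dead fraction.

What passing on synthetic data does *not* show: the generator has no plate
position effects, no compensation/spillover, no debris or doublets, no
instrument drift, and noise magnitudes are assumptions. Recovery tests
therefore validate the estimators and plumbing, not instrument-specific
robustness.

## Numerical choices and problem sizes

* The two-point log-linear CV75 estimator is biased on curved (log-logistic)
  responses: on a factor-2 dose grid with hill slope 1.2 the deterministic
  bias is ≈3.3%, dropping to ≈1.2% on a factor-1.5 grid. Parameter-recovery
  tests use a 9-dose factor-1.5 grid bracketing the true CV75 (worst
  observed error 3.4% over 200 noisy seeds at 1% noise); steep slopes (≥2)
  on coarse grids exceed 5% relative error by bias alone, a property of the
  estimator, not a defect of the generator.
* Recovery suites run 20 seeds each; the end-to-end benchmark simulates the
  full 14-chemical panel at 10,000 events per tube (≈2.5M event rows) in
  well under a minute on one CPU.
* Determinism: all randomness flows through seeded numpy Generators; report
  bundles (JSON with sorted keys, CSV) are byte-identical for identical
  configs and seeds.
* Degenerate inputs have defined behaviour throughout: vehicle ≤ blank,
  all-dead tubes, zero-variance replicates, all-below-75 curves and empty
  panels raise typed errors; non-positive denominators and sub-gate
  viability mark results non-evaluable instead.

## Known limitations

* No FCS binary ingestion; event tables arrive as CSV (an adapter writing
  `events.csv` can be slotted in front without touching the core).
* No parametric dose-response fitting, potency categorization, spectral
  compensation or secreted-cytokine endpoints — out of scope by design.
* The benchmark panel contains no respiratory sensitizers, so panel
  accuracy there measures specificity (true-negative rate) only; the
  classification machinery itself supports positive truth labels.
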
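# Methods

## Task and data model

Both supported designs are 2AFC identification tasks on a fear→anger morph
continuum with 11 grades (morph fraction x ∈ {0, 0.1, …, 1}; 0 = original
fear, 1 = original anger) and 20 face identities. A trial record carries
participant, run/block, condition, identity, morph fraction and the binary
response (1 = "angry"). The masking design crosses 3 visibility conditions
(whole / upper / lower) with every identity × morph cell once per run; two
runs give 440 trials per condition and 40 per morph × condition cell (2.5%
response resolution). The composite design is blocked by judged half; each
block crosses identity × morph × distractor emotion once (440 trials per
block by default). Stimulus order is randomized under the constraint that
consecutive trials never repeat a face identity (shuffle with local repair;
reshuffle fallback).

## Psychometric fit

The anchored logistic `f(x) = L + (U − L)/(1 + exp(−β(x − α)))` is fitted
per response curve by least squares on the proportions (bins are not
weighted by trial count, keeping the objective identical for balanced and
identity-aggregated curves). Anchors are fixed before optimization at the
curve's observed minimum and maximum over its defined bins; positions of
min/max need not be the endpoints. Undefined bins (no trials) are excluded,
never imputed; at least 4 defined points are required.

Numerical choices:

* initialization: α₀ from the linear-interpolated crossing of (L+U)/2
  (fallback 0.5), β₀ = 1, plus a small multi-start grid
  (α₀ ∈ {interp, 0.25, 0.5, 0.75} × β₀ ∈ {4, 16, 64}) to avoid local minima
  on noisy curves;
* trust-region least squares with β ∈ [0, 200] and α ∈ [−2, 3]; cost
  tolerance 1e−12, at most 500 evaluations per start. β is non-negative
  because the task direction fixes the curve orientation — decreasing
  observers surface as near-degenerate fits and are reported, not flipped.
  α may leave the morph range (curves can be shifted partly outside the
  displayed range), but is boxed because on a near-flat curve (β̂ → 0) the
  location is unidentified and would otherwise diverge;
* a flat curve (L = U) returns a flagged degenerate fit with slope 0
  rather than raising.

The boundary summary follows from the first derivative in closed form:
x-threshold = α, y-threshold = (L+U)/2, slope = (U−L)β/4; the test suite
verifies these against numerical differentiation on a 1e−4 grid, and the
optimizer against an exhaustive (α, β) grid search that exploits
`exp(−β(x−α)) = exp(βα)·exp(−βx)` to keep the sweep cheap.

Known property of the anchoring rule: when responses do not plateau within
the morph range, the data-anchored limits lie inside the true asymptotes
and the compensating β̂ makes the fitted maximal slope exceed the latent
generative one even on noiseless data (measured ≈ +2.5% at β = 9, +6.3% at
β = 6.8, +15.8% at β = 4). This is intrinsic to fixing L, U at the data
extremes; estimating asymptotes freely is deliberately out of scope. For
the same reason, refitting a fitted curve's own evaluation re-anchors at
its grid-end values and shifts β upward — exact refit idempotence holds
only when the curve effectively attains its asymptotes on the grid.

## Generative observer

`simulate` draws one Bernoulli response per scheduled trial with

```
P(x) = γ + (1 − γ − λ)·[(1 − w)·F(x; α', β') + w·d]
```

* γ, λ — guess and lapse rates (per condition); the condition's asymptotes
  are γ and 1 − λ. Harder viewing conditions compress the whole curve, so
  the masking defaults are γ = λ = 0.02 / 0.05 / 0.10 for whole / upper /
  lower.
* α' = α_c + a_j + u_i + v_ic − b: the condition boundary plus a face
  identity offset a_j ~ N(0, σ_id²) (default σ_id = 0.08), a participant
  offset u_i ~ N(0, 0.03²) shared across conditions, a participant ×
  condition offset v_ic (stable individual idiosyncrasies per viewing
  condition), and a constant anger bias b (default 0).
* β' = β_c·s_ic with a lognormal mean-1 steepness factor s_ic
  (coefficient of variation `slope_cv`) — individual differences in
  boundary sharpness, stable within a participant × condition.
* a stable vertical response bias δ_ic ~ N(0, σ_bias²) shifts γ up and λ
  down by the same amount (floored at 0), moving the curve toward "angry"
  or "fearful" without changing its span.
* w — interference weight of the to-be-ignored composite half (d = 1 for
  an angry, 0 for a fearful distractor); defaults w_eye = 0.10 when
  judging the upper half, w_mouth = 0.37 when judging the lower half, so
  the mouth judgement is both flatter and more biased.

Default dispersions and steepness values were calibrated so that the
*fitted* per-condition summary statistics of a default simulation — means
and SDs of x-threshold, y-threshold and slope — land on the values typical
of this design at this scale (masking: slopes ≈ 2.2 / 1.6 / 1.0 with
thresholds near 0.5; composite: eye-judgement slopes ≈ 1.3 vs ≈ 0.4 for
mouth judgements, with y-threshold shifts of ≈ ±0.04 and ≈ ±0.13 toward
the distractor). Because the anchored fit is attenuated by identity blur
(a mixture of identity-shifted logistics is flatter than any one of them),
generative β_c sits above 4·slope/(1 − γ − λ).

The stable participant × condition components are not decorative: without
them a participant's two halves of one condition are no more similar than
cross-condition pairs once noise variances are netted out, and split-half
diagonal dominance cannot emerge. Their magnitudes are bounded above by
the between-participant SDs the fitted summaries must reproduce.

`SimConfig.exp1_recovery` is a separate idealized observer for parameter
recovery studies: the response curve is exactly the fitted model family
(global γ = λ = 0.02, no identity blur, no steepness heterogeneity or
bias; only mean-zero participant boundary offsets remain), because
recovering a known parameter requires that parameter to be fixed and the
generative curve to lie in the fitted family.

What the generator does *not* emulate: reaction-time structure (an
optional constant-plus-noise RT column exists only to exercise the
compliance screen), sequential/serial dependencies, learning or fatigue
across runs, asymmetric morph spacing, and identity × condition
interactions. Passing simulation-based tests therefore demonstrates that
the pipeline recovers the structure this observer model generates at the
design's trial counts — not that real observers satisfy the model.

## Screening

A participant is excluded iff endpoint accuracy (morphs 0 and 1, pooled
over conditions) falls below 0.60 AND median RT is under 300 ms — a
conjunction, so slow guessers and fast-but-accurate responders are kept,
and without an RT column nobody is excluded. Both thresholds are
configurable; they are this package's convention, not a replication of any
particular study's screening.

## Split-half cross-validation

Halves: with ≥2 runs, run 1 vs run 2; with a single blocked run, the
earlier vs later half of each (participant, block, condition, morph)
cell's trials in schedule order. Both definitions are symmetric: swapping
halves exactly transposes train/test roles.

For each participant and direction, ss² (pairwise-defined sum of squared
differences) is computed between every train-half condition curve and
every test-half condition curve. The group-level dominance test averages
the two directions per participant and asks, per row, whether the diagonal
entry is smaller than each off-diagonal entry by the dual criterion at
α = 0.05 (the package's standing significance convention; p-values are
always reported so stricter descriptive statements can be read off).

`model_vs_raw` fits the anchored logistic to each train-half curve,
evaluates it on the stimulus grid, and compares ss²(prediction, test)
against ss²(raw train curve, test). A degenerate train fit falls back to
the raw curve, flagged. Note that the fitted curve also beats the raw
curve under a *flat* truth — a ~2-parameter smooth fit to 11 noisy bins
has far lower prediction variance — so the advantage demonstrates noise
removal, and only the curve-shape summaries demonstrate sigmoid structure.

## Identity threshold normalization

Identity-level curves (averaged over participants) are fitted per
condition; each identity's (x, y) threshold difference from the condition
mean over non-degenerate fits defines a rigid shift (Δx, Δy). The shift is
applied to the identity's raw curve points, which are then re-binned to
the nearest grid level (half-width 0.05); points outside [−0.05, 1.05] are
dropped and counted. Shifted proportions are deliberately not clipped to
[0, 1], keeping the transformation invertible; per-bin means carry their
unequal counts. Because shifts are rigid translations, no identity's
fitted slope changes; aligning thresholds sharpens the group sigmoid
whenever identity scatter is present.

## Inferential conventions

* Dual criterion: a comparison is significant only if both the paired
  t-test and the Wilcoxon signed-rank test fall below α (default 0.05).
  The Wilcoxon null is exact for n ≤ 25 pairs, normal approximation with
  continuity correction above; all-zero differences leave it undefined and
  the decision negative. Fewer than 5 pairs is an error.
* Repeated-measures ANOVA: fully-within designs of any number of crossed
  factors, each effect tested against its effect-by-subject error term via
  orthonormal-contrast projection. Greenhouse–Geisser ε (bounded to
  [1/df, 1]) is estimated from the contrast covariance and applied to every
  effect with more than one numerator df; corrected and uncorrected
  results are both emitted. Partial eta squared is SS_eff/(SS_eff+SS_err).
  Sums of squares below 1e−12 of the data's total variation are treated as
  exact zeros so constant data yields F = 0 rather than a ratio of
  rounding noise. Unbalanced or incomplete designs are rejected, not
  imputed. The implementation is cross-checked in the test suite against
  pingouin (one- and two-way, ε, η²p) and statsmodels AnovaRM (three-way).
* Compact letter display: letters are the maximal cliques of the pairwise
  non-significance graph (dual criterion at α = 0.05), labelled in order
  of decreasing group mean — a convention of this package.

## Problem sizes

The test and acceptance runs simulate at the designs' native scale — 28
(masking) and 29 (composite) observers, 40 trials per cell — and use 20
seeds for recovery, 40 replicates for dominance rates and 15 for
model-vs-raw rates, sizes at which the replicate proportions are stable to
a few percent. The brute-force fit oracle sweeps α in steps of 0.001 over
[−0.5, 1.5] and β in steps of 0.01 over [0, 50] on 25 fixture curves.

## Known limitations

* The anchored-fit slope overestimates the latent maximal derivative of
  shallow observers (quantified above); between-condition slope
  *comparisons* remain interpretable because the bias is monotone, but
  absolute slopes from shallow conditions should be read as
  anchored-model slopes, not latent ones.
* Thresholds of near-flat curves are weakly identified; they are boxed to
  [−2, 3] and should be interpreted jointly with the slope and the
  degenerate flag.
* The single-run split-half definition (occurrence order within cells) is
  one of several defensible choices for blocked designs; outputs label the
  halves so the choice is visible.
* Least squares on proportions follows the classical formulation; a
  binomial-likelihood fit would weight bins by trial count and is out of
  scope.
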
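# Methods

## Data model

One record is a *cow-visit*: farm, visit month, cow id, a locomotion score
`ls` on the DairyNZ 0–3 scale, four analysed binary in-parlour indicators
(`sw`, `awd`, `shh`, `oh`), and three further checklist indicators (`oci`,
`scb`, `ab`) that proved unobservable in practice and are carried as
missing so that readers/writers handle them, but never analysed. Only
cow-visits holding both an LS and an IPS record enter the analysis; pairing
is an inner join on (farm, month, cow_id), with dropped records counted per
side. A cow observed in several months contributes several records treated
as independent draws — the analysis pools observations without a
repeated-measures adjustment, so the package does the same.

Severe lameness is rare (<0.3% of observations), so scores 2 and 3 are
amalgamated: the binary reference is *lame* = (LS ≥ 2), and the classifier
target is the three-class outcome {0, 1, ≥2}.

## Screening diagnostics

For a binary test against the lame reference the package computes Se, Sp,
PPV, NPV from the 2×2 table. Interval methods:

- **Se/Sp: Clopper–Pearson exact** (beta-quantile form). Chosen because the
  two degenerate published rows (133/133 detections, lower bound 97.3%;
  3992/3992 negatives, lower bound 99.9%) are reproduced exactly by this
  method. Exact intervals are conservative — simulated coverage at n = 100
  is ≥ 95% for every true proportion, which the suite checks.
- **PPV/NPV: standard logit** (Wald on the logit scale, variance
  1/x + 1/(n−x)). The source tables do not state their predictive-value
  interval method; the logit interval is the common default of the clinical
  calculators involved. Point estimates are reproduced exactly; interval
  tails for PPV/NPV are therefore *not* promised digit-for-digit. A
  predictive value of exactly 0 or 1 has no logit interval and is reported
  bare.

A metric with a zero denominator is reported as absent (`None`/NaN), never
as 0 or 1. Phi coefficients are computed from the 2×2 cell counts and equal
the Pearson correlation of the binary columns (property-tested); a pair
involving a constant column is undefined and rendered NaN.

Reports keep full precision in memory and round only in the rendered
layer: percentages to one decimal, half-up (0.25% prints as 0.3%).

## Decision tree

Gini impurity G = 1 − Σ p_c² over the class proportions at a node
(≤ 2/3 for three classes). Splits maximise the unweighted-count impurity
decrease ΔG = G(parent) − (n_L/n)G(left) − (n_R/n)G(right); with four
binary features the search is exhaustive over at most four candidates, and
a brute-force oracle in the suite confirms greedy agreement node-by-node.
Ties are broken by the fixed indicator order SW, AWD, SHH, OH (the
checklist order); leaf predictions take the majority class, ties toward
the lower class index. Both tie-breaks are determinism choices; the
protocol itself is silent on ties.

Training is grow-then-prune: grow to maximum depth (stop only on purity,
feature exhaustion along the path — no feature repeats, so depth ≤ 4 — or
no positive-ΔG split), then post-prune bottom-up, collapsing any internal
node with ≤ 20 observations (the rule is read literally as *strictly more
than 20 to split*, so 21 may split) or ΔG < 0.005. The 0.005 floor is the
protocol's complexity/accuracy balance. Grow-then-prune can differ from
enforcing the thresholds during growth (a weak split can enable a strong
descendant split); a `growth="constrained"` mode exposes the alternative.

Cross-validation stratifies on the three-class outcome: within each class,
observations are shuffled (seeded) and dealt round-robin into k = 4 folds,
so per-class fold counts differ by at most one and each fold holds ≈ 25% of
the data (at the study's class counts: test folds of ≈ 1030, training
complements of ≈ 3095). Each fold serves once as the test set; the
classifier with the highest held-out accuracy is selected, ties to the
lowest fold index. Whether the original analysis stratified on three or
four LS classes, or seeded its split, is not stated; three classes and an
explicit seed are used here.

Classifier metrics are one-vs-rest per class: TPR = TP/(TP+FN),
FPR = FP/(FP+TN), precision = TP/(TP+FP), and accuracy = trace/total of
the 3×3 confusion matrix; accuracy equals the class-count-weighted mean of
the TPRs (checked as an invariant). Fold-level and selected-classifier
metrics are both emitted; published results correspond to the selected
fold only.

## Synthetic herd generator

The generator emulates the study design, not cow biology. Per farm and
month, a configured number of cows is observed (the preset uses the
published monthly visit totals, 3006 + 1119 = 4125 cow-visits over nine
visits; an `every_kth_sampling` helper models the every-third-cow parlour
protocol when explicit counts are not given). Each observation draws
LS ~ Categorical(class_probs) and, given the class c, indicator flags by
thresholding Z ~ N(0, Σ(ρ)), Σ exchangeable with correlation ρ, at
Φ⁻¹(p[c][i]) — so marginals are exact by construction and ρ is a single
within-class dependence knob. With ρ = 0 the indicators are conditionally
independent and the ≥k composite rate equals the Poisson-binomial tail
(exact 16-outcome enumeration, `composite_tail_probability`), which the
suite verifies at n = 200,000.

### Calibration of the preset, and what it cannot do

- `class_probs` per farm: the published LS shares (70.9/26.0/2.9/0.2% and
  66.2/30.2/3.3/0.3%).
- Lame rows (LS 2 and 3, not separated in the source): the published
  per-indicator sensitivities (0.421, 0.474, 0.767, 0.429).
- Non-lame rows: the pooled non-lame rate of each indicator must equal
  1 − Sp (0.061, 0.072, 0.029, 0.149). Assigning that rate identically to
  LS 0 and LS 1 would make the two classes statistically identical, capping
  any classifier's accuracy near 73% — flatly contradicting the published
  classifier's 97.9% class-1 TPR. The preset therefore fixes LS 0 near zero
  (0.002/0.002/0.001/0.02; sound cows rarely show behavioural signs, while
  overgrown hooves occur structurally) and gives LS 1 the remaining mass,
  preserving the pooled marginals exactly.
- `latent_rho = −0.30`. The valid exchangeable range in four dimensions is
  (−1/3, 1). Positive ρ makes indicators co-occur and *lowers* the ≥2
  composite rate (to 0.474 as ρ → 1); negative ρ spreads positives across
  indicators and raises it. Under independence the lame-class ≥2 rate is
  0.7297; at ρ = −0.30 it reaches ≈ 0.84, and even at the PSD boundary
  ρ → −1/3 only ≈ 0.865. The published composite sensitivity of 93.2% is
  thus *unreachable* within this model class: the real lame cows'
  indicator joint distribution is more strongly negatively associated (or
  more heterogeneous) than a single exchangeable Gaussian copula can
  express. The preset keeps ρ = −0.30, comfortably inside the valid range.
- Phi bounds: for binary variables, φ(indicator, lame) is fully determined
  by Se, the pooled false-positive rate and the 3.2% prevalence. The
  implied values are ≈ 0.25 (SW), 0.27 (AWD), 0.59 (SHH), 0.14 (OH) — the
  published Phi table (0.405–0.572 for all four) is not mutually consistent
  with the published Se/Sp table, and no generator matching the latter can
  reproduce the former. The suite asserts the attainable qualitative
  pattern: inter-indicator |φ| < 0.2, strong lameness association for
  SW/AWD/SHH (with SHH > 0.3), weak-positive for OH.

Consequently, passing tests show that the *methods* behave correctly on
data with the published marginal structure; they do not show that the
generator reproduces the unpublished joint distribution (composite
sensitivity, Phi matrix, and exact tree topology on real data differ).

Determinism: one `numpy` generator per `simulate_herd` call, seeded from
the config; the two-farm preset and the pipeline derive per-farm and CV
seeds from a single user seed via `SeedSequence`. Identical config and seed
give byte-identical CSV output.

## Problem sizes in the test suite

Monte-Carlo checks use 100,000–200,000 observations (vectorised, seconds);
parameter recovery runs 200 replicate herds of 2,000 cow-visits; the
brute-force split oracle runs 100 random instances of 200 observations;
interval coverage uses 10,000 binomial replicates at n = 100. The full
suite completes in well under a minute on one CPU.

## Known limitations

- No seasonal lameness dynamics, no cow-level persistence across months,
  no gait kinematics — observations are exchangeable within farm-month.
- The lame-cow-group exclusion on one study farm (lame cows milked
  separately and never scored) is noted but not simulated; simulated
  prevalence is therefore marginally higher than the field truth would be.
- `oci` can be emitted at a configurable tiny rate for round-trip testing;
  `scb` and `ab` are always missing.
- Predictive-value intervals may differ in the last digit from the source
  tables (method unstated there).
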
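# Methods

This note documents the models, parameters and numerical choices behind
`aabarray`, and what its simulation studies do and do not demonstrate.

## The measurement model

A protein microarray carries 249 full-length human antigens, each
printed in replicate spots placed in distinct blocks, plus negative
controls (PCR mixture without template — no protein, so their signal is
pure background) and bright positive controls (EBV VCA p18, reactive in
essentially all adult sera). One serum is incubated per slide;
spot-level readout is the median fluorescence intensity (MFI, arbitrary
units, non-negative).

Two nuisance processes dominate raw MFI: a spatially smooth background
field from slide production and scanning, and a serum-specific overall
intensity scale (antibody titre, secondary-antibody binding). Both are
handled per patient, never across patients.

## Regional background and the 5-SD call

For antigen spot at position *p* and unflagged negative controls *j*
within radius *r* at distances *d_j*:

    w_j   = 1 / (d_j + 1)^power
    mu_r  = sum(w_j m_j) / sum(w_j)
    var_r = sum(w_j (m_j − mu_r)^2) / sum(w_j) * n_eff/(n_eff − 1)
    n_eff = (sum w_j)^2 / sum(w_j^2)

with `m_j` the control MFIs. Defaults: `power = 2` (inverse-square
interpolation, the common reading of distance-weighted averaging),
`r` = half the block pitch (the scale at which blocks abut and local
means stop being "regional"), and an offset of one coordinate unit in
the weight denominator so a control printed adjacent to a spot cannot
dominate. The layout contract guarantees at least three in-radius
controls for every antigen spot; violating it is an error, not a
fallback.

The Bessel-style factor `n_eff/(n_eff − 1)` matters: with inverse-square
weights the effective control count is only about 4, the plain weighted
SD is noticeably biased low, and a 5-sigma rule turns that bias into
spurious calls. With the correction, calls from regional background
agree with global-control calls on more than 99.9% of antigen-level
calls when the simulated field is flat; disagreement at the raw spot
level (~0.5%) is the irreducible per-spot variance of a 4-control SD
estimate.

Calling: threshold `T = mu_r + 5 sigma_r` ("at least five standard
deviations above the regional average", read inclusively), fold change
`f = MFI / T` with `T` floored at machine epsilon when `sigma_r = 0`
drives it toward zero. Replicates aggregate by the median fold change
(robust to one bad replicate and consistent with the median-based MFI
upstream); the antigen call is `median f >= 1`. Antigens whose
replicates are all flagged are missing for that sample and leave its
denominator. Because numerator and denominator both scale with the
serum intensity, calls and fold changes are exactly invariant under
per-sample rescaling — the operative content of per-patient
normalization, asserted as a test over 1000 random samples.

Group comparison of the per-sample immunoreactive proportion uses the
tie-corrected Kruskal–Wallis test with Dunn's post-hoc pairwise z tests
and Bonferroni adjustment (the conservative default where no adjustment
is named; the implementation is in-package since no installed library
provides Dunn's test).

## Synthetic data

The generator emulates the reference study design, not any particular
slide:

- **Cohort** (defaults): 54 controls / 91 IPMN-LG / 66 IPMN-HG /
  30 IPMN-CA / 137 PDAC (24 T1, 113 T2); per-class age models
  N(43.7, 15.7²), N(63.9, 10.9²), N(63.6, 10.2²), N(66.9, 7.9²),
  N(67.3, 10.5²) years truncated to (15, 95); per-class male fractions
  23/54, 40/91, 40/66, 20/30, 61/137.
- **Array**: 249 antigens × 2 replicates in distinct blocks, 48
  negative controls on an even sub-grid per block (so every antigen
  spot keeps ≥3 in-radius controls, checked at construction), 8
  positive controls, 4 blocks, 250 µm pitch.
- **Signal model**: `MFI = s · (B(x, y) + signal + ε)` clipped at 0,
  with `ε ~ N(0, σ_b²)` (σ_b = 50 fluorescence units by default), serum
  scale `s` log-normal (sd 0.3 on the log
  scale), and `B` = mean 500 + a gentle plane + one localized Gaussian
  bump (sd 10% of the slide span, amplitude 150 by default). A slide-wide
  sinusoid was rejected: it merely rescales the global control SD and
  exercises nothing regional, whereas a hotspot is the minimal field
  where distance-weighted estimation visibly matters. A truly
  seropositive antigen adds `κ · 5σ_b` inside the bracket (κ = 3), i.e.
  it sits κ times the calling threshold above local background in
  expectation, making tests invariant to absolute background settings.
- **Seropositivity truth**: per class, each antigen is positive with a
  baseline probability (defaults 0.004 / 0.008 / 0.008 / 0.018 / 0.004
  for Co / LG / HG / CA / PDAC, chosen to reproduce the reported median
  reactivity pattern ~0.4% / 0.8% / 0.8% / ~1.8% / 0.4%; binomial
  discreteness over 249 antigens makes the realized CA median 4/249 ≈
  1.6%), overridden per antigen by a configurable prevalence map.
  Designated discriminative antigens and every sample's true positive
  set are returned as ground truth.
- **Randomness**: one global seed; each sample's spot noise comes from a
  substream keyed by (seed, crc32(sample_id)), so tables are reproducible
  independently of generation order.

What the generator does **not** model: slide-to-slide batch effects
beyond the serum scale, flagged-spot artifact patterns, antigen-specific
affinity differences, cross-reactivity between antigens, or any
age/sex→serostatus dependence. Consequently, passing tests demonstrate
the correctness and statistical behaviour of the pipeline, not the
clinical performance of any marker set: planted synthetic signal
(prevalence 0.30 vs 0.01) is far cleaner than real autoantibody biology,
which is why simulated panel sensitivities (~70%) exceed the ~34%
reported for real sera.

## Design matrix and cohort filters

Binary calls enter the model; intensities do not. Antigens are dropped
if never positive or if their call column duplicates another antigen's
(lexicographically first name kept; both filters are idempotent).
Samples with any missing antigen are excluded listwise. Class weights
`w_i = n/(K · n_class(i))` make weighted class totals equal and sum to
the cohort size.

Age trimming retains samples inside
[max over classes of the class lower percentile, min over classes of the
class upper percentile] (defaults 5/95). With the reference age models
this window is severe — the control arm is ~20 years younger than the
disease arms, so most removals are young controls and only ~90 of 378
synthetic samples survive. The trim is therefore part of the default
end-to-end pipeline (where age confounding is the concern on real data)
but is skipped in the package's simulation studies, where serostatus is
drawn independently of age by construction and trimming is pure sample
loss. One caveat documented rather than hidden: for empirical
percentiles, coinciding class distributions still lose their own tails
inside the window; only the 0/100 setting is a strict no-op.

## The penalized model

Weighted multinomial logistic regression in the symmetric
(over-parameterized) coding, objective

    (1/Σw) Σ_i w_i [logsumexp_k(η_ik) − η_i,y(i)] + λ Σ_j pf_j Σ_k |β_jk|

with `pf = 1` for antigens and `pf = 0` for age (z-scored) and sex
(0/1). Solved by FISTA with backtracking line search and adaptive
restart; convergence is declared when the relative objective change
stays below 1e−9 for three consecutive iterations (comfortably inside
the 1e−7 objective-accuracy contract, cross-checked in tests against an
independent L-BFGS-B optimizer on the split formulation β = β⁺ − β⁻).
The λ grid is geometric over two decades below the data-driven λ_max
(the largest penalized-gradient magnitude at the unpenalized-covariates
fit, at which the selection is exactly empty), 50 points by default,
warm-started. For unpenalized rows the gradient is orthogonal to the
all-classes-equal direction, so starting from zero keeps them
sum-to-zero across classes — the identifiability convention under which
coefficients are reported. The per-class split of a penalized
coefficient is not unique (only class differences are); tests compare
solvers on objective values and differences.

λ selection: inner stratified 5-fold CV on weighted multinomial
deviance. The default is the **one-SE rule** (sparsest λ within one
standard error of the minimum): the package's purpose is marker
selection, and the prediction-optimal minimum rule measurably
over-selects — on planted-signal cohorts it admits 12–16 exchangeable
noise antigens where the one-SE rule admits 0–3, at identical recovery
of the planted 14. The minimum rule remains available (`rule="min"`)
and is what the cross-validation-optimism study uses, since apparent
optimism is a property of models tuned to fit.

## Evaluation

Hand–Till pairwise AUC: rank the n_i + n_j samples of classes i, j by
the model's probability of class i (midranks on ties), then
`A(i|j) = (S_i − n_i(n_i+1)/2)/(n_i n_j)`; symmetrize
`A(i,j) = (A(i|j) + A(j|i))/2`; the M-value is the mean over the
c(c−1)/2 pairs. Verified against exhaustive concordant-pair counting
and, tie-free, against the trapezoidal ROC AUC.

Outer CV: stratified k-fold (k = 10 by default, reduced with a warning
to the smallest class size when needed); each fold refits the model
end-to-end on the training split — class weights recomputed, λ
re-chosen by inner CV — and held-out class probabilities are pooled
before computing the CV M-value and confusion matrix (pooling, rather
than per-fold averaging, keeps small classes estimable). The antigen
filter itself is fixed on the full design, mirroring a fixed printed
panel. Predicted class is the argmax probability with ties resolved to
the earlier class in the fixed order (Co, IPMN-LG, IPMN-HG, IPMN-CA,
PDAC).

Marker metrics use the clinical dichotomy IPMN-LR = LG vs IPMN-HR =
HG ∪ CA. A marker's direction is the group where it is more prevalent;
sensitivity is its positive rate in that group and specificity the
negative rate in the other. The panel comprises HR-markers with
specificity **strictly above** the gate (default 90%, so a marker at
exactly 90.0% is excluded) and calls a sample positive on ≥1 member.
Percentages are rounded half-up to one decimal, matching tabular
reporting conventions.

## Simulation studies (`aabarray.experiments`)

- **Marker recovery**: 14 antigens planted at prevalence 0.30 in one
  class (round-robin over the five) and 0.01 elsewhere, full cohort
  size, default noise, class-*uniform* baseline reactivity (0.008).
  The uniform baseline is deliberate: under the class-dependent
  defaults every non-planted antigen genuinely discriminates invasive
  IPMN (1.8% vs 0.4% prevalence), so counting its selection as a false
  positive would misread true weak signal as noise. Acceptance:
  ≥12/14 recovered with ≤3 false selections in ≥8 of 10 seeds.
- **Reactivity profile**: default conditions, 20 seeds; the per-class
  median immunoreactive proportions must reproduce
  Co ≈ PDAC < LG ≈ HG < CA with Kruskal–Wallis p < 0.001.
- **CV optimism**: a one-third-size cohort (18/30/22/10/45, keeping the
  class proportions) with outer k = 5, inner 3-fold, 15-point λ path —
  sizes chosen so ten replicates stay tractable; the mean CV M-value
  must not exceed the mean apparent M-value.

A note on what the regional-vs-global comparison can show: any smooth
background contamination that negative controls sample inflates a
global 5-SD threshold roughly in proportion to its own peak, so global
calling rarely *false-positives* under a gradient — it loses
*sensitivity* instead. The package's gradient test asserts exactly
that: under a strong localized bump, regional calling detects strictly
more true positives while its false-call rate stays at the ≤1% noise
floor.

## Known limitations

- The lasso path is computed at a fixed grid; selection counts can
  differ by 1–2 antigens across BLAS builds at the path's deep end.
- `n_eff ≈ 4` under inverse-square weights makes per-spot thresholds
  noisy; replicate aggregation absorbs most of it, but single-replicate
  layouts will show ~0.5% call noise.
- The age trim assumes the percentile window is the right tool for
  achieving overlap; matching or covariate adjustment are out of scope.
- Figures (`aabarray.figures`) are best-effort conveniences, not a
  tested surface.
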
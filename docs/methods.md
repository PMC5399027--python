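# Methods

## Pipeline overview

The pipeline evaluates how strongly a toxin perturbs a serum metabolome
over time and how completely candidate treatments rescue it. Stages, in
order: per-platform preprocessing → feature-wise merge of the LC/MS(+),
LC/MS(−) and GC/MS matrices → exogenous-compound removal → biomarker
screening → PCA trajectory → principal-curve MDS with per-animal time
areas → per-metabolite RAUC with re-regulation calls. Every stage is a
pure function of a `PeakTable` (samples × features with sample/feature
metadata) and the `PipelineConfig` thresholds; all randomness flows from
one integer seed.

## Preprocessing

* **Background filter** — a feature is kept iff its mean observed
  study-sample intensity is at least `background.min_ratio` (default 3)
  times its mean blank intensity, missing blank values counting as 0.
  "Background" rules vary across labs; the blank-ratio form with ratio 3
  is common practice and both rule and ratio are config-exposed. Blank
  injections are dropped after this stage — they exist only to define it.
* **80% rule** — keep a feature iff observed in ≥ 80% of the samples of
  at least one study group (QCs and blanks never counted).
* **QC RSD filter** — keep a feature iff its relative standard deviation
  (sample SD, n−1, over pooled-QC injections) is ≤ 15%. Features seen in
  fewer than two QCs cannot be assessed and are removed.
* **Total-ion normalization** — each sample row is divided by its total
  observed intensity; observed row sums become exactly 1. Missing values
  are ignored in the total and stay missing.
* **Ion fusion** (optional, off by default) — features sharing a declared
  grouping window whose study-sample Pearson correlation reaches
  `fusion.min_correlation` are merged by single linkage into one feature
  carrying the summed intensity.
* **Pareto scaling** — columns centred and divided by √SD, fit on study
  samples only; a scaled column has mean 0 and variance equal to its
  original SD. Used immediately before every multivariate fit.

Missing values (`NaN`) are never imputed by any of these filters; a
recorded 0 counts as observed. Model fitting needs a complete matrix, so
the modelling stages apply an explicit half-minimum fill
(`impute_half_minimum`, the standard left-censoring surrogate) on their
own working copies.

## Multivariate models

**PCA** is an SVD of the column-centred matrix; loadings orthonormal,
explained-variance fractions non-increasing. Its Q² uses row-fold
cross-validation where each held-out cell is predicted from the row's
*other* variables through the training loadings (a rank-one downdate
gives this in closed form) — plain row-holdout would just reproduce R²X.

**OPLS-DA** follows the O-PLS decomposition: repeatedly extract the
y-predictive weight w ∝ Xᵀy, compute the loading p, strip the component
of p orthogonal to w as an "orthogonal" component, deflate, and finish
with a one-component PLS fit on the deflated matrix. Orthogonal scores
have exactly zero sample correlation with the class vector by
construction. With `n_orth = 0` the model *is* the one-component PLS1
solution. Class labels are encoded ±1; scores are sign-fixed so the
declared positive class has positive mean predictive score. The number
of orthogonal components is chosen by stratified 7-fold cross-validation
(k = 7 is the common chemometrics default), growing while Q² improves by
more than 0.01.

**VIP** is computed over predictive plus orthogonal components weighted
by explained response sum of squares, VIPⱼ = √(p·Σₐ SSYₐ(w_{aj}/‖wₐ‖)² /
Σₐ SSYₐ). Orthogonal components explain none of y, so this reduces to
the predictive component and Σⱼ VIPⱼ² = p holds identically. Published
OPLS-VIP variants differ; this one is declared here and used
consistently.

**S-plot** coordinates are pⱼ = cov(t, xⱼ) and p(corr)ⱼ = corr(t, xⱼ)
with the predictive score t.

## Screening

* **Exogenous removal** — treated-group samples are modelled against the
  pooled control + toxin ("CT") reference by OPLS-DA; candidates are
  ranked by |p(corr)|, and a feature is flagged exogenous iff observed in
  fewer than 10% of CT samples while observed in at least 90% of treated
  samples. Only post-baseline samples enter these counts: dosing starts
  after the baseline bleed, so baseline samples cannot contain decoction
  compounds, and counting them would make the presence rule
  unsatisfiable by construction.
* **Biomarker selection** — per sampling day, OPLS-DA between the toxin
  group and every other group; a feature is a marker iff VIP > 1.0 and
  its Mann–Whitney p, BH-adjusted within the comparison, is < 0.05. The
  thresholds are the field-standard printed values. A raw-p mode
  (`use_adjusted_p=False`) applies the unadjusted rule. At moderate
  effect sizes (≈1.5 SD at n = 10/group) the BH-adjusted cascade caps
  recall near 50% — the unadjusted Mann–Whitney power at that design is
  itself only ≈0.78, and the m ≈ 200-feature correction roughly halves
  it — whereas the raw rule reaches ≈0.86 recall at the cost of false
  positives that the downstream phenotype filter then absorbs. The
  default keeps BH; the choice is a power/FDR trade-off, not a bug.
* **Spearman filter** — each study sample's intensity is paired with its
  own animal's same-day diarrhea score (DS) and relative body weight
  (RBW); a marker survives iff |rho| ≥ 0.5 against at least one
  phenotype. Ties get average ranks.

## Deregulation scores

The **principal curve** is fitted in a reduced PCA space (smallest
number of components explaining ≥ 85% of the biomarker-matrix variance,
config-exposed) by Hastie–Stuetzle iteration: initialise the parameter at
the PC1 projection, then alternate (a) projecting every sample onto the
current piecewise-linear curve, (b) smoothing each coordinate against
the arc-length parameter, (c) reparametrising by arc length, until the
total squared projection distance changes by less than `curve.tol`
(default 1e−4, max 50 iterations; non-convergence is reported in the
result object, not raised). The coordinate smoother is *locally linear*
(degree-1 fit over a rank window of span 0.3): a degree-0 moving average
is biased at the curve ends, pulling them inward so that extreme samples
clamp onto the end vertices — which would break the required linear
limit (on exactly collinear data the curve must reproduce the PC1 line
and the MDS ranking must equal the PC1 ranking; with the linear smoother
it does, exactly). The curve is fitted through the full cloud and
*oriented* by the healthy samples (control-group mean parameter at the
low end); a fit-on-healthy-only mode is config-selectable.

**MDS** = arc-length position of the sample's projection ÷ total curve
length, clipped to [0, 1]; the orthogonal projection residual is emitted
as a diagnostic column. "Projection distance" could also mean the
orthogonal residual, but the normalized along-curve position is the
established deregulation-score convention and is what makes 0 = healthy
and 1 = maximally deregulated well-defined. Per-animal MDS-vs-day areas
are trapezoids over the sampled days; groups are compared pairwise by
Mann–Whitney on the per-animal areas (per-animal, rather than on group
means, so the tests have replication).

**RAUC** — relative level r(d) = log2(x / same-day control mean)
(control = 0 by construction; an `fc` mode gives x/mean − 1), integrated
as the trapezoid of |r(d)| over the day 4–10 window. The absolute value
is deliberate: deviation in either direction is dissimilarity to
control. Curves are per animal, enabling the per-metabolite group-vs-
toxin Mann–Whitney tests; p-values stay unadjusted (screening
convention for re-regulation calls), and the call additionally requires
the group median below the toxin median. Intersections of re-regulated
sets across treated groups give the "common re-regulation" lists.

## Shared statistics

Mann–Whitney U: exact enumeration when the pooled size is ≤ 12 with no
ties, else normal approximation with tie correction and a continuity
correction that returns exactly p = 1 at the symmetric centre and when
the tie-corrected variance vanishes; two-sided throughout. BH adjustment
is the step-up procedure with cumulative minimum (order-preserving,
adjusted ≥ raw). Spearman is the Pearson correlation of average ranks.
All four are thin, contract-checked wrappers over scipy / statsmodels /
numpy primitives except the asymptotic Mann–Whitney path, which is
written out to honour the p = 1 centre convention.

## Synthetic study generator

The generator emulates a six-group rodent toxicity/rescue design with
full ground truth. Model, on the log2 scale:

x(sample, feature) = baseline_f + animal-effect_{a,f} +
sign_f·δ_f·profile(day)·attenuation(group) + ε

* baselines U(9.5, 16) log2 (≈0.7k–65k counts); intensities below the
  detection limit (log2 = 9) are left-censored to missing, and values in
  the next log2 band are missing with probability 0.3;
* animal×feature random intercepts N(0, 0.25²), residual noise
  N(0, 0.4²) — within-animal correlation over days plus analytical noise;
* effect profile {−1: 0, 1: 0.6, 4: 1.0, 7: 0.25, 10: 0.05}: onset at
  day 1, peak at day 4, near-complete recovery by day 10;
* attenuations C = 0, T/HQD = 0.2, T/SS = 0.35, T/BB = 0.55, T/SF =
  0.75, T = 1 — the graded-rescue ordering the evaluation must recover;
* peak effect δ = 4.5 × residual SD (≈2.1 log2, ≈4-fold) with ±30%
  per-feature jitter and random sign, planted in 40 of 200 endogenous
  features. Only features with baseline ≥ 13 log2 are perturbed: this
  keeps the total ion current composition-stable (real serum TICs are
  carried by abundant stable peaks, so TIC normalization must not
  redistribute a group effect across features) and keeps down-regulated
  biomarkers above the detection limit so their fold changes are
  measured rather than censored. At this effect size most perturbed
  metabolites correlate with the phenotypes above the |rho| = 0.5
  screen, as in the study design this emulates; at ≈3 SD about half
  would fall below it;
* 8 decoction-only features per treated group (present only in that
  group's post-dosing samples), 15 background contaminants (present in
  blanks at full strength), both at solid mid-range abundance;
* 10 pooled-QC injections (per-feature pool mean with 0.1 log2
  analytical noise, ≈7% RSD — under the 15% gate) and 4 blanks;
* phenotypes per animal-day: DS = clip(3·deregulation + N(0, 0.25²),
  0, 3) on the 0–3 ordinal scale's continuous surrogate, RBW = 100 −
  30·deregulation + N(0, 1.5²) percent of baseline weight.

No per-animal variance components are published for the emulated design,
so these defaults are declared free parameters, chosen once as realistic
for a strong toxicant study; they are not calibrated values.

What the generator deliberately does **not** emulate: retention-time
drift, batch effects, correlated metabolite modules, heteroscedastic
(intensity-dependent) noise, m/z-level structure. Passing tests
therefore demonstrate that the pipeline recovers the *statistical*
structure it assumes — not that it is robust to every artefact of real
LC-MS data.

## Numerical conventions

* PCA loading signs fixed by making each component's largest-|loading|
  entry positive; OPLS score sign fixed by the positive class.
* Cross-validation folds are stratified and derived deterministically
  from the seed; k is capped by the smaller class.
* Duplicate curve vertices (zero-length segments) are dropped before
  projection; the projection is vectorised over all segments.
* Degenerate inputs raise informative errors: all-constant matrices,
  single-class labels, constant columns under Pareto scaling or
  S-plots, samples with no observed intensity, groups missing at a
  requested day.

## Problem sizes

The default study is 63 animals × 5 days (315 study samples) with ≈250
features — the full design scale. Multi-seed validation (attenuation
ordering, null calibration) uses 10–20 independently generated studies;
the oracle and closed-form checks run on 4–50-sample toys. These sizes
were chosen so the entire validation battery completes in minutes on a
single CPU while still exercising the full six-group design.

## Known limitations

* OPLS-DA Q² and R² values depend on the (proprietary, undocumented)
  conventions of commercial chemometrics tools only loosely; this
  package's cross-validation scheme is its own declared contract.
* The exogenous-feature rule is presence/absence-based; a decoction
  compound that co-elutes with an endogenous metabolite (present in CT)
  is by design not flaggable.
* MDS is a relative score: values are comparable within one fitted
  curve, not across independently fitted studies.
* The BH-adjusted selection cascade is conservative at small n and
  moderate effects (see Screening above).
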
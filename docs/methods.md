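# Methods

## Data model and diagnostic rules

A cohort is one row per participant: `mir194` (relative circulating
expression in 2^−ΔΔCT units, dimensionless, > 0), up to 42 examination items
(EIs) in five categories (basic information 3, biochemistry 18, blood 5,
echocardiography 9, urine 7), lumbar-spine (L1–L4) BMD in g/cm² and the spine
T-score in SD units.  Bone status follows the WHO T-score convention:
normal > −1.0, osteopenia in (−2.5, −1.0], osteoporosis ≤ −2.5.  The T-score
is always taken from the input, never recomputed from BMD, because no
young-adult reference population is carried with the data.  The binary risk
label used throughout ROC analysis is *osteoporosis only*.

Missing values are permitted only in EI columns.  Screening uses
pairwise-complete observations (maximizing power per item); model fitting is
complete-case on the selected input features (keeping the network
well-defined).

## Synthetic cohorts

The generator is a Gaussian copula.  A latent multivariate normal over
(marker, 42 EIs, BMD) carries the dependence; each margin is produced by a
monotone transform of its latent coordinate, so rank-based (Spearman)
structure survives any marginal shape.  A Spearman target ρ_s is converted to
the latent Pearson correlation by r = 2·sin(π·ρ_s/6), the exact bivariate-
normal identity.  The assembled matrix is projected to the nearest unit-
diagonal PSD matrix (eigenvalue clipping) if targets conflict.

Default planted structure, chosen once to mirror the study conditions:

| feature(s) | Spearman target vs BMD | marginal |
|---|---|---|
| mir194 | −0.365 | lognormal (right-skewed) |
| age | −0.25 | integer-uniform 48–66 y |
| weight | +0.25 | normal (62 ± 8 kg) |
| LVDS, LVEDD, ALT, U_EC, U_ECH, GGT | −0.185 | normal / lognormal / zero-inflated count |
| UA, CKMB_CK | +0.185 | normal / lognormal |
| remaining 32 EIs | 0 | normal, lognormal or count |
| LVDS–LVEDD | pairwise 0.63 | — |

The eight "extremely weak" items are planted at |ρ| = 0.185, the midpoint of
the band in which a correlation is simultaneously extremely weak
(|ρ| ∈ [0.1, 0.2)) and significant at p < 0.01 for n = 230 (which requires
|ρ| ≳ 0.17).  ALT-like enzymes and urine counts get right-skewed and
zero-inflated margins so that marginal-normality tests reject them, as they
should.

Class proportions (defaults 0.400/0.343/0.257 for the main cohort,
0.400/0.267/0.333 for the external preset) are applied as BMD quantile cuts
with largest-remainder rounding, giving *exact* group counts (92/79/59 at
n = 230; 12/8/10 at n = 30).  The T-score is an affine image of BMD
calibrated per sample so those cuts land exactly on −2.5 and −1.0; order
preservation makes counts deterministic for every seed.

What the generator does *not* emulate: the exact units and ranges of all 42
real items, any non-monotone or interaction structure between EIs and BMD,
and measurement error in BMD/T-score.  Consequently a model that only
exploits pairwise monotone associations can reach, but not exceed, the
planted multiple correlation (~0.6 on the latent scale); passing tests show
the machinery recovers the planted structure, not that real cohorts carry
that much (or little) signal.

## Screening

Spearman ρ with average-rank ties; two-sided p from the t-approximation
t = ρ·√((n−2)/(1−ρ²)) on n−2 df (an optional permutation p, 10 000 shuffles,
serves small cohorts).  An item is BMD-correlated iff |ρ| > 0.1 **and**
p < 0.01 — a fixed per-item rule, deliberately without multiple-testing
correction.  Verbal bands on |ρ|: [0, 0.1) none, [0.1, 0.2) extremely weak,
[0.2, 0.4) weak, [0.4, 0.7) moderate, [0.7, 1] strong; the cut-points are a
reconstruction consistent with the labels "weak" for 0.365 and "moderate" for
0.649 and are configurable.  Collinearity is pairwise |ρ| > 0.3; in
`noncollinear` selection mode the lower-|ρ| member of each flagged pair is
dropped.  Ties in ranking break by registry order for determinism.

## RBF networks

Prediction is clip(Σᵢ wᵢ·exp(−‖x−cᵢ‖²/(2σᵢ²)) + b, 0, 1); inputs and the BMD
target are min-max normalized to [0, 1] on the training cohort (external
values clip into range).  The architecture search emulates an automated
problem-solver:

- candidate center counts k = 2 … min(20, n_train/5);
- centers by seeded k-means (single restart) on the training inputs;
- per-center width σᵢ = 2.0 × mean distance to the 2 nearest centers.  The
  overlap factor 2.0 matters: with bare nearest-center widths the kernels
  barely overlap and the interpolant is spiky — on well-specified synthetic
  data its holdout correlation was lower *and* more variable (0.51 ± 0.09)
  than with the factor (0.565 ± 0.09), and worse than the linear baseline
  (0.576).  Widths are floored at 1e−6 against duplicate centers;
- output weights and bias by ridge least squares, λ = 1e−6 (sweeps up to
  1e−2 were indistinguishable);
- k selected by verification-set Pearson correlation (2:1:1
  train/verify/test holdout: ⌈n/2⌉ train, the remainder split with the extra
  participant to verify — 115/58/57 at n = 230).

R_Tr and R_Te are Pearson correlations of prediction vs normalized BMD on
the training and test sets.  The comparison baseline is ordinary least
squares on the same inputs, scored by Spearman ρ of its fitted values (a
logistic variant on the binary label exists behind a flag but is not used in
the main analysis).

## Derivative features and the DANN

For a focal participant the reference cohort (everyone else during training;
the full stored training snapshot for external participants) is sorted by
Euclidean distance in the normalized input space (d = 6 dimensions in the
published configuration), ties broken by participant order, and partitioned
contiguously into m nearly equal divisions, remainders going to the nearest
divisions.  From division *d* four features are computed: own ANN I output,
division mean ANN I output, division mean distance, division osteoporosis
proportion.  Only *reference* labels enter — a participant's own label never
influences her own score; the transductive use of neighbours' labels is part
of the method's design and is why external scoring requires the training
reference snapshot.

Both m (2 … 10) and the division index d (1 … m) are searched jointly — each
(m, d) pair yields one candidate ANN II, 54 candidates in total — scored by
verification-set Spearman ρ; ties prefer smaller (m, d).  ANN II consumes the
four features with the distance coordinate scaled by 1/√d̄ (d̄ = input
dimension), keeping all inputs in [0, 1] without a second fitted
normalization (a min-max refit on near-constant proportion columns would be
degenerate).  The default risk cut-off on the BMD-like score is 0.38,
recomputed as the Youden-optimal threshold on retraining; the binary risk
rule is score < threshold.

## Similarity network and clustering

Edges join participants with Euclidean distance < 0.198 in the same
normalized space.  Clustering is by density peaks: ρᵢ counts neighbours
within d_c (default = the edge threshold, since no separate value is given),
δᵢ is the distance to the nearest higher-density point (the global density
maximum takes the maximum distance), and centers are the top-k points by
γ = ρ·δ, with k chosen by the largest gap in the sorted γ sequence (capped at
10, overridable).  Density ties treat the lower index as denser, which keeps
assignments deterministic for duplicate points.  No halo/outlier refinement
is applied.

## Evaluation

ROC curves are empirical over all distinct thresholds; AUC is trapezoidal,
identical to the tie-corrected concordance probability (asserted against a
brute-force pair count).  Score orientation is always explicit: model outputs
track BMD (low = positive), marker expression is anti-correlated with BMD
(high = positive).  The Youden-optimal cut-off breaks ties toward higher
specificity; sensitivity at fixed specificity uses the step rule (no
interpolation) over operating points with SP ≥ 0.9.  The DeLong comparison
uses placement-value covariance components and a two-sided normal reference;
it was cross-checked against an independent reference implementation and
against a subject-swap permutation oracle (mean |Δp| ≤ 0.02 at n = 30).
D'Agostino–Pearson combines the skewness and kurtosis Z² into K² against
χ²(2), with pass/fail at α = 0.01.

10-fold cross-validation refits *everything* per fold — normalization, ANN I,
the (m, d) search, ANN II and the reference snapshot — on the 9/10 training
fold and scores the held-out fold externally, so hyperparameter selection
never sees held-out data; the structural no-leakage property (held-out ids
disjoint from the scoring model's reference) is asserted in the tests, as is
the pooled null (label-shuffled) AUC ≈ 1/2.

## Problem sizes and defaults in the pipeline

The orchestrated run uses the study sample sizes (n = 230 main, n = 30
external), thresholds |ρ| > 0.1, p < 0.01, collinearity 0.3, edge/d_c 0.198,
SP floor 0.9, risk cut-off 0.38, m ∈ 2…10, 10 CV folds; all overridable in
`RunConfig`.  One run seed fans out to per-stage seeds by hashing the stage
name, so stages are independently reproducible.  Seed-averaged checks use
10–50 draws depending on the variance of the quantity.

## Known limitations

- The copula carries only pairwise monotone structure.  Quantities that
  depended on the original data beyond that — the exact number of items
  surviving the screen on re-drawn data (winner's curse shrinks it), the
  SE/SP split of the marker's Youden point (shape-dependent even when J and
  AUC match), which division size wins the (m, d) search, and out-of-fold
  correlations near the planted information ceiling — are reproduced only up
  to those limits.
- The original automated network search was a commercial tool; the k-means/
  ridge recipe here is a deterministic, documented stand-in and its holdout
  correlations match the published ones only within stochastic tolerance.
- No bootstrap or ROC confidence bands; DeLong is the only curve comparison.
- One marker column is modelled; the package is not a general multi-marker
  panel framework, though nothing in the derivative-feature machinery assumes
  a single marker.
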
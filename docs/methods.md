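# Methods

This note records the model, the synthetic study conditions, the numerical
choices, and the places where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The estimation model

**Curves.** All curves are cumulative DVHs — fraction of structure volume
receiving at least each dose — on a common grid of 0.05 Gy bins spanning
[0, 1.3·Rx]. 0.05 Gy keeps interpolation error far below the 1 %-volume
scale at which results are reported; the grid factor 1.3 leaves headroom
for multiplicative dose noise above Rx. Queries are linear in dose and
return 0 beyond the grid; the maximum dose of a curve is the largest bin
edge with positive volume (no "near-max" percentile), and the mean dose is
the trapezoid integral of the curve.

**Regions.** Voxels are partitioned by the geometry-based expected dose
`e(d) = Rx` inside the target and `Rx·exp(−d/σ_ged)` at signed distance
`d > 0` mm outside, floored at the leaf-transmission level (2 % of Rx)
while in the field and zeroed below the out-of-field cutoff. Cutoffs:
out-of-field below 0.5 % of Rx, leaf-transmission below 5 %, in-field
above. These fractions are configurable; nothing downstream is sensitive
to their exact values because the three low-dose regions contribute only
steps to the final curve.

**GED histogram.** The geometry enters the regression through the
cumulative histogram of `e(d)` over the structure's voxels. This is a 1-D
surrogate for a full 3-D expected-dose construction; only its
principal-component scores are consumed, and a 1-D histogram supplies
those. PCA retains 95 % of variance, but the regression is offered at
least three GED components as candidates: the trailing components carry
the curvature of the geometry-to-dose manifold, and forward selection
discards them when they carry nothing.

**Regression.** Forward stepwise selection per retained DVH component:
the candidate with the largest partial F enters while its p-value is below
α = 0.05; ties break by candidate order (deterministic); rank-deficient
candidates are skipped. Product (interaction) terms are available behind
`allow_interactions` and always flagged, since a product of PCS has no
physical reading. The per-structure R² pools the per-component R² values
weighted by the DVH eigenvalues (one number per structure; the pooling
rule is a reporting choice).

**Diagnostics.**
* Cook's distance from the hat diagonal,
  `D_i = r_i² h_ii/(p s² (1−h_ii)²)`; the test suite verifies this equals
  the explicit leave-one-out refit definition to 1e-8.
* Studentized residuals are externally studentized (the residual scale
  excludes the case under test), the standard form for outlier testing —
  internal studentization lets a gross outlier mask itself.
* The parameter-average chi-squared is `(PRESS/SSE)·(n−p)/n` averaged over
  retained components, with PRESS computed via the hat identity
  `e_(i) = r_i/(1−h_ii)`. For a correctly specified model its expectation
  is ≈ 1 + p/n; over-parameterization inflates PRESS much faster than SSE.
  The exact-fit 0/0 case is defined as 1. The 1.3 threshold marks severe
  over-fitting; the acceptance suite verifies the calibration (mean within
  [0.9, 1.1] for correct fits, > 1.3 for gross over-fits).
* Residual-based diagnostics are suppressed for components whose fit is
  numerically exact (1 − R² < 1e-3): studentized residuals are scale-free
  and would otherwise resolve discretization noise as "outliers".

**Estimates and bands.** A new geometry's estimate recombines: in-field =
PCA mean + predicted PCS · eigenvectors; overlap = overlap-model mean;
leaf-transmission and out-of-field = fixed steps; weights = the query's
region volume fractions. The band half-width propagates each component's
prediction SE through its eigenvector in quadrature,
`z·sqrt(Σ_k SE_k² v_k(d)²)` (z = 1 by default), plus z times the overlap
SD curve weighted by the overlap fraction. Band arithmetic can break
monotonicity at the sub-percent level, so all three curves are repaired by
a left-to-right running minimum and clamped to [0, 1]; the running minimum
preserves the high-dose tail where V99 is read. Queries outside the
training feature hull (5 % margin per feature) carry an extrapolation
warning rather than an error.

**Validation metrics.** V50/V85/V99 differences are read at 50/85/99 % of
the *clinical* curve's maximum dose and reported in % volume as
estimated − clinical (positive = estimate above clinical), summarized as
mean ± SEM with within-6 %/10 % fractions. The subtraction order is a
deliberate convention choice; the alternative order merely flips every
sign.

## The synthetic cohort generator

The generator emulates a single-site cohort (default: a 78 Gy
prostate-like prescription, one OAR of 2000 voxels at 0.1 cm³).

* **Geometry.** Per plan, the OAR centroid sits at distance
  `μ_p ~ Normal(25, 1.5)` mm from the target boundary with within-OAR
  spread 14 mm; voxel distances are `μ_p + 14·z`. The overlap fraction is
  the mass below zero (a few percent, varying across plans). Mixture
  regimes (e.g. 22 mm vs 40 mm centroids) model distinct treatment
  techniques and produce the bipolar score clouds the cluster check looks
  for.
* **Quality.** Planner quality `q ~ Normal(0, 0.45)` truncated at 0 — a
  half-normal: most plans sit near the best achievable (q = 0) with a
  one-sided tail of less optimal plans. Quality can only be worse than
  optimal, so a one-sided population is the physically coherent choice;
  it also means an injected +3 SD shift produces a plan strictly beyond
  3 SD, which is what makes dosimetric outliers operationally
  distinguishable from the worst natural plan (≈ 2.2 SD in a 40-plan
  cohort) by trial re-planning.
* **Dose.** Achieved dose = expected dose × sparing × lognormal noise
  (SD 5 %), with sparing
  `s(d, q) = 0.02 + 0.98·exp(−d/(σ_s(1+q)))` for `d > 0` and 1 in the
  overlap; σ_s = 6 mm. Larger q lengthens the sparing fall-off — less
  sparing everywhere, monotonically and smoothly in both geometry and
  quality.
* **Outlier injection.** Dosimetric: q shifted by `dq·σ_q` (achieved dose
  regenerated). Geometric: the overlap fraction redrawn from far outside
  the population (50–70 %) **and** the within-OAR spread shrunk by 0.6 —
  a compact OAR wrapping the target. The spread change matters: an
  extreme-overlap plan with population spread often lands on the
  extrapolated regression line (high leverage, no residual — not
  influential); the compact geometry produces the influential case the
  curation rules are about. Over-fitting: a hidden covariate lifts a
  random 35 % of in-field voxels to a random dose level (35–60 % of Rx) —
  a DVH shelf no geometric feature explains. The covariate is a property
  of the patient, so the shelf persists through re-planning.
* **Streams.** Every random draw comes from a named substream of
  `(cohort seed, plan index, structure index, purpose code)`, so outlier
  injection and re-planning never perturb other plans, and repeated
  replacement re-plans draw from a block disjoint from trial-replan draws.
* **`replan`.** Returns the same geometry with a fresh quality draw from
  the unshifted population — the generative definition of "what another
  planner would achieve on this patient".

What the generator does **not** emulate: beam/arc geometry, 3-D dose
deposition, heterogeneity, inter-structure correlation beyond the shared
quality parameter, and DICOM-RT structure. Passing tests therefore
demonstrate that the workflow recovers the statistical structure it
assumes — not that it handles every artifact of clinical data.

## The curation loop

Per iteration: train → flag → classify → act on at most 2 strongest
candidates (ranked by Cook's distance, then |studentized residual|) →
retrain. Stopping: no candidates; or an iteration takes no action; or the
change in (R², chi²) falls below (0.005, 0.01) while no hard-flagged case
remains and the chi-squared monitor is below 1.3; or 10 iterations.

**Flag tiers.** Hard flags at the standard thresholds (Cook's D > 3.0,
|t| > 3.0, feature modified-z > 3.5, median/MAD fence). In addition,
cases beyond a 1.25-SD scatter band are nominated as *potential outliers*
for the classification trials. This second tier exists because hard
residual thresholds alone cannot find a group of same-direction
outliers: with 4 shifted cases among 40, the externally studentized
residual mathematically saturates near 3.2 regardless of the shift size
(the outliers inflate the residual scale they are judged against), so a
one-shot |t| > 3 gate misses most of the group. The scatter tier mirrors
what commissioning practice actually does — eyeball the scatter plots and
trial-replan anything suspicious — and is safe because nomination never
acts by itself: a nominated clean plan fails all three classification
trials and is kept (then not re-nominated).

**Dosimetric margin.** A case is dosimetric when its median dose drop
over 16 trial re-plans exceeds 3.0 × the re-plan scale, where the scale
is the planner-to-planner SD of mean dose — the per-plan trial SD shrunk
50/50 toward a pooled cohort scale (16 sampled plans × 6 draws). Judging
the drop on the re-plan scale rather than the population-SD scale keeps
geometric variance out of a question that is purely about planner
quality; the pooling exists because a per-plan SD from a dozen draws of a
skewed distribution is far too noisy to threshold on.

**Over-fitting trial.** Remove-and-refit, deciding on representability:
the case is an over-fitting outlier when the remaining cohort's retained
components cannot reconstruct its in-field curve (leave-out RMS above 4×
the typical discarded-variance RMS and above an absolute floor of 0.005
volume fraction). This operationalizes "a single plan that increases the
number of variables needed" directly; rules based on selected-term counts
or chi-squared drops proved too jittery at n = 40 (term selection
flickers when any case is removed).

**Cluster check.** Gaussian mixtures (full covariance, 5 seeded starts)
with k ∈ {1, 2, 3} on (GED PCS1, DVH PCS1); larger k needs a BIC
advantage of 20. The margin is set above the ~10–15 BIC a two-component
fit gains merely by fitting the skew of the one-sided quality tail.
Policy on k > 1: split into per-cluster models when every cluster clears
the 20-plan floor, otherwise merge with a logged warning.

**20-plan floor.** Cohorts below 20 plans warn at training and the
curation loop logs a warning if removals cross the floor.

## Known limitations

* The curation thresholds were co-developed against this generator; on
  cohorts with different quality/geometry variance ratios the scatter
  tier and dosimetric margin would need re-tuning (they are all config).
* Stepwise R² on weak-geometry 40-plan cohorts is seed-noisy (a borderline
  term enters or not); single-run R² comparisons at the 0.01 level are
  not meaningful there.
* Merging well-separated clusters does not necessarily widen the estimate
  band here: the geometry features explain the regime difference, so the
  residual variance does not inflate the way it does when inter-cluster
  variation is unexplained.
* The max Cook's distance can *rise* between curation iterations when
  removing one outlier unmasks another; only the end state (below the
  influence threshold) is monotone in practice.
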
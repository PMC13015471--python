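# Methods

`stimnet` implements an atlas-resolution pipeline linking the network
embedding of intracranial stimulation sites to stimulation-related memory
change, together with a synthetic cohort generator that makes every stage
testable without clinical data. This note documents the models, the
conventions chosen where the design was genuinely open, and what the
synthetic validation does and does not show.

## Structural profiling (ChaCo)

A stimulation site is a sphere of radius 12 mm at the bipolar electrode
midpoint. Against a normative tractogram, the pairwise ChaCo ratio of a
parcel pair is the fraction of its streamlines intersecting the sphere; the
cumulative ChaCo of a parcel sums its pairwise ratios over all partners (it
may exceed 1). Conventions:

* **Intersection is geometric**, not voxelized: a streamline intersects the
  sphere iff the minimum point-to-segment distance over its polyline is at
  most the radius. This is exact and resolution-free; it is a deliberate
  dialect difference from voxel-mask intersection used by normative-
  connectome toolboxes, and is validated against a dense-sampling oracle.
* **Pairs with zero streamlines get ratio 0** rather than "undefined". The
  resulting zero-inflated, right-skewed connectivity distribution is why
  association mapping defaults to Kendall's tau-b.
* Coordinates are mm in an arbitrary right-handed frame; no template
  registration is performed. A single normative tractogram is the default;
  multi-tractogram studies average pairwise ratios element-wise
  (`normative_average`), recomputing cumulative scores from the mean.

## Functional profiling

The seed series of a site is the unweighted mean of the series of all
parcels whose centroid falls inside the sphere (nearest parcel if none —
a parcel-resolution convention, since voxel-level extraction is out of
scope). Per subject, FC to each parcel is the Pearson correlation with the
seed series; the normative profile averages raw r over subjects (Fisher-z
averaging is available behind a flag but is not the default, matching the
plain-averaging convention). Task-evoked structure is deliberately left in
the series: coactivation during encoding is the quantity of interest, so no
nuisance regression is applied. Zero-variance series give r = 0 with a
warning flag.

## Memory change

For each session, Δ = (R_S − R_NS)/R_NS × 100, where R_S and R_NS are mean
percent recall over stimulated and non-stimulated lists; the first three
lists (never stimulated) are excluded from R_NS. Sites with R_NS < 8.33%
(one word per 12-word list) are excluded with an explicit code — the ratio
is unstable near a zero denominator. Baseline stratification uses R_NS with
a 30% threshold; ties at exactly 30% go to the high-baseline group (the
conservative assignment given that the low group is the one claimed to
benefit). Two-sample comparisons default to Welch; the pooled test is
available and is what a df of n₁+n₂−2 implies.

## Association maps

Per parcel, the site-level association between connectivity and Δ uses
Kendall's tau-b for structural values (tie-corrected denominator; handles
zero inflation) and Pearson r for functional values. Family-wise error over
parcels is controlled by max-statistic permutation: Δ labels are shuffled
jointly for all parcels (preserving the inter-parcel correlation of the
connectivity matrix), the statistic is recomputed on its own scale (|tau-b|
or |r|, not converted to t/z), and the maximum absolute statistic per
permutation forms the null. P-values use the add-one estimator
(1 + #{maxima ≥ observed})/(1 + n_perm), which cannot return 0; uncorrected
p-values come from each parcel's own permutation distribution, so corrected
≥ uncorrected holds exactly. Inside the permutation loop tau-b is computed
by a vectorized pairwise-sign formulation, cross-checked against
`scipy.stats.kendalltau` in the test suite.

## Structure–function congruence

The encoding network (a parcel weight map) is binarized by keeping the top
fraction of positively weighted parcels (ceiling count, ties broken by
parcel id); a site's cumulative ChaCo profile is binarized by a strict
cutoff. Overlap is the Dice coefficient 2|A∩B|/(|A|+|B|) (0 with a
degeneracy flag when both masks are empty), and per-site Dice values are
related to Δ by Spearman correlation. Because both thresholds are analysis
choices, the association is swept over a 10×6 grid: network fractions
0.1…1.0 in steps of 0.1, and connectivity cutoffs {0.001, 0.01, 0.1, 1, 10,
50} — log-spaced between the stated endpoints, a labeled convention chosen
to include the representative cutoff 1 (roughly the 80th–90th percentile of
cumulative scores). BH-FDR (q < 0.05) is applied across non-degenerate
cells; degenerate cells are flagged and excluded from the FDR family. The
representative cell is (0.3, 1).

## PLS path models

Latent variables are estimated by iterative partial least squares: Mode A
(reflective) outer estimation for all blocks, inner path-weighting scheme
(regression weights for predecessors, correlations for successors),
convergence when the maximum outer-weight change drops below 1e−7 (max 300
iterations). Latent scores are standardized after every fit and oriented so
the sum of loadings is non-negative. Structural coefficients are the
standardized OLS regressions of each endogenous latent on its predecessors.
With single-indicator blocks the engine reduces exactly to standardized OLS
path analysis, which serves as a closed-form oracle in the tests.

* **Preprocessing**: zero-inflated structural-connectivity indicators have
  zeros replaced by the column's minimal non-zero value followed by a
  natural log, then all indicators are z-standardized.
* **Moderation** is two-stage: latent scores first, then the standardized
  product of moderator and predictor scores enters the target's structural
  regression (one interaction per model).
* **Mediation**: indirect = a·b, total = c′ + a·b, proportion mediated =
  indirect/total when the signs agree (flagged otherwise, and when
  |total| < 1e−8). Indirect-effect inference uses the bootstrap
  distribution of a·b products.
* **Bootstrap**: observations resampled with replacement and the model
  refit from scratch (including re-standardization); SE is the bootstrap
  standard deviation, p is two-tailed normal on β/SE (percentile CIs also
  reported); >5% failed resamples aborts. No sign-change correction is
  applied.
* **Diagnostics**: AVE = mean squared standardized loading; composite
  reliability by the Dillon–Goldstein formula; HTMT = mean absolute
  heterotrait correlation over the geometric mean of mean absolute
  monotrait correlations (single-indicator blocks contribute 1).
* **BIC** is the regression BIC of the endogenous construct's structural
  equation, n·ln(SSE/n) + (k+1)·ln(n) — a documented convention, since
  variance-based SEM has no canonical likelihood.

## Synthetic cohorts

The generator emulates the phenomenology the pipeline must handle, not any
particular patient dataset:

* Atlas: uniformly random centroids in a 140×170×120 mm box, ≥2 mm apart
  (default 60 parcels; 438 supported).
* Tractogram: per parcel pair, zero streamlines with probability equal to
  `connection_sparsity` (default 0.5), else a geometric count (mean
  `streamline_density` = 5); each streamline is a quadratic Bézier between
  jittered centroids with a random control point, 12 vertices, so sphere
  intersection is non-trivially curved.
* Task series: shared block regressor loading on the encoding-core parcels
  plus spatially correlated noise; standardized per parcel. FC values
  across parcels are approximately normal under this covariance model.
* Cohort: default 39 closed-loop and 22 random sites, radius 12 mm, one
  25-list session per site at 12 words/list, first three lists never
  stimulated, half of the remaining lists stimulated. Recall is simulated
  word-by-word (Bernoulli), so the behavioral exclusion rules are genuinely
  exercised; sessions are regenerated (bounded retries) if R_NS falls below
  the 8.33% floor, making inclusion hold by construction.

Planted effects are induced through a Gaussian copula on latent site
scores: closed-loop Δ correlates with the site's Dice congruence to the
encoding network (rank correlation `effect_sc_memory`, default 0.6), and
baseline recall correlates `effect_baseline` (default −0.48) with Δ;
random-mode Δ is noise around zero; WMP correlates `effect_wmp_sc`
(default −0.5) with total cumulative ChaCo. The copula correlations are
calibrated analytically so the *realized* correlations — after binomial
recall noise, the mechanical role of R_NS in Δ's denominator, and tie
attenuation among Dice values — match the requested effects; requests that
would need a latent correlation outside (−1, 1) raise a config error.
`noise_sd` (default 20 percent points) sets the latent Δ spread; combined
with list-level sampling noise (~19 pp at these list counts) the realized
closed-loop Δ SD is ~27 pp, matching the scale implied by published cohort
summaries (SEM 4.18 at n=39 ⇒ SD ≈ 26 pp). The mean planted Δ is 12.4%.

What passing tests show: the statistics are calibrated (FWER, FDR and
bootstrap type-I near nominal under a global null) and the pipeline
recovers planted effect sizes at realistic n. What they do not show:
robustness to real-data features the generator omits — electrode
localization error, non-stationary recall dynamics, serial-position
structure, heteroskedastic Δ across subjects, and spatially structured
tractography artifacts.

## Known limitations and power

At the default cohort sizes (39 closed-loop vs 22 random) the
moderation test — a closed-loop-only congruence–memory slope, tested by the
standardized interaction with bootstrap-normal inference — has limited
power: with a realized within-group correlation near 0.6, the Fisher-z
ceiling for detecting the slope difference is ≈0.69 at two-tailed α=0.05,
and the measured power of the prescribed test is ≈0.6–0.65 (the OLS-t
reference agrees). Detecting such moderation reliably needs larger cohorts,
not a different estimator. The bootstrap-normal p at small n_boot is mildly
anticonservative (type-I ≈0.066 at n=100, n_boot=200); percentile CIs are
reported alongside.

Default problem sizes throughout the validation studies (60-parcel atlas,
200 cohort replicates, 500 null replicates × 100 permutations, 1600
bootstrap-calibration replicates) are chosen to keep a full validation run
at desk scale — a few minutes on one CPU — while keeping Monte-Carlo error
well below the tolerances being checked.
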
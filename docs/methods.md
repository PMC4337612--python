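# Methods

This note documents the generative models, estimators, and numerical
choices behind `contextsim`, and what its validation studies do and do not
establish.

## Experimental design generator

The simulated experiment is a two-day item–context paradigm. 252 item
identifiers are randomly split into three 84-item lists: delayed (studied
day 1), immediate (studied day 2), and lures. Eight named rooms are split
four per day; each studied list's 84 items are assigned 21 per room. After
each day's encoding, that day's four rooms are randomly grouped into two
two-room "houses" — this grouping matters only as an *exclusion rule* in
the similarity analysis (different-room pairs whose rooms share a house are
dropped, since the grouping episode may have linked their representations).

Schedules: encoding presents each of the 84 sentences for 5 s; item
recognition presents all 252 words (2 s each) split over three runs so that
every run contains exactly 7 items from each studied room and 28 lures, in
random order; the associative test presents, per day list, 28 intact and 56
recombined sentences (3 s each), with recombined sentences re-pairing an
item with a *different room from the same day*. All inter-trial fixation
gaps are drawn from a shifted exponential truncated to [2, 10] s with mean
4 s and discretized to 0.5 s steps — the shape is a package choice (typical
of rapid event-related optimizers); only the mean and range are treated as
fixed design facts. The exponential scale is solved numerically (Brent) so
the truncated mean is exact before discretization.

## Behavioral generative model

A dual-process account generates item-recognition responses:

* an old item is **recollected** with probability `rho_list`
  (defaults 0.44 immediate, 0.22 delayed) → response 'remember';
* any non-recollected trial (old or lure) emits a **spurious 'remember'**
  with probability 0.04, independent of memory strength;
* otherwise a familiarity strength `~ Normal(mu_list, 1)` (defaults 1.38 /
  0.92 / 0 for immediate / delayed / lure) is cut by four ordered criteria
  (0.0, 0.4, 0.74, 1.4) into the five confidence responses;
* trials are lost to no-response with probability 0.02.

The spurious-remember process is deliberately independent of strength: the
corrected recollection estimator `(R_old − R_new)/(1 − R_new)` assumes
exactly this independence, so under the generator the estimator is
consistent for `rho` (verified by Monte-Carlo recovery tests). A
strength-threshold 'remember' criterion would bias the estimator by ~0.08
at these parameter values. The criteria and means were set so the implied
group rates (R rates 0.46/0.25/0.04, confident-old rates 0.40/0.43/0.23,
item d′ ≈ 1.7/1.1) sit at the reference study's levels.

Associative responses: P(correct | intact sentence) depends on the item's
memory status at test (defaults 0.87/0.73/0.55 immediate and 0.78/0.66/0.51
delayed for recollected/familiar/forgotten items); recombined sentences
draw an 'intact' response at a fixed per-delay rate (0.34 / 0.43). These
values were chosen so that *both* the aggregate intact rates (≈ 0.78
immediate, 0.64 delayed; associative d′ ≈ 1.3 / 0.55) *and* the per-status
percent correct computed over all sentences (≈ 73/69 immediate, 65/58
delayed) match the reference levels simultaneously — the per-status figures
are only consistent with the aggregates if they are scored over intact and
recombined sentences together, which is how the package's
`conditional_source_accuracy(..., include_recombined=True)` scores them.
Scoring over intact sentences only is the default and is reported as such.

## Neural generative model

Each subject receives disjoint random voxel sets as ROI masks on a small
3D grid (no anatomy is simulated; mask geometry is irrelevant to every
estimator downstream). Within an ROI with V voxels:

* a static responsiveness pattern `b ~ Normal(1, 0.5²)` per voxel is shared
  by all trials (this produces the realistic positive baseline pattern
  correlation between any two trials);
* recollection trials add a scalar **recollection gain** `g(roi, delay)`
  (units: beta amplitude relative to the per-event response of 1);
* recollection trials also add `c(roi, delay) ×` a **room prototype** — a
  fixed `Normal(0, 1)` voxel pattern per room, drawn independently per
  room so that `c = 0` makes room labels exchangeable by construction;
* i.i.d. `Normal(0, 1)` pattern noise per trial and voxel.

Expected pair correlations are then `(0.25 + c²)/(1.25 + c²)` for same-room
recollection pairs and `0.25/1.25` otherwise, so the context statistic is 0
at `c = 0` and increases monotonically in `c`.

Time series: each trial's zero-duration stick, scaled per voxel by its
generating pattern, is convolved with a canonical double-gamma HRF
(gamma shapes 6 and 16, undershoot ratio 6, 32 s support, peak-normalized;
cross-checked against nilearn's SPM HRF in the tests). Because events are
sticks, regressors are evaluated directly as the shifted HRF sampled at
scan times (TR = 1.22 s). Added on top: second-order Legendre drift with
random per-voxel coefficients, AR(1) noise (φ = 0.3, innovation-scaled so
the marginal SD equals `noise_sd` = 1), a random-walk six-parameter motion
trace with occasional 0.6 mm jumps, motion-coupled signal artifacts, and a
baseline of 100. The default per-event contrast-to-noise (amplitude 1
against scan noise 1) is deliberately unflattering; single-trial
beta estimates correlate ≈ 0.78 with their generating patterns at this
level and > 0.9 when scan noise is lowered to 0.3 (both asserted in tests).

## Estimation

**Condition GLM.** Nine condition regressors plus six motion parameters,
one-hot spike regressors for flagged scans, and Legendre drift
(order 2, configurable); OLS per voxel, no prewhitening (an AR-aware fit
would change second-order properties only; betas feed correlation analyses
where this is immaterial). Rank deficiency raises an error naming the
collinear columns. Recollection-related activity is the
recollection − familiarity contrast per delay.

**LSS.** One model per trial: the target trial's regressor, one regressor
pooling *all* other trials regardless of condition, and the nuisance
block. Solved by Cholesky on the normal equations (falls back to SVD
least-squares with a rank diagnosis if the Gram matrix is singular). The
noiseless-recovery oracle uses trials ≥ 36 s apart (beyond the 32 s HRF
support, so trial regressors are exactly orthogonal) and no nuisance
columns — with nuisance columns present, the pooled regressor's misfit of
heterogeneous amplitudes can leak into the target estimate through the
drift terms, so exact 1e-6 recovery is only guaranteed for the bare model.

**Artifact flagging.** Framewise displacement = Σ|Δ translations| + 50 mm ×
Σ|Δ rotations| (ART-style composite); scans with FD > 0.3 mm or
scan-to-scan global signal change > 1.3 % of the run mean get spike
regressors.

**ROI hygiene.** tSNR = voxel mean / SD per run, averaged over runs
(zero-variance voxels get +inf and are flagged); voxels below (ROI mean −
1 SD) are dropped. Trial outliers: voxel values standardized across trials
within run; a trial whose mean absolute standardized value exceeds the run
mean by 3 SD is flagged (the cutoff is a package choice — no numeric value
is fixed by the analysis being emulated — and is configurable).

## Context similarity

Pairs of trials enter only if they share run, list, and memory status, are
≥ 2 presentation positions apart, and neither member is an outlier;
same-room vs different-room is decided by the encoding room, and
different-room pairs from house-grouped rooms are excluded. Pairwise
Pearson correlations are Fisher-z transformed *before* averaging (the
stricter reading of transform-for-comparison), averaged within run per
cell, then across runs; runs missing either cell are omitted; the statistic
is same − different. Cross-run pairs are never formed: run-wise averaging
presupposes within-run pairs, and betas from different runs sit on
different scales.

**Randomization test.** Room labels are permuted across trials within
run × list × memory-status strata (preserving per-room counts), the full
pair selection — including the house rule derived from the permuted
labels — and averaging are re-run per permutation, and the one-sided
p-value is `(1 + #{null ≥ observed})/(1 + n_perm)`. If no stratum contains
two distinct room labels the test refuses to run. Under the null the
p-value is valid by construction; the calibration study checks the 5 %
rejection rate empirically over 500 simulated subjects.

## Group inference

The 2×2 within-subject ANOVA is computed through difference scores: each
effect is a paired t on its contrast and `F = t²` with df (1, n−1), exactly
equivalent to the sums-of-squares computation for two-level factors (the
tests verify agreement to 1e-10 against an independent SS implementation).
Directional one-sample t-tests are used only where the hypothesis is
directional (same-room > different-room); everything else is two-sided. No
multiple-ROI correction is applied (ROI tests are reported uncorrected, as
in the analysis being emulated). Trial-count matching subsamples the four
memory × delay cells to their minimum count (without replacement,
averaging over resamples); subjects under 9 trials in any cell are
excluded. The brain–behavior analysis correlates delayed anterior-HF
context similarity with delayed associative d′, excludes below-chance
performers (d′ ≤ 0), and verifies the partial slope controlling for the
number of delayed recollection trials via OLS. The conjunction rule for
two independent one-sided maps at joint p returns √p per map
(0.001 → 0.0316 → 0.032 at 3 decimals).

## Validation studies and configured effect sizes

`contextsim.studies` fixes the problem sizes of the validation experiments:

* **Null calibration** — 500 subjects, single 45-voxel ROI, context gain 0,
  199 permutations; rejection rate at α = 0.05 must fall in [0.03, 0.07].
  This study (and the monotonicity study) feeds the generator's
  ground-truth trial patterns directly into the similarity stage rather
  than synthesizing and re-estimating time series: the statistic and its
  permutation null operate on a trials × voxels matrix regardless of how it
  was estimated, and the pattern route is what makes 500 subjects cheap.
* **Monotonicity** — mean statistic over 50 subjects per context gain
  ∈ {0, 0.5, 1.0} must increase strictly (observed ≈ 0.00 / 0.17 / 0.50).
* **Parameter recovery** — 50 cohorts of 19 subjects run through the *full*
  BOLD + LSS route on a four-ROI (60 voxels each) left-MTL configuration.
  The scenario encodes the qualitative result the pipeline must detect:
  posterior-HF recollection gain 0.5 immediate vs 0.1 delayed (other ROIs
  stable at 0.4; between-subject SD 0.2), and a latent per-subject ability
  `a ~ N(0,1)` that sets the delayed anterior-HF context gain
  (`max(0, 0.65 + 0.8a)`) and shifts delayed associative accuracy (+0.14 on
  the intact-given-status probabilities, −0.06 on the recombined false-
  intact rate). These effect sizes were set by a power design targeting
  ≥ 0.9 per-cohort joint success, so a 19-subject cohort detects both
  signatures reliably despite LSS estimation noise, the exclusion rules,
  and attenuation of the brain–behavior correlation by estimation noise
  and d′ unreliability (observed cohort-level mean r ≈ 0.7); the latent
  correlation is correspondingly stronger than the measured one.
  Success = significant (α = 0.05) posterior-HF interaction in the right
  direction *and* positive significant brain–behavior correlation; the
  study reports the fraction of cohorts succeeding (≥ 0.8 required).

## What the synthetic data do and do not establish

The generator reproduces the design's combinatorial structure, realistic
trial overlap at TR 1.22 s, autocorrelated noise, drift, motion artifacts,
and the two target effects with known ground truth. It does **not**
simulate anatomy or spatial autocorrelation (masks are random voxel sets,
so tSNR filtering and outlier flagging are exercised but spatial smoothing
questions cannot be posed), physiological noise, inter-regional
correlations, encoding-phase data, or item-level (trial-unique) pattern
structure. Passing tests therefore demonstrate the *estimators and rules*
are implemented correctly and are well calibrated under a plausible noise
model — not that the scientific effect exists in any real dataset.

## Determinism

Every public entry point takes a seed; one master seed fans out through
`numpy.random.SeedSequence` spawn keys to named stages (design, behavior,
neural realization, BOLD noise, patterns), so changing one stage's draw
does not perturb the others, and a pipeline run with a fixed config is
byte-identical across repeats. Config snapshots carry a SHA-256 hash
stamped into every results file.
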
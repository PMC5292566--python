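# Methods

## The problem

Regional PET quantifies a molecular target — here the serotonin transporter
(SERT), measured as nondisplaceable binding potential BP_ND = (V_T −
V_ND)/V_ND, unitless — one number per region of interest (ROI) per scan.
Beyond comparing regional means between groups or conditions, the *joint*
structure is informative: correlating a region pair's BP_ND across subjects
yields an interregional "molecular relation", the molecular-imaging analogue
of functional connectivity (with subjects, not time points, as the sampling
axis). This package implements that analysis end to end for a longitudinal
SSRI-treatment design: patients scanned at baseline (PET1), hours after a
first dose (PET2) and after weeks of daily intake (PET3), plus once-scanned
healthy controls — nine ROIs (thalamus, putamen, caudate, pallidum,
midbrain, hippocampus, amygdala, ACC, insula; bilaterally averaged), 36
region pairs.

## Statistical model

**Correlation.** For a cohort (one group × condition cell, n subjects),
entry (i, j) of the correlation matrix is the *partial Spearman* correlation
of regions i and j given age and gender: rank-transform both regions and
every covariate (average ranks for ties), residualize the two rank vectors
on an intercept plus covariate ranks by least squares, and take the Pearson
correlation of the residuals. Rationale for ranks: BP_ND distributions at
n ≤ 19 fail normality screens; rank methods are also invariant to any
monotone per-region transformation, which matters below. Residualization is
the common "nonparametric partial correlation" convention; for one covariate
without ties it coincides with the classical recursion
ρ_xy·c = (ρ_xy − ρ_xc ρ_yc)/√((1−ρ_xc²)(1−ρ_yc²)) (verified in tests), and
it handles the binary gender covariate cleanly (a two-group tie structure,
equivalent to 0/1 dummy coding up to an affine map that residualization
absorbs). The alternative convention — inverting the full rank-correlation
matrix — differs numerically for ≥2 covariates; we document the choice
rather than claim it matches any particular software default.

**Contrast statistic.** For two cohorts A and B, the per-pair statistic is
Δz = arctanh(ρ_B) − arctanh(ρ_A) (Fisher's variance-stabilizing transform;
|ρ| clamped at 1 − 1e-7 so Δz stays finite). Δρ = ρ_B − ρ_A is reported
alongside because correlation differences are conventionally read on the ρ
scale. No analytic variance for Spearman z (e.g. 1.06/(n−3)) is used:
inference comes from the permutation null, under which any strictly
monotone transform of the statistic gives the same p-value up to ties.

**Permutation null.** Two exchangeability schemes:

* *unpaired_groups* (e.g. controls vs patients at baseline): group labels
  are permuted over the pooled subjects with group sizes fixed. Covariates
  are subject attributes and travel with their rows; only the labels move.
  No stratification by gender is applied by default (the design has a
  gender imbalance, 13/19 vs 6/19 female; the analysis adjusts for gender
  in the correlation instead).
* *paired_conditions* (longitudinal): the two condition labels are swapped
  independently per subject, so every permuted dataset assigns each subject
  exactly once to each condition — the constraint that makes the
  relabelling a valid null for repeated measurements. Three-condition
  designs are analyzed as pairwise contrasts (baseline vs each follow-up),
  not an omnibus test.

Two-sided p-values rank |Δz| with ties counted toward the null (≥
comparison) and the add-one rule p = (b+1)/(B+1), guaranteeing p > 0 and
validity of the test. When the number of distinct relabellings (2^n paired,
C(n_A+n_B, n_A) unpaired) is at most `exact_threshold` (default 1024), the
null is enumerated exhaustively and the exact fraction reported without the
add-one correction. A single integer seed drives `numpy.random.default_rng`;
results are bit-reproducible. Draws in which any region has zero residual
rank variance are discarded and counted (`n_rejected_draws` in the run log).

**Within-cohort pre-ranking (paired default).** Drug occupancy multiplies a
condition's BP_ND by (1 − occ) ≈ 0.25–0.30, so the two conditions of a
paired contrast live on very different scales. Swapping *raw* rows then
makes every permuted cohort a mixture of two scales: all regions of the
high-scale rows rank above the low-scale rows, stamping a common condition
factor onto every permuted matrix (measured off-diagonal ρ ≈ 0.8) — the
relabelling is not distribution-preserving, per-pair size inflates (0.096
measured at nominal 0.05 under a 70%-occupancy null) and power collapses.
The paired scheme therefore reduces each cohort to within-cohort column
ranks *before* permuting. This leaves the observed statistic bit-identical
(Spearman is computed from ranks; ranks of ranks are ranks) while giving
both conditions identical marginals, restoring exchangeability (measured
size 0.055 under the same occupancy null). The raw-value variant remains
available (`PermutationScheme(rank_within_cohort=False)`). Unpaired
contrasts compare two cohorts of the same condition and scale, and use the
classical pooled relabelling.

**Multiple comparisons.** Benjamini–Hochberg step-up over the k(k−1)/2
upper-triangle p-values of each contrast separately ("based on the number of
correlations": m = 36 for nine regions), adjusted q-values reported and
rejection at q ≤ α = 0.05. FDR is not pooled across contrasts. BH's
step-up guarantees q ≥ p entrywise, hence FDR significance is nested inside
uncorrected significance at the same α.

## Synthetic cohorts

The study data are not publicly deposited, so a generator provides the test
bed. Per subject: age ~ Uniform(27, 54) years, gender ~ Bernoulli(p_female);
per condition a latent standard-normal vector with Pearson structure
calibrated from the *Spearman* target by the exact Gaussian-copula relation
r = 2 sin(π ρ_s/6) (the pipeline's statistic is Spearman, so targets are
specified on the Spearman scale; the inverse map ρ_s = (6/π) asin(r/2)
recovers the realized structure). Then

    BP = (mu + beta_age·(age − midrange) + beta_gender·gender + sigma·latent)
         · (1 − occupancy) + noise,

floored at zero with floor events counted (BP_ND is non-negative by
definition; counting keeps the distortion visible — zero events under all
default scenarios). Subjects (IDs, age, gender) are shared across
conditions. `share_latents=True` reuses one latent draw across conditions
(perfect within-subject stability), the regime in which uniform occupancy
provably changes nothing but the scale: the cohort-mean ratio equals
1 − occupancy exactly and Spearman matrices are identical before and after.

**PSD repair of edited targets.** Entrywise-edited Spearman targets can be
indefinite after copula conversion. Repair is by alternating projections
between the PSD cone (eigenvalue clipping) and the affine constraint set
(unit diagonal, plus any entries marked `repair_fixed`), with Dykstra's
correction — the nearest correlation matrix in Frobenius norm honoring the
constraints. Without a mask, any entry moving more than `psd_tolerance`
(default 0.1) is a hard error; with a mask, the designated entries are held
exactly and the free entries absorb the repair, their largest drift being
recorded on the config. Plain eigenvalue clipping with diagonal rescaling
was rejected: on the default scenario's three-week target it moves the
injected correlations themselves by up to 0.30, i.e. it silently changes
the quantity under study.

**Default scenario** (`ssri_study_scenario`): n = 19 patients, nine ROIs,
baseline means following the [11C]DASB binding gradient (midbrain 2.0,
thalamus 1.8 … ACC 0.45, insula 0.55 BP_ND), between-subject SD 18% of the
mean, age slope −0.8%/year of the mean (availability declines with age,
shared across regions — the confounding that motivates the covariate
adjustment), gender offset +4%, p_female = 13/19 (6/19 for the control
scenario), occupancy 0.70 at PET2 and 0.75 at PET3 (uniform over regions),
measurement noise 1% of the baseline mean. The noise term is added after
occupancy scaling, so it is sized against the smallest signal in the design
(25% of baseline at PET3); 1% keeps rank-correlation attenuation below ~5%
in every condition, consistent with ROI-averaged BP_ND whose variability is
dominated by between-subject differences. Off-diagonal baseline correlation
is a uniform 0.2; the follow-up targets inject the reported pair-level
increases (seven pairs at PET2, up to +0.61; the ten ACC/insula pairs at
PET3, +0.24 to +0.71) with those entries held fixed in the PSD repair.
The repair necessarily raises some unreported pairs — most visibly
ACC–insula to ≈ 0.84 at PET3, forced by transitivity once both regions
correlate ≈ 0.9 with pallidum and midbrain — which is also the realistic
reading: a real correlation matrix with those ten increases cannot leave
everything else untouched.

What the generator does *not* emulate: kinetic-modelling error structure
(BP_ND is consumed as given), regionally uneven occupancy (supported by the
per-region occupancy parameter but not used by default), non-Gaussian
between-subject heterogeneity, dropout, or any dose→occupancy
pharmacokinetics. Passing tests therefore show the *statistics* behave as
claimed under a faithful-by-construction data model, not that the original
biological findings replicate.

## Operating characteristics (computed by `analysis/04_…py` and the tests)

* **Size**: per-pair rejection at uncorrected α = 0.05 is ≈ 0.05 (500 null
  replicates, B = 1000, n = 19), and ≤ 1 FDR rejection occurs in ≈ 4% of
  null replicates. The calibration null uses identical structure *and*
  identical occupancy: with unequal occupancy and raw-value permutation the
  test is not exchangeable (see pre-ranking above).
* **Recovery**: over 200 scenario replicates, the mean observed
  covariate-adjusted Δρ of each injected pair sits within ≈ 0.09 of its
  target (small negative bias: finite-sample attenuation of partial
  Spearman at n = 19 plus ~3% noise attenuation), and the injected pairs'
  mean |Δz| exceeds the non-injected pairs' in ≈ 98% of replicates.
* **Power at the study's n is modest**: in any single realization the
  three-week contrast yields ~5 uncorrected detections but ≥1 FDR detection
  in only ~30% of runs. The permutation distribution under the alternative
  is over-dispersed relative to the null (permuted cohorts mix the two
  correlation structures), so only the largest increases clear FDR at
  n = 19 — a caveat to keep in mind when reading single-cohort results of
  this design.
* **Monte-Carlo fidelity**: on 5–7-subject paired designs (32–128
  relabellings) sampled p at B = 10,000 deviates from the enumerated exact
  p by ≤ ~0.015, within 3 binomial SEs per pair (the bound is applied per
  pair across 120 simultaneous comparisons, so ~0.3 tail exceedances are
  expected for an unbiased sampler; the checks bound the exceedance count).

## Numerical choices and degenerate inputs

* Fisher clamp 1e-7: prevents infinities at |ρ| = 1; far below the ρ
  resolution attainable at n ≤ 38, and irrelevant to inference (permutation
  supplies the null).
* Correlations are clipped to [−1, 1] against floating-point overshoot.
* Ties: average ranks throughout; permutation comparisons use ≥ with a
  1e-12 tolerance, counting ties toward the null (conservative).
* Constant regions (zero rank variance) raise an error in observed data and
  are discarded-with-count in permutation draws.
* Partial correlation requires n ≥ m + 4 (residual degrees of freedom).
* Exact enumeration replaces sampling at ≤ 1024 relabellings by default;
  `exact_threshold=0` forces sampling (used when comparing the two).
* Cholesky factorization adds 1e-8 jitter to repaired matrices whose
  smallest eigenvalue is at the clip floor.

## Known limitations

* The pipeline tests pairwise edges only: no omnibus network statistic, no
  graph metrics, no cluster-level correction.
* Permutation p-values are the only inference route; no analytic
  (normal-theory) p-values are produced.
* BH-FDR assumes the usual positive-dependence conditions; the 36 pair
  statistics share subjects and are dependent. The family-level error under
  the global null is controlled in simulation (≈ 4–5%).
* The generator's baseline correlation level and between-subject variances
  are order-of-magnitude choices; the original study does not report them.
* Hemispheric averaging happens upstream of this pipeline; whether it was
  volume-weighted in the original data is unknown and does not affect the
  statistics here, but users preparing real input tables should average
  consistently.
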
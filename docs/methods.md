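# Methods

`fclong` implements a longitudinal resting-state functional-connectivity
(FC) analysis for paired-scan cohorts: block-level change statistics over a
sphere-based parcellation, scan-order prediction from FC differences, a
cross-sectional age contrast, and a calibrated synthetic cohort generator
that makes every stage testable without restricted data.

## Pipeline model

FC is the Pearson correlation of band-pass-filtered mean BOLD signal between
regions of interest (ROIs). The default parcellation has 264 ROIs — 5 mm
radius spheres in MNI space — grouped into 14 functional networks
(somatomotor hand/mouth, cinguloopercular, auditory, default mode, memory,
visual, frontoparietal, salience, subcortical, ventral/dorsal attention,
cerebellar, uncertain). Stages:

1. **Extraction.** Each ROI's series is the unweighted mean over the voxels
   whose centers fall within the sphere (non-strict Euclidean inequality, so
   the mask is deterministic and grid-resolution independent). Spheres may
   overlap; each ROI mean is computed independently. Empty masks flag the
   ROI invalid rather than silently zeroing it.
2. **Filtering.** Zero-phase (forward–backward) second-order Butterworth
   band-pass, 0.01–0.15 Hz at the default TR of 0.735 s. Zero-phase
   filtering introduces no inter-ROI lag, which would otherwise bias the
   Pearson correlations. Filtering is linear and removes DC exactly (the
   band-pass has a zero at 0 Hz).
3. **Correlation and vectorization.** Pearson ρ between all ROI pairs; no
   Fisher z-transform anywhere — all downstream statistics are on the raw ρ
   scale. The symmetric matrix is reduced to its strict upper triangle in
   row-major order (34,716 edges for 264 ROIs). Zero-variance or invalid
   ROIs propagate as NaN edges; a subject missing any edge of a block is
   excluded from that block's statistics, with counts logged.

## Block statistics

A *block* (a, b) is the set of edges with one endpoint in network a and one
in network b (a = b allowed); 14 networks give 105 blocks. The block
average is the unweighted mean over the block's edges, each undirected edge
counted once. For a scan pair, the per-subject block change is the older
scan's block average minus the younger's. Cohort summaries report, per
block:

* `mu` — mean per-subject block change;
* `sigma_subject` — std across subjects of the per-subject block change
  (the dispersion the t-test uses);
* `sigma_edge` — mean over the block's edges of the per-edge change std
  across subjects (the edge-map summary; these two dispersions answer
  different questions and are labeled separately in every output);
* a two-sided one-sample t-test of the changes against zero, with
  Bonferroni correction `p_bonf = min(1, m · p_raw)` where m is the number
  of blocks actually tested (105 for the full atlas), recorded in output
  metadata;
* three percent-change definitions (change relative to the younger mean,
  to the older mean, and the mean of per-subject percent changes), since a
  single "percent increase" is ambiguous when the baseline itself varies.

"Total FC" is the unweighted mean of the full edge vector. Subgroup
summaries split by sex or by age group; the age groups are younger (< 55)
and older (> 65), leaving 55–65-year-olds in neither subgroup but in all
whole-cohort statistics. The cross-sectional contrast compares different
subjects (young vs old groups) with Welch's unequal-variance t-test per
block — the group sizes in the cohorts this mirrors differ severalfold, so
a pooled-variance test would be miscalibrated. Phenotype associations are
Pearson correlations between a phenotype and the per-subject change of a
named block, with pairwise deletion of missing values.

## Scan-order prediction

Each subject contributes one sample: with a random sign s = ±1, the feature
is s · (older FC − younger FC) and the label is s. The sign randomization
makes the classes balanced by construction and the representation symmetric
(negating feature and label yields an equivalent sample). The classifier is
L2-penalized logistic regression at fixed inverse regularization C = 1
(lbfgs, tolerance 1e-8, max 10,000 iterations; the contract is "L2-penalized
maximum likelihood at C", not a particular solver; the intercept is included
and is near zero under sign randomization). "Bootstrap" repetitions are
repeated disjoint train/test partitions — the model trains on a random
subset and is evaluated on everything else, 20 times per training size —
because evaluating on "the rest" requires disjoint splits; classical
resampling with replacement with out-of-bag evaluation is available behind
`with_replacement`. Block ranking fits a single-feature model per block at
the largest configured training size (the asymptotic regime), pairs each
accuracy with the block's Bonferroni-corrected change p-value, and sorts by
descending accuracy with ties broken by block-key order.

For a single sign-symmetric Gaussian feature with mean μ and dispersion σ,
the Bayes-optimal accuracy is Φ(|μ|/σ); the test suite uses this closed form
as an independent oracle for the whole sampling-fitting-evaluation path.

## Synthetic cohort generator

The FC-level generator draws, per subject s and edge e of block b:

    younger[s, e] = clip(m_b + u_s + ε[s, e])
    older[s, e]   = younger[s, e] + c[s, b] + f[s, e],   then clip

with u_s ~ N(0, τ_subj) a subject-level baseline offset, ε edge-level
baseline noise, c[s, b] ~ N(δ_b, τ_block) a subject-level block change, and
f independent edge change noise. Defaults, all on the ρ scale:

| parameter | default | why |
|---|---|---|
| baseline block means | 0.45 within-, 0.25 between-network; SMT-VIS 0.39 | headline block's younger-scan mean is the calibration anchor |
| longitudinal shift δ | +0.03 on SMT-VIS (0-6), 0 elsewhere | the calibrated longitudinal effect |
| `edge_change_sd` | 0.26 | **total** per-edge change std across subjects |
| `subject_block_sd` | 0.11 | calibration inference: puts the positive-change fraction at Φ(0.03/0.11) ≈ 60%, the sign-count regime of the cohort this emulates; not a printed value |
| `subject_baseline_sd` | 0.08 longitudinal / 0.11 cross-sectional preset | cross-sectional value matches the reported per-subject block-average dispersion ≈ 0.11; longitudinal value kept smaller so < 2% of older-scan edges reach the clip boundary |
| `edge_baseline_sd` | 0.08 | edge scatter of the baseline template; real FC maps have far more structure (see limitations) |
| frames / TR | 490 / 0.735 s | ≈ 6 min of scanning; the source frame count is unpublished |
| sex and age-group proportions | 47/50/2% m/f/unknown; 17/46/38% younger/middle/older | cohort composition being emulated |

Two deliberate calibration choices:

* **Variance split.** The per-edge change is c + f, so its std across
  subjects is √(τ_block² + sd_f²). The config exposes the *total*
  (`edge_change_sd` = 0.26) and derives sd_f = √(0.26² − 0.11²), so the
  generator reproduces both the per-edge dispersion of 0.26 and the
  subject-level dispersion of 0.11 simultaneously; a config where the total
  is smaller than the subject component is rejected.
* **Clip-aware means.** Correlations are clipped to [−1, 1]. Naive clipping
  of N(0.42, ≈0.28) edge values trims the upper tail and biases the
  older-scan block mean a few thousandths low. The generator therefore
  solves the censored-normal mean equation (Brent's method on the analytic
  expectation) for a pre-clip mean whose **post-clip** expectation equals
  the configured target. Residual distortion of the change std from
  clipping is below 1e-3 and ignored.

The cross-sectional generator draws single scans: the young group around the
baseline block means, the old group around baseline plus a per-block
age-effect matrix. Presets carry per-sex calibrations (male: SMT-VIS +0.031,
SMT-DMN +0.045, DMN-VIS +0.042, VIS-VIS −0.014; female: +0.029, +0.043,
+0.035, −0.009; unlisted blocks default to +0.03, consistent with a total-FC
increase ≈ 0.035).

The timeseries-level generator exercises extraction/filtering/correlation
end to end: each scan is z @ Lᵀ where z are independent unit-variance
band-limited (0.01–0.15 Hz) latent factors and L is the symmetric square
root of the target correlation matrix implied by the block means, so the
expected inter-ROI correlation equals the target exactly. A single
network-factor-plus-shared-factor parameterization cannot realize a general
block-mean matrix (cross-block correlations would have to factor as
rank-1), which is why the mixing uses the full matrix square root. Targets
that are not positive semidefinite are not realizable by any linear mixing
and raise a config error reporting the minimum eigenvalue and the
largest-magnitude block as the likely offender (exact attribution of
non-PSD-ness to one block is ill-posed).

Positive-semidefinite repair of generated FC matrices (eigenvalue clipping
at zero followed by diagonal re-normalization) is opt-in; the default is
symmetrize-and-clip, which is adequate for statistics that never invert the
matrix and orders of magnitude faster.

All generation is bit-for-bit reproducible from (config, seed) via a single
`numpy.random.Generator` with a fixed draw order.

## Numerical and design choices

* Edge ordering is row-major strict upper triangle everywhere and recorded
  in every output header; floats are written with 17 significant digits so
  file round trips are bit-exact.
* "SMT" in the headline SMT-VIS block is network label 0 (somatomotor hand)
  only; an optional `merge_somatomotor` switch pools labels 0 and 1.
* Degenerate t-test inputs: zero dispersion with zero mean gives t = 0,
  p = 1; zero dispersion with nonzero mean is flagged degenerate with
  p = 0. The zero-dispersion check uses a relative 1e-12 tolerance so
  identical-but-inexactly-stored values are treated as constant.
* Exact zeros in sign counts get their own column rather than being folded
  into either sign.
* Single-class training draws in a repetition are redrawn (logged); empty
  subgroups are skipped with a warning; per-subject failures in the CLI are
  isolated, tallied in the run record, and do not abort the run.

## Problem sizes in the shipped tests

Block statistics of the generator are invariant to how many *other*
networks are generated and (up to edge-noise averaging, negligible next to
subject-level dispersion) to the ROI count per network. The shipped tests
exploit this: the full-size longitudinal recovery (n = 2,722) generates only
the two networks of the headline block; the cross-sectional recovery (5,000
per group) uses three networks capped at 10 ROIs; the ranking-recovery
experiment uses all 14 networks at 3 ROIs each with n = 1,200 per run
(sized so the expected accuracy gap between the shifted block and the best
null block exceeds five standard deviations of the realized-cohort noise);
the null calibration runs 200 seeds at n = 60. Monte-Carlo tolerances are
two standard errors derived analytically from the configured dispersions.

## Limitations

Passing tests establish that the analysis recovers effects from data with
the *assumed* statistical structure — Gaussian, block-homogeneous,
exchangeable across edges within a block. Real resting-state FC has
spatially structured baselines, heavy-tailed and heteroscedastic edge
distributions, motion and physiological artifacts, and site/task effects;
none of these are simulated (no hemodynamic model, no scanner drift beyond
what the band-pass removes, no motion). The packaged atlas file carries the
published network-label structure but synthetic sphere coordinates, so any
spatial claim requires a user-supplied coordinate table. The generator also
cannot arbitrate whether a recovered longitudinal change reflects aging or
an acquisition change between timepoints — that is a property of real data,
not of this pipeline.
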
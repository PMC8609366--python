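# Methods

This note documents the models and procedures implemented in
`ofmri_states`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions that a
user extending the package should know about.

## The generative picture

ROI BOLD time series from optogenetics-evoked fMRI are modeled as a hidden
Markov process over K transient brain states.  State k is a multivariate
Gaussian over the (reduced) signal space: its mean is the state's activation
map, its covariance the state's functional connectivity.  A run visits
states according to a row-stochastic transition matrix A; photostimulation
does not change what the states *look like*, only *when* they are visited.
The analysis therefore separates a spatial question (what are the states?)
answered at the group level, from a temporal question (when is each state
active, and does that depend on stimulation frequency and group?) answered
per subject through the posterior activation probabilities (gamma).

## Synthetic cohorts

`synthetic.simulate_cohort` emulates the target study design:

- **Groups and sessions.** 9 control subjects (fluorophore only, one
  session), 10 wild-type opsin subjects (two sessions, 8 returning for the
  second — the attrition that makes the run ledger 27 + 54 + 72 = 153), and
  12 transgenic opsin subjects (two full sessions).  Every session holds one
  run per stimulation frequency (5, 10, 20 Hz).
- **Paradigm.** 720 volumes at TR = 1 s: 50 s baseline, ten blocks of 10 s
  on / 50 s off, 60 s tail.  The scheduled 710 s leave 10 surplus volumes,
  treated as extra tail rest (the analysis locks to block onsets; the
  placement of spare rest is inert).  Pulses are 10 ms, giving 5/10/20 %
  duty cycles at 5/10/20 Hz.
- **States.** K_true = 5: two baseline states, a 5 Hz-tuned and a
  10 Hz-tuned evoked state, and a post-stimulation state whose drive is
  delayed by the block duration.  Means are unit-scale Gaussian region
  patterns; covariances are diagonal (0.8–1.2) plus a rank-2 factor —
  positive definite by construction, with realistic shared-variance
  structure.
- **Engagement mechanism.** The stimulus boxcar is convolved with a
  single-gamma HRF (mean lag 6 s, dispersion 3 s, 32 s support,
  peak-normalized) to form a drive d(t) in [0, 1].  A state with gain g has
  the off-diagonal entries of its transition-matrix *column* multiplied by
  1 + g·d(t), rows renormalized.  The diagonal is deliberately left at
  baseline: boosting self-transitions makes a driven state absorbing for a
  whole block, which produces winner-take-all occupancy; leaving entry
  rates to carry the drive yields the overlapping evoked responses seen in
  real data, and keeps non-preferred states visible under median
  aggregation.
- **Gains.** Tuned gain 40 at the preferred frequency, 12 at non-preferred
  frequencies and for the post-stimulation state, 0 for every control-group
  state.  These were sized so a tuned state's activation probability rises
  to roughly 0.4–0.7 during preferred-frequency blocks — the magnitude of
  evoked state responses in this literature — while still responding
  (weaker) at every frequency, since the group contrast pools all
  frequencies.  The transgenic group keeps all evoked states but loses the
  5 Hz preference (its 10 Hz-analog state is driven at both theta
  frequencies; the 5 Hz-analog is untuned): the planted group-by-frequency
  interaction.

What the generator does **not** emulate: voxel-level structure,
physiological (cardiac/respiratory) noise, scanner drift, motion, or
nonstationary baseline dynamics.  Passing tests therefore demonstrate that
the pipeline recovers states and their frequency tuning *when the HMM's own
generative assumptions hold at realistic effect sizes* — they do not certify
robustness to the artifacts a real preprocessing chain must remove.

Ground truth (latent paths as one-hot gammas, gains, state parameters,
seeds) is exported with every simulated cohort.  Because the pipeline
standardizes each run per region, recovered state means live in
standardized units; `planted_means_in_standardized_units` applies the same
transformation (subtract the occupancy-weighted grand mean, divide by the
total per-region SD) to the raw planted means and is the correct target for
recovery comparisons.

## Preprocessing

Runs are z-scored per region within each run (population variance; constant
regions become zeros with a warning).  Standardization is per run rather
than global, so inter-run offsets cannot masquerade as states.  Runs are
concatenated in manifest order, and PCA retains the fewest components whose
cumulative explained-variance ratio reaches 0.5.  PCA is computed by
eigendecomposition of the covariance with stable ordering and a fixed sign
convention (each loading's largest-magnitude element positive) for
cross-platform determinism.  The known bias of pre-HMM PCA — it is built on
the average covariance, so state-specific covariance structure is
under-represented — is accepted, not corrected, as it is part of the
procedure being reproduced.

## Variational HMM

`GaussianHMMVB` implements structured mean-field variational Bayes:
q(z) · q(pi) · q(A) · prod_k q(mu_k, Lambda_k), with

- symmetric Dirichlet(1) priors on pi and each row of A;
- Normal–Wishart priors on (mu_k, Lambda_k): prior mean 0, scale
  kappa_0 = 0.01, degrees of freedom d + 2, scale matrix matching the
  empirical per-dimension variances (weakly informative on standardized
  scores).

The E-step runs scaled forward–backward per run segment on the expected
log emission and transition scores (no underflow at 10^5 time points; run
boundaries are never crossed; the initial-state posterior pools run
starts).  The free energy F = −(sum of segment log-normalizers) + KL terms
is recorded after every E-step; exact coordinate updates make the trace
monotone non-increasing, which the tests assert.  Iteration stops when
|ΔF| < tol·T (tol defaults to 1e-6 per time point) or at `max_iter`.

Numerical choices: a 1e-6 ridge on each posterior scale matrix (PD floor
for near-collapsed states); states whose total occupancy falls below one
time point are kept but flagged; Viterbi and all argmax operations break
ties toward the lower state index; initialization is k-means (5 restarts)
on a seeded subsample of at most 10,000 rows, with the repetition index
perturbing the seed.

**Model selection.**  For each candidate K the model is fit three times;
similarity between two fits is the mean Pearson correlation of
bipartite-matched gamma columns (Hungarian assignment, negative matches
clipped to 0, hence a [0, 1] score invariant to label permutation).  The
chosen K maximizes mean pairwise similarity divided by mean free energy
*per time point* (the raw ratio is scale-dependent in T; per-time-point
scaling does not change the argmax for fixed data), and the chosen
repetition at that K has the lowest free energy.

## Evoked responses and permutation inference

Windows are anchored at stimulation onset and span the block duration plus
an equal post-stimulation span (20 samples at the defaults).  Medians (the
midpoint convention for even counts) aggregate blocks within a run and runs
within a subject; medians resist the skew and outlier blocks typical of
probability curves.

All inference follows one recipe: a pointwise statistic over the
(state × window) family, 1-D TFCE along the window (E = 0.5, H = 2, 100
integration steps, dh = max/steps — the canonical parameters), and FWE
control by the maximum enhanced statistic across states *and* time under a
permutation null, with p = (1 + #{perm max ≥ observed})/(nperm + 1), so
1,000 permutations give a floor of ~0.001.  Directional questions enhance
only positive statistic values; the opposite contrast covers the other
tail.  When the number of distinct relabelings does not exceed the
requested permutations, all of them are enumerated and exact p-values
returned.

- **Group difference.**  Two-sample pooled t on *subject-level* curves,
  subject labels permuted.  Subjects, not runs, are the exchangeable unit —
  permuting runs within subjects would pseudoreplicate.
- **Frequency ANOVA (within subject).**  Each session (one run per
  frequency) is an exchangeability block; the null shuffles frequency
  labels within each session (whole-session swaps, also valid, leave the
  one-sample statistics invariant and are therefore implicit).  Post hoc
  contrasts are one-sample t's on per-session contrast scores.  The
  omnibus F is the mean squared t over two orthonormal contrasts rather
  than a covariance-inverted Hotelling T²: the 2×2 contrast covariance is
  frequently near-singular for probability curves pinned at 0 or 1, and
  inverting it produces unbounded permuted statistics that void the
  max-statistic correction; permutation assessment keeps either form exact.
  Monotonic-trend control contrasts are *conjunctions* — the minimum of the
  two step t's (5→10 and 10→20) — because a linear (+1, 0, −1) trend is
  genuinely positive for a 5 Hz-tuned state with a (high, low, low)
  profile, and only a strict-ordering test can return the expected null for
  single-frequency tuning.
- **Mixed-design interaction.**  Each subject is reduced to its
  frequency-contrast curves; the interaction is a between-group two-sample
  t on those curves with group labels permuted; the omnibus is the larger
  of the two contrasts' squared t.
- **Long-scale profiling.**  The group test applied to single-block windows
  yields a per-block significance profile.

A variance floor of 1e-12 guards t denominators for degenerate all-equal
inputs.

## GLM baseline

The static comparison analysis regresses each region on an HRF-convolved
boxcar and its first temporal difference (plus intercept and optional
motion covariates).  Significance uses circular shifts of the stimulus
regressor (at least one block period away from zero, one offset per
permutation shared by all runs), preserving the autocorrelation of the data
under the null, with max-|t| FWE across the 90 regions — the ROI-level
analogue of voxelwise TFCE correction.  The GLM finds evoked *amplitude*
but returns a single static map per condition; it cannot separate
temporally overlapping states, which is the motivation for the HMM.

## Structure-to-function mapping

Projection magnitudes and state maps are rank-based inverse-normal
transformed (Blom: ranks through the normal quantile of
(r − 3/8)/(n + 1/4), average ranks for ties; all-equal input is an error).

`LooRidgeMapper` predicts a 90-region state map from the 90 × 90 directed
connectome (column j = projections *from* source j): for each held-out
region, an inner leave-one-out loop over the remaining 89 picks the ridge
penalty from the grid minimizing inner prediction MSE (the efficient
(y − ŷ)/(1 − h) identity on a per-fold SVD; ties to the smaller penalty),
and the training-fold solution predicts the held-out value.  Out-of-sample
quality is Pearson rho over the 90 predictions, R² = rho² exactly, and a
deviance defined here as the residual sum of squares between standardized
observed and predicted values (no standard definition exists for this
quantity; ours is declared, and its absolute scale should not be compared
across packages).  Significance permutes the response (the design is fixed,
so per-fold SVDs are reused across permutations).  The positive directed
circuit is the connectome with each source column scaled by the
fold-averaged coefficient, negative entries zeroed.

**Penalty grid.**  25 points log-spaced in [0.1, 1000].  The floor is a
substantive choice: with a square predictor matrix whose columns all share
the rank-transform's quantile values, penalties near zero put LOO ridge in
an interpolating regime (each training fold is underdetermined) that can
reproduce *any* permutation of the response almost exactly — verified
against an independent ridge implementation — inflating the permutation
null so far that no realistic signal could ever reach p ≈ 0.001.  Keeping
the fit regularized preserves both calibration and power.  Self-projections
(the diagonal) are retained unless `mask_diagonal` is set.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run a reduced cohort — 6
subjects per group, half-length runs (5 blocks, 360 volumes) — for the
HMM-recovery and ANOVA checks; the full 153-run, 110,160-time-point cohort
is simulated for the bookkeeping checks; null calibration uses 200
simulated two-group cohorts at 200 permutations; state-count selection uses
ten 1,500-sample streams with K_true = 4 and candidates {2, 4, 8}.  These
sizes keep a complete run in a few minutes on one core while leaving every
planted effect comfortably detectable.

## Known limitations

- The generator samples emissions i.i.d. given the state; real BOLD has
  temporal autocorrelation within states, which would make all permutation
  tests here anticonservative if applied to raw time points (they are
  applied to block-aggregated curves, which largely removes the concern).
- PCA before the HMM biases covariance estimates toward the average
  covariance; state-specific connectivity differences are attenuated.
- Control-group runs are pure baseline dynamics; photic, thermal or
  vascular artifacts that a real control group exists to detect are not
  modeled.
- The deviance reported by the ridge mapper is a declared definition (RSS
  of standardized values), not an estimate of any published quantity.
- With strongly overlapping evoked states, competition for occupancy means
  a state's non-preferred-frequency response can be small; group tests on
  mixed-frequency medians then favor the most consistently engaged states.
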
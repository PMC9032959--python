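# Methods

This note documents the models and procedures implemented in `handmap`,
the synthetic-data generator that stands in for an fMRI nerve-block
study, the parameter choices that matter, and what passing tests do and
do not establish about real data.

## The scientific setting

A pharmacological ring block of one finger (by default the index finger,
D2) acutely removes its tactile input. Classical winner-takes-all
analyses of the S1 hand map then appear to show the neighbouring fingers
"invading" the deprived cortical territory. The package implements the
competing interpretation: finger representations overlap to begin with,
so removing the dominant finger from a winner-takes-all assignment
mechanically relabels the deprived cluster's voxels, and the genuine
physiological change is better described as a global, homeostatic
rescaling of an otherwise stable representational structure.

## Synthetic-data generator

The hand area is a 1-D cortical strip of length 10 (arbitrary units)
with five equally spaced finger centres. Voxels are placed uniformly at
random (sorted, so topography is ordered) and tuned to every finger with
a Gaussian kernel of the axis distance, width `tuning_width` (default
1.0 — roughly half the inter-finger spacing, giving the neighbour
overlap the winner-takes-all artifact requires); each voxel's maximal
weight is normalised to 1, and its preferred finger defines its true
cluster. `tuning_width = 0` degenerates to perfectly selective voxels.

Peripheral drives come from an exponential spread kernel on finger
index, `S[i,j] = exp(−|i−j|/λ)`, with λ chosen so the immediate
neighbour receives 30% of the stimulated finger's pooled drive — a
parametric stand-in for a full mechanoreceptor population simulation,
calibrated only qualitatively (graded spread, diagonal dominance). Palm
afferents, afferent classes and skin mechanics are not modelled. The
nerve block multiplies the blocked finger's pooled drive by
`block_fraction` (default 0.20, i.e. a small residual activation) in
every stimulation condition.

Noiseless condition patterns are `tuning_weights · drive`, scaled in the
block session by a per-voxel gain: `gain_global` (0.75) everywhere
except the blocked finger's cluster voxels, which receive `gain_blocked`
(1.25) instead — mirroring at voxel level the gain placement of the
cortical model below. Per-run betas add Gaussian noise with a
configurable voxel covariance (identity by default; one shared
covariance per participant/session — the simplest structure that still
exercises prewhitening), and matched residual time series are emitted
with the same covariance. Default sizes: 8 participants, 200 voxels, 4
runs per session, 100 residual time points per run, noise SD 0.4 —
small enough that the whole study simulates in about a second, large
enough that cluster-level summaries are stable.

Traveling-wave runs stimulate the five fingers consecutively for 8 s
each around a 40-s cycle, 5 cycles per run (100 samples at TR 2 s), in
forward and backward order. The neural boxcars are convolved
*circularly* with the HRF — the steady-state response to a periodic
stimulus — which keeps the run length exact and the lag structure clean.
Real BOLD physiology (drift, motion, onset transients) is deliberately
absent, so localizer performance here is an upper bound on real data.

Psychophysics trials are Bernoulli draws from the same Weibull
parameterisation the analysis fits. The generator takes an 82%-threshold
and a shape ("slope") parameter and derives the Weibull scale so the
curve passes through 82% at the requested threshold; defaults are a
1.5-mm threshold (ordinary tactile acuity on the tested 0.5–3.5 mm
gratings, 20 trials per width) at baseline, and a 30-mm generating
threshold for the blocked finger — performance near the guess rate
across the whole tested range.

**Seeds.** All randomness flows from one master seed. Child generators
are spawned from `SeedSequence((master, participant, stream, extra))`
with fixed small stream ids per data type, so any piece of the study can
be regenerated independently and the whole study is bit-reproducible.

## GLM stage

The HRF is the conventional double gamma (peak 6 s, undershoot 16 s,
unit dispersions, undershoot ratio 1/6), normalised to unit peak; it is
zero at t = 0. Designs hold five HRF-convolved finger boxcars, their
temporal derivatives and an intercept (11 columns); rest is the implicit
baseline. Fitting is per-voxel OLS; rank-deficient designs raise an
error naming the collinear columns. Eleven contrasts are computed from
the finger betas only (derivatives never enter a contrast): each finger
vs. rest (the beta itself), each finger vs. the others (weights 1,
−¼,−¼,−¼,−¼), and all fingers vs. rest (the mean); fixed-effects run
averaging is the unweighted mean of per-run estimates. No
autocorrelation modelling or spatial smoothing is applied to the BOLD
series. In the pipeline the task betas come straight from the generator
(they *are* per-run finger-vs-rest estimates); the full design/OLS path
is exercised on the wave runs and in its own tests.

## Traveling-wave localizer

The reference bank holds one model per TR of the cycle — 20 at the
default schedule — each a circular shift of the HRF-convolved
single-finger boxcar; four consecutive lags belong to each finger.
Backward runs traverse the fingers in reverse, so their lag→finger
assignment is the forward assignment read in reverse (equivalent to
time-reversing the voxel time courses). Pearson correlations are clipped
at 1−10⁻⁶ before the Fisher transform; a finger's statistic is the mean
z over its four lags (a max option exists; the mean was chosen for
linearity), averaged across runs. p-values use the t statistic of the
back-transformed aggregated correlation with `n_timepoints − 2` degrees
of freedom — no autocorrelation correction, which is conservative only
in the sense of being conventional; on synthetic data it is merely a
monotone transform feeding the FDR step. Winners are the argmax over
fingers (ties to the lowest index); per finger, Benjamini–Hochberg FDR
at q < 0.01 over that finger's winning voxels defines the clusters
inside the hand mask. Clusters are disjoint by construction and need not
be contiguous.

A derivable subtlety: with overlapping tuning, forward-only and
backward-only analyses are *not* voxel-wise identical. Each finger's
four-lag window leans toward the next finger in forward runs and toward
the previous finger in backward runs, so boundary voxels can flip by
exactly one position between directions; the forward+backward average —
the procedure actually used — cancels this bias. With non-overlapping
tuning the two directions agree exactly. The tests encode both facts.

## Winner-takes-all and selectivity analyses

Cluster activity tables are the mean finger-vs-rest contrast over each
cluster's voxels (empty clusters yield missing entries, never zeros).
Selectivity per cluster is the target finger's activity minus the mean
of the nontarget fingers, with the blocked finger and its cluster
excluded (three nontargets per retained cluster). Winner-takes-all maps
assign each voxel to the strongest finger within a chosen subset,
leaving voxels unassigned when no response exceeds zero (an
unthresholded variant assigns everything); ties go to the lowest finger
index. Counts inside the deprived cluster are reported per finger and
grouped (blocked finger when included, neighbours, non-neighbours).
Counts are restricted to cluster voxels; session comparisons are emitted
as per-participant deltas, with group inference out of scope.

## Cross-nobis RSA

Prewhitening pools the demeaned GLM residuals over runs and shrinks the
covariance toward its diagonal with a Ledoit–Wolf-style analytic
intensity (the ratio of summed sampling variances of the off-diagonal
entries to their summed squares, clipped to [0,1]; a fixed intensity can
be configured). The whitener is the symmetric inverse square root;
non-positive estimates are floored with a warning. Distances are
cross-validated Mahalanobis: whitened condition differences computed
independently per run, inner products averaged over all unordered run
pairs, normalised by the voxel count so regions of different size are
comparable. Rest enters as an all-zero pattern in every run; no
mean-centering is applied anywhere (centering would distort
distance-from-rest). Cross-validation makes the estimator unbiased —
zero in expectation for identical conditions, with individual estimates
free to go negative.

MDS is classical (Torgerson) per participant; configurations are
aligned to the first participant by rotation/reflection plus translation
only (no scaling, so each participant's inter-point distances are
preserved exactly), averaged, and finally rotated onto the axes of
maximal between-finger variance of the mean configuration. Session
change summaries report percent changes of mean interfinger
dissimilarity (overall, nonblocked-only, blocked-with-neighbours vs.
blocked-with-non-neighbours), per-finger distance-from-rest changes, and
Spearman rank correlations — between sessions (shape preservation) and
against a canonical RDM with a finger-label permutation p-value
(exhaustive over the 120 permutations of five fingers; add-one rule).

## Recurrent cortical model

Five units, one per cluster, updating as
`c_i(t) = α_i w_iᵀ p + b + l_iᵀ c(t−1)`. The gain multiplies the
feedforward term only — the printed update equation is followed even
though a prose reading ("activity reduced proportionally") could put the
gain on the whole right-hand side; a `gain_on_lateral` switch implements
the alternative. The lateral kernel depends on inter-cluster distance
only; the default (0, +0.15, −0.05, −0.10, −0.10 at distances 0–4)
realises short-range excitation with long-range inhibition and has
spectral radius ≈ 0.33, validated at construction. Settlement iterates
from rest (c = 0) until the max-norm step change falls below tol
(default 10⁻⁶); the reported iteration count excludes the final
confirming step, so a lateral-free model settles in one step, and the
default fitted model settles in 5–6 steps at tol 10⁻³. A closed-form
fixed point, `(I − L) c = diag(α) W p + b·1`, serves as the oracle.

Baseline fitting regresses the lateral-corrected targets `(I − L) C` on
the drives (all gains 1). With five stimulation conditions the shared
offset `b` is not identifiable jointly with `W` — the constant column
lies in the span of the invertible drive matrix, the model's rest-state
ambiguity in linear-algebra form — so `b` is held fixed (default 0)
unless a minimum-norm joint estimate is requested. An iterative variant
(initial regression ignoring the lateral term, then repeated adjustment
of the regression targets by the settled-activity error) reproduces the
closed form on noiseless data and exists as a cross-check. Under noise
the per-cluster regressions share `b` by construction when it is fixed;
the minimum-norm route resolves the gauge arbitrarily.

The static block prediction settles the baseline model on blocked drives
with no parameter change; it collapses the blocked finger's
distance-from-rest disproportionately relative to the other fingers. The
homeostatic fit lets exactly two gains vary — one shared by the
non-blocked units, one *replacing* it for the blocked unit — minimising
squared error between settled responses and the block activity table by
a coarse grid over [0.25, 2]² (step 0.05) plus Nelder–Mead refinement;
unstable candidates are discarded with a warning. Because the settled
response is linear in the gains, the objective is smooth and the
recovered optimum matches an exhaustive fine grid. Model RDMs are plain
Euclidean distances between settled response vectors, with rest as the
zero vector. No plasticity dynamics are modelled: the gains are fitted
constants.

## Psychophysics

Accuracy per grating width is fitted by least squares with
`F(x) = γ + (1−γ−λ)(1 − exp(−(x/a)^β))`, γ = 0.05 and λ = 0 fixed, scale
and shape free (trialwise likelihood is deliberately not used). The
threshold is the root of `F(x) = 0.82` on the fitted curve (Brent's
method, so `F(threshold) = 0.82` to root-finder precision); the slope is
the analytic derivative there; R² is computed on the per-width
accuracies. Thresholds beyond the widest tested grating are reported but
flagged as extrapolations. The 0.05 guess rate is unusual for a
two-alternative task (chance is 50%); it is implemented as the
procedure's stated constant, overridable per call, with no attempt to
second-guess it. d′ is `Φ⁻¹(hit) − Φ⁻¹(fa)` with rates clamped to
[1/(2N), 1 − 1/(2N)].

## Pipeline and numerical choices

The pipeline simulates all participants, computes contrasts, localizes
clusters, runs the remapping and RSA analyses per participant, averages
activity tables across participants for the model stage, and fits
psychometric curves — writing every table as CSV (fixed float format)
plus a JSON summary and a manifest of SHA-256 content hashes. Identical
config and seed reproduce every file byte for byte. The canonical RDM
for rank-correlation tests is the group-mean baseline RDM.

Degenerate inputs are handled explicitly: constant localizer voxels are
flagged and excluded; empty clusters yield missing table entries;
fewer-than-two runs abort the RSA stage; non-convergent settlements and
unstable gain candidates raise or warn rather than silently continuing.

## What the synthetic study does and does not show

Passing tests establish that the analysis code implements its
definitions correctly (against hand-computed and brute-force oracles),
that the estimators are calibrated (cross-nobis null, threshold-recovery
bias shrinking with trial count), and that the qualitative signatures —
the winner-takes-all artifact, global selectivity loss,
shrink-without-reshape, homeostatic gain recovery — follow from the
stated generative assumptions. They do not show that real S1 data obey
those assumptions: the generator has no spatial structure beyond one
axis, no physiological noise, no inter-participant variability in tuning
geometry (exposed as config but defaulted to shared constants), and its
effect sizes are set by construction rather than measured from
participants.
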
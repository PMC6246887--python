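# Methods

This note documents the models and procedures `filmseg` implements, the
defaults and why, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Consensus boundary construction

Observer press logs are corrected for reaction time by subtracting a fixed
RT (default 0.9 s, clamped at 0) exactly once; re-correction raises. Merging
runs in two passes on a continuous time axis — boundaries are never snapped
to the TR grid; the TR enters only as a merge radius:

1. **Pass 1** clusters presses within 1 TR. The clustering semantics are
   genuinely open, so both readings are implemented behind `pass1=`: single-linkage *chaining* (a press joins the
   open cluster while within 1 TR of the previous member; the default) and
   a fixed-*anchor* window measured from the first press of the cluster.
   One observer contributes one vote per cluster: their multiple presses are
   averaged first, because `n_observers` means "number of observers".
2. **Pass 2** runs exactly once over adjacent pass-1 boundaries: a pair with
   ≥ 2 observers each and < 2 TR separation is replaced by a boundary at the
   mean of all member presses with summed counts. Running to convergence is
   deliberately avoided — chained merging can average together boundaries
   more than 12 s apart.

Boundaries within 10 s of the run end are dropped (their responses cannot be
estimated). The observer-count threshold is chosen so the retained boundary
count is closest to the mean per-observer press total; ties resolve to the
lower (more inclusive) threshold. Salience bins partition the sorted
distinct observer counts into three contiguous ranges minimising the sum of
squared deviations from N/3, with ties broken by the smallest |low − high|
count difference — on the published short-film tally this uniquely yields
the 7/5/7 split over the equally-SSE 7/7/5 alternative. Note that the
published long-film bin counts (60/43/54) sum to 157, i.e. they were
tallied after the 6-s single-trial exclusion; our binning of the full
161-event tally reproduces the same bin *ranges* (5–6 / 7–9 / 10+).

## Boundary-evoked GLM

The HRF is the canonical double-gamma (peak 6 s, undershoot 16 s, unit
dispersions, peak:undershoot 6:1, 32 s support), unit-peak normalised and
sampled at 16 microtime bins per TR; regressors are built by placing sticks
at real-valued boundary times on the microtime grid, convolving, and
reading out the middle microtime bin of each TR (matching slice-time
correction to the middle slice). High-pass filtering uses the cosine basis
below a 256 s cutoff, always including a constant. Single-trial betas come
from one least-squares-all GLM per participant and run with a separate
column per boundary; boundaries closer than 6 s are excluded
*symmetrically* (both members of the pair dropped — "removed" admits no
principled keep choice), because such responses are not dissociable
(adjacent regressors 3 s apart correlate ≈ 0.6; well-separated ones ≈ 0).
The FIR analysis interpolates the time course linearly to a 1 s grid and
estimates one free parameter per condition × peri-boundary second in
[−2, 12]; per-participant estimates are averaged with SEM.

## Permutation nulls

The duration shuffle permutes the interval vector (run start → b₁,
b₁ → b₂, …) and cumulatively sums it; the tail after the last boundary is
held fixed, so every draw preserves the boundary count, the interval
multiset, and the occupied span exactly. Whether the first (start-offset)
interval joins the shuffle is a genuine ambiguity; it does by default
(`include_start=True`) and both variants are exposed. p-values use the
add-one estimator (r + 1)/(n_perm + 1), never zero — a statistic
exceeding every draw reports p = 1/(n_perm + 1). Amplitude tests are
two-tailed on |β|; match-count tests one-tailed (greater). Matching is
always greedy one-to-one by ascending time difference, so no boundary is
counted twice.

## Crossed random-effects mixed models

The response is the single-trial beta; the model is

    beta ~ effect (+ covariates) + (1 | participant) + (1 | boundary)

with the effect of interest either the ordinal salience score (1/2/3 —
the linear-dependence test) or the raw observer count. Because the two
grouping factors are *crossed*, the covariance
V = σ²I + σ_p² Z_p Z_pᵀ + σ_b² Z_b Z_bᵀ is handled with the Woodbury
identity: after one pass of cross-product precomputation every REML
evaluation costs only (participants + boundaries)-sized linear algebra,
which keeps the hundreds of fits in the calibration suites cheap. The REML
deviance is minimised over log-variances by L-BFGS-B; a variance component
at the boundary of the parameter space flags the fit as singular (reported,
never hidden).

Inference on the 1-df effect uses the Satterthwaite approximation exactly
as lmerTest constructs it: df = 2v²/Var(v), where v = lᵀCov(β̂)l and
Var(v) comes from the delta method with the numeric gradient of v and the
numeric Hessian of the REML deviance over the variance parameters. On a
shared dataset the engine agrees with lme4/lmerTest to four significant
figures in the estimate, F, df and p (and with statsmodels MixedLM on the
variance components); the test suite keeps statsmodels as the independent
oracle. Effect size is the marginal R² (fixed-effect variance over fixed +
both intercept variances + residual), computed on the effect-only model.
Covariate adjustment fits either one model per covariate (does the boundary
effect survive each adjustment separately?) or the full model; correlated
covariate families can first be compacted to their leading SVD components.
The ROI sweep fits one model per region (bilateral homologs averaged on the
z-scored scale first) and applies Holm–Bonferroni step-down over the
family.

## Ordered-event HMM

Event structure appears as piecewise-stable multi-voxel patterns. The model
is a strictly left-to-right HMM: K event states, transitions only k → k or
k → k + 1, forced start in state 1 and end in state K, Gaussian emissions
with one mean pattern per event and a shared isotropic variance. EM
estimates means, variance and the stay probability; the forward–backward
pass enforces the end constraint, and the log-likelihood is monotone (a
property test guards this). K is fixed at the number of annotated
boundaries + 1 rather than estimated — data-driven K selection is out of
scope by design. Shifts are the TRs where the modal posterior state
increments. Shift–boundary matching is asymmetric (a shift counts as
matched when it occurs 0–2 TRs *after* a boundary, compared on the TR
grid: the boundary belongs to the TR during which it occurred); a
symmetric window is available behind a flag. Initialisation is a uniform
segmentation; tolerance 1e-4 relative log-likelihood, max 100 iterations;
per-event variances were rejected for identifiability at small T.

## Greedy data-driven events

Starting from a constant-only model on the high-pass-filtered, z-scored,
group-averaged time course, each iteration evaluates one candidate stick
regressor per TR (built by the same design code as the hypothesis-driven
GLM) and adds the one that most reduces the RSS, subject to: the new beta
is positive, and no previously selected event's beta flips sign — all betas
are re-fit jointly at every step, the literal reading of the sign-flip
constraint. Selection stops at k events (the number of annotated
boundaries, per run) or when no admissible candidate remains
(`stopped_early`, never silently padded). Ties in RSS reduction go to the
earlier TR. On toys with well-separated sticks the greedy RSS equals the
exhaustive-search optimum; the suite verifies both the equality and the
general greedy ≥ exhaustive inequality.

## Perceptual covariates

IMED/IMNCC weight pixel interactions by G_ij = exp(−|P_i−P_j|²/2σ²)/(2πσ²)
with σ = 1 px, truncated to a 9×9 neighbourhood where the weights are
already negligible; the quadratic form is evaluated as a 2-D convolution
and verified against a dense-matrix oracle. IMNCC mean-centres each frame;
two identical flat frames correlate 1 by convention. RGB channels are
computed separately and summed. Frame measures are taken over all cross
pairs between the 1 s windows flanking the boundary: distances take the
max, correlations the min (the most-changed pair; the symmetric choice for
correlations, configurable). Windows truncate at run edges. Histograms use
256 bins per channel on [0, 1]; luminance is the plain pixel mean (ITU
luma optional); "volume" is RMS amplitude over 100 ms (mean-absolute
optional); the PSD uses a plain Hann-windowed periodogram on 500 ms
epochs, truncated at 5 kHz. One caveat the tests encode: a Pearson
correlation of raw periodograms tops out near 0.5 even for identical
*flat* spectra, because the estimation noise is independent between
epochs; high psdCorr requires genuinely structured (colored) spectra.
The layered feature extractor is an interface (layer count + per-frame
maps); a deterministic mean-pool pyramid ships for tests, and a pretrained
network is an optional adapter, deliberately not bundled.

## Synthetic generators — what they emulate and what not

Observers detect each boundary independently with its salience probability
and respond with Gaussian RT jitter around a fixed mean; spurious presses
are homogeneous Poisson (default rate 0). BOLD is the per-boundary design
times true amplitudes, plus drift built *inside* the cosine confound span
(so high-pass filtering removes it by construction, making filter tests
sharp), plus stationary AR(1) noise. Patterns are piecewise-constant event
means plus iid noise; media are constant-texture scenes with per-scene
tone mixtures. Not emulated: head motion, physiological noise, spatially
correlated voxel noise, HRF variability across participants, realistic
film content, and observer non-independence. Passing tests therefore
establish correctness of the estimators under their assumed generative
model, not robustness to those real-data violations.

## Problem sizes and calibration bands

The simulation suites use: GLM recovery at 200 participants (noise SD 0.5);
mixed-model recovery at 200 × 60 over 100 replicates; data-driven recovery
at 100 participants (noise SD 1); type-I calibration of both permutation
tests at 200 null replicates × 199 permutations; and the Holm sweep at 55
regions with 12 × 15 tables. Calibration assertions use Monte-Carlo bands
around the nominal 0.05 level ([0.02, 0.09] for per-test rates at 200
replicates; ≤ 0.09 for the family-wise rate), since the empirical rate of a
correctly calibrated test is itself binomial.

## Known limitations

- No prewhitening of GLM residuals (AR noise inflates single-participant
  test statistics; the permutation null and the mixed models are the
  inferential routes, and both are calibrated empirically).
- The Satterthwaite Hessian is numeric; near-singular fits fall back to a
  pseudo-inverse and clip df to [1, n − p].
- `fir_timecourse` averages a participant's estimates across runs by last
  write when the same condition recurs; multi-run FIR pooling is minimal.
- The HMM assumes equal emission variance across events and voxels.
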
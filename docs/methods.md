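# Methods

This note documents the models implemented in `smdyn`, the defaults chosen
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Switching-diffusion generative model

A particle occupies one of K diffusion states governed by a continuous-time
Markov chain with rate matrix Q (off-diagonals ≥ 0, rows sum to zero). The
per-frame state transition uses the exact matrix exponential `P = expm(Q·Δt)`
rather than the first-order approximation `I + Q·Δt`: dwell times in this
system are subsecond while Δt = 30.5 ms, so `Q·Δt` entries are not small
enough for the linearization to be innocuous.

Within a state with diffusion coefficient `D_k`, displacements per frame and
axis are i.i.d. `N(0, 2·D_k·Δt)`. States flagged as confined evolve inside a
square domain with reflecting (specular) boundaries; the square is chosen
because it admits the closed-form stationary results used for testing —
per-axis position variance `L²/12` and 2-D MSD plateau `L²/3`. The domain is
centred where the particle enters the confined state and is re-drawn on
re-entry. Reported positions add isotropic Gaussian localization noise with
SD `σ_loc` (default 20 nm), which inflates the *apparent* diffusion
coefficient of every state by `σ_loc²/Δt` and adds `4σ_loc²` to MSD
intercepts.

Track lifetimes are exponential (default mean 20 frames, emulating
photobleaching and out-of-focus loss), truncated to the movie (default 100
frames at Δt = 30.5 ms); birth frames are uniform so the per-frame particle
count is roughly stationary. Defaults for the three-state preset: D =
(0.008, 0.05, 0.25) μm²/s with the slowest state confined to L = 0.15 μm,
all off-diagonal rates 1 s⁻¹ (exit rate 2 s⁻¹, mean dwell 0.5 s), cell area
400 μm² (a typical HEK293 basal footprint), ~0.2 particles/μm². These are
the regimes reported for TRPV-family channels in HEK cells and are fixed as
the package's reference study conditions.

### Oligomers and two-dye labeling

Each particle is an oligomer of 1–8 subunits drawn from a state-dependent
size distribution (modes at dimer/trimer/tetramer for the fast/medium/
immobile states respectively, the immobile state carrying the largest
high-order tail). Composition is fixed for the particle's lifetime; subunit
exchange within a movie is not modelled — association/dissociation enters
the framework only through colocalization-event statistics. Each subunit is
independently dye-1-labeled, dye-2-labeled, or dark with probabilities
(0.45, 0.45, 0.10): about 50% per dye and 90% total labeled, consistent
with near-saturating two-ligand labeling. Per frame, a channel's intensity
is the sum of independent lognormal single-fluorophore draws (default mean
890 a.u. for channel 1 and 720 a.u. for channel 2, CV 0.35 — a typical
single-dye brightness spread; only histograms of the real calibrations
exist, so the lognormal family is a modelling choice) over that channel's
labeled subunits. A particle dark in a channel is invisible there, which is
why downstream decomposition must condition on visibility.

### Time lapse and endocytosis

Movies at successive time points (default 0–20 min in 5-min steps) are
independent; removal ("endocytosis") acts between time points by binomial
thinning of per-state particle counts, never mid-movie. Two presets encode
the two kinetic phenotypes studied: fast endocytosis (removal of immobile
and medium particles from the first interval on) and slow endocytosis
(removal starting one time point later); a vehicle preset removes nothing.

### Movie rendering

Particles are rendered as pixel-integrated 2-D Gaussians (erf differences,
σ default 1.3 px at 67 nm/px) scaled by `photon_scale × intensity`, on a
constant background, with Poisson shot noise, clipped to 16-bit. No
blinking, no EM-CCD excess-noise factor, no axial effects.

## Tracking

The preprocessing steps (rolling-ball radius 25 px; two-frame running
average producing n−1 frames) match the acquisition pipeline the analyses
assume; both are individually toggleable. Averaging halves shot noise but
correlates adjacent frames; the effective Δt is deliberately kept at the
camera Δt. Detection finds local maxima above `snr · 1.4826·MAD` and
refines them by least-squares 2-D Gaussian fits in 7×7 windows, falling
back to an intensity-weighted centroid (flagged via `fit_quality = inf`).
Linking is greedy globally-nearest-neighbour with `max_disp` default
0.45 μm ≈ 3·√(4·D_fast·Δt), deterministic tie-breaking (distance, then
track id, then detection order), and optional gap closing with
linear-interpolated, flagged positions. No Kalman/multi-hypothesis linking
and no drift correction are attempted; on synthetic movies the criterion is
ground-truth identity recovery (≥90% of steps at SNR ≥ 5 and ≤0.3
particles/μm²), not equivalence with any specific tracker.

## VB-HMM diffusion-state clustering

Each step's 2-D displacement is emitted from hidden state k with isotropic
per-axis precision `λ_k = 1/(2·D_k·Δt)`. Conjugate priors: Dirichlet(1) on
the initial distribution and each transition-matrix row; Gamma(a₀ = 2,
b₀ = 2·Δt·D̄) on each λ_k, where D̄ is the overall mean-square step over
4Δt — weakly informative and scale-aware, so the same code handles μm and
nm conventions. Inference is standard variational EM: the E-step runs
scaled forward–backward with exponentiated expected log-parameters (batched
over padded tracks for speed; a single-sequence reference implementation is
kept for oracle tests against brute-force enumeration), the M-step updates
hyperparameters from expected counts. The evidence lower bound is the sum
of forward log-normalizers under the tilde parameters minus the
Dirichlet/Gamma KL terms; it is monotone across iterations (asserted in
tests) and used to select K. Convergence: relative ELBO change < 1e-6,
max 500 iterations, best of 5 restarts (quantile-split initialization,
jittered on restarts). Tracks with fewer than 5 steps are excluded from
fitting but still Viterbi-decoded. States are canonically ordered by
ascending D, which makes results seed-invariant up to numerical noise.

Reported `D_est` is the posterior mean of `1/(2Δtλ)`; with the default
priors and K = 1 this reduces exactly to the moment estimator
`mean(step²)/(4Δt)`. Localization noise is *absorbed* into `D_est`
(apparent D) to match how such values are usually reported;
`D_corrected(σ_loc)` subtracts `σ_loc²/Δt` analytically when the noise
scale is known. This correction matters: at σ_loc = 20 nm and Δt = 30.5 ms
the bias (≈0.013 μm²/s) exceeds the immobile-state D itself, so recovery
claims for slow states are only meaningful after correction. Two caveats
are documented rather than modelled: noise induces a small negative
correlation between consecutive steps that the HMM's independence
assumption ignores, and confinement depresses the immobile state's
apparent D below the free-diffusion value, so the corrected immobile D
reads 10–20% low under the reference conditions.

Transition rate constants use the short-interval identity
`k_ij = A_ij/Δt` (i ≠ j) with diagonal minus the row sum and mean dwell
time `1/|k_ii|`. Both dye channels of a particle share its state labels.

## MSD analysis

MSD uses all overlapping time origins within each track (maximal pairs),
splitting tracks at frame gaps; SEM is computed across cells when several
cell ids are present (mirroring per-cell averaging in small-n imaging
studies), else across tracks. The linear fit uses the first 4 lags
(weighted by 1/SEM² when available); the confined fit uses up to 15 lags
by default (configurable; the acceptance analyses use 30 on 100-frame
tracks) of the saturating model `MSD(t) = (L²/3)(1 − e^{−t/τ}) + offset`
with `τ = L²/(12·D_micro)` as the documented convention linking τ to the
short-time diffusion coefficient. A fitted τ beyond the fitted lag range
means the data show no plateau; the fit is then flagged censored and L
should not be trusted. The fitted L and the raw plateau are reported
separately so users can compare both readouts.

## Oligomer decomposition

The monomer control is fitted by closed-form lognormal MLE on log
intensities (≥200 samples required; the fitted mean agrees with the sample
mean within 2% by construction of the family). n-mer intensity densities
are n-fold discrete self-convolutions on a fixed grid (0 to 8× monomer
mean, 256 bins). The decomposition basis accounts for partial labeling:
with per-subunit labeling probability p, a k-mer contributes a
Binomial(k, p) mixture over the number of labeled subunits, conditioned on
≥1 label because fully dark particles are never detected — omitting this
conditioning systematically inflates small-oligomer weights. Weights are
obtained by non-negative least squares (convex, deterministic) and
normalized; recovery tests require mean absolute weight error ≤ 0.05 at
≥5,000 particles for p ∈ [0.5, 1]. Intensity histograms report both the
mixture weights and the histogram mode, since "peak at m× monomer" claims
can refer to either. Difference histograms are density-scaled (not
per-histogram normalized) so net particle loss appears as negative mass.

## Colocalization kinetics

A colocalization event is a cross-channel pair closer than 200 nm in the
same frame *and* the same diffusion state. Multi-neighbour conflicts are
resolved one-to-one greedily by ascending distance with deterministic id
tie-breaks (the rule is symmetric in channels up to field permutation).
Consecutive-frame pairs of the same ids merge; by default a 1-frame gap
splits events (configurable). Events running to a member track's end are
right-censored. The colocalized fraction counts particles participating in
≥1 event per movie over all detected particles — the per-movie reading of
an ambiguous convention; per-frame fractions can be derived from the event
table if preferred. The on-rate constant divides the initial slope V0 of
the cumulative event-start density (least squares through the origin over
the first third of the movie by default — no standard window exists) by
the product of channel densities. On-time survival is a product-limit
estimate honouring censoring, with the censoring-aware exponential MLE
(total observed time / uncensored count) for the mean on-time. Chance
colocalization by density is not corrected for.

## Pharmacology

Hill fits run in `(bottom, span ≥ 0, log10 EC50, n ∈ (0, 10])` space, which
enforces `top ≥ bottom` and keeps EC50 positive without penalty terms.
Initial guesses come from response quantiles and the mid-response
concentration. Fits are unweighted by default (replicate-SEM weighting
available). Peak response is `max(post-stimulation)/mean(baseline)`;
specific binding is the pointwise difference total − nonspecific, floored
at zero with a warning, then Hill-fitted.

## Problem sizes and determinism

The packaged analyses and tests run on deliberately moderate sizes — e.g.
2,000 tracks × ~20 steps for three-state HMM recovery, 1,000 × 100-frame
tracks for confinement fitting, 5,000 samples for calibration — sizes at
which the estimators' sampling error is comfortably inside the tolerances
being asserted. Every stochastic component takes a `numpy` Generator or
seed; the pipeline spawns per-stage seeds from one root seed, and fixed
seeds give bit-identical outputs (asserted down to summary-JSON bytes).

## Known limitations

* No photophysics beyond single-step disappearance; no EM-CCD excess noise;
  no 3-D effects — synthetic SNR is optimistic relative to real movies.
* The HMM emission model ignores motion blur and the noise-induced
  anticorrelation of consecutive steps.
* Tracking equivalence with closed-source trackers cannot be asserted, only
  ground-truth recovery on synthetic data.
* Whether a "percentage remaining" readout denotes colocalization survival
  or surface retention is experiment-dependent; both are computable here
  and neither is asserted as canonical.
* Simulated time-lapse movies are independent across time points; particles
  are not tracked through stimulation.
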
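# smdyn

Single-molecule dynamics of membrane channels from TIRF time-lapse imaging.

`smdyn` is a Python toolkit for the quantitative questions that arise when a
tetrameric ion channel (for example TRPV1 or TRPV4 in HEK293 cells) is imaged
one molecule at a time: how fast do individual channels diffuse, how do they
switch between mobility states, how large are the oligomers behind each
diffraction-limited spot, how often do two differently labeled subunits meet,
and how does agonist stimulation change all of the above through
state-selective endocytosis. Because raw single-molecule movies of this kind
are rarely deposited, the package ships a first-class synthetic-data
generator that reproduces the statistical structure of such experiments with
known ground truth, so every analysis stage is testable end to end.

## What it computes

* **Switching-diffusion simulation** — K-state continuous-time Markov
  trajectories (per-frame transition matrix `expm(Q·Δt)`), per-state
  diffusion coefficients, square confinement domains with reflecting walls,
  exponential track lifetimes, Gaussian localization noise, state-dependent
  oligomer sizes, stochastic two-dye labeling, lognormal single-fluorophore
  intensities, 5-min-interval time lapse with state-selective particle
  removal, rendered 16-bit TIFF movies, and Hill-shaped dose-response tables.
* **Tracking** — rolling-ball background subtraction and two-frame running
  average, Gaussian-fit spot detection, greedy nearest-neighbour linking.
* **VB-HMM diffusion-state clustering** — variational-Bayes inference of a
  hidden Markov model whose emissions are 2-D displacement steps with
  per-axis variance `2·D_k·Δt` (Dirichlet priors on π and A, Gamma prior on
  the step precision). Model selection over K by the evidence lower bound;
  transition rate constants `k_ij = A_ij/Δt` and mean dwell times from the
  posterior transition matrix; Viterbi state labels per step.
* **MSD analysis** — time-and-ensemble-averaged MSD with overlapping
  origins; linear fit `MSD = 4DΔt + 4σ_loc²`; confined-diffusion fit
  `MSD(t) = (L²/3)(1 − e^{−t/τ}) + offset` giving the membrane-domain side
  length L; per-state densities, fractions, and density–MSD correlations.
* **Oligomer decomposition** — single-fluorophore calibration from a
  monomeric control (CD86-like), n-mer intensity models by n-fold
  convolution, non-negative least-squares mixture decomposition with
  partial-labeling correction, difference histograms across time points.
* **Two-color colocalization** — events defined by <200 nm separation in
  the same frame and same diffusion state, colocalized fractions, on-rate
  constants `k_on = V0/([Ch1]·[Ch2])`, and censoring-aware on-time survival.
* **Pharmacology** — Hill-equation fits
  `f(x) = bottom + (top − bottom)/(1 + (EC50/x)^n)` for FLIPR dose-response
  and saturation binding, peak-response normalization, specific-binding
  computation.

## Worked example

```python
import numpy as np
from smdyn import *
from smdyn.params import three_state_preset

params = three_state_preset(seed=1, n_particles=500, n_frames=100)
traj, truth = simulate_trajectories(params)
traj = simulate_oligomer_intensities(params, traj, truth)

result = fit_vbhmm(traj, K=3, seed=0, n_restarts=3)
print("D (apparent, um^2/s):", np.round(result.D_est, 4))
print("D (noise-corrected): ", np.round(result.D_corrected(params.loc_sigma), 4))
print("state fractions:     ", np.round(result.state_fractions, 3))
print("mean dwell times (s):", np.round(result.mean_dwell_times(), 3))

labeled = assign_states(traj, result)
curve = compute_msd(labeled, max_lag=30, state=0)
fit = fit_msd_confined(curve, n_fit_points=30)
print(f"immobile-state confinement L = {fit.L*1000:.0f} nm (tau = {fit.tau:.3f} s)")
```

prints

```
D (apparent, um^2/s): [0.0196 0.0625 0.2593]
D (noise-corrected):  [0.0064 0.0494 0.2461]
state fractions:      [0.313 0.384 0.303]
mean dwell times (s): [0.449 0.479 0.524]
immobile-state confinement L = 157 nm (tau = 0.088 s)
```

The three apparent diffusion coefficients are inflated by the 20 nm
localization noise (`σ_loc²/Δt ≈ 0.013 μm²/s`); after the analytic
correction they bracket the generating values (0.008, 0.05, 0.25 μm²/s; the
immobile state reads slightly low because confinement itself curbs its
apparent mobility). Dwell times are subsecond, matching the generating exit
rate of 2 s⁻¹, and the confined-MSD fit on immobile-state steps recovers
the 150 nm domain side to within a few percent.

A full synthetic pipeline (time lapse → HMM → densities → oligomers →
colocalization) runs from the command line:

```bash
smdyn run --seed 1 --outdir out/
smdyn simulate --seed 1 --n-particles 100 --out traj.csv
smdyn fit-hmm --traj traj.csv --kmin 1 --kmax 4 --out hmm.json
```

## Layout

```
src/smdyn/
  params.py        simulation parameters and study presets
  trajectories.py  TrajectorySet container + CSV I/O
  simulate.py      trajectory / intensity / time-lapse / dose-response generators
  render.py        synthetic TIFF movie rendering
  tracking.py      preprocessing, spot detection, linking
  vbhmm.py         variational-Bayes HMM and model selection
  diffusion.py     MSD curves and fits, densities, step histograms
  oligomer.py      monomer calibration and NNLS oligomer decomposition
  coloc.py         two-color colocalization kinetics
  pharm.py         Hill fits, peak response, specific binding
  pipeline.py      end-to-end driver
  cli.py           `smdyn` command-line interface
```

See `docs/methods.md` for the models, assumptions, parameter defaults, and
known limitations.
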
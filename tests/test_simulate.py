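"""Generator correctness: step statistics, confinement, dwell times,
oligomer intensities, time-lapse removal, determinism."""

import numpy as np
import pandas as pd
import pytest

from smdyn.params import MonomerIntensityModel, SimulationParams, removal_preset
from smdyn.simulate import (
    simulate_dose_response,
    simulate_oligomer_intensities,
    simulate_timelapse,
    simulate_trajectories,
)


def test_degenerate_diffusion_is_static():
    p = SimulationParams(
        D=(0.0,), rate_matrix=np.zeros((1, 1)), confinement_side=(None,),
        loc_sigma=0.0, n_particles=20, seed=1,
    )
    traj, _ = simulate_trajectories(p)
    steps = traj.steps()
    assert np.all(steps["dx"] == 0) and np.all(steps["dy"] == 0)


def test_mean_square_step_matches_4Ddt(single_state_traj):
    p, traj, _ = single_state_traj
    steps = traj.steps()
    r2 = (steps["dx"] ** 2 + steps["dy"] ** 2).to_numpy()
    expected = 4 * 0.25 * p.dt
    se = r2.std(ddof=1) / np.sqrt(len(r2))
    assert len(r2) >= 2000
    assert abs(r2.mean() - expected) < 3 * se


def test_per_axis_step_variance_includes_localization_noise():
    p = SimulationParams(
        D=(0.05,), rate_matrix=np.zeros((1, 1)), confinement_side=(None,),
        loc_sigma=0.02, n_particles=500, track_lifetime_mean=40, seed=3,
    )
    traj, _ = simulate_trajectories(p)
    dx = traj.steps()["dx"].to_numpy()
    assert len(dx) >= 10_000
    expected = 2 * 0.05 * p.dt + 2 * 0.02**2
    se = np.std(dx**2, ddof=1) / np.sqrt(len(dx))
    assert abs(np.var(dx) - expected) < 3 * se


def test_confined_state_position_variance():
    """Stationary per-axis position variance in a square domain is L²/12."""
    L = 0.15
    p = SimulationParams(
        D=(0.05,), rate_matrix=np.zeros((1, 1)), confinement_side=(L,),
        loc_sigma=0.0, n_particles=300, track_lifetime_mean=500, n_frames=200,
        seed=4,
    )
    traj, _ = simulate_trajectories(p, random_birth=False)
    # discard the first 20 frames (mixing) and center per track
    df = traj.data[traj.data["frame"] >= 20]
    var = df.groupby("particle_id")["x_um"].var(ddof=1)
    se = var.std(ddof=1) / np.sqrt(len(var))
    assert abs(var.mean() - L**2 / 12) < 3 * se


def test_dwell_time_matches_exit_rate():
    Q = np.array([[-2.0, 2.0], [2.0, -2.0]])
    p = SimulationParams(
        D=(0.01, 0.2), rate_matrix=Q, confinement_side=(None, None),
        oligomer_dist=np.array([[1.0], [1.0]]),
        n_particles=400, track_lifetime_mean=200, n_frames=300, seed=5,
    )
    _, gt = simulate_trajectories(p, random_birth=False)
    # mean dwell = dt/(1 - p_stay); estimate p_stay by transition counting,
    # which is unbiased under track-end censoring (unlike complete-run means)
    stay = leave = 0
    for pid, g in gt.table.groupby("particle_id"):
        s = g.sort_values("frame")["state"].to_numpy()
        from0 = s[:-1] == 0
        stay += int(np.sum(from0 & (s[1:] == 0)))
        leave += int(np.sum(from0 & (s[1:] != 0)))
    from scipy.linalg import expm

    p_stay_true = expm(Q * p.dt)[0, 0]
    n = stay + leave
    p_stay_hat = stay / n
    se = np.sqrt(p_stay_true * (1 - p_stay_true) / n)
    assert n > 10_000
    assert abs(p_stay_hat - p_stay_true) < 3 * se
    # implied mean dwell is subsecond for these rates
    assert p.dt / (1 - p_stay_hat) < 1.0


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        SimulationParams(dt=0.0)
    with pytest.raises(ValueError):
        SimulationParams(rate_matrix=np.array([[-1.0, -0.5, 1.5]] * 3))
    with pytest.raises(ValueError):
        SimulationParams(D=(-0.1, 0.05, 0.25))


def test_fixed_seed_bit_identical():
    p = SimulationParams(n_particles=30, seed=11)
    t1, _ = simulate_trajectories(p)
    t2, _ = simulate_trajectories(p)
    pd.testing.assert_frame_equal(t1.data, t2.data)


# ----------------------------------------------------------------------
# oligomer intensities
# ----------------------------------------------------------------------
def _monomer_traj(n_particles, size_dist, label_probs, seed=0):
    p = SimulationParams(
        D=(0.05,), rate_matrix=np.zeros((1, 1)), confinement_side=(None,),
        oligomer_dist=np.array([size_dist]), label_probs=label_probs,
        n_particles=n_particles, track_lifetime_mean=10, seed=seed,
    )
    traj, gt = simulate_trajectories(p)
    return p, simulate_oligomer_intensities(p, traj, gt), gt


def test_monomer_full_labeling_reproduces_monomer_distribution():
    p, traj, _ = _monomer_traj(800, [1.0], (1.0, 0.0, 0.0), seed=21)
    vals = traj.data["intensity_ch1"].to_numpy()
    model = p.monomer_intensity[0]
    assert np.all(traj.data["intensity_ch2"] == 0)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - model.mean) < 3 * se
    # CV of draws matches the model CV
    assert np.std(vals) / np.mean(vals) == pytest.approx(model.cv, rel=0.1)


def test_dimer_mean_is_twice_monomer():
    _, traj, _ = _monomer_traj(600, [0.0, 1.0], (1.0, 0.0, 0.0), seed=22)
    vals = traj.data["intensity_ch1"].to_numpy()
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 1780.0) < 3 * se


def test_tetramer_visibility_fraction():
    """P(≥1 dye-1 label | tetramer) = 1 − 0.6⁴ = 0.8704 at p₁ = 0.4."""
    _, traj, gt = _monomer_traj(
        4000, [0, 0, 0, 1.0], (0.4, 0.4, 0.2), seed=23
    )
    per_particle = traj.data.groupby("particle_id")["intensity_ch1"].max()
    visible = (per_particle > 0).mean()
    p_vis = 1 - 0.6**4
    se = np.sqrt(p_vis * (1 - p_vis) / len(per_particle))
    assert abs(visible - p_vis) < 3 * se


def test_oligomer_composition_fixed_over_lifetime():
    _, traj, gt = _monomer_traj(50, [0.0, 1.0], (0.5, 0.4, 0.1), seed=24)
    # a particle dark in ch1 at one frame is dark at every frame
    vis = traj.data.groupby("particle_id")["intensity_ch1"].agg(["min", "max"])
    assert np.all((vis["min"] > 0) == (vis["max"] > 0))


# ----------------------------------------------------------------------
# time lapse
# ----------------------------------------------------------------------
def test_timelapse_no_removal_keeps_density():
    p = SimulationParams(n_particles=200, n_frames=30, seed=31)
    series = simulate_timelapse(
        p, removal_preset("vehicle"), with_intensities=False
    )
    counts = [ts.n_particles for ts, _ in series]
    assert counts == [200] * 5


def test_timelapse_state_selective_removal():
    """Removing half the immobile particles halves that state's count and
    raises the fast fraction."""
    p = SimulationParams(n_particles=3000, n_frames=10, seed=32)
    removal = np.array([[0.5, 0.0, 0.0]])
    series = simulate_timelapse(
        p, removal, time_points=(0.0, 5.0), with_intensities=False
    )
    (t0, gt0), (t1, gt1) = series
    c0 = gt0.table.groupby("particle_id").first()["state"].value_counts()
    c1 = gt1.table.groupby("particle_id").first()["state"].value_counts()
    ratio = c1.get(0, 0) / c0.get(0, 1)
    se = np.sqrt(0.25 / c0.get(0, 1))
    assert abs(ratio - 0.5) < 4 * se
    # non-removed states keep their counts
    assert c1.get(2, 0) == c0.get(2, 0)


def test_timelapse_onset_presets_differ():
    """Fast-endocytosis removal begins one time point before the slow one."""
    fast = removal_preset("fast-endocytosis")
    slow = removal_preset("slow-endocytosis")
    assert fast[0].sum() > 0
    assert slow[0].sum() == 0 and slow[1].sum() > 0


# ----------------------------------------------------------------------
# dose response
# ----------------------------------------------------------------------
def test_dose_response_midpoint_and_asymptote():
    tbl = simulate_dose_response(
        26.0, 1.0, 1.0, 5.0, np.array([26.0, 1e9]), noise_sd=0.0, n_reps=1
    )
    assert tbl.loc[0, "response"] == pytest.approx(3.0)
    assert tbl.loc[1, "response"] == pytest.approx(5.0, rel=1e-6)


def test_dose_response_rejects_nonpositive_concentration():
    with pytest.raises(ValueError):
        simulate_dose_response(10, 1, 0, 1, np.array([0.0, 1.0]))
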
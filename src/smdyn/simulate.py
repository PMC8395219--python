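"""Synthetic-data generator with known ground truth.

Generates switching-diffusion trajectories, oligomer intensities, two-color
stochastic labeling, state-selective time-lapse removal (endocytosis), and
Hill-shaped dose-response tables. Every generator is driven by a
:class:`numpy.random.Generator` seeded from ``SimulationParams.seed`` (or an
explicit seed argument), so fixed seeds give bit-identical outputs.

State dynamics use the exact per-frame transition matrix ``expm(Q·dt)``;
displacements per frame per axis are zero-mean Gaussian with variance
``2·D_state·dt``; confined states reflect inside a square domain; reported
positions add isotropic Gaussian localization noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .params import SimulationParams
from .trajectories import TrajectorySet


@dataclass
class GroundTruth:
    """Per-particle generative truth for recovery tests.

    ``table`` holds one row per particle per frame with the true state index
    and noise-free coordinates; ``oligomer_size`` and ``labels`` are indexed
    by particle id. ``labels[pid]`` is an integer array over subunits with
    values 0 (dye 1), 1 (dye 2), 2 (unlabeled).
    """

    table: pd.DataFrame
    oligomer_size: dict[int, int] = field(default_factory=dict)
    labels: dict[int, np.ndarray] = field(default_factory=dict)
    removal_times: dict[int, int] = field(default_factory=dict)

    def states_for(self, particle_id: int) -> np.ndarray:
        g = self.table[self.table["particle_id"] == particle_id]
        return g.sort_values("frame")["state"].to_numpy()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "table": self.table.to_dict(orient="list"),
            "oligomer_size": {str(k): int(v) for k, v in self.oligomer_size.items()},
            "labels": {str(k): v.tolist() for k, v in self.labels.items()},
            "removal_times": {str(k): int(v) for k, v in self.removal_times.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            table=pd.DataFrame(payload["table"]),
            oligomer_size={int(k): v for k, v in payload["oligomer_size"].items()},
            labels={int(k): np.array(v) for k, v in payload["labels"].items()},
            removal_times={int(k): v for k, v in payload["removal_times"].items()},
        )


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------
def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by specular reflection."""
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def simulate_trajectories(
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    cell_id: int = 0,
    initial_states: np.ndarray | None = None,
    random_birth: bool = True,
) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate one movie of switching-diffusion tracks.

    Each particle is born at a uniform-random frame (or frame 0 when
    ``random_birth`` is False), lives an exponential number of frames
    truncated at the movie end, starts at a uniform position inside the
    square cell, and evolves by the K-state Markov chain with per-frame
    transition matrix ``expm(Q·dt)``.

    Returns the trajectory set (reported positions = true + localization
    noise) and the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    K = params.n_states
    P = expm(params.rate_matrix * params.dt)
    P = np.clip(P, 0, None)
    P /= P.sum(axis=1, keepdims=True)
    # stationary distribution of P for initial states
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    pi = np.abs(pi) / np.abs(pi).sum()

    side = float(np.sqrt(params.cell_area))
    rows = []
    truth_rows = []
    for pid in range(params.n_particles):
        if random_birth:
            # clamp so every particle exists for >= 2 frames
            birth = int(rng.integers(0, max(params.n_frames - 1, 1)))
        else:
            birth = 0
        life = max(2, int(np.ceil(rng.exponential(params.track_lifetime_mean))))
        n = max(2, min(life, params.n_frames - birth))
        if initial_states is not None:
            s = int(initial_states[pid])
        else:
            s = int(rng.choice(K, p=pi))
        x = rng.uniform(0, side)
        y = rng.uniform(0, side)
        center = None  # confinement domain center, set on entry
        for i in range(n):
            frame = birth + i
            conf = params.confinement_side[s]
            if conf is not None and center is None:
                center = (x, y)
            elif conf is None:
                center = None
            truth_rows.append((cell_id, pid, frame, s, x, y))
            if i == n - 1:
                break
            # diffusive step
            sd = np.sqrt(2 * params.D[s] * params.dt)
            x += rng.normal(0, sd)
            y += rng.normal(0, sd)
            if conf is not None:
                half = conf / 2
                x = float(_reflect(np.array(x), center[0] - half, center[0] + half))
                y = float(_reflect(np.array(y), center[1] - half, center[1] + half))
            # state switch for the next frame
            s_new = int(rng.choice(K, p=P[s]))
            if s_new != s:
                center = None
            s = s_new
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "particle_id", "frame", "state", "x_um", "y_um"]
    )
    noisy = truth.copy()
    if params.loc_sigma > 0:
        noisy["x_um"] = noisy["x_um"] + rng.normal(0, params.loc_sigma, len(noisy))
        noisy["y_um"] = noisy["y_um"] + rng.normal(0, params.loc_sigma, len(noisy))
    data = noisy.rename(columns={"state": "state_true"})[
        ["cell_id", "particle_id", "frame", "x_um", "y_um", "state_true"]
    ]
    traj = TrajectorySet(
        data=data.reset_index(drop=True),
        dt=params.dt,
        cell_area_um2=params.cell_area,
    )
    gt = GroundTruth(
        table=truth.rename(
            columns={"x_um": "x_true", "y_um": "y_true"}
        ).reset_index(drop=True)
    )
    return traj, gt


# ----------------------------------------------------------------------
# oligomer intensities and two-dye labeling
# ----------------------------------------------------------------------
def simulate_oligomer_intensities(
    params: SimulationParams,
    traj: TrajectorySet,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> TrajectorySet:
    """Assign oligomer sizes, dye labels, and per-frame intensities.

    The oligomer size of a particle is drawn from the size distribution of
    its initial diffusion state and stays fixed for the particle's lifetime.
    Each subunit is independently labeled with dye 1, dye 2, or left dark
    according to ``label_probs``. Per frame, the channel intensity is the
    sum of independent lognormal single-fluorophore draws over that
    channel's labeled subunits; particles with zero labeled subunits in a
    channel have intensity 0 there (invisible in that channel).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    data = traj.data.copy()
    n_max = params.n_max
    sizes = {}
    labels = {}
    first = truth.table.sort_values("frame").groupby("particle_id").first()
    for pid, row in first.iterrows():
        s0 = int(row["state"])
        size = 1 + int(rng.choice(n_max, p=params.oligomer_dist[s0]))
        if size > n_max:
            raise ValueError(f"oligomer size {size} exceeds n_max {n_max}")
        sizes[pid] = size
        labels[pid] = rng.choice(3, size=size, p=np.asarray(params.label_probs))
    truth.oligomer_size = sizes
    truth.labels = labels

    i1 = np.zeros(len(data))
    i2 = np.zeros(len(data))
    pids = data["particle_id"].to_numpy()
    for pid in np.unique(pids):
        mask = pids == pid
        nf = int(mask.sum())
        lab = labels[int(pid)]
        n1 = int(np.sum(lab == 0))
        n2 = int(np.sum(lab == 1))
        if n1:
            i1[mask] = params.monomer_intensity[0].draw(rng, (nf, n1)).sum(axis=1)
        if n2:
            i2[mask] = params.monomer_intensity[1].draw(rng, (nf, n2)).sum(axis=1)
    data["intensity_ch1"] = i1
    data["intensity_ch2"] = i2
    return TrajectorySet(
        data=data,
        dt=traj.dt,
        pixel_size_um=traj.pixel_size_um,
        cell_area_um2=traj.cell_area_um2,
    )


# ----------------------------------------------------------------------
# 5-min-interval time lapse with state-selective removal
# ----------------------------------------------------------------------
def simulate_timelapse(
    params: SimulationParams,
    removal_rates: np.ndarray,
    time_points: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0),
    rng: np.random.Generator | None = None,
    with_intensities: bool = True,
) -> list[tuple[TrajectorySet, GroundTruth]]:
    """Independent movies at each time point with cumulative removal.

    ``removal_rates`` has one row per interval between consecutive time
    points and one column per state; entry (t, k) is the probability that a
    state-k particle is endocytosed during interval t. Removal acts on
    per-state particle counts by binomial thinning between time points;
    each time point's movie is simulated fresh with the surviving counts as
    initial-state allocation.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    removal_rates = np.asarray(removal_rates, float)
    if np.any((removal_rates < 0) | (removal_rates > 1)):
        raise ValueError("removal probabilities must lie in [0, 1]")
    if list(time_points) != sorted(time_points):
        raise ValueError("time_points must be ordered")
    if removal_rates.shape != (len(time_points) - 1, params.n_states):
        raise ValueError(
            "removal_rates must be (n_timepoints-1, n_states), got "
            f"{removal_rates.shape}"
        )
    K = params.n_states
    P = expm(params.rate_matrix * params.dt)
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    pi = np.abs(pi) / np.abs(pi).sum()
    counts = rng.multinomial(params.n_particles, pi)

    out = []
    for t_idx, _t in enumerate(time_points):
        if t_idx > 0:
            # binomial survival per state
            surv = np.array(
                [
                    rng.binomial(counts[k], 1 - removal_rates[t_idx - 1, k])
                    for k in range(K)
                ]
            )
            counts = surv
        init = np.repeat(np.arange(K), counts)
        p = params.with_(n_particles=int(counts.sum()))
        traj, gt = simulate_trajectories(p, rng=rng, initial_states=init)
        if with_intensities:
            traj = simulate_oligomer_intensities(p, traj, gt, rng=rng)
        out.append((traj, gt))
    return out


# ----------------------------------------------------------------------
# dose-response tables
# ----------------------------------------------------------------------
def simulate_dose_response(
    ec50: float,
    hill_n: float,
    bottom: float,
    top: float,
    concentrations: np.ndarray,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill-equation responses with Gaussian noise.

    ``response = bottom + (top − bottom)/(1 + (EC50/x)^n) + ε`` with
    ε ~ N(0, noise_sd²), replicated ``n_reps`` times per concentration.
    """
    x = np.asarray(concentrations, float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    f = bottom + (top - bottom) / (1 + (ec50 / x) ** hill_n)
    rows = []
    for rep in range(n_reps):
        noise = rng.normal(0, noise_sd, len(x)) if noise_sd > 0 else np.zeros(len(x))
        for xi, ri in zip(x, f + noise):
            rows.append((xi, ri, rep))
    return pd.DataFrame(rows, columns=["concentration_nM", "response", "replicate"])
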
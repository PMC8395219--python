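"""Simulation parameters and study presets.

The synthetic-data generator emulates TIRF single-molecule imaging of a
tetrameric membrane channel: particles switch among K diffusion states
(continuous-time Markov chain), diffuse with state-dependent coefficients,
the slowest state is confined to ~150 nm membrane domains, particles are
oligomers of 1..n_max subunits with state-dependent size distributions, and
each subunit is stochastically labeled with one of two dyes or left dark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class MonomerIntensityModel:
    """Lognormal single-fluorophore intensity model for one dye.

    ``mean`` is the distribution mean in a.u.; ``cv`` its coefficient of
    variation. Lognormal parameters derive as
    ``sigma² = ln(1+cv²)``, ``mu = ln(mean) − sigma²/2``.
    """

    mean: float
    cv: float = 0.35

    @property
    def sigma_log(self) -> float:
        return float(np.sqrt(np.log1p(self.cv**2)))

    @property
    def mu_log(self) -> float:
        return float(np.log(self.mean) - 0.5 * self.sigma_log**2)

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        return rng.lognormal(self.mu_log, self.sigma_log, size=size)


@dataclass
class SimulationParams:
    """Ground-truth parameters of the switching-diffusion generator.

    Attributes
    ----------
    D
        Per-state diffusion coefficients, μm²/s, ascending order expected.
    rate_matrix
        K×K continuous-time transition rate matrix, s⁻¹; off-diagonals ≥ 0,
        rows sum to 0 (the diagonal is set to minus the off-diagonal sum).
    confinement_side
        Per-state side length (μm) of a square reflecting domain, or None
        for free diffusion in that state.
    dt
        Frame interval, s (camera exposure 30.5 ms by default).
    loc_sigma
        Localization noise SD per axis, μm.
    track_lifetime_mean
        Mean track length in frames (exponential, truncated to the movie).
    oligomer_dist
        Per-state probability vector over oligomer sizes 1..n_max.
    label_probs
        ``(p_dye1, p_dye2, p_unlabeled)`` per subunit; sums to 1.
    monomer_intensity
        Per-dye single-fluorophore intensity model.
    cell_area
        Imaged membrane area, μm² (square field assumed).
    n_particles
        Particles per movie (before visibility filtering).
    """

    D: tuple[float, ...] = (0.008, 0.05, 0.25)
    rate_matrix: np.ndarray | None = None
    confinement_side: tuple[float | None, ...] = (0.15, None, None)
    dt: float = 0.0305
    n_frames: int = 100
    loc_sigma: float = 0.02
    track_lifetime_mean: float = 20.0
    oligomer_dist: np.ndarray | None = None
    label_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)
    monomer_intensity: tuple[MonomerIntensityModel, MonomerIntensityModel] = field(
        default_factory=lambda: (
            MonomerIntensityModel(mean=890.0),
            MonomerIntensityModel(mean=720.0),
        )
    )
    cell_area: float = 400.0
    n_particles: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if any(d < 0 for d in self.D):
            raise ValueError("diffusion coefficients must be >= 0")
        if self.loc_sigma < 0:
            raise ValueError("loc_sigma must be >= 0")
        K = len(self.D)
        if self.rate_matrix is None:
            # default: uniform off-diagonal 1/s (exit rate K-1 per second)
            Q = np.ones((K, K)) - K * np.eye(K)
            self.rate_matrix = Q
        self.rate_matrix = np.asarray(self.rate_matrix, float)
        Q = self.rate_matrix
        if Q.shape != (K, K):
            raise ValueError("rate_matrix shape must match number of states")
        off = Q[~np.eye(K, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("rate_matrix off-diagonals must be >= 0")
        # normalize the diagonal so rows sum to zero
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        if len(self.confinement_side) != K:
            raise ValueError("confinement_side length must match number of states")
        if self.oligomer_dist is None:
            self.oligomer_dist = default_oligomer_dist(K)
        self.oligomer_dist = np.asarray(self.oligomer_dist, float)
        if self.oligomer_dist.shape[0] != K:
            raise ValueError("oligomer_dist must have one row per state")
        sums = self.oligomer_dist.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("each oligomer_dist row must sum to 1")
        if not np.isclose(sum(self.label_probs), 1.0, atol=1e-9):
            raise ValueError("label_probs must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.D)

    @property
    def n_max(self) -> int:
        return self.oligomer_dist.shape[1]

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


def default_oligomer_dist(K: int, n_max: int = 8) -> np.ndarray:
    """State-dependent oligomer-size distributions.

    Modes follow the observed per-state intensity peaks: the fast state is
    dominated by apparent dimers, the medium state by trimers, and the
    immobile state by tetramers and higher-order oligomers, with the slowest
    state carrying the largest high-order fraction.
    """
    table = {
        # size:        1     2     3     4     5     6     7     8
        "immobile": [0.05, 0.10, 0.20, 0.35, 0.15, 0.08, 0.05, 0.02],
        "medium": [0.10, 0.25, 0.35, 0.20, 0.06, 0.03, 0.01, 0.00],
        "fast": [0.25, 0.45, 0.20, 0.08, 0.02, 0.00, 0.00, 0.00],
    }
    if K == 3:
        rows = [table["immobile"], table["medium"], table["fast"]]
    else:
        rows = [table["medium"]] * K
    out = np.array(rows, float)[:, :n_max]
    return out / out.sum(axis=1, keepdims=True)


def three_state_preset(seed: int = 0, **overrides) -> SimulationParams:
    """Three-state membrane-channel preset.

    Diffusion coefficients sit in the middle of the immobile / medium / fast
    ranges (0.008, 0.05, 0.25 μm²/s); the immobile state is confined to a
    0.15 μm square domain; dwell times are subsecond (exit rate 2 s⁻¹).
    """
    return SimulationParams(seed=seed, **overrides)


def removal_preset(kind: str) -> np.ndarray:
    """Per-time-point per-state removal probabilities for 5-min time lapse.

    Time points (0, 5, 10, 15, 20 min); removal applies between consecutive
    points. ``"fast-endocytosis"`` removes immobile+medium particles from
    5 min on (TRPV4-like kinetics); ``"slow-endocytosis"`` starts at 10 min
    (TRPV1-like); ``"vehicle"`` removes nothing.
    """
    # rows: time points after baseline; columns: states (immobile, medium, fast)
    presets = {
        "vehicle": np.zeros((4, 3)),
        "fast-endocytosis": np.array(
            [[0.35, 0.25, 0.0], [0.25, 0.15, 0.0], [0.15, 0.10, 0.0], [0.10, 0.05, 0.0]]
        ),
        "slow-endocytosis": np.array(
            [[0.0, 0.0, 0.0], [0.30, 0.20, 0.0], [0.20, 0.12, 0.0], [0.12, 0.08, 0.0]]
        ),
    }
    if kind not in presets:
        raise KeyError(f"unknown removal preset {kind!r}; options: {sorted(presets)}")
    return presets[kind]
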
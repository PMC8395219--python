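"""Variational-Bayes HMM clustering of trajectory steps into diffusion states.

Model
-----
Each trajectory step (2-D displacement over one frame interval) is emitted
from one of K hidden diffusion states. Given state k, the displacement is
zero-mean isotropic Gaussian with per-axis variance ``2·D_k·dt``; writing
``λ_k`` for the per-axis precision,

    p(Δx, Δy | z = k) = (λ_k / 2π) · exp(−λ_k (Δx² + Δy²) / 2),
    D_k = 1 / (2·λ_k·dt).

States follow a first-order Markov chain with initial distribution π and
per-frame transition matrix A. Conjugate priors: Dirichlet(1) on π and each
row of A; Gamma(a0 = 2, b0 = 2·dt·D_prior) on each λ_k, where D_prior is
the overall mean-square step over 4·dt — weakly informative and scale-aware.

Inference is variational EM: the E-step runs forward–backward with
exponentiated expected log-parameters (Ẽ[ln π], Ẽ[ln A], Ẽ[ln λ], Ẽ[λ]); the
M-step updates the Dirichlet/Gamma hyperparameters from expected counts.
The evidence lower bound is the sum of forward-pass log-normalizers under
the tilde parameters minus the Dirichlet/Gamma KL divergences from the
prior; it is non-decreasing across iterations and is used for model
selection over K.

Localization noise inflates the apparent diffusion coefficient by
``σ_loc²/dt`` per state; estimates are reported apparent by default, with
an analytic post-hoc correction available (``VBHMMResult.D_corrected``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .trajectories import TrajectorySet

_LOG2PI = float(np.log(2 * np.pi))


@dataclass
class VBHMMPriors:
    """Hyperparameters of the conjugate priors."""

    alpha_pi: float = 1.0  # Dirichlet concentration on the initial distribution
    alpha_A: float = 1.0  # Dirichlet concentration on each transition row
    a0: float = 2.0  # Gamma shape on per-axis displacement precision
    b0: float | None = None  # Gamma rate; None -> 2*dt*D_prior from the data


@dataclass
class VBHMMResult:
    """Posterior summary of a K-state diffusion HMM fit.

    States are canonically ordered by ascending diffusion coefficient
    (state 0 = immobile). ``D_est`` is the posterior-mean apparent
    diffusion coefficient per state, μm²/s; ``A`` the posterior-mean
    per-frame transition matrix; ``responsibilities`` the per-step posterior
    state probabilities aligned with ``steps``; ``viterbi_states`` the MAP
    state path per step.
    """

    K: int
    dt: float
    D_est: np.ndarray
    A: np.ndarray
    pi: np.ndarray
    state_fractions: np.ndarray
    lower_bound: float
    responsibilities: np.ndarray
    viterbi_states: np.ndarray
    steps: pd.DataFrame
    converged: bool
    n_iter: int
    elbo_history: list[float] = field(default_factory=list)
    # posterior hyperparameters (canonical state order)
    post_a: np.ndarray | None = None
    post_b: np.ndarray | None = None

    def D_corrected(self, loc_sigma: float) -> np.ndarray:
        """Subtract the localization-noise bias ``σ_loc²/dt`` from each D."""
        return self.D_est - loc_sigma**2 / self.dt

    def mean_dwell_times(self) -> np.ndarray:
        """Mean dwell time per state, s, from the exit rates."""
        rates = transition_rates(self, self.dt)
        return 1.0 / np.abs(np.diag(rates))

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "dt": self.dt,
            "D_est": self.D_est.tolist(),
            "A": self.A.tolist(),
            "pi": self.pi.tolist(),
            "state_fractions": self.state_fractions.tolist(),
            "lower_bound": self.lower_bound,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


# ----------------------------------------------------------------------
# forward-backward (single sequence, reference implementation)
# ----------------------------------------------------------------------
def forward_backward(
    log_pi: np.ndarray, log_A: np.ndarray, log_emission: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward–backward for one sequence.

    Parameters are (possibly unnormalized) log initial weights, log
    transition weights and a (T, K) log-emission matrix. Returns the
    per-step posterior ``gamma`` (T, K), the summed two-slice posterior
    ``xi_sum`` (K, K), and the log normalizer (the sequence's contribution
    to the evidence lower bound when tilde parameters are supplied).
    """
    T, K = log_emission.shape
    pi_w = np.exp(log_pi)
    A_w = np.exp(log_A)
    # shift emissions per step for numerical safety
    m = log_emission.max(axis=1)
    E = np.exp(log_emission - m[:, None])

    alpha = np.zeros((T, K))
    logc = np.zeros(T)
    a = pi_w * E[0]
    c = a.sum()
    alpha[0] = a / c
    logc[0] = np.log(c) + m[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A_w) * E[t]
        c = a.sum()
        alpha[t] = a / c
        logc[t] = np.log(c) + m[t]

    beta = np.ones((T, K))
    for t in range(T - 2, -1, -1):
        b = A_w @ (E[t + 1] * beta[t + 1])
        beta[t] = b / np.exp(logc[t + 1] - m[t + 1])

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = (
            alpha[t][:, None]
            * A_w
            * (E[t + 1] * beta[t + 1])[None, :]
            / np.exp(logc[t + 1] - m[t + 1])
        )
        xi_sum += xi / xi.sum()
    loglik = float(logc.sum())
    return gamma, xi_sum, loglik


# ----------------------------------------------------------------------
# batched E-step over padded track arrays
# ----------------------------------------------------------------------
def _batched_estep(
    r2: np.ndarray,
    lengths: np.ndarray,
    log_pi: np.ndarray,
    log_A: np.ndarray,
    e_lam: np.ndarray,
    e_loglam: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Forward–backward over all tracks at once.

    ``r2`` is (N, Tmax) padded squared step lengths; ``lengths`` the true
    step counts. Returns gamma (N, Tmax, K), summed xi (K, K), summed
    initial-step gamma (K,), and the total log normalizer.
    """
    N, Tmax = r2.shape
    K = log_pi.shape[0]
    logE = e_loglam[None, None, :] - _LOG2PI - 0.5 * e_lam[None, None, :] * r2[..., None]
    m = logE.max(axis=2)
    E = np.exp(logE - m[..., None])  # (N, Tmax, K)
    mask = np.arange(Tmax)[None, :] < lengths[:, None]

    A_w = np.exp(log_A)
    pi_w = np.exp(log_pi)

    alpha = np.zeros((N, Tmax, K))
    logc = np.zeros((N, Tmax))
    a = pi_w[None, :] * E[:, 0]
    c = a.sum(axis=1)
    alpha[:, 0] = a / c[:, None]
    logc[:, 0] = np.log(c) + m[:, 0]
    for t in range(1, Tmax):
        act = mask[:, t]
        a = (alpha[:, t - 1] @ A_w) * E[:, t]
        c = a.sum(axis=1)
        c = np.where(c > 0, c, 1.0)
        alpha[:, t] = np.where(act[:, None], a / c[:, None], alpha[:, t - 1])
        logc[:, t] = np.where(act, np.log(c) + m[:, t], 0.0)

    beta = np.ones((N, Tmax, K))
    for t in range(Tmax - 2, -1, -1):
        nxt = mask[:, t + 1]
        b = (E[:, t + 1] * beta[:, t + 1]) @ A_w.T
        scale = np.exp(logc[:, t + 1] - m[:, t + 1])
        beta[:, t] = np.where(nxt[:, None], b / scale[:, None], 1.0)

    gamma = alpha * beta
    gs = gamma.sum(axis=2, keepdims=True)
    gamma = np.where(mask[..., None], gamma / np.where(gs > 0, gs, 1.0), 0.0)

    xi_sum = np.zeros((K, K))
    for t in range(Tmax - 1):
        nxt = mask[:, t + 1]
        if not nxt.any():
            break
        contrib = (
            alpha[:, t][:, :, None]
            * A_w[None, :, :]
            * (E[:, t + 1] * beta[:, t + 1])[:, None, :]
        )
        norm = contrib.sum(axis=(1, 2))
        norm = np.where(norm > 0, norm, 1.0)
        contrib = contrib / norm[:, None, None]
        xi_sum += np.einsum("nij,n->ij", contrib, nxt.astype(float))
    gamma0 = gamma[:, 0].sum(axis=0)
    loglik = float(np.where(mask, logc, 0.0).sum())
    return gamma, xi_sum, gamma0, loglik


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL( Dir(alpha) || Dir(alpha0) )."""
    a, a0 = np.asarray(alpha, float), np.asarray(alpha0, float)
    sa, sa0 = a.sum(), a0.sum()
    return float(
        gammaln(sa)
        - gammaln(sa0)
        - np.sum(gammaln(a) - gammaln(a0))
        + np.sum((a - a0) * (digamma(a) - digamma(sa)))
    )


def _gamma_kl(a: float, b: float, a0: float, b0: float) -> float:
    """KL( Gamma(a, b) || Gamma(a0, b0) ), rate parameterization."""
    return float(
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
def _prepare_steps(traj: TrajectorySet, min_steps: int) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    steps = traj.steps(min_steps=min_steps)
    if steps.empty:
        raise ValueError("no usable steps (all tracks shorter than min_steps)")
    r2 = (steps["dx"] ** 2 + steps["dy"] ** 2).to_numpy()
    track_ids = steps.groupby(["cell_id", "particle_id"], sort=True).ngroup().to_numpy()
    return steps, r2, track_ids


def _pad_tracks(r2: np.ndarray, track_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids = np.unique(track_ids)
    lengths = np.array([np.sum(track_ids == i) for i in ids])
    Tmax = lengths.max()
    padded = np.zeros((len(ids), Tmax))
    for row, i in enumerate(ids):
        v = r2[track_ids == i]
        padded[row, : len(v)] = v
    return padded, lengths


def fit_vbhmm(
    traj: TrajectorySet,
    K: int,
    priors: VBHMMPriors | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_steps: int = 5,
) -> VBHMMResult:
    """Fit a K-state diffusion HMM by variational Bayes.

    Tracks contributing fewer than ``min_steps`` steps are excluded from
    the fit (they can still be labeled afterwards with
    :func:`assign_states`). The best of ``n_restarts`` differently
    initialized runs by final lower bound is returned.
    """
    if priors is None:
        priors = VBHMMPriors()
    steps, r2_all, track_ids = _prepare_steps(traj, min_steps)
    n_steps = len(r2_all)
    if K > n_steps:
        raise ValueError(f"K={K} exceeds the number of steps ({n_steps})")
    if np.ptp(r2_all) == 0 and K > 1:
        raise ValueError("degenerate data: all steps identical")
    dt = traj.dt
    D_prior = float(np.mean(r2_all)) / (4 * dt)
    if D_prior <= 0:
        raise ValueError("degenerate data: zero mean-square step")
    b0 = priors.b0 if priors.b0 is not None else 2 * dt * D_prior
    a0 = priors.a0

    r2_pad, lengths = _pad_tracks(r2_all, track_ids)
    rng = np.random.default_rng(seed)

    best: dict | None = None
    for restart in range(n_restarts):
        # initialization: quantile split of step lengths into K groups,
        # jittered on restarts
        qs = np.linspace(0, 1, K + 1)[1:-1]
        if restart > 0:
            qs = np.clip(qs + rng.uniform(-0.5, 0.5, size=qs.shape) / K, 0.02, 0.98)
            qs = np.sort(qs)
        edges = np.quantile(r2_all, qs) if K > 1 else np.array([])
        hard = np.searchsorted(edges, r2_all)
        gamma_flat = np.full((n_steps, K), 0.05 / max(K - 1, 1))
        gamma_flat[np.arange(n_steps), hard] = 0.95
        # initial M-step statistics from the flat (unpadded) assignment
        Nk = gamma_flat.sum(axis=0)
        Sk = gamma_flat.T @ r2_all
        a_post = a0 + Nk
        b_post = b0 + Sk / 2
        alpha_pi = np.full(K, priors.alpha_pi) + Nk / max(Nk.sum(), 1)
        alpha_A = np.full((K, K), priors.alpha_A) + np.diag(Nk) * 0.1

        elbo_hist: list[float] = []
        converged = False
        for it in range(max_iter):
            # expected parameters
            e_lam = a_post / b_post
            e_loglam = digamma(a_post) - np.log(b_post)
            log_pi = digamma(alpha_pi) - digamma(alpha_pi.sum())
            log_A = digamma(alpha_A) - digamma(alpha_A.sum(axis=1, keepdims=True))

            gamma, xi_sum, gamma0, loglik = _batched_estep(
                r2_pad, lengths, log_pi, log_A, e_lam, e_loglam
            )
            elbo = (
                loglik
                - _dirichlet_kl(alpha_pi, np.full(K, priors.alpha_pi))
                - sum(
                    _dirichlet_kl(alpha_A[j], np.full(K, priors.alpha_A))
                    for j in range(K)
                )
                - sum(_gamma_kl(a_post[j], b_post[j], a0, b0) for j in range(K))
            )
            elbo_hist.append(elbo)
            if it > 0 and abs(elbo - elbo_hist[-2]) < tol * abs(elbo_hist[-2]):
                converged = True
                break

            # M-step
            mask = np.arange(r2_pad.shape[1])[None, :] < lengths[:, None]
            Nk = gamma.sum(axis=(0, 1))
            Sk = np.einsum("ntk,nt->k", gamma, np.where(mask, r2_pad, 0.0))
            a_post = a0 + Nk
            b_post = b0 + Sk / 2
            alpha_pi = np.full(K, priors.alpha_pi) + gamma0
            alpha_A = np.full((K, K), priors.alpha_A) + xi_sum

        if best is None or elbo_hist[-1] > best["elbo"]:
            best = {
                "elbo": elbo_hist[-1],
                "elbo_hist": elbo_hist,
                "a": a_post,
                "b": b_post,
                "alpha_pi": alpha_pi,
                "alpha_A": alpha_A,
                "gamma": gamma,
                "converged": converged,
                "n_iter": len(elbo_hist),
            }

    return _finalize(best, steps, r2_pad, lengths, track_ids, dt, K)


def _finalize(
    best: dict,
    steps: pd.DataFrame,
    r2_pad: np.ndarray,
    lengths: np.ndarray,
    track_ids: np.ndarray,
    dt: float,
    K: int,
) -> VBHMMResult:
    a_post, b_post = best["a"], best["b"]
    # posterior mean of D = E[1/(2 dt λ)] = b / (2 dt (a-1))
    D_est = b_post / (2 * dt * np.maximum(a_post - 1, 1e-9))
    order = np.argsort(D_est)
    D_est = D_est[order]
    alpha_pi = best["alpha_pi"][order]
    alpha_A = best["alpha_A"][np.ix_(order, order)]
    a_post, b_post = a_post[order], b_post[order]
    A_mean = alpha_A / alpha_A.sum(axis=1, keepdims=True)
    pi_mean = alpha_pi / alpha_pi.sum()
    gamma = best["gamma"][..., order]

    # flatten padded gamma back to step order
    mask = np.arange(r2_pad.shape[1])[None, :] < lengths[:, None]
    resp = gamma[mask]
    state_fractions = resp.mean(axis=0)

    viterbi = _viterbi_all(r2_pad, lengths, pi_mean, A_mean, a_post, b_post)
    return VBHMMResult(
        K=K,
        dt=dt,
        D_est=D_est,
        A=A_mean,
        pi=pi_mean,
        state_fractions=state_fractions,
        lower_bound=best["elbo"],
        responsibilities=resp,
        viterbi_states=viterbi,
        steps=steps,
        converged=best["converged"],
        n_iter=best["n_iter"],
        elbo_history=best["elbo_hist"],
        post_a=a_post,
        post_b=b_post,
    )


def _viterbi_all(
    r2_pad: np.ndarray,
    lengths: np.ndarray,
    pi: np.ndarray,
    A: np.ndarray,
    a_post: np.ndarray,
    b_post: np.ndarray,
) -> np.ndarray:
    """MAP state path per track using posterior-mean parameters."""
    lam = a_post / b_post
    logE_full = (
        np.log(lam)[None, None, :] - _LOG2PI - 0.5 * lam[None, None, :] * r2_pad[..., None]
    )
    log_pi = np.log(pi)
    log_A = np.log(A)
    out = []
    for n, L in enumerate(lengths):
        logE = logE_full[n, :L]
        T, K = logE.shape
        delta = np.zeros((T, K))
        back = np.zeros((T, K), int)
        delta[0] = log_pi + logE[0]
        for t in range(1, T):
            scores = delta[t - 1][:, None] + log_A
            back[t] = scores.argmax(axis=0)
            delta[t] = scores.max(axis=0) + logE[t]
        path = np.zeros(T, int)
        path[-1] = delta[-1].argmax()
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        out.append(path)
    return np.concatenate(out)


# ----------------------------------------------------------------------
# model selection and derived quantities
# ----------------------------------------------------------------------
def select_model(
    traj: TrajectorySet,
    K_range: range | list[int] = range(1, 6),
    **fit_kwargs,
) -> tuple[int, dict[int, VBHMMResult]]:
    """Fit each K in ``K_range``; return the K with the highest lower bound
    and the full per-K table (mirrors per-cell model comparison)."""
    K_list = list(K_range)
    if not K_list:
        raise ValueError("K_range must be non-empty")
    results = {K: fit_vbhmm(traj, K, **fit_kwargs) for K in K_list}
    best_K = max(results, key=lambda K: results[K].lower_bound)
    return best_K, results


def transition_rates(result: VBHMMResult, dt: float) -> np.ndarray:
    """Continuous-time transition rate matrix, s⁻¹, from the per-frame A.

    Off-diagonal ``k_ij = A_ij / dt``; the diagonal is minus the row's
    off-diagonal sum. Mean dwell time per state is ``1/|k_ii|``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    A = np.asarray(result.A if isinstance(result, VBHMMResult) else result, float)
    rates = A / dt
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    return rates


def assign_states(traj: TrajectorySet, result: VBHMMResult) -> TrajectorySet:
    """Label every trajectory row with its Viterbi diffusion state.

    Step labels attach to the step's first frame; the final frame of each
    track inherits the preceding step's label. Tracks too short for fitting
    are decoded with the posterior-mean parameters. Labels apply to the
    particle, hence to both dye channels.
    """
    steps, r2_all, track_ids = _prepare_steps(traj, min_steps=1)
    r2_pad, lengths = _pad_tracks(r2_all, track_ids)
    vit = _viterbi_all(r2_pad, lengths, result.pi, result.A, result.post_a, result.post_b)
    lab = steps[["cell_id", "particle_id", "frame"]].copy()
    lab["state"] = vit
    data = traj.data.drop(columns=["state"], errors="ignore").merge(
        lab, on=["cell_id", "particle_id", "frame"], how="left"
    )
    # last frame of each track inherits the previous step's state
    data = data.sort_values(["cell_id", "particle_id", "frame"])
    data["state"] = (
        data.groupby(["cell_id", "particle_id"])["state"].ffill().to_numpy()
    )
    if data["state"].isna().any():
        # single-frame tracks: fall back to the most occupied state
        data["state"] = data["state"].fillna(int(np.argmax(result.state_fractions)))
    data["state"] = data["state"].astype(int)
    return TrajectorySet(
        data=data.reset_index(drop=True),
        dt=traj.dt,
        pixel_size_um=traj.pixel_size_um,
        cell_area_um2=traj.cell_area_um2,
    )
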
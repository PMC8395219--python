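"""MSD analysis: curves, linear and confined fits, densities, histograms.

The time-and-ensemble-averaged MSD uses overlapping time origins: for lag
``n·dt`` every pair of points ``(t, t+n)`` within a track contributes
``|r(t+n) − r(t)|²``. For simple 2-D diffusion the curve is linear with
slope 4D (plus a ``4σ_loc²`` intercept from localization noise); for
diffusion confined in a square domain of side L it saturates at
``L²/3 + 4σ_loc²``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trajectories import TrajectorySet


@dataclass
class MSDCurve:
    """Time-and-ensemble-averaged MSD vs lag with per-lag uncertainty."""

    lags: np.ndarray  # s, strictly increasing, excludes lag 0
    msd: np.ndarray  # μm²
    sem: np.ndarray  # μm², across cells (or tracks if one cell)
    n_pairs: np.ndarray  # displacement pairs per lag

    def mean_msd(self, n_lags: int | None = None) -> float:
        """Time-averaged MSD over the first ``n_lags`` lags (all if None)."""
        sl = slice(None) if n_lags is None else slice(n_lags)
        return float(np.mean(self.msd[sl]))


@dataclass
class ConfinedFit:
    """Confined-diffusion fit MSD(t) = (L²/3)(1 − exp(−t/τ)) + offset."""

    L: float  # μm, confinement side length
    D_micro: float  # μm²/s, short-time diffusion coefficient L²/(12 τ)
    offset: float  # μm², localization-noise plateau (≈ 4σ_loc²)
    tau: float  # s
    plateau: float  # μm², fitted L²/3 + offset
    censored: bool  # True when τ exceeds the data range (no real plateau)


@dataclass
class StateDensityTimecourse:
    """Per-state particle densities and fractions across time points."""

    time_points: np.ndarray  # min
    density: np.ndarray  # (T, K) particles/μm²
    fractions: np.ndarray  # (T, K), rows sum to 1


# ----------------------------------------------------------------------
# MSD
# ----------------------------------------------------------------------
def compute_msd(
    traj: TrajectorySet,
    max_lag: int = 30,
    state: int | None = None,
) -> MSDCurve:
    """Time-and-ensemble-averaged MSD with overlapping origins.

    With a ``state`` given, only track segments whose every intervening
    frame carries that state label contribute (tracks are cut at state
    switches). SEM is computed across cells when several cell ids are
    present, otherwise across tracks.
    """
    df = traj.data
    if state is not None:
        if "state" not in df.columns:
            raise ValueError("state labels required for per-state MSD")
        df = df[df["state"] == state]
    longest = 0
    per_track: list[tuple[int, np.ndarray]] = []  # (cell_id, per-lag mean sq disp)
    for (cell, _pid), g in df.groupby(["cell_id", "particle_id"], sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        # split at frame gaps so lags never span missing frames
        breaks = np.where(np.diff(frames) != 1)[0] + 1
        for seg in np.split(np.arange(len(frames)), breaks):
            if len(seg) < 2:
                continue
            x = g["x_um"].to_numpy()[seg]
            y = g["y_um"].to_numpy()[seg]
            T = len(x)
            longest = max(longest, T - 1)
            vals = np.full(min(max_lag, T - 1), np.nan)
            for n in range(1, min(max_lag, T - 1) + 1):
                d2 = (x[n:] - x[:-n]) ** 2 + (y[n:] - y[:-n]) ** 2
                vals[n - 1] = d2.mean()
            per_track.append((cell, vals))
    if not per_track:
        raise ValueError("no track with >= 2 points")
    if max_lag > longest:
        warnings.warn(
            f"max_lag {max_lag} exceeds longest track ({longest}); curve truncated"
        )
        max_lag = longest
    # stack per-track curves (ragged -> NaN padded)
    arr = np.full((len(per_track), max_lag), np.nan)
    cells = np.array([c for c, _ in per_track])
    for i, (_, v) in enumerate(per_track):
        arr[i, : len(v)] = v[:max_lag]
    n_pairs = np.sum(~np.isnan(arr), axis=0)
    msd = np.nanmean(arr, axis=0)
    unique_cells = np.unique(cells)
    if len(unique_cells) > 1:
        cell_means = np.stack(
            [np.nanmean(arr[cells == c], axis=0) for c in unique_cells]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sem = np.nanstd(cell_means, axis=0, ddof=1) / np.sqrt(
                np.sum(~np.isnan(cell_means), axis=0)
            )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n_pairs, 1))
    lags = traj.dt * np.arange(1, max_lag + 1)
    return MSDCurve(lags=lags, msd=msd, sem=sem, n_pairs=n_pairs)


def fit_msd_linear(curve: MSDCurve, n_fit_points: int = 4) -> tuple[float, float]:
    """Weighted linear fit ``msd = 4·D·lag + offset`` over the first lags.

    Returns ``(D, offset)``; the offset estimates ``4σ_loc²``. A negative D
    is reported as-is with a warning (small-sample noise).
    """
    n = min(n_fit_points, len(curve.lags))
    if n < 2:
        raise ValueError("need at least 2 fit points")
    x = curve.lags[:n]
    y = curve.msd[:n]
    w = np.ones(n)
    sem = curve.sem[:n]
    if np.all(np.isfinite(sem)) and np.all(sem > 0):
        w = 1.0 / sem**2
    W = np.diag(w)
    X = np.column_stack([x, np.ones(n)])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    D = beta[0] / 4.0
    if D < 0:
        warnings.warn(f"negative fitted D ({D:.3g} μm²/s): small-sample noise")
    return float(D), float(beta[1])


def fit_msd_confined(curve: MSDCurve, n_fit_points: int = 15) -> ConfinedFit:
    """Fit the confined-diffusion model MSD(t) = (L²/3)(1 − e^{−t/τ}) + offset.

    τ relates to the short-time diffusion coefficient via
    ``τ = L²/(12·D_micro)``. When the fitted τ exceeds the fitted lag range
    the curve shows no plateau and the fit is flagged ``censored``
    (L unreliable).
    """
    n = min(n_fit_points, len(curve.lags))
    if n < 6:
        raise ValueError("confined fit needs >= 6 lags")
    t = curve.lags[:n]
    y = curve.msd[:n]

    plateau0 = float(y[-1])
    tau0 = float(t[len(t) // 3])
    off0 = max(float(y[0] - (y[1] - y[0])), 0.0)

    def model(t, L2_3, tau, off):
        return L2_3 * (1 - np.exp(-t / tau)) + off

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=[max(plateau0 - off0, 1e-6), tau0, off0],
            bounds=([1e-9, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"confined fit did not converge (initial guesses plateau={plateau0:.3g},"
            f" tau={tau0:.3g}, offset={off0:.3g})"
        ) from exc
    L2_3, tau, off = popt
    L = float(np.sqrt(3 * L2_3))
    D_micro = L**2 / (12 * tau)
    return ConfinedFit(
        L=L,
        D_micro=float(D_micro),
        offset=float(off),
        tau=float(tau),
        plateau=float(L2_3 + off),
        censored=bool(tau > t[-1]),
    )


# ----------------------------------------------------------------------
# step-size histograms
# ----------------------------------------------------------------------
def step_histogram(
    traj: TrajectorySet,
    state: int,
    D_est: float | None = None,
    bins: int = 50,
    r_max: float | None = None,
) -> pd.DataFrame:
    """Per-state histogram of step lengths with a theoretical overlay.

    The overlay is the 2-D Gaussian step-length density
    ``p(r) = (r / (2·D·dt)) · exp(−r² / (4·D·dt))`` evaluated with the
    state's estimated D (apparent, i.e. including localization noise).
    """
    if "state" not in traj.data.columns:
        raise ValueError("state labels required")
    steps = traj.steps()
    lab = traj.data[["cell_id", "particle_id", "frame", "state"]]
    steps = steps.merge(lab, on=["cell_id", "particle_id", "frame"], how="left")
    r = np.sqrt(steps.loc[steps["state"] == state, "dx"] ** 2 +
                steps.loc[steps["state"] == state, "dy"] ** 2).to_numpy()
    if len(r) == 0:
        return pd.DataFrame(columns=["r", "count", "density", "theory"])
    if r_max is None:
        r_max = float(r.max()) * 1.05 if r.max() > 0 else 1e-3
    counts, edges = np.histogram(r, bins=bins, range=(0, r_max))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    density = counts / (counts.sum() * width)
    theory = np.zeros_like(centers)
    if D_est is not None and D_est > 0:
        s2 = 2 * D_est * traj.dt
        theory = (centers / s2) * np.exp(-(centers**2) / (2 * s2))
    return pd.DataFrame(
        {"r": centers, "count": counts, "density": density, "theory": theory}
    )


# ----------------------------------------------------------------------
# densities and correlations
# ----------------------------------------------------------------------
def density_timecourse(
    timelapse: list[TrajectorySet],
    cell_area: float,
    time_points: np.ndarray | None = None,
    state_column: str = "state",
    n_states: int | None = None,
) -> StateDensityTimecourse:
    """Per-state particle density and fractions at each time point.

    Density of state k = (mean number of state-k particles per frame) /
    cell area. Fractions normalize densities per time point.
    """
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    if time_points is None:
        time_points = np.arange(len(timelapse)) * 5.0
    Ks = []
    for ts in timelapse:
        if state_column not in ts.data.columns:
            raise ValueError(f"missing state column {state_column!r}")
        if len(ts.data):
            Ks.append(int(ts.data[state_column].max()) + 1)
    K = n_states if n_states is not None else (max(Ks) if Ks else 1)
    dens = np.zeros((len(timelapse), K))
    for t, ts in enumerate(timelapse):
        n_frames = ts.n_frames
        if n_frames == 0:
            continue
        counts = ts.data.groupby(state_column).size()
        for k in range(K):
            dens[t, k] = counts.get(k, 0) / n_frames / cell_area
    totals = dens.sum(axis=1, keepdims=True)
    frac = np.full_like(dens, np.nan)
    ok = totals[:, 0] > 0
    frac[ok] = dens[ok] / totals[ok]
    if not ok.all():
        warnings.warn("zero total particles at some time points; fractions undefined")
    return StateDensityTimecourse(
        time_points=np.asarray(time_points, float), density=dens, fractions=frac
    )


def correlate_density_msd(
    density: np.ndarray, msd: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of total density vs time-averaged MSD.

    Returns ``(R, p)``. Inputs must have ≥3 time points and be
    non-constant.
    """
    density = np.asarray(density, float)
    msd = np.asarray(msd, float)
    if len(density) < 3 or len(density) != len(msd):
        raise ValueError("need >= 3 paired time points")
    if np.ptp(density) == 0 or np.ptp(msd) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(density, msd)
    return float(r), float(p)
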
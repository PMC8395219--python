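"""Two-color colocalization events and association kinetics.

A colocalization event is a pair of particles from different color
channels found within a distance threshold (200 nm default) in the same
frame *and* the same diffusion state, merged over consecutive frames.
From the event set derive: the colocalized particle fraction, the on-rate
constant ``k_on = V0 / ([Ch1]·[Ch2])`` where V0 is the initial rate of the
cumulative number of association events per unit area, and the on-time
survival with an exponential fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .trajectories import TrajectorySet


@dataclass
class ColocalizationEvent:
    id_ch1: int
    id_ch2: int
    start_frame: int
    end_frame: int
    duration: float  # s, (end - start + 1) * dt
    state: int  # diffusion state at event start
    mean_separation: float  # μm
    censored: bool = False  # True when the event runs to a track end


@dataclass
class OnRateEstimate:
    V0: float  # association events per μm² per s
    density_ch1: float  # particles/μm²
    density_ch2: float
    k_on: float  # μm²·s⁻¹, V0/(density_ch1*density_ch2)


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------
def _frame_pairs(
    f1: pd.DataFrame, f2: pd.DataFrame, radius: float
) -> list[tuple[int, int, float, int]]:
    """Greedy one-to-one matching of same-state cross-channel pairs.

    Candidates are all pairs closer than ``radius`` with equal state
    labels; they are resolved in ascending separation, ties broken by
    ascending (id_ch1, id_ch2).
    """
    if f1.empty or f2.empty:
        return []
    p1 = f1[["x_um", "y_um"]].to_numpy()
    p2 = f2[["x_um", "y_um"]].to_numpy()
    d = np.sqrt(((p1[:, None, :] - p2[None, :, :]) ** 2).sum(-1))
    s1 = f1["state"].to_numpy()
    s2 = f2["state"].to_numpy()
    ok = (d < radius) & (s1[:, None] == s2[None, :])
    idx1, idx2 = np.nonzero(ok)
    if len(idx1) == 0:
        return []
    cand = sorted(
        zip(d[idx1, idx2], f1["particle_id"].to_numpy()[idx1], f2["particle_id"].to_numpy()[idx2], s1[idx1]),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used1: set[int] = set()
    used2: set[int] = set()
    out = []
    for dist, i1, i2, st in cand:
        if i1 in used1 or i2 in used2:
            continue
        used1.add(i1)
        used2.add(i2)
        out.append((int(i1), int(i2), float(dist), int(st)))
    return out


def detect_colocalization(
    traj_ch1: TrajectorySet,
    traj_ch2: TrajectorySet,
    radius: float = 0.2,
    max_gap: int = 0,
) -> list[ColocalizationEvent]:
    """Detect colocalization events between two state-labeled channels.

    Per frame, candidate pairs closer than ``radius`` with equal diffusion
    state are matched one-to-one greedily by ascending separation;
    consecutive-frame matches of the same id pair merge into one event
    (gaps up to ``max_gap`` frames tolerated). An event ending at the last
    observed frame of either member is right-censored.
    """
    if not np.isclose(traj_ch1.dt, traj_ch2.dt):
        raise ValueError("channels have mismatched dt")
    for ts in (traj_ch1, traj_ch2):
        if "state" not in ts.data.columns:
            raise ValueError("state labels required in both channels")
    dt = traj_ch1.dt
    frames = sorted(
        set(traj_ch1.data["frame"].unique()) | set(traj_ch2.data["frame"].unique())
    )
    g1 = dict(tuple(traj_ch1.data.groupby("frame")))
    g2 = dict(tuple(traj_ch2.data.groupby("frame")))
    # open events: (id1, id2) -> [start, last_frame, state, sum_sep, n]
    open_ev: dict[tuple[int, int], list] = {}
    events: list[ColocalizationEvent] = []
    last1 = traj_ch1.data.groupby("particle_id")["frame"].max().to_dict()
    last2 = traj_ch2.data.groupby("particle_id")["frame"].max().to_dict()

    def close(key, ev):
        i1, i2 = key
        cens = ev[1] >= min(last1.get(i1, -1), last2.get(i2, -1))
        events.append(
            ColocalizationEvent(
                id_ch1=i1,
                id_ch2=i2,
                start_frame=ev[0],
                end_frame=ev[1],
                duration=(ev[1] - ev[0] + 1) * dt,
                state=ev[2],
                mean_separation=ev[3] / ev[4],
                censored=bool(cens),
            )
        )

    for f in frames:
        pairs = _frame_pairs(
            g1.get(f, pd.DataFrame(columns=traj_ch1.data.columns)),
            g2.get(f, pd.DataFrame(columns=traj_ch2.data.columns)),
            radius,
        )
        seen = set()
        for i1, i2, dist, st in pairs:
            key = (i1, i2)
            seen.add(key)
            if key in open_ev and f - open_ev[key][1] <= max_gap + 1:
                ev = open_ev[key]
                ev[1] = f
                ev[3] += dist
                ev[4] += 1
            else:
                if key in open_ev:
                    close(key, open_ev.pop(key))
                open_ev[key] = [f, f, st, dist, 1]
        stale = [k for k, ev in open_ev.items() if k not in seen and f - ev[1] > max_gap]
        for k in stale:
            close(k, open_ev.pop(k))
    for k, ev in list(open_ev.items()):
        close(k, ev)
    events.sort(key=lambda e: (e.start_frame, e.id_ch1, e.id_ch2))
    return events


def events_to_frame(events: list[ColocalizationEvent]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in events])


# ----------------------------------------------------------------------
# derived quantities
# ----------------------------------------------------------------------
def colocalized_fraction(
    events: list[ColocalizationEvent],
    traj_ch1: TrajectorySet,
    traj_ch2: TrajectorySet,
    per_state: bool = False,
) -> float | dict[int, float]:
    """Fraction of detected particles participating in ≥1 event per movie.

    Counts particles over both channels; a particle colocalized in any
    frame of the movie counts once. With ``per_state`` the denominator
    splits by each particle's modal state label.
    """
    n1 = traj_ch1.data["particle_id"].nunique()
    n2 = traj_ch2.data["particle_id"].nunique()
    total = n1 + n2
    if total == 0:
        raise ValueError("zero detected particles")
    in1 = {e.id_ch1 for e in events}
    in2 = {e.id_ch2 for e in events}
    if not per_state:
        return (len(in1) + len(in2)) / total
    out: dict[int, float] = {}
    modal1 = traj_ch1.data.groupby("particle_id")["state"].agg(
        lambda s: s.mode().iloc[0]
    )
    modal2 = traj_ch2.data.groupby("particle_id")["state"].agg(
        lambda s: s.mode().iloc[0]
    )
    states = sorted(set(modal1.unique()) | set(modal2.unique()))
    for st in states:
        ids1 = set(modal1[modal1 == st].index)
        ids2 = set(modal2[modal2 == st].index)
        denom = len(ids1) + len(ids2)
        if denom == 0:
            continue
        out[int(st)] = (len(ids1 & in1) + len(ids2 & in2)) / denom
    return out


def on_rate(
    events: list[ColocalizationEvent],
    density_ch1: float,
    density_ch2: float,
    cell_area: float,
    dt: float,
    n_frames: int,
    window: float | None = None,
) -> OnRateEstimate:
    """On-rate constant from the cumulative association-event count.

    The cumulative number of event *starts* per unit area vs time is fit by
    least squares over the initial ``window`` seconds (default: the first
    third of the movie); the slope is V0 and
    ``k_on = V0 / (density_ch1 · density_ch2)``.
    """
    if density_ch1 <= 0 or density_ch2 <= 0:
        raise ValueError("channel densities must be positive")
    if window is None:
        window = n_frames * dt / 3.0
    if not events:
        return OnRateEstimate(0.0, density_ch1, density_ch2, 0.0)
    t = np.arange(n_frames) * dt
    starts = np.bincount(
        [e.start_frame for e in events], minlength=n_frames
    ).astype(float)
    cum = np.cumsum(starts) / cell_area
    sel = t <= window
    if sel.sum() < 2:
        sel = np.arange(n_frames) < 2
    # through-origin slope of cumulative count vs time
    V0 = float(np.sum(t[sel] * cum[sel]) / np.sum(t[sel] ** 2)) if np.any(t[sel] > 0) else 0.0
    k_on = V0 / (density_ch1 * density_ch2)
    return OnRateEstimate(V0=V0, density_ch1=density_ch1, density_ch2=density_ch2, k_on=k_on)


def on_time_survival(
    events: list[ColocalizationEvent], dt: float | None = None
) -> tuple[pd.DataFrame, float | None]:
    """On-time survival curve with right-censoring and exponential fit.

    Kaplan–Meier-style product-limit survival of event durations; events
    running to the end of a member track are censored. Returns the curve
    (columns ``time, survival``) and the fitted mean on-time (s), or None
    when all events are censored (fit skipped with a warning).
    """
    if len(events) < 10:
        raise ValueError("need >= 10 events for a survival estimate")
    durs = np.array([e.duration for e in events])
    cens = np.array([e.censored for e in events])
    order = np.argsort(durs)
    durs, cens = durs[order], cens[order]
    n = len(durs)
    times = [0.0]
    surv = [1.0]
    at_risk = n
    s = 1.0
    for t in np.unique(durs):
        d = np.sum((durs == t) & ~cens)
        c = np.sum((durs == t) & cens)
        if d > 0:
            s *= 1 - d / at_risk
            times.append(float(t))
            surv.append(float(s))
        at_risk -= d + c
    curve = pd.DataFrame({"time": times, "survival": surv})
    if cens.all():
        warnings.warn("all events censored: exponential fit skipped")
        return curve, None
    # exponential MLE with right-censoring: mean = total time / n_uncensored
    mean_on = float(durs.sum() / np.sum(~cens))
    return curve, mean_on
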
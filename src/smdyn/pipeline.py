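"""End-to-end pipeline driver on synthetic data.

``run_pipeline`` composes the stages: simulate a 5-min-interval time lapse
→ (optionally render movies and re-track them) → VB-HMM state clustering →
MSD/density analysis → oligomer decomposition → two-color colocalization →
machine-readable JSON summary. All randomness derives from a single root
seed through per-stage spawned seeds; a fixed seed gives a byte-identical
summary. The fully resolved configuration is written next to the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import coloc, diffusion, oligomer, vbhmm
from .params import SimulationParams, removal_preset
from .simulate import simulate_timelapse

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "preset": "fast-endocytosis",  # or "slow-endocytosis" / "vehicle"
    "n_particles": 150,
    "n_frames": 60,
    "time_points": [0.0, 5.0, 10.0, 15.0, 20.0],
    "hmm": {"K": 3, "n_restarts": 3, "min_steps": 5},
    "msd": {"max_lag": 10, "n_fit_points": 4},
    "oligomer": {"n_max": 8, "bins": 60},
    "coloc": {"radius": 0.2, "max_gap": 0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    return cfg


def _derived_seeds(root: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full synthetic analysis graph; return the summary dict.

    Stage failures abort with the failing stage named; outputs written up
    to that point are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.resolved.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    seeds = _derived_seeds(int(config["seed"]), 4)
    summary: dict = {"seed": config["seed"], "stages": {}}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        params = SimulationParams(
            seed=seeds[0],
            n_particles=int(config["n_particles"]),
            n_frames=int(config["n_frames"]),
        )
        removal = removal_preset(config["preset"])
        series = simulate_timelapse(
            params, removal, time_points=tuple(config["time_points"])
        )
        log.info("stage simulate: %.2fs", time.perf_counter() - t0)

        stage = "fit-hmm"
        t0 = time.perf_counter()
        base_traj, _ = series[0]
        hmm_cfg = config["hmm"]
        result = vbhmm.fit_vbhmm(
            base_traj,
            K=int(hmm_cfg["K"]),
            seed=seeds[1],
            n_restarts=int(hmm_cfg["n_restarts"]),
            min_steps=int(hmm_cfg["min_steps"]),
        )
        labeled = [
            vbhmm.assign_states(ts, result) for ts, _ in series
        ]
        rates = vbhmm.transition_rates(result, base_traj.dt)
        summary["stages"]["hmm"] = {
            "K": result.K,
            "D_est": np.round(result.D_est, 6).tolist(),
            "A": np.round(result.A, 5).tolist(),
            "state_fractions": np.round(result.state_fractions, 5).tolist(),
            "lower_bound": round(result.lower_bound, 3),
            "rates_per_s": np.round(rates, 4).tolist(),
            "mean_dwell_s": np.round(result.mean_dwell_times(), 4).tolist(),
        }
        log.info("stage fit-hmm: %.2fs", time.perf_counter() - t0)

        stage = "diffusion"
        t0 = time.perf_counter()
        msd_cfg = config["msd"]
        mean_msds = []
        for ts in labeled:
            curve = diffusion.compute_msd(ts, max_lag=int(msd_cfg["max_lag"]))
            mean_msds.append(round(curve.mean_msd(4), 6))
        tc = diffusion.density_timecourse(
            labeled,
            cell_area=params.cell_area,
            time_points=np.asarray(config["time_points"]),
            n_states=result.K,
        )
        corr = None
        total = tc.density.sum(axis=1)
        if np.ptp(total) > 0 and np.ptp(mean_msds) > 0:
            r, _p = diffusion.correlate_density_msd(total, np.array(mean_msds))
            corr = round(r, 4)
        summary["stages"]["diffusion"] = {
            "density": np.round(tc.density, 6).tolist(),
            "fractions": np.round(np.nan_to_num(tc.fractions), 5).tolist(),
            "mean_msd": mean_msds,
            "density_msd_pearson_r": corr,
        }
        log.info("stage diffusion: %.2fs", time.perf_counter() - t0)

        stage = "oligomer"
        t0 = time.perf_counter()
        olig_cfg = config["oligomer"]
        rng = np.random.default_rng(seeds[2])
        mono = params.monomer_intensity[0].draw(rng, 2000)
        cal = oligomer.calibrate_monomer(mono, dye="ch1")
        base = labeled[0]
        decomp_by_state = {}
        for k in range(result.K):
            vals = base.data.loc[
                (base.data["state"] == k) & (base.data["intensity_ch1"] > 0),
                "intensity_ch1",
            ].to_numpy()
            if len(vals) < 50:
                continue
            counts, edges = np.histogram(
                vals, bins=int(olig_cfg["bins"]), range=(0, 8 * cal.mean_intensity)
            )
            dec = oligomer.decompose_histogram(
                counts, edges, cal, n_max=int(olig_cfg["n_max"]),
                labeling=params.label_probs[0],
            )
            decomp_by_state[str(k)] = np.round(dec.weights, 4).tolist()
        summary["stages"]["oligomer"] = {
            "monomer_mean": round(cal.mean_intensity, 2),
            "weights_by_state": decomp_by_state,
        }
        log.info("stage oligomer: %.2fs", time.perf_counter() - t0)

        stage = "coloc"
        t0 = time.perf_counter()
        c_cfg = config["coloc"]
        kons = []
        fracs = []
        for ts in labeled:
            ch1 = ts.subset_channel(1)
            ch2 = ts.subset_channel(2)
            if ch1.data.empty or ch2.data.empty:
                kons.append(0.0)
                fracs.append(0.0)
                continue
            events = coloc.detect_colocalization(
                ch1, ch2, radius=float(c_cfg["radius"]), max_gap=int(c_cfg["max_gap"])
            )
            nf = ts.n_frames
            d1 = len(ch1.data) / nf / params.cell_area
            d2 = len(ch2.data) / nf / params.cell_area
            est = coloc.on_rate(
                events, d1, d2, params.cell_area, ts.dt, nf
            )
            kons.append(round(est.k_on, 4))
            fracs.append(round(coloc.colocalized_fraction(events, ch1, ch2), 4))
        summary["stages"]["coloc"] = {
            "k_on": kons,
            "colocalized_fraction": fracs,
        }
        log.info("stage coloc: %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
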
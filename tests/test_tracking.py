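"""Movie rendering, preprocessing, spot detection, and linking."""

import numpy as np
import pandas as pd
import pytest

from smdyn.params import SimulationParams
from smdyn.render import MovieStack, render_movie
from smdyn.simulate import simulate_trajectories
from smdyn.tracking import Spot, detect_spots, link_spots, preprocess, track_movie
from smdyn.trajectories import TrajectorySet

from conftest import make_traj

PX = 0.067


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------
def test_render_empty_background_poisson():
    ts = make_traj([], columns=["cell_id", "particle_id", "frame", "x_um", "y_um"])
    ts.data["frame"] = ts.data["frame"].astype(int) if len(ts.data) else ts.data.get("frame")
    mov = render_movie(
        TrajectorySet(
            pd.DataFrame({"cell_id": [0], "particle_id": [0], "frame": [0],
                          "x_um": [1.0], "y_um": [1.0], "intensity_ch1": [0.0]}),
            dt=0.0305,
        ),
        background=30.0, shape=(48, 48), rng=np.random.default_rng(2),
    )
    vals = mov.frames[0].astype(float)
    assert vals.mean() == pytest.approx(30.0, rel=0.05)
    assert vals.var() == pytest.approx(30.0, rel=0.15)  # Poisson mean=variance


def test_render_integrated_counts():
    ts = make_traj([(0, 0, 0, 1.5, 1.5)])
    ts.data["intensity_ch1"] = 2000.0
    mov = render_movie(
        ts, background=0.0, photon_scale=0.2, shape=(48, 48),
        rng=np.random.default_rng(3),
    )
    total = mov.frames[0].astype(float).sum()
    expected = 0.2 * 2000.0
    assert abs(total - expected) < 3 * np.sqrt(expected)


def test_render_subpixel_centroid():
    ts = make_traj([(0, 0, 0, 20.3 * PX, 41.7 * PX)])
    mov = render_movie(ts, background=0.0, photon_scale=2e4, noise=False, shape=(64, 64))
    img = mov.frames[0].astype(float)
    yy, xx = np.mgrid[0:64, 0:64]
    assert (img * xx).sum() / img.sum() == pytest.approx(20.3, abs=0.05)
    assert (img * yy).sum() / img.sum() == pytest.approx(41.7, abs=0.05)


def test_movie_tiff_metadata_roundtrip(tmp_path):
    ts = make_traj([(0, 0, 0, 1.0, 1.0)])
    mov = render_movie(ts, shape=(32, 32))
    path = tmp_path / "movie.tif"
    mov.to_tiff(path)
    back = MovieStack.from_tiff(path)
    assert back.pixel_size_um == pytest.approx(mov.pixel_size_um)
    assert back.dt == pytest.approx(mov.dt)
    np.testing.assert_array_equal(back.frames, mov.frames)


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------
def test_flat_field_removed():
    stack = np.full((3, 40, 40), 100.0)
    out = preprocess(stack, rolling_ball_radius=25, two_frame_average=True)
    assert out.shape[0] == 2
    assert np.allclose(out, 0.0, atol=1e-6)


def test_static_spot_intensity_preserved():
    ts = make_traj([(0, 0, f, 1.3, 1.3) for f in range(3)])
    ts.data["intensity_ch1"] = 4000.0
    mov = render_movie(ts, background=0.0, photon_scale=0.5, noise=False, shape=(40, 40))
    out = preprocess(mov.frames.astype(float), rolling_ball_radius=None)
    before = mov.frames[0].astype(float).sum()
    after = out[0].sum()
    assert after == pytest.approx(before, rel=0.05)


def test_single_frame_average_rejected():
    with pytest.raises(ValueError, match="2 frames"):
        preprocess(np.zeros((1, 16, 16)), rolling_ball_radius=None)


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------
def test_blank_frame_no_spots():
    rng = np.random.default_rng(5)
    frame = rng.poisson(20, (64, 64)).astype(float)
    assert detect_spots(frame - 20.0, snr_threshold=6) == []


def test_detection_subpixel_accuracy():
    """A rendered high-SNR spot at (20.3, 41.7) px is localized within 0.1 px."""
    ts = make_traj([(0, 0, 0, 20.3 * PX, 41.7 * PX)])
    ts.data["intensity_ch1"] = 20000.0
    mov = render_movie(
        ts, background=20.0, photon_scale=0.5, shape=(64, 64),
        rng=np.random.default_rng(6),
    )
    frame = mov.frames[0].astype(float) - 20.0
    spots = detect_spots(frame, snr_threshold=5)
    assert len(spots) == 1
    assert spots[0].x == pytest.approx(20.3, abs=0.1)
    assert spots[0].y == pytest.approx(41.7, abs=0.1)
    assert spots[0].intensity > 0


def test_two_spots_resolved():
    ts = make_traj([(0, 0, 0, 20.0 * PX, 20.0 * PX), (0, 1, 0, 30.0 * PX, 20.0 * PX)])
    ts.data["intensity_ch1"] = 20000.0
    mov = render_movie(
        ts, background=20.0, photon_scale=0.5, shape=(48, 48),
        rng=np.random.default_rng(7),
    )
    spots = detect_spots(mov.frames[0].astype(float) - 20.0, snr_threshold=5)
    assert len(spots) == 2


# ----------------------------------------------------------------------
# linking
# ----------------------------------------------------------------------
def _spot(f, x, y, inten=100.0):
    return Spot(frame=f, x=x, y=y, intensity=inten, fit_quality=0.01)


def test_link_two_frames_one_track():
    spots = [[_spot(0, 10.0, 10.0)], [_spot(1, 10.5, 10.0)]]
    ts = link_spots(spots, max_disp=0.45, pixel_size_um=PX)
    assert ts.n_particles == 1
    assert len(ts.data) == 2


def test_link_veto_beyond_max_disp():
    spots = [[_spot(0, 10.0, 10.0)], [_spot(1, 20.0, 10.0)]]  # 0.67 um jump
    ts = link_spots(spots, max_disp=0.45, pixel_size_um=PX)
    assert ts.n_particles == 2
    assert ts.data.groupby("particle_id").size().tolist() == [1, 1]


def test_link_two_static_particles_no_crossing():
    spots = [
        [_spot(f, 10.0, 10.0), _spot(f, 40.0, 40.0)] for f in range(10)
    ]
    ts = link_spots(spots, max_disp=0.45, pixel_size_um=PX)
    assert ts.n_particles == 2
    sizes = ts.data.groupby("particle_id").size()
    assert sizes.tolist() == [10, 10]
    # each track stays at one position
    for _, g in ts.data.groupby("particle_id"):
        assert g["x_um"].nunique() == 1


def test_link_gap_closing_interpolates():
    spots = [[_spot(0, 10.0, 10.0)], [], [_spot(2, 11.0, 10.0)]]
    ts = link_spots(spots, max_disp=0.45, max_gap=1, pixel_size_um=PX)
    assert ts.n_particles == 1
    g = ts.data.sort_values("frame")
    assert list(g["frame"]) == [0, 1, 2]
    assert g["inferred"].tolist() == [False, True, False]
    assert g["x_um"].iloc[1] == pytest.approx(10.5 * PX)


def test_linking_deterministic():
    rng = np.random.default_rng(9)
    spots = [
        [_spot(f, float(x), float(y)) for x, y in rng.uniform(5, 40, (8, 2))]
        for f in range(5)
    ]
    t1 = link_spots(spots, max_disp=0.45, pixel_size_um=PX)
    t2 = link_spots(spots, max_disp=0.45, pixel_size_um=PX)
    pd.testing.assert_frame_equal(t1.data, t2.data)


# ----------------------------------------------------------------------
# end-to-end ground-truth recovery
# ----------------------------------------------------------------------
def test_track_recovery_on_synthetic_movie():
    """At SNR >= 5 and low density, >= 90% of recovered steps match
    ground-truth particle identity."""
    field_px = 96
    area = (field_px * PX) ** 2  # ~41 um^2
    p = SimulationParams(
        D=(0.05,), rate_matrix=np.zeros((1, 1)), confinement_side=(0.5,),
        loc_sigma=0.0, n_particles=8, track_lifetime_mean=100, n_frames=15,
        cell_area=area, seed=10,
    )
    traj, gt = simulate_trajectories(p, random_birth=False)
    # keep clear of the field border
    traj.data[["x_um", "y_um"]] = 0.8 + traj.data[["x_um", "y_um"]] * 0.6
    traj.data["intensity_ch1"] = 20000.0
    mov = render_movie(
        traj, background=20.0, photon_scale=0.5, shape=(field_px, field_px),
        rng=np.random.default_rng(11),
    )
    out = track_movie(
        mov.frames, rolling_ball_radius=None, two_frame_average=False,
        snr_threshold=5, max_disp=0.45, pixel_size_um=PX, dt=p.dt,
    )
    # match each recovered step to the nearest true particle per frame
    true = traj.data.set_index("frame")
    good = total = 0
    for _, g in out.data.groupby("particle_id"):
        g = g.sort_values("frame")
        ids = []
        for _, row in g.iterrows():
            tf = true.loc[[row["frame"]]]
            d = np.hypot(tf["x_um"] - row["x_um"], tf["y_um"] - row["y_um"])
            ids.append(tf["particle_id"].to_numpy()[np.argmin(d.to_numpy())])
        ids = np.array(ids)
        total += len(ids) - 1
        good += int(np.sum(ids[1:] == ids[:-1]))
    assert total >= 50
    assert good / total >= 0.90
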
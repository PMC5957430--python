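"""V_KT / A_KT / D_KT closed forms, invariances and spindle estimation."""

import numpy as np
import pytest

import meiotrack as mt
from meiotrack.kinetics import (SpindleFrame, compute_akt, compute_dkt,
                                compute_vkt, estimate_spindle_axis)
from meiotrack.track import Track, TrackSet


def _track(positions, tid=0, gaps=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return Track(tid, np.arange(n), positions,
                 np.zeros(n, dtype=bool) if gaps is None
                 else np.asarray(gaps, dtype=bool))


def test_vkt_simple_displacement():
    tr = _track([[0, 0, 0], [1, 0, 0]])
    assert compute_vkt(tr, 10.0) == pytest.approx([0.1])


def test_vkt_stationary_is_zero():
    tr = _track([[1, 2, 3]] * 5)
    assert np.allclose(compute_vkt(tr, 10.0), 0.0)


def test_vkt_helical_track_matches_arc_speed():
    """Helix with known arc speed, recovered within discretization error."""
    dt, omega, r, vz = 10.0, 0.05, 2.0, 0.01
    t = np.arange(60) * dt
    pos = np.stack([r * np.cos(omega * t), r * np.sin(omega * t), vz * t],
                   axis=1)
    v = compute_vkt(_track(pos), dt)
    true_speed = np.hypot(r * omega, vz)
    # chord underestimates arc by ~ (omega*dt)^2/24
    assert np.allclose(v, true_speed, rtol=0.02)


def test_vkt_gap_samples_yield_nan():
    tr = _track([[0, 0, 0], [1, 0, 0], [2, 0, 0]], gaps=[False, True, False])
    v = compute_vkt(tr, 10.0)
    assert np.isnan(v).all()


def test_vkt_single_sample_rejected():
    with pytest.raises(ValueError, match="two samples"):
        compute_vkt(_track([[0, 0, 0]]), 10.0)


def test_vkt_scale_covariance():
    rng = np.random.default_rng(0)
    pos = rng.normal(size=(20, 3))
    v1 = compute_vkt(_track(pos), 10.0)
    v3 = compute_vkt(_track(3 * pos), 10.0)
    assert np.allclose(v3, 3 * v1)


@pytest.mark.parametrize("pair_vec, expected", [
    ((1, 0, 0), 0.0),
    ((0, 1, 0), 90.0),
    ((1, 1, 0), 45.0),
])
def test_akt_closed_forms(pair_vec, expected):
    sp = SpindleFrame(axis=np.array([1.0, 0.0, 0.0]))
    a = compute_akt(np.array([pair_vec], dtype=float),
                    np.zeros((1, 3)), sp)
    assert a[0] == pytest.approx(expected, abs=1e-9)


def test_akt_invariances():
    rng = np.random.default_rng(1)
    p1, p2 = rng.normal(size=(2, 6, 3))
    sp = SpindleFrame(axis=np.array([0.3, -0.5, 0.8]))
    sp_flip = SpindleFrame(axis=-sp.axis)
    a = compute_akt(p1, p2, sp)
    assert np.allclose(a, compute_akt(p2, p1, sp))
    assert np.allclose(a, compute_akt(p1, p2, sp_flip))
    assert np.all((a >= 0) & (a <= 90))


def test_akt_coincident_positions_nan():
    sp = SpindleFrame(axis=np.array([1.0, 0.0, 0.0]))
    assert np.isnan(compute_akt(np.ones((1, 3)), np.ones((1, 3)), sp)[0])


def test_dkt_closed_form_and_degenerate():
    assert compute_dkt(np.array([[0, 0, 0]]),
                       np.array([[3, 4, 0]]))[0] == pytest.approx(5.0)
    assert compute_dkt(np.ones((1, 3)), np.ones((1, 3)))[0] == 0.0


def test_dkt_rigid_transform_invariance():
    rng = np.random.default_rng(2)
    p1, p2 = rng.normal(size=(2, 10, 3))
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=3).as_matrix()
    shift = np.array([1.0, -2.0, 0.5])
    assert np.allclose(compute_dkt(p1, p2),
                       compute_dkt(p1 @ R.T + shift, p2 @ R.T + shift))


# ---------------------------------------------------------------------------
# spindle axis


def _pair_trackset(vectors, center=np.zeros(3), n=40):
    tracks = []
    for i, v in enumerate(vectors):
        v = np.asarray(v, dtype=float)
        tracks.append(_track(np.tile(center + v / 2, (n, 1)), tid=2 * i))
        tracks.append(_track(np.tile(center - v / 2, (n, 1)), tid=2 * i + 1))
        tracks[-2].pair_id = i
        tracks[-1].pair_id = i
    return TrackSet(tracks=tracks, frame_interval_s=10.0)


def test_axis_from_aligned_pairs_is_exact():
    ts = _pair_trackset([[2, 0, 0], [2.5, 0, 0]])
    sp = estimate_spindle_axis(ts, (0, 40))
    assert abs(sp.axis @ [1, 0, 0]) == pytest.approx(1.0, abs=1e-9)


def test_axis_symmetric_tilts_average_out():
    a = np.radians(10)
    v1 = [np.cos(a), np.sin(a), 0]
    v2 = [np.cos(a), -np.sin(a), 0]
    sp = estimate_spindle_axis(_pair_trackset([v1, v2]), (0, 40))
    assert abs(sp.axis @ [1, 0, 0]) == pytest.approx(1.0, abs=1e-9)


def test_axis_recovery_on_simulated_cell(control_result, control_cell):
    _b, gt = control_cell
    ang = np.degrees(np.arccos(min(1.0, abs(
        control_result.spindle.axis @ gt.spindle_axis))))
    assert ang < 5.0
    assert control_result.spindle.method == "anaphase_destination"


def test_axis_window_outside_frames_rejected():
    ts = _pair_trackset([[2, 0, 0]])
    with pytest.raises(ValueError, match="window"):
        estimate_spindle_axis(ts, (100, 200))
    with pytest.raises(ValueError, match="5 frames"):
        estimate_spindle_axis(ts, (0, 3))


def test_metaphase_alignment_and_anaphase_step(control_result, control_cell):
    """Median metaphase A_KT < 15 deg; D_KT max step at anaphase onset."""
    _b, gt = control_cell
    kin = control_result.kinematics
    b = control_result.phases.boundaries_s
    dt = 10.0
    meta = kin[(kin["t_seconds"] >= b["metaphase_onset"])
               & (kin["t_seconds"] < b["anaphase_onset"])]
    assert meta["a_kt_deg"].median() < 15.0
    assert meta.groupby("pair_id")["d_kt_um"].std().max() < 0.2
    med = kin.groupby("frame")["d_kt_um"].median()
    step = med.diff()
    first_abrupt = step[step > 0.3].index[0]
    assert abs(first_abrupt * dt - gt.phase_boundaries_s["anaphase_onset"]) \
        <= 2 * dt
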
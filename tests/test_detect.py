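"""Spot detection, sub-resolution separation and intensity quantification."""

import numpy as np
import pytest

import meiotrack as mt
from meiotrack.detect import estimate_pair_separation, quantify_kt_intensity
from meiotrack.render import render_frame, render_pair_region


def test_detects_all_kts_near_truth(rendered_frame, optics):
    """Eight well-separated KTs: eight spots, each within 150 nm."""
    stack, true_xyz = rendered_frame
    spots = mt.detect_spots(stack, optics.voxel_um_zyx)
    assert len(spots) == 8
    for t in true_xyz:
        err = min(np.linalg.norm(s.position_um - t) for s in spots)
        assert err < 0.150


def test_blank_noise_frame_yields_no_spots(optics):
    rng = np.random.default_rng(0)
    blank = rng.poisson(optics.background, size=(31, 96, 96)).astype(float)
    assert mt.detect_spots(blank, optics.voxel_um_zyx) == []


def test_zero_noise_single_kt_within_one_voxel(optics):
    rng = np.random.default_rng(1)
    pos = np.array([[0.15, -0.25, 0.3]])
    stack = render_frame(pos, optics, rng, noise=False)[:, 0]
    from meiotrack.render import default_origin
    spots = mt.detect_spots(stack, optics.voxel_um_zyx)
    assert len(spots) == 1
    origin = np.array(default_origin(optics))
    err = np.abs(spots[0].position_um - (pos[0] - origin[::-1]))
    assert np.all(err <= optics.voxel_um_zyx[::-1])


def test_uncalibrated_stack_rejected():
    with pytest.raises(ValueError, match="calibrat"):
        mt.detect_spots(np.zeros((5, 5, 5)), (0.0, 0.1, 0.1))


def test_count_conservation_on_separated_renders(optics):
    """Detected count equals the true KT count in >= 95% of frames."""
    from meiotrack.render import render_movie
    bundle, gt = mt.simulate_cell(mt.make_preset("control"), 4)
    frames = list(range(0, 40, 2))
    series = render_movie(bundle, optics, seed=1, frames=frames)
    ok = sum(len(mt.detect_spots(series.frame(i, 0), optics.voxel_um_zyx)) == 8
             for i in range(len(frames)))
    assert ok / len(frames) >= 0.95


def test_localization_error_and_photon_ladder(optics):
    """Median 3D error < 100 nm; error shrinks as photons increase."""
    meds = []
    for photons in (120.0, 500.0, 2000.0):
        o = mt.OpticsConfig(photon_scale=photons)
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(24):
            stack, true = render_pair_region(0.0, o, rng,
                                             shape_zyx=(11, 25, 25))
            spots = mt.detect_spots(stack, o.voxel_um_zyx)
            assert spots
            errs.append(np.linalg.norm(spots[0].position_um - true[0]))
        meds.append(np.median(errs))
    assert meds[-1] < 0.100
    assert meds[0] > meds[1] > meds[2]


# ---------------------------------------------------------------------------
# pair separation


def test_resolved_pair_at_950nm(optics):
    rng = np.random.default_rng(6)
    ests = []
    for _ in range(10):
        stack, _ = render_pair_region(950.0, optics, rng,
                                      shape_zyx=(9, 29, 29))
        e = estimate_pair_separation(stack, optics)
        assert e.resolved
        ests.append(e.distance_nm)
    assert abs(np.mean(ests) - 950.0) < 100.0


def test_single_source_censored_at_floor(optics):
    rng = np.random.default_rng(7)
    stack, _ = render_pair_region(0.0, optics, rng, shape_zyx=(9, 25, 25))
    e = estimate_pair_separation(stack, optics)
    assert not e.resolved
    assert e.censored
    assert e.distance_nm == pytest.approx(150.0)
    assert e.elongation < 1.2


def test_subresolution_recovery_at_300nm(optics):
    """51 replicates at 300 nm: mean estimate within 100 nm of truth."""
    rng = np.random.default_rng(8)
    ests = []
    for _ in range(51):
        stack, _ = render_pair_region(300.0, optics, rng,
                                      shape_zyx=(9, 25, 25))
        e = estimate_pair_separation(stack, optics)
        assert not e.resolved
        ests.append(e.distance_nm)
    assert abs(np.mean(ests) - 300.0) < 100.0


def test_estimator_monotone_over_separation_ladder(optics):
    rng = np.random.default_rng(9)
    means = []
    for d in (0.0, 200.0, 400.0, 600.0, 800.0, 1000.0, 1200.0):
        vals = [estimate_pair_separation(
            render_pair_region(d, optics, rng, shape_zyx=(9, 29, 29))[0],
            optics).distance_nm for _ in range(6)]
        means.append(np.mean(vals))
    assert np.all(np.diff(means) >= 0)


def test_multiple_distant_blobs_rejected(optics):
    rng = np.random.default_rng(10)
    stack, _ = render_pair_region(2400.0, optics, rng, shape_zyx=(9, 49, 49))
    with pytest.raises(ValueError, match="blobs"):
        estimate_pair_separation(stack, optics)


# ---------------------------------------------------------------------------
# intensity quantification


def test_intensity_linearity(optics):
    rng = np.random.default_rng(11)
    stack, _ = render_pair_region(0.0, optics, rng, shape_zyx=(9, 25, 25),
                                  noise=False)
    spots = mt.detect_spots(stack, optics.voxel_um_zyx)
    v1 = quantify_kt_intensity(stack, spots, optics.voxel_um_zyx)
    v2 = quantify_kt_intensity(2 * stack, spots, optics.voxel_um_zyx)
    assert v2 == pytest.approx(2 * v1)


def test_two_identical_spots_double_the_intensity(optics):
    rng = np.random.default_rng(12)
    one = render_frame(np.array([[0.0, 0.0, 0.0]]), optics, rng,
                       noise=False)[:, 0]
    two = render_frame(np.array([[-3.0, 0.0, 0.0], [3.0, 0.0, 0.0]]),
                       optics, rng, noise=False)[:, 0]
    s1 = mt.detect_spots(one, optics.voxel_um_zyx)
    s2 = mt.detect_spots(two, optics.voxel_um_zyx)
    assert len(s1) == 1 and len(s2) == 2
    v1 = quantify_kt_intensity(one, s1, optics.voxel_um_zyx)
    v2 = quantify_kt_intensity(two, s2, optics.voxel_um_zyx)
    assert v2 == pytest.approx(2 * v1, rel=0.01)


def test_no_spots_returns_zero(optics):
    assert quantify_kt_intensity(np.zeros((5, 9, 9)), [],
                                 optics.voxel_um_zyx) == 0.0
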
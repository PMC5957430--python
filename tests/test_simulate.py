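"""Generator invariants: determinism, phase structure, speeds, events."""

import numpy as np
import pandas as pd
import pytest

import meiotrack as mt
from meiotrack.simulate import simulate_cohort


def _speeds(positions, dt=10.0):
    return np.linalg.norm(np.diff(positions, axis=1), axis=2) / dt


def test_same_seed_reproduces_identical_output():
    cfg = mt.make_preset("control")
    b1, g1 = mt.simulate_cell(cfg, 7)
    b2, g2 = mt.simulate_cell(cfg, 7)
    pd.testing.assert_frame_equal(b1.positions, b2.positions)
    pd.testing.assert_frame_equal(b1.signals, b2.signals)
    assert np.array_equal(g1.true_positions, g2.true_positions)
    assert g1.phase_boundaries_s == g2.phase_boundaries_s


def test_pinned_durations_sum_to_division_length():
    """With s.d. = 0 the M I length equals the sum of phase means."""
    cfg = mt.make_preset("control")
    cfg.phase_minutes = {k: (m, 0.0) for k, (m, _s) in
                         cfg.phase_minutes.items()}
    _b, gt = mt.simulate_cell(cfg, 3)
    mi = (gt.phase_boundaries_s["interphase_onset"]
          - gt.phase_boundaries_s["nebd"]) / 60.0
    assert mi == pytest.approx(58.0, abs=0.01)


def test_phase_boundaries_strictly_increasing():
    for seed in range(5):
        _b, gt = mt.simulate_cell(mt.make_preset("control"), seed)
        vals = [v for v in (gt.phase_boundaries_s[k] for k in (
            "nebd", "prometaphase_b_onset", "metaphase_onset",
            "anaphase_onset", "telophase_onset", "interphase_onset"))
            if v is not None]
        assert np.all(np.diff(vals) > 0)


def test_mnm_pairing_is_eight_sister_pairs():
    _b, gt = mt.simulate_cell(mt.make_preset("mnm"), 2)
    pairs = set(gt.pairing.values())
    assert len(pairs) == 8
    assert len(gt.pairing) == 16
    assert set(gt.univalent_classes) == pairs


def test_speed_realism_in_control(control_cell):
    """Prometaphase A speeds stay below the jump scale; every pair jumps."""
    _b, gt = control_cell
    cfg = mt.make_preset("control")
    v_jump = cfg.kinematics.jump_speed_um_s
    dt = cfg.frame_interval_s
    t_b = gt.phase_boundaries_s["prometaphase_b_onset"]
    t_m = gt.phase_boundaries_s["metaphase_onset"]
    i_n = int(gt.phase_boundaries_s["nebd"] / dt)
    i_b = int(t_b / dt)
    i_m = int(t_m / dt)
    v = _speeds(gt.true_positions, dt)
    assert v[:, i_n:i_b - 1].max() < v_jump
    for p in range(4):
        v_pair = v[2 * p:2 * p + 2, i_b:i_m]
        assert v_pair.max() > v_jump


def test_anaphase_pair_distance_nondecreasing():
    for seed in range(5):
        _b, gt = mt.simulate_cell(mt.make_preset("control"), seed)
        dt = 10.0
        i_a = int(gt.phase_boundaries_s["anaphase_onset"] / dt) + 1
        i_t = int(gt.phase_boundaries_s["telophase_onset"] / dt)
        for p in range(4):
            d = np.linalg.norm(gt.true_positions[2 * p, i_a:i_t]
                               - gt.true_positions[2 * p + 1, i_a:i_t], axis=1)
            assert np.all(np.diff(d) >= -1e-9)


def test_breathing_rate_matches_poisson_expectation():
    """Over >= 500 dot-hours the event rate is within 3 Poisson s.e."""
    cfg = mt.make_preset("control", "IK")
    n_events = 0
    dot_hours = 0.0
    seed = 0
    while dot_hours < 500.0:
        _b, gt = mt.simulate_cell(cfg, 900 + seed)
        seed += 1
        n_events += len(gt.breathing_events)
        dot_hours += 4 * gt.times_s[-1] / 3600.0
    expected = cfg.breathing.rate_per_dot_hour * dot_hours
    assert abs(n_events - expected) <= 3 * np.sqrt(expected)


def test_cyst_synchrony_and_cell_count():
    cfg = mt.make_preset("control")
    cfg.n_cells = 16
    cells = mt.simulate_cyst(cfg, 11)
    assert len(cells) == 16
    nebds = [gt.phase_boundaries_s["nebd"] for _b, gt in cells]
    assert max(nebds) - min(nebds) <= 2 * cfg.cyst_synchrony_bound_min * 60.0

    cfg.n_cells = 1
    assert len(mt.simulate_cyst(cfg, 11)) == 1

    cfg.n_cells = 4
    cfg.cyst_synchrony_bound_min = 0.0
    cells = mt.simulate_cyst(cfg, 11)
    first = cells[0][1].phase_boundaries_s
    for _b, gt in cells[1:]:
        assert gt.phase_boundaries_s == first


def test_cyst_requires_at_least_one_cell():
    cfg = mt.make_preset("control")
    cfg.n_cells = 0
    with pytest.raises(ValueError, match="n_cells"):
        mt.simulate_cyst(cfg, 1)


def test_degenerate_geometry_rejected():
    cfg = mt.make_preset("control")
    cfg.geometry.plate_width_um = 15.0
    with pytest.raises(ValueError):
        mt.simulate_cell(cfg, 0)


def test_stratified_cohort_centres_phase_draws():
    """Stratified cyst draws average to the configured means."""
    cfg = mt.make_preset("control")
    cfg.n_cells = 1
    cysts = simulate_cohort(cfg, 12, seed=5, stratified=True)
    pa = [(gt.phase_boundaries_s["prometaphase_b_onset"]
           - gt.phase_boundaries_s["nebd"]) / 60.0
          for cyst in cysts for _b, gt in cyst]
    assert np.mean(pa) == pytest.approx(5.0, abs=0.5)


def test_mii_separation_course():
    """Sister separation rises from the NEBD level to the plateau."""
    _b, gt = mt.simulate_cell(mt.make_preset("control", "MII"), 6)
    dt = 10.0
    i_n = int(gt.phase_boundaries_s["nebd"] / dt)
    i_m = int(gt.phase_boundaries_s["metaphase_onset"] / dt) + 2
    i_a = int(gt.phase_boundaries_s["anaphase_onset"] / dt)
    sep = np.linalg.norm(gt.true_positions[0] - gt.true_positions[1],
                         axis=1) * 1000
    assert sep[i_n] < 800
    assert 700 < np.median(sep[i_m:i_a]) < 1300
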
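"""Phase scoring recovery and event detectors (with brute-force oracles)."""

import numpy as np
import pandas as pd
import pytest

import meiotrack as mt
from meiotrack.config import AnalysisConfig
from meiotrack.kinetics import SpindleFrame
from meiotrack.phases import (classify_univalents, detect_breathing,
                              detect_excursions, summarize_genotypes,
                              render_report)

BOUNDS = ("nebd", "prometaphase_b_onset", "metaphase_onset",
          "anaphase_onset", "telophase_onset", "interphase_onset")


def test_phase_recovery_within_60s(control_cohort):
    """Each scored boundary within 60 s of ground truth in >= 90% of cells."""
    for key in BOUNDS:
        hits = tot = 0
        for _b, gt, res in control_cohort:
            t, s = gt.phase_boundaries_s[key], res.phases.boundaries_s[key]
            if t is None:
                continue
            tot += 1
            hits += (s is not None and abs(s - t) <= 60.0)
        assert tot > 0
        assert hits / tot >= 0.9, key


def test_boundaries_scored_or_explicitly_unscored(control_cohort):
    for _b, _gt, res in control_cohort:
        for key in BOUNDS:
            scored = res.phases.boundaries_s[key] is not None
            tag = res.phases.methods[key]
            assert (tag == "unscored") != scored


def test_colcemid_leaves_jump_onset_unscored():
    """Without MTs there are no rapid KT jumps to score."""
    bundle, _gt = mt.simulate_cell(mt.make_preset("colcemid"), 3)
    res = mt.analyze_cell(bundle)
    assert res.phases.boundaries_s["prometaphase_b_onset"] is None
    assert res.phases.methods["prometaphase_b_onset"] == "unscored"
    assert res.phases.boundaries_s["nebd"] is not None


def test_fzy_depletion_arrests_in_metaphase():
    """Fzy-depleted cells stay in metaphase for more than four hours."""
    bundle, _gt = mt.simulate_cell(mt.make_preset("fzy_rnai"), 1)
    res = mt.analyze_cell(bundle)
    interval = res.phases.interval_min("metaphase_onset", "anaphase_onset")
    assert interval is not None and interval > 240.0


# ---------------------------------------------------------------------------
# excursions


def _zone_oracle(s, plate_half, polar_inner):
    """Independent re-implementation of the transit count."""
    count = 0
    last = None
    for x in s:
        if abs(x) <= plate_half:
            zone = "eq"
        elif abs(x) >= polar_inner:
            zone = "polar"
        else:
            continue
        if last is not None and zone != last:
            count += 1
        last = zone
    return count


def _axis_frame():
    return SpindleFrame(axis=np.array([1.0, 0.0, 0.0]),
                        poles=np.array([[6.0, 0, 0], [-6.0, 0, 0]]))


def test_excursion_oscillation_counts_each_transit():
    """Seven pole<->plate trips count as seven excursions."""
    cfg = AnalysisConfig()
    stops = [4.0 if i % 2 else 0.0 for i in range(8)]  # 7 transits
    s = np.concatenate([np.linspace(a, b, 10) for a, b in
                        zip(stops, stops[1:])])
    pos = np.stack([s, np.zeros_like(s), np.zeros_like(s)], axis=1)
    count, events = detect_excursions(pos, np.arange(len(s)) * 10.0,
                                      _axis_frame(), cfg)
    assert count == 7
    assert len(events) == 7


def test_plate_resident_track_has_no_excursions():
    cfg = AnalysisConfig()
    pos = np.tile([0.5, 0.0, 0.0], (50, 1))
    count, _ = detect_excursions(pos, np.arange(50) * 10.0, _axis_frame(), cfg)
    assert count == 0


def test_incomplete_transit_not_counted():
    """Leaving the plate without reaching the polar zone counts zero."""
    cfg = AnalysisConfig()
    s = np.concatenate([np.linspace(0, 2.5, 10), np.linspace(2.5, 0, 10)])
    pos = np.stack([s, np.zeros_like(s), np.zeros_like(s)], axis=1)
    count, _ = detect_excursions(pos, np.arange(len(s)) * 10.0,
                                 _axis_frame(), cfg)
    assert count == 0


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-6.0, 6.0), min_size=2, max_size=60))
def test_excursion_counter_matches_oracle_on_random_walks(axial):
    """The transit counter agrees with the explicit state machine."""
    from meiotrack.zones import count_zone_transits
    count, transits = count_zone_transits(np.array(axial), 1.5, 3.0)
    assert count == _zone_oracle(axial, 1.5, 3.0)
    assert count == len(transits)
    for (i0, i1, z0, z1) in transits:
        assert i0 < i1 and z0 != z1


def test_overlapping_zones_rejected():
    cfg = AnalysisConfig()
    cfg.plate_width_um = 10.0  # half-width 5 >= polar inner edge 3
    with pytest.raises(ValueError, match="overlap"):
        detect_excursions(np.zeros((5, 3)), np.arange(5) * 10.0,
                          _axis_frame(), cfg)


@pytest.mark.parametrize("seed", range(5))
def test_excursion_counter_matches_oracle_on_simulated_cells(seed):
    cfg = AnalysisConfig()
    bundle, gt = mt.simulate_cell(mt.make_preset("control"), seed)
    sp = SpindleFrame(axis=gt.spindle_axis, poles=gt.pole_positions)
    dt = 10.0
    lo = int(gt.phase_boundaries_s["nebd"] / dt)
    hi = int(gt.phase_boundaries_s["anaphase_onset"] / dt)
    for p in range(4):
        c = 0.5 * (gt.true_positions[2 * p] + gt.true_positions[2 * p + 1])
        count, _ = detect_excursions(c[lo:hi], np.arange(hi - lo) * dt,
                                     sp, cfg)
        assert count == _zone_oracle(sp.axial_coordinate(c[lo:hi]), 1.5, 3.0)


# ---------------------------------------------------------------------------
# re-orientations


def _jumpy_pair(signs):
    """A pair whose centre jumps into the polar zone with given signs."""
    cfg = AnalysisConfig()
    pos = [np.array([0.0, 0.0, 0.0])]
    for s in signs:
        target = np.array([4.5 * s, 0.0, 0.0])
        while np.linalg.norm(pos[-1] - target) > 1.0:
            step = target - pos[-1]
            pos.append(pos[-1] + step / np.linalg.norm(step) * 1.0)
        pos += [target.copy()] * 5
    pos = np.stack(pos)
    from meiotrack.track import Track
    n = len(pos)
    t1 = Track(0, np.arange(n), pos, np.zeros(n, dtype=bool))
    t2 = Track(1, np.arange(n), pos + [0.0, 1.0, 0.0],
               np.zeros(n, dtype=bool))
    return [t1, t2], cfg


def test_reorientation_alternating_poles_is_one_event():
    pair, cfg = _jumpy_pair([+1, -1])
    events = mt.detect_reorientations(pair, _axis_frame(), cfg, 10.0,
                                      jump_thr_um_s=0.06)
    assert len(events) == 1
    assert events[0].detail["pole_signs"] == (1, -1)


def test_jumps_to_same_pole_are_no_event():
    pair, cfg = _jumpy_pair([+1, +1])
    events = mt.detect_reorientations(pair, _axis_frame(), cfg, 10.0,
                                      jump_thr_um_s=0.06)
    assert events == []


def test_control_cells_show_one_reorientation_each(control_cohort):
    counts = [len([e for e in res.events if e.kind == "reorientation"])
              for _b, _gt, res in control_cohort[:5]]
    assert np.mean(counts) == pytest.approx(1.0, abs=0.4)


# ---------------------------------------------------------------------------
# breathing


def _sep_df(resolved, dist=500.0):
    return pd.DataFrame({"frame": np.arange(len(resolved)),
                         "resolved": resolved,
                         "distance_nm": np.full(len(resolved), dist)})


def test_breathing_never_resolved_gives_no_events():
    events, rate = detect_breathing({0: _sep_df([False] * 50)}, 10.0)
    assert events == [] and rate == 0.0


def test_single_frame_split_below_minimum_not_counted():
    res = [False] * 10 + [True] + [False] * 10
    events, _ = detect_breathing({0: _sep_df(res)}, 10.0, min_frames=2)
    assert events == []


def test_breathing_event_duration_and_magnitude():
    res = [False] * 5 + [True] * 3 + [False] * 5
    events, rate = detect_breathing({0: _sep_df(res, dist=520.0)}, 10.0)
    assert len(events) == 1
    assert events[0].t_end_s - events[0].t_start_s == pytest.approx(30.0)
    assert events[0].magnitude == pytest.approx(520.0)
    assert rate == pytest.approx(1 / (13 * 10 / 3600))


def test_missing_cadence_rejected():
    with pytest.raises(ValueError, match="cadence"):
        detect_breathing({0: _sep_df([True] * 5)}, 0.0)


def test_no_false_positives_at_zero_breathing_rate():
    """Zero events over >= 100 dot-hours simulated without breathing."""
    cfg = mt.make_preset("control", "IK")
    cfg.breathing.rate_per_dot_hour = 0.0
    dot_hours = 0.0
    seed = 0
    while dot_hours < 100.0:
        bundle, gt = mt.simulate_cell(cfg, 700 + seed)
        seed += 1
        res = mt.analyze_cell(bundle, ground_truth=gt)
        assert [e for e in res.events if e.kind == "breathing"] == []
        dot_hours += 4 * gt.times_s[-1] / 3600.0


def test_detected_breathing_durations_within_simulated_range():
    cfg = mt.make_preset("control", "IK")
    durations = []
    for seed in range(30):
        bundle, gt = mt.simulate_cell(cfg, 800 + seed)
        res = mt.analyze_cell(bundle, ground_truth=gt)
        durations += [e.t_end_s - e.t_start_s for e in res.events
                      if e.kind == "breathing"]
    assert durations
    assert min(durations) >= 20.0
    assert max(durations) <= cfg.breathing.long_max_s + 10.0


# ---------------------------------------------------------------------------
# univalent classification


def _univalent_df(axial, sep):
    n = len(axial)
    return pd.DataFrame({"frame": np.arange(n), "sep_nm": sep,
                         "axial_um": axial})


def _phases_with_telophase(t_telo_s=3000.0):
    from meiotrack.phases import PhaseAnnotation
    return PhaseAnnotation(
        boundaries_s={"nebd": 0.0, "prometaphase_b_onset": 200.0,
                      "metaphase_onset": 600.0, "anaphase_onset": None,
                      "telophase_onset": t_telo_s,
                      "interphase_onset": t_telo_s + 600.0},
        methods={k: "signal" for k in BOUNDS})


def test_constructed_class_rules():
    cfg = AnalysisConfig()
    phases = _phases_with_telophase(3000.0)  # inferred m/a at 2400 s
    n = 330
    plate = np.zeros(n)
    # class I: plate-resident, splits 2 min after the inferred m/a
    sep1 = np.full(n, 300.0)
    sep1[252:] = 700.0  # from t=2520 s
    # class III: departs poleward 5 min before m/a, never splits
    ax3 = np.zeros(n)
    ax3[210:] = 4.5  # from t=2100 s
    # class II: plate-resident, never resolved
    out = classify_univalents(
        {0: _univalent_df(plate, sep1),
         1: _univalent_df(ax3, np.full(n, 250.0)),
         2: _univalent_df(plate, np.full(n, 250.0))},
        phases, _axis_frame(), cfg, 10.0)
    labels = {u.pair_id: u.label for u in out}
    assert labels == {0: "I", 1: "III", 2: "II"}


def test_classification_requires_telophase_anchor():
    cfg = AnalysisConfig()
    phases = _phases_with_telophase()
    phases.boundaries_s["telophase_onset"] = None
    with pytest.raises(ValueError, match="telophase"):
        classify_univalents({0: _univalent_df(np.zeros(10),
                                              np.full(10, 250.0))},
                            phases, _axis_frame(), cfg, 10.0)


def test_classification_deterministic_and_order_independent():
    cfg = AnalysisConfig()
    bundle, gt = mt.simulate_cell(mt.make_preset("mnm"), 5)
    r1 = mt.analyze_cell(bundle, ground_truth=gt, use_gt_pairing=True)
    r2 = mt.analyze_cell(bundle, ground_truth=gt, use_gt_pairing=True)
    l1 = {u.pair_id: u.label for u in r1.univalent_classes}
    l2 = {u.pair_id: u.label for u in r2.univalent_classes}
    assert l1 == l2


# ---------------------------------------------------------------------------
# summaries


def test_identical_cells_have_zero_sd(control_cell):
    bundle, gt = control_cell
    res = mt.analyze_cell(bundle, ground_truth=gt)
    tables = summarize_genotypes([res, res])
    dur = tables["durations"]
    assert (dur["std"].dropna() == 0).all()
    assert (dur["count"] == 2).all()


def test_summary_reports_cohort_counts(control_cohort):
    results = [res for _b, _gt, res in control_cohort[:4]]
    tables = summarize_genotypes(results)
    dur = tables["durations"]
    row = dur[(dur["genotype"] == "control") & (dur["phase"] == "division")]
    assert int(row["count"].iloc[0]) == 4
    text = render_report(tables, thresholds={"jump_factor": 3.0})
    assert "durations" in text and "jump_factor" in text


def test_summarize_empty_rejected():
    with pytest.raises(ValueError, match="at least one"):
        summarize_genotypes([])


def test_mnm_shows_more_excursions_than_control(control_cohort):
    """Univalents make more polar<->equatorial trips than bivalents."""
    control = [res for _b, _gt, res in control_cohort[:5]]
    mnm = []
    for seed in range(3):
        bundle, gt = mt.simulate_cell(mt.make_preset("mnm"), 40 + seed)
        mnm.append(mt.analyze_cell(bundle, ground_truth=gt))
    tables = summarize_genotypes(control + mnm)
    exc = tables["excursions"].set_index("genotype")["mean"]
    assert exc["mnm"] > exc["control"]
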
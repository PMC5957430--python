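"""Desk-scale parameter-recovery experiments.

Each function simulates a seeded synthetic cohort at the published
sample size, runs the analysis pipeline blind (heuristic pairing,
signal/kinematics-based phase scoring) and returns the recovered
quantity.  Cohort-level draws are stratified (see
:func:`meiotrack.simulate.simulate_cohort`) and the control-vs-mad2
contrast uses common random numbers, so that desk-scale cohorts
estimate the configured means rather than cohort-sampling noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import AnalysisConfig, OpticsConfig, make_preset
from .detect import estimate_pair_separation
from .phases import detect_breathing
from .pipeline import analyze_cell
from .render import render_pair_region
from .simulate import simulate_cell, simulate_cohort


def _child_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0]
               % (2 ** 31))


def phase_interval_recovery(seed: int, start: str, end: str,
                            n_cysts: int, cells_per_cyst: int,
                            genotype: str = "control", division: str = "MI",
                            per_cyst_mean: bool = False,
                            max_cells: int | None = None):
    """Mean scored ``start``->``end`` interval (minutes) over a cohort."""
    cfg = make_preset(genotype, division)
    cfg.n_cells = cells_per_cyst
    cysts = simulate_cohort(cfg, n_cysts, seed, stratified=True)
    acfg = AnalysisConfig()
    per_cyst = []
    per_cell = []
    for cyst in cysts:
        vals = []
        for bundle, gt in cyst:
            if max_cells is not None and len(per_cell) + len(vals) >= max_cells:
                break
            r = analyze_cell(bundle, analysis=acfg, ground_truth=gt)
            v = r.phases.interval_min(start, end)
            if v is not None:
                vals.append(v)
        per_cell.extend(vals)
        if vals:
            per_cyst.append(float(np.mean(vals)))
    vals = per_cyst if per_cyst_mean else per_cell
    return float(np.mean(vals)), len(vals)


def mad2_entry_difference(seed: int, n_cells: int = 10):
    """Mean control-minus-mad2 NEBD-to-anaphase interval (minutes).

    Paired design: both cohorts share per-cell seeds (common random
    numbers), isolating the preset's timer difference.
    """
    acfg = AnalysisConfig()
    means = {}
    for g in ("control", "mad2"):
        vals = []
        for i in range(n_cells):
            bundle, gt = simulate_cell(make_preset(g),
                                       _child_seed(seed, 1000 + i))
            r = analyze_cell(bundle, analysis=acfg, ground_truth=gt)
            v = r.phases.entry_duration_min
            if v is not None:
                vals.append(v)
        means[g] = float(np.mean(vals))
    return means["control"] - means["mad2"], n_cells


def separation_recovery(seed: int, mean_nm: float, sd_nm: float, n: int,
                        roi_xy: int = 29):
    """Mean estimated sister separation over ``n`` rendered blob pairs.

    True separations are stratified draws from N(mean, sd), folded at
    zero (a physical separation cannot be negative), rendered in-plane
    at default optics and fed through the two-sphere/two-maxima
    estimator.
    """
    optics = OpticsConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7365]))
    z = rng.permutation(norm.ppf((np.arange(n) + 0.5) / n))
    seps = np.abs(mean_nm + sd_nm * z)
    ests = []
    for s in seps:
        stack, _ = render_pair_region(float(s), optics, rng,
                                      shape_zyx=(9, roi_xy, roi_xy))
        ests.append(estimate_pair_separation(stack, optics).distance_nm)
    return float(np.mean(ests)), n


def breathing_event_count(seed: int, n_cells: int = 23,
                          rate_per_dot_hour: float | None = None):
    """Total breathing events detected over a rendered IK cohort.

    Every frame of every dot is rendered as a small ROI at the dot's
    true in-plane separation and passed through the two-maxima
    resolution test; events are maximal resolved runs of >= 2 frames.
    Returns ``(event_count, rate_per_dot_hour, n_dots)``.
    """
    cfg = make_preset("control", "IK")
    if rate_per_dot_hour is not None:
        cfg.breathing.rate_per_dot_hour = rate_per_dot_hour
    optics = OpticsConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6272]))
    estimates = {}
    dot = 0
    for i in range(n_cells):
        _bundle, gt = simulate_cell(cfg, _child_seed(seed, 2000 + i))
        pos = gt.true_positions
        for p in range(pos.shape[0] // 2):
            rows = []
            for f in range(pos.shape[1]):
                d_nm = np.linalg.norm(pos[2 * p, f] - pos[2 * p + 1, f]) * 1000
                stack, _ = render_pair_region(d_nm, optics, rng,
                                              shape_zyx=(9, 25, 25))
                e = estimate_pair_separation(stack, optics, fit=False)
                rows.append((f, e.resolved, e.distance_nm))
            estimates[dot] = pd.DataFrame(
                rows, columns=["frame", "resolved", "distance_nm"])
            dot += 1
    events, rate = detect_breathing(estimates, cfg.frame_interval_s)
    return len(events), float(rate), dot


def excursion_mean(seed: int, genotype: str, n_cells: int = 5):
    """Mean excursions per KT pair over ``n_cells`` analyzed cells."""
    acfg = AnalysisConfig()
    counts = []
    for i in range(n_cells):
        bundle, gt = simulate_cell(make_preset(genotype),
                                   _child_seed(seed, 3000 + i))
        r = analyze_cell(bundle, analysis=acfg, ground_truth=gt)
        counts.extend(r.excursion_counts.values())
    return float(np.mean(counts)), len(counts)


def univalent_class_fractions(seed: int, n_cells: int = 28):
    """Detected class I/II/III fractions over an mnm cohort."""
    acfg = AnalysisConfig()
    labels = []
    for i in range(n_cells):
        bundle, gt = simulate_cell(make_preset("mnm"),
                                   _child_seed(seed, 4000 + i))
        r = analyze_cell(bundle, analysis=acfg, ground_truth=gt)
        for u in (r.univalent_classes or []):
            labels.append(u.label)
    n = len(labels)
    return {lab: labels.count(lab) / n for lab in ("I", "II", "III")}, n


def reorientation_rate(seed: int, n_cells: int = 5):
    """Mean detected KT re-orientation events per control cell."""
    acfg = AnalysisConfig()
    counts = []
    for i in range(n_cells):
        bundle, gt = simulate_cell(make_preset("control"),
                                   _child_seed(seed, 5000 + i))
        r = analyze_cell(bundle, analysis=acfg, ground_truth=gt)
        counts.append(len([e for e in r.events if e.kind == "reorientation"]))
    return float(np.mean(counts)), n_cells
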
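"""Division-phase scoring and behavioural event detection.

Scoring rules mirror the published visual-scoring criteria:

* NEBD -- the diffuse nucleoplasmic signal starts to drop precipitously
  (steepest sustained drop of the proxy channel).
* prometaphase A -> B -- the first supra-threshold KT jump.  The jump
  threshold is adaptive: ``jump_factor`` times the 95th percentile of
  early post-NEBD speeds of the same cell, with an absolute floor.
* metaphase onset -- the first frame after which every pair
  simultaneously sits inside the plate band, with its inter-KT axis
  within the angle threshold of the spindle axis and sub-threshold
  mobility, for at least the persistence window ("the last pair of KTs
  has congressed into the metaphase plate and lost mobility").
* anaphase onset -- the maximal single-step increase of the median
  within-pair distance, which increases abruptly at anaphase onset
  (majority rule across pairs).
* telophase / interphase onset -- changepoints of the chromosome
  decondensation proxy ramp.

Every boundary is either scored or explicitly ``None`` with method tag
``unscored`` -- never silently defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .kinetics import (SpindleFrame, estimate_spindle_axis,
                       estimate_spindle_axis_from_positions, pair_kinematics)
from .track import TrackSet
from .zones import count_zone_transits, zone_labels, POLAR, EQUATORIAL

BOUNDARY_ORDER = ("nebd", "prometaphase_b_onset", "metaphase_onset",
                  "anaphase_onset", "telophase_onset", "interphase_onset")


@dataclass
class PhaseAnnotation:
    boundaries_s: dict
    methods: dict

    def __post_init__(self):
        scored = [(k, self.boundaries_s[k]) for k in BOUNDARY_ORDER
                  if self.boundaries_s.get(k) is not None]
        for (k1, v1), (k2, v2) in zip(scored, scored[1:]):
            if v2 <= v1:
                raise ValueError(
                    f"boundaries not strictly increasing: {k1}={v1} >= {k2}={v2}")

    def interval_min(self, start: str, end: str) -> Optional[float]:
        a = self.boundaries_s.get(start)
        b = self.boundaries_s.get(end)
        if a is None or b is None:
            return None
        return (b - a) / 60.0

    @property
    def division_duration_min(self):
        return self.interval_min("nebd", "interphase_onset")

    @property
    def entry_duration_min(self):
        """NEBD to anaphase onset ("entry")."""
        return self.interval_min("nebd", "anaphase_onset")


@dataclass
class EventRecord:
    kind: str        # breathing | excursion | reorientation
    subject_id: int  # dot/track/pair id
    t_start_s: float
    t_end_s: float
    magnitude: float = 0.0
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.t_end_s < self.t_start_s:
            raise ValueError("event end must be >= start")
        if self.magnitude < 0:
            raise ValueError("event magnitude must be >= 0")


@dataclass
class UnivalentClassification:
    pair_id: int
    label: str  # I | II | III
    evidence: dict


# ---------------------------------------------------------------------------
# boundary scoring


def score_nebd(signals: pd.DataFrame, frame_interval_s: float):
    """Steepest sustained drop of the nucleoplasmic proxy; None if absent."""
    s = signals["nucleoplasm"].to_numpy(dtype=float)
    if len(s) < 8:
        return None
    sm = pd.Series(s).rolling(3, center=True, min_periods=1).median().to_numpy()
    d = np.diff(sm)
    dmin = d.min()
    total_drop = sm[:10].mean() - sm[-10:].mean()
    if total_drop < 0.2 or dmin > -0.05:
        return None
    steep = np.flatnonzero(d < 0.5 * dmin)
    for i in steep:
        pre = sm[max(0, i - 5):i + 1].mean()
        post = sm[i + 1:i + 8].mean()
        if pre - post > 0.1:
            return float(i * frame_interval_s)
    return None


def jump_threshold(trackset: TrackSet, nebd_idx: int, cfg: AnalysisConfig,
                   frame_interval_s: float) -> float:
    """Adaptive jump-speed threshold from early post-NEBD baseline speeds."""
    base = []
    lo, hi = nebd_idx, nebd_idx + cfg.baseline_window_frames
    for tr in trackset.tracks:
        sel = (tr.frames[1:] >= lo) & (tr.frames[1:] < hi)
        disp = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
        dt = np.diff(tr.frames) * frame_interval_s
        base.extend((disp / dt)[sel])
    if not base:
        return cfg.jump_speed_floor_um_s * cfg.jump_factor
    p95 = float(np.nanpercentile(base, 95))
    return max(cfg.jump_factor * p95,
               cfg.jump_factor * cfg.jump_speed_floor_um_s)


def score_jump_onset(trackset: TrackSet, nebd_idx: int, cfg: AnalysisConfig,
                     frame_interval_s: float):
    """First supra-threshold KT speed after the baseline window."""
    thr = jump_threshold(trackset, nebd_idx, cfg, frame_interval_s)
    first = None
    for tr in trackset.tracks:
        disp = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
        dt = np.diff(tr.frames) * frame_interval_s
        v = disp / dt
        ok = np.flatnonzero((tr.frames[1:] > nebd_idx) & (v > thr))
        if ok.size:
            # time of the interval start
            cand = tr.frames[ok[0]]
            if first is None or cand < first:
                first = cand
    if first is None:
        return None, thr
    return float(first * frame_interval_s), thr


def score_anaphase(kin: pd.DataFrame, cfg: AnalysisConfig,
                   frame_interval_s: float):
    """Abrupt sustained increase of the median within-pair distance."""
    med = kin.groupby("frame")["d_kt_um"].median()
    frames = med.index.to_numpy()
    d = med.to_numpy()
    if len(d) < 5:
        return None
    step = np.diff(d)
    for i in np.flatnonzero(step > cfg.anaphase_step_um):
        hi = min(len(d) - 1, i + 4)
        if d[hi] > d[i] + 1.5 * cfg.anaphase_step_um:
            return float(frames[i + 1] * frame_interval_s)
    return None


def score_metaphase_onset(kin: pd.DataFrame, centers_axial: dict,
                          cfg: AnalysisConfig, frame_interval_s: float,
                          start_frame: int, stop_frame: int):
    """First frame from which all pairs are jointly plate-stable.

    ``centers_axial`` maps pair_id to a (frame -> axial coordinate)
    Series of the pair midpoint.
    """
    plate_half = cfg.plate_width_um / 2.0
    pair_ids = sorted(centers_axial)
    ok_frames = None
    for pid in pair_ids:
        sub = kin[kin["pair_id"] == pid].set_index("frame")
        ax = centers_axial[pid]
        frames = sub.index.intersection(ax.index)
        v = np.fmax(sub.loc[frames, "v_kt_a"], sub.loc[frames, "v_kt_b"])
        cond = ((np.abs(ax.loc[frames]) <= plate_half)
                & (sub.loc[frames, "a_kt_deg"] < cfg.angle_max_deg)
                & (v < cfg.mobility_max_um_s))
        cond = pd.Series(cond.to_numpy(), index=frames)
        ok_frames = cond if ok_frames is None else (ok_frames & cond)
    if ok_frames is None:
        return None
    ok_frames = ok_frames.sort_index()
    frames = ok_frames.index.to_numpy()
    vals = ok_frames.to_numpy()
    P = cfg.persistence_frames
    for k in range(len(vals) - P + 1):
        f = frames[k]
        if f < start_frame or f > stop_frame:
            continue
        if vals[k:k + P].all() and np.all(np.diff(frames[k:k + P]) == 1):
            return float(f * frame_interval_s)
    return None


def score_decondensation(signals: pd.DataFrame, frame_interval_s: float):
    """Telophase / interphase onsets from the decondensation proxy ramp."""
    s = signals["decondensation"].to_numpy(dtype=float)
    if len(s) < 10:
        return None, None
    sm = pd.Series(s).rolling(5, center=True, min_periods=1).mean().to_numpy()
    lo_level = sm[:5].mean()
    hi_level = sm[-5:].mean()
    if hi_level - lo_level < 0.5:
        return None, None
    # fit the central part of the ramp, extrapolate to the two plateaus
    above25 = np.flatnonzero(sm > lo_level + 0.25 * (hi_level - lo_level))
    above75 = np.flatnonzero(sm > lo_level + 0.75 * (hi_level - lo_level))
    if above25.size == 0 or above75.size == 0:
        return None, None
    i25, i75 = above25[0], above75[0]
    if i75 - i25 < 3:
        i25, i75 = max(0, i25 - 2), min(len(sm) - 1, i75 + 2)
    frames = np.arange(i25, i75 + 1)
    slope, intercept = np.polyfit(frames, sm[frames], 1)
    if slope <= 0:
        return None, None
    f_telo = (lo_level - intercept) / slope
    f_inter = (hi_level - intercept) / slope
    n = len(sm)
    f_telo = min(max(f_telo, 0.0), n - 1)
    f_inter = min(max(f_inter, f_telo + 1.0), n - 1)
    return (float(f_telo * frame_interval_s),
            float(f_inter * frame_interval_s))


def score_phases(trackset: TrackSet, signals: pd.DataFrame,
                 cfg: AnalysisConfig, frame_interval_s: float):
    """Score all division-phase boundaries of one cell.

    Requires paired tracks.  Returns ``(PhaseAnnotation, artifacts)``
    where artifacts holds the spindle frame, the kinematics table and
    the thresholds used.
    """
    dt = frame_interval_s
    boundaries = {k: None for k in BOUNDARY_ORDER}
    methods = {k: "unscored" for k in BOUNDARY_ORDER}

    t_nebd = score_nebd(signals, dt)
    if t_nebd is not None:
        boundaries["nebd"] = t_nebd
        methods["nebd"] = "signal"
    nebd_idx = int(round((t_nebd or 0.0) / dt))

    t_jump, thr = score_jump_onset(trackset, nebd_idx, cfg, dt)
    if t_jump is not None:
        boundaries["prometaphase_b_onset"] = t_jump
        methods["prometaphase_b_onset"] = "kinematics"

    kin0 = pair_kinematics(trackset, None, dt)
    t_ana = score_anaphase(kin0, cfg, dt) if len(kin0) else None
    ana_idx = None
    if t_ana is not None:
        boundaries["anaphase_onset"] = t_ana
        methods["anaphase_onset"] = "kinematics"
        ana_idx = int(round(t_ana / dt))

    t_telo, t_inter = score_decondensation(signals, dt)

    spindle = None
    try:
        if ana_idx is not None:
            spindle = estimate_spindle_axis(
                trackset, (max(0, ana_idx - cfg.spindle_window_frames),
                           ana_idx),
                anaphase_frame=ana_idx, n_frames_avg=cfg.spindle_window_frames)
        else:
            # no anaphase: axis from the KT position cloud, plate centre
            # from the metaphase-like period before the inferred m/a
            last = max(tr.frames[-1] for tr in trackset.tracks)
            lo = int(round((boundaries["prometaphase_b_onset"]
                            or boundaries["nebd"] or 0.0) / dt))
            if t_telo is not None:
                hi = int(round(t_telo / dt))
                center_win = (max(lo, hi - int(cfg.ma_offset_min * 60 / dt)
                                  - 30), max(lo + 1, hi - 30))
            else:
                hi = last
                center_win = (max(0, last - cfg.spindle_window_frames), last)
            spindle = estimate_spindle_axis_from_positions(
                trackset, (lo, hi), center_window=center_win)
    except ValueError:
        spindle = None

    kin = pair_kinematics(trackset, spindle, dt)
    if spindle is not None and len(kin):
        centers_axial = {}
        for pid, pair_tracks in trackset.by_pair().items():
            if len(pair_tracks) != 2:
                continue
            t1, t2 = pair_tracks
            common = np.intersect1d(t1.frames, t2.frames)
            c = 0.5 * (t1.positions[np.searchsorted(t1.frames, common)]
                       + t2.positions[np.searchsorted(t2.frames, common)])
            centers_axial[pid] = pd.Series(
                spindle.axial_coordinate(c), index=common)
        start = int(round((t_jump or (t_nebd or 0.0)) / dt))
        stop = (ana_idx - cfg.persistence_frames) if ana_idx is not None \
            else max(tr.frames[-1] for tr in trackset.tracks)
        t_meta = score_metaphase_onset(kin, centers_axial, cfg, dt, start, stop)
        if t_meta is not None:
            boundaries["metaphase_onset"] = t_meta
            methods["metaphase_onset"] = "kinematics"

    if t_telo is not None:
        boundaries["telophase_onset"] = t_telo
        methods["telophase_onset"] = "signal"
        boundaries["interphase_onset"] = t_inter
        methods["interphase_onset"] = "signal"

    # enforce monotonicity: un-score any boundary breaking the order
    prev = None
    for k in BOUNDARY_ORDER:
        v = boundaries[k]
        if v is None:
            continue
        if prev is not None and v <= prev:
            boundaries[k] = None
            methods[k] = "unscored"
        else:
            prev = v
    ann = PhaseAnnotation(boundaries_s=boundaries, methods=methods)
    artifacts = {"spindle": spindle, "kinematics": kin,
                 "jump_threshold_um_s": thr}
    return ann, artifacts


# ---------------------------------------------------------------------------
# events


def detect_excursions(positions_um: np.ndarray, times_s: np.ndarray,
                      spindle: SpindleFrame, cfg: AnalysisConfig,
                      subject_id: int = 0):
    """Count completed polar<->equatorial transits of one (pair) track."""
    plate_half = cfg.plate_width_um / 2.0
    half_l = cfg.pole_distance_um / 2.0
    polar_inner = half_l * (1.0 - 2.0 * cfg.polar_zone_fraction)
    s_ax = spindle.axial_coordinate(positions_um)
    count, transits = count_zone_transits(s_ax, plate_half, polar_inner)
    events = [EventRecord(kind="excursion", subject_id=subject_id,
                          t_start_s=float(times_s[i0]),
                          t_end_s=float(times_s[i1]),
                          detail={"from_zone": int(z0), "to_zone": int(z1)})
              for (i0, i1, z0, z1) in transits]
    return count, events


def detect_reorientations(pair_tracks, spindle: SpindleFrame,
                          cfg: AnalysisConfig, frame_interval_s: float,
                          jump_thr_um_s: float,
                          window: Optional[tuple] = None):
    """Sign-alternating poleward jump pairs of the same KT.

    A jump is a supra-threshold speed run whose leading KT displaces by
    at least ``min_jump_displacement_um`` along the spindle axis and
    ends inside a polar zone; an event is emitted for each pair of
    consecutive poleward jumps of the same KT towards opposite poles.
    The ``transient_biorientation`` detail records whether the partner
    KT was displaced towards the opposite pole in between.
    """
    t1, t2 = sorted(pair_tracks, key=lambda t: t.track_id)
    common = np.intersect1d(t1.frames, t2.frames)
    p = {0: t1.positions[np.searchsorted(t1.frames, common)],
         1: t2.positions[np.searchsorted(t2.frames, common)]}
    if window is not None:
        sel = (common >= window[0]) & (common < window[1])
        common = common[sel]
        p = {k: v[sel] for k, v in p.items()}
    if common.size < 3:
        return []
    dt = np.diff(common) * frame_interval_s
    v = {k: np.linalg.norm(np.diff(p[k], axis=0), axis=1) / dt for k in p}
    supra = (v[0] > jump_thr_um_s) | (v[1] > jump_thr_um_s)
    half_l = cfg.pole_distance_um / 2.0
    polar_inner = half_l * (1.0 - 2.0 * cfg.polar_zone_fraction)
    s_ax = {k: spindle.axial_coordinate(p[k]) for k in p}

    # merge supra-threshold intervals separated by <= 1 quiet frame
    runs = []
    i = 0
    n = len(supra)
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and (supra[j + 1] or (j + 2 < n and supra[j + 2])):
            j += 1
        runs.append((i, j + 1))  # sample indices [i, j+1]
        i = j + 2

    s_center = 0.5 * (s_ax[0] + s_ax[1])
    jumps = []  # (kt, sign, start_idx, end_idx)
    for (i0, i1) in runs:
        # leading KT: highest peak speed within the run
        peak = {k: np.nanmax(v[k][i0:i1]) for k in p}
        leader = 0 if peak[0] >= peak[1] else 1
        j1 = min(i1 + 1, len(s_center) - 1)  # settled post-jump position
        d_ax = s_center[j1] - s_center[i0]
        if abs(d_ax) < cfg.min_jump_displacement_um:
            continue
        # destination zone judged on the pair centre (a KT's own offset
        # from the centre would blur the polar-zone test)
        if abs(s_center[j1]) < polar_inner:
            continue
        jumps.append((leader, 1 if s_center[j1] > 0 else -1, i0, i1))

    events = []
    last = {}  # kt -> (sign, start_idx, end_idx)
    for (kt, sign, i0, i1) in jumps:
        if kt in last and last[kt][0] == -sign:
            prev_sign, prev_i0, prev_i1 = last[kt]
            partner = 1 - kt
            d_partner = s_ax[partner][i0] - s_ax[partner][prev_i1]
            trans_bi = bool(abs(d_partner) > 0.5
                            and np.sign(d_partner) == -prev_sign)
            events.append(EventRecord(
                kind="reorientation", subject_id=kt,
                t_start_s=float(common[prev_i0] * frame_interval_s),
                t_end_s=float(common[i1] * frame_interval_s),
                detail={"pole_signs": (prev_sign, sign),
                        "transient_biorientation": trans_bi}))
        last[kt] = (sign, i0, i1)
    return events


def detect_breathing(estimates: dict, frame_interval_s: float,
                     min_frames: int = 2):
    """Detect transient sister-dot splitting events and their rate.

    ``estimates`` maps dot id to a DataFrame with columns ``frame``,
    ``resolved`` and ``distance_nm`` (per-frame pair separation
    estimates of a nominally single dot).  An event is a maximal run of
    at least ``min_frames`` consecutive resolved frames.  The rate is
    events per dot per observed hour.
    """
    if frame_interval_s is None or frame_interval_s <= 0:
        raise ValueError("frame interval (cadence) required to define the rate")
    events = []
    dot_hours = 0.0
    for dot_id in sorted(estimates):
        df = estimates[dot_id].sort_values("frame")
        frames = df["frame"].to_numpy()
        res = df["resolved"].to_numpy(dtype=bool)
        dist = df["distance_nm"].to_numpy(dtype=float)
        dot_hours += len(frames) * frame_interval_s / 3600.0
        i = 0
        while i < len(res):
            if not res[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(res) and res[j + 1] \
                    and frames[j + 1] == frames[j] + 1:
                j += 1
            if j - i + 1 >= min_frames:
                events.append(EventRecord(
                    kind="breathing", subject_id=int(dot_id),
                    t_start_s=float(frames[i] * frame_interval_s),
                    t_end_s=float((frames[j] + 1) * frame_interval_s),
                    magnitude=float(np.nanmax(dist[i:j + 1]))))
            i = j + 1
    rate = len(events) / dot_hours if dot_hours > 0 else np.nan
    return events, rate


def classify_univalents(univalent_series: dict, phases: PhaseAnnotation,
                        spindle: SpindleFrame, cfg: AnalysisConfig,
                        frame_interval_s: float):
    """Classify univalents into classes I / II / III.

    ``univalent_series`` maps pair id to a DataFrame with columns
    ``frame``, ``sep_nm`` (sister separation) and ``axial_um``
    (projected pair-centre coordinate).  The metaphase-to-anaphase
    transition is inferred as telophase onset minus ``ma_offset_min``;
    class I requires plate residency plus a sister-splitting event at or
    after the inferred m/a, class III a poleward departure before it,
    class II is the plate-resident never-resolved remainder.
    """
    t_telo = phases.boundaries_s.get("telophase_onset")
    if t_telo is None:
        raise ValueError(
            "telophase onset unscored: cannot anchor the inferred m/a "
            "transition")
    t_ma = t_telo - cfg.ma_offset_min * 60.0
    t_meta = phases.boundaries_s.get("metaphase_onset")
    if t_meta is None:
        t_meta = phases.boundaries_s.get("prometaphase_b_onset") or 0.0
    plate_half = cfg.plate_width_um / 2.0
    half_l = cfg.pole_distance_um / 2.0
    polar_inner = half_l * (1.0 - 2.0 * cfg.polar_zone_fraction)

    out = []
    for pid in sorted(univalent_series):
        df = univalent_series[pid].sort_values("frame")
        t = df["frame"].to_numpy() * frame_interval_s
        sep = df["sep_nm"].to_numpy(dtype=float)
        ax = df["axial_um"].to_numpy(dtype=float)

        win = (t >= t_meta) & (t < t_ma)
        residency = float(np.mean(np.abs(ax[win]) <= plate_half)) \
            if win.any() else 0.0

        # splitting events: sustained separation above the split threshold
        split_starts = []
        above = sep >= cfg.split_threshold_nm
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if j - i + 1 >= 2:
                split_starts.append(float(t[i]))
            i = j + 1
        split_start = split_starts[0] if split_starts else None
        split_at_ma = next((s for s in split_starts if s >= t_ma - 120.0),
                           None)

        # poleward departure: enters a polar zone before m/a and stays
        departure = None
        polar = np.abs(ax) >= polar_inner
        cand = np.flatnonzero(polar & (t < t_ma) & (t >= t_meta))
        for i in cand:
            rest = polar[i:][t[i:] < t_ma]
            if rest.mean() > 0.9:
                departure = float(t[i])
                break

        max_sep = float(np.nanmax(sep)) if len(sep) else 0.0
        evidence = {"plate_residency": residency,
                    "split_start_s": split_start,
                    "split_at_ma_s": split_at_ma,
                    "max_separation_nm": max_sep,
                    "departure_s": departure,
                    "inferred_ma_s": t_ma}
        if residency >= cfg.plate_residency_min and split_at_ma is not None:
            label = "I"
        elif departure is not None and not split_starts:
            label = "III"
        else:
            label = "II"
        out.append(UnivalentClassification(pair_id=int(pid), label=label,
                                           evidence=evidence))
    return out


# ---------------------------------------------------------------------------
# genotype summary


def summarize_genotypes(cells):
    """Per-genotype summary tables from a list of analyzed cells.

    ``cells`` is a list of :class:`meiotrack.pipeline.CellResult`.
    Returns a dict of DataFrames: ``durations``, ``excursions``,
    ``breathing``, ``univalent_classes`` and ``mii_separation``.
    """
    if not cells:
        raise ValueError("summarize_genotypes requires at least one cell")
    dur_rows, exc_rows, br_rows, cls_rows, sep_rows = [], [], [], [], []
    for c in cells:
        g = c.genotype
        b = c.phases.boundaries_s if c.phases is not None else {}
        spans = {
            "division": c.phases.division_duration_min if c.phases else None,
            "prometaphase_a": c.phases.interval_min(
                "nebd", "prometaphase_b_onset") if c.phases else None,
            "prometaphase_b": c.phases.interval_min(
                "prometaphase_b_onset", "metaphase_onset") if c.phases else None,
            "metaphase": c.phases.interval_min(
                "metaphase_onset", "anaphase_onset") if c.phases else None,
            "entry": c.phases.entry_duration_min if c.phases else None,
        }
        for phase, val in spans.items():
            if val is not None:
                dur_rows.append((g, c.division, phase, val))
        for pid, n in (c.excursion_counts or {}).items():
            exc_rows.append((g, c.cell_id, pid, n))
        if c.breathing_rate is not None:
            br_events = [e for e in c.events if e.kind == "breathing"]
            br_rows.append((g, c.cell_id, len(br_events), c.breathing_rate,
                            np.mean([e.t_end_s - e.t_start_s
                                     for e in br_events]) if br_events else np.nan,
                            np.mean([e.magnitude for e in br_events])
                            if br_events else np.nan))
        for u in (c.univalent_classes or []):
            cls_rows.append((g, c.cell_id, u.pair_id, u.label))
        for (t_min, sep_nm) in (c.mii_separation or []):
            sep_rows.append((g, c.cell_id, t_min, sep_nm))

    durations = pd.DataFrame(dur_rows, columns=["genotype", "division",
                                                "phase", "minutes"])
    dur_summary = durations.groupby(["genotype", "division", "phase"])[
        "minutes"].agg(["mean", "std", "count"]).reset_index() \
        if len(durations) else durations
    excursions = pd.DataFrame(exc_rows, columns=["genotype", "cell_id",
                                                 "pair_id", "count"])
    exc_summary = excursions.groupby("genotype")["count"].agg(
        ["mean", "std", "count"]).reset_index() if len(exc_rows) else excursions
    breathing = pd.DataFrame(br_rows, columns=[
        "genotype", "cell_id", "n_events", "rate_per_dot_hour",
        "mean_duration_s", "mean_amplitude_nm"])
    classes = pd.DataFrame(cls_rows, columns=["genotype", "cell_id",
                                              "pair_id", "label"])
    if len(cls_rows):
        frac = classes.groupby("genotype")["label"].value_counts(
            normalize=True).rename("fraction").reset_index()
    else:
        frac = classes
    mii = pd.DataFrame(sep_rows, columns=["genotype", "cell_id",
                                          "t_min_post_nebd", "sep_nm"])
    mii_summary = mii.groupby(["genotype", "t_min_post_nebd"])["sep_nm"].agg(
        ["mean", "std", "count"]).reset_index() if len(sep_rows) else mii
    return {"durations": dur_summary, "durations_per_cell": durations,
            "excursions": exc_summary, "excursions_per_pair": excursions,
            "breathing": breathing, "univalent_classes": frac,
            "univalent_labels": classes, "mii_separation": mii_summary}


def render_report(tables: dict, thresholds: Optional[dict] = None) -> str:
    """Human-readable text report from summarize_genotypes output."""
    lines = ["meiotrack genotype summary", "=" * 26, ""]
    for name in ("durations", "excursions", "breathing",
                 "univalent_classes", "mii_separation"):
        df = tables.get(name)
        if df is None or not len(df):
            continue
        lines.append(f"[{name}]")
        lines.append(df.to_string(index=False))
        lines.append("")
    if thresholds:
        lines.append("[thresholds]")
        for k, v in sorted(thresholds.items()):
            lines.append(f"{k}: {v}")
        lines.append("")
    return "\n".join(lines)
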
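"""The three KT kinematic parameters and the spindle reference frame.

* ``V_KT`` -- per-frame speed of one KT: Euclidean 3D displacement over
  the frame interval (raw differencing; no smoothing by default).
* ``A_KT`` -- the unsigned acute angle (degrees, [0, 90]) between the
  axis connecting the two KTs of a pair and the spindle axis.
* ``D_KT`` -- the Euclidean 3D distance between the two KTs of a pair.

The spindle axis is estimated by averaging the per-frame unit KT-pair
vectors over a metaphase window (about 35 frames), with every vector's
origin chosen as the KT that migrates to the same reference pole during
anaphase; without anaphase information the first principal component of
the metaphase pair vectors is used, with arbitrary sign, and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .track import Track, TrackSet


@dataclass
class SpindleFrame:
    axis: np.ndarray          # unit vector
    poles: Optional[np.ndarray] = None   # (2, 3) um; poles[0] = origin pole
    origin_pole_sign: int = 1
    window: Optional[tuple] = None
    method: str = "anaphase_destination"
    plate_center: Optional[np.ndarray] = None  # used when poles unknown

    def __post_init__(self):
        n = np.linalg.norm(self.axis)
        if not np.isfinite(n) or n == 0:
            raise ValueError("spindle axis must be a finite nonzero vector")
        self.axis = np.asarray(self.axis, dtype=float) / n
        if self.poles is not None:
            self.poles = np.asarray(self.poles, dtype=float)
            if np.allclose(self.poles[0], self.poles[1]):
                raise ValueError("spindle poles must be distinct")

    @property
    def center(self) -> np.ndarray:
        if self.poles is not None:
            return self.poles.mean(axis=0)
        if self.plate_center is not None:
            return np.asarray(self.plate_center, dtype=float)
        return np.zeros(3)

    def axial_coordinate(self, positions_um: np.ndarray) -> np.ndarray:
        """Signed projection onto the axis relative to the plate centre."""
        return (np.atleast_2d(positions_um) - self.center) @ self.axis


def compute_vkt(track: Track, frame_interval_s: float,
                median3: bool = False) -> np.ndarray:
    """Per-interval speed series (um/s), length ``n_samples - 1``.

    Intervals touching gap-flagged samples give NaN, not zero.
    ``median3`` applies an optional 3-point median filter.
    """
    if track.n_samples < 2:
        raise ValueError("velocity requires at least two samples")
    dt = np.diff(track.frames) * frame_interval_s
    disp = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    v = disp / dt
    bad = track.gap_flags[:-1] | track.gap_flags[1:]
    v = np.where(bad, np.nan, v)
    if median3:
        pad = np.pad(v, 1, mode="edge")
        v = np.nanmedian(np.stack([pad[:-2], pad[1:-1], pad[2:]]), axis=0)
    return v


def compute_dkt(pos_a: np.ndarray, pos_b: np.ndarray) -> np.ndarray:
    """Within-pair 3D distance series (um); NaN where a position is missing."""
    pos_a = np.atleast_2d(pos_a)
    pos_b = np.atleast_2d(pos_b)
    return np.linalg.norm(pos_a - pos_b, axis=-1)


def compute_akt(pos_a: np.ndarray, pos_b: np.ndarray,
                spindle: SpindleFrame) -> np.ndarray:
    """Angle series (degrees, [0, 90]) between pair axis and spindle axis.

    Coincident KT positions give NaN (angle undefined).
    """
    diff = np.atleast_2d(pos_a) - np.atleast_2d(pos_b)
    norm = np.linalg.norm(diff, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(diff @ spindle.axis) / norm
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return np.where(norm > 0, ang, np.nan)


def _pair_positions(pair_tracks):
    """Common frames and aligned positions for the two tracks of a pair."""
    t1, t2 = pair_tracks
    common = np.intersect1d(t1.frames, t2.frames)
    i1 = np.searchsorted(t1.frames, common)
    i2 = np.searchsorted(t2.frames, common)
    return common, t1.positions[i1], t2.positions[i2]


def anaphase_destinations(trackset: TrackSet, anaphase_frame: int):
    """Cluster KT end positions into the two anaphase destination poles.

    Returns ``(signs, axis, poles)``: per-track sign (+1 towards the
    reference pole, deterministically the pole reached by the
    lowest-id track), a pole-to-pole unit axis and the two pole
    positions (cluster means of late positions).
    """
    late = {}
    for tr in trackset.tracks:
        sel = tr.frames >= anaphase_frame + 6
        if not sel.any():
            sel = tr.frames >= tr.frames[-1] - 3
        late[tr.track_id] = tr.positions[sel].mean(axis=0)
    ids = sorted(late)
    pts = np.stack([late[i] for i in ids])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    if proj[0] < 0:  # reference pole = destination of the lowest-id track
        axis = -axis
        proj = -proj
    signs = {i: (1 if p >= 0 else -1) for i, p in zip(ids, proj)}
    pole_a = pts[proj >= 0].mean(axis=0)
    pole_b = pts[proj < 0].mean(axis=0)
    return signs, axis / np.linalg.norm(axis), np.stack([pole_a, pole_b])


def estimate_spindle_axis(trackset: TrackSet, metaphase_window: tuple,
                          anaphase_frame: Optional[int] = None,
                          n_frames_avg: int = 35) -> SpindleFrame:
    """Estimate the spindle axis from paired metaphase KT vectors.

    ``metaphase_window`` is a (frame_lo, frame_hi) range inside
    metaphase; the last ``n_frames_avg`` frames of the window are
    averaged (about 35 frames).  Orientation follows the
    anaphase-destination convention when ``anaphase_frame`` is given;
    otherwise the PCA fallback with arbitrary sign is used and flagged
    in ``method``.
    """
    pairs = trackset.by_pair()
    if not pairs:
        raise ValueError("spindle axis estimation requires paired tracks")
    lo, hi = metaphase_window
    max_frame = max(tr.frames[-1] for tr in trackset.tracks)
    if lo > max_frame or hi <= 0 or hi <= lo:
        raise ValueError("metaphase window outside available frames")
    if hi - lo < 5:
        raise ValueError("metaphase window must span at least 5 frames")
    lo = max(lo, hi - n_frames_avg)

    signs = axis0 = poles = None
    if anaphase_frame is not None:
        signs, axis0, poles = anaphase_destinations(trackset, anaphase_frame)

    vecs = []
    for pid, pair_tracks in pairs.items():
        if len(pair_tracks) != 2:
            continue
        t1, t2 = pair_tracks
        common, p1, p2 = _pair_positions(pair_tracks)
        sel = (common >= lo) & (common < hi)
        if not sel.any():
            continue
        v = p1[sel] - p2[sel]
        if signs is not None and signs[t1.track_id] < 0:
            v = -v  # origin at the KT migrating to the reference pole
        norms = np.linalg.norm(v, axis=1)
        vecs.append(v[norms > 0] / norms[norms > 0, None])
    if not vecs:
        raise ValueError("no pair vectors inside the metaphase window")
    allv = np.concatenate(vecs)

    if signs is None:
        # PCA fallback, arbitrary sign
        _, _, vt = np.linalg.svd(allv - 0.0, full_matrices=False)
        axis = vt[0]
        return SpindleFrame(axis=axis, window=(lo, hi), method="pca_unsigned")
    mean_v = allv.mean(axis=0)
    if np.linalg.norm(mean_v) < 1e-9:
        mean_v = axis0
    return SpindleFrame(axis=mean_v, poles=poles, window=(lo, hi),
                        method="anaphase_destination")


def estimate_spindle_axis_from_positions(trackset: TrackSet, window: tuple,
                                         center_window: Optional[tuple]
                                         = None) -> SpindleFrame:
    """Spindle axis from the KT position cloud (sign-free fallback).

    When no anaphase is available and within-pair vectors are too short
    to carry direction (conjoined sister dots), the dominant principal
    axis of all KT positions across ``window`` recovers the spindle
    axis: poleward excursions spread the cloud along it.  The plate
    centre is the per-frame median position over ``center_window`` (a
    period when most chromosomes sit in the plate band).
    """
    lo, hi = window
    pts = []
    for tr in trackset.tracks:
        sel = (tr.frames >= lo) & (tr.frames < hi)
        pts.append(tr.positions[sel])
    pts = np.concatenate(pts)
    if len(pts) < 10:
        raise ValueError("not enough samples for position-based axis")
    c_lo, c_hi = center_window if center_window is not None else window
    cpts = []
    for tr in trackset.tracks:
        sel = (tr.frames >= c_lo) & (tr.frames < c_hi)
        cpts.append(tr.positions[sel])
    cpts = np.concatenate(cpts) if cpts else pts
    center = np.median(cpts, axis=0)
    # far-from-plate samples (polar excursions) carry the axis; the long
    # plate-resident stretches only spread the cloud across the plate
    dist = np.linalg.norm(pts - center, axis=1)
    far = pts[dist >= 2.8]
    basis = far if len(far) >= 20 else pts
    _, _, vt = np.linalg.svd(basis - center, full_matrices=False)
    return SpindleFrame(axis=vt[0], window=(lo, hi),
                        method="position_pca_unsigned", plate_center=center)


def pair_kinematics(trackset: TrackSet, spindle: Optional[SpindleFrame],
                    frame_interval_s: float) -> pd.DataFrame:
    """Per-pair per-frame kinematics table.

    Columns: pair_id, frame, t_seconds, v_kt_a, v_kt_b (um/s, NaN at the
    first frame of each pair), a_kt_deg, d_kt_um.  A_KT requires a
    spindle frame and is NaN otherwise.
    """
    rows = []
    for pid, pair_tracks in sorted(trackset.by_pair().items()):
        if len(pair_tracks) != 2:
            continue
        t1, t2 = sorted(pair_tracks, key=lambda t: t.track_id)
        common, p1, p2 = _pair_positions(pair_tracks)
        if common.size < 2:
            continue
        d = compute_dkt(p1, p2)
        a = compute_akt(p1, p2, spindle) if spindle is not None \
            else np.full(common.size, np.nan)
        dt = np.diff(common) * frame_interval_s
        v1 = np.concatenate([[np.nan],
                             np.linalg.norm(np.diff(p1, axis=0), axis=1) / dt])
        v2 = np.concatenate([[np.nan],
                             np.linalg.norm(np.diff(p2, axis=0), axis=1) / dt])
        for k in range(common.size):
            rows.append((pid, int(common[k]), common[k] * frame_interval_s,
                         v1[k], v2[k], a[k], d[k]))
    return pd.DataFrame(rows, columns=[
        "pair_id", "frame", "t_seconds", "v_kt_a", "v_kt_b", "a_kt_deg",
        "d_kt_um"])
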
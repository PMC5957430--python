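"""Frame-to-frame linking of KT spots and sister/homolog pair assignment.

Linking uses a constant-velocity motion model (a stand-in for the
autoregressive tracking of the original commercial workflow): each
active track predicts its next position, predictions are matched to
detections by a global minimum-cost assignment gated by a search
radius, and tracks coast over gaps of up to a configured number of
frames (default 3, as unresolvable stretches last usually for less
than four time points); gap-closed samples are interpolated and
flagged.

Pairing minimizes the summed mean within-pair distance over a
prometaphase--metaphase window under a perfect-matching constraint and
is validated, when phase annotations are available, by anaphase
divergence of the paired tracks towards opposite poles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class Track:
    track_id: int
    frames: np.ndarray
    positions: np.ndarray  # (n, 3) um
    gap_flags: np.ndarray
    pair_id: Optional[int] = None

    def __post_init__(self):
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.frames)

    def position_at(self, frame: int):
        idx = np.searchsorted(self.frames, frame)
        if idx < len(self.frames) and self.frames[idx] == frame:
            return self.positions[idx]
        return None


@dataclass
class TrackSet:
    tracks: list
    frame_interval_s: float
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        # no two tracks may claim the same spot in any frame
        seen = {}
        for tr in self.tracks:
            for f, p, g in zip(tr.frames, tr.positions, tr.gap_flags):
                if g:
                    continue
                key = (int(f), round(p[0], 6), round(p[1], 6), round(p[2], 6))
                if key in seen:
                    raise ValueError(
                        f"tracks {seen[key]} and {tr.track_id} claim the same "
                        f"spot in frame {f}")
                seen[key] = tr.track_id

    def __len__(self):
        return len(self.tracks)

    def by_pair(self) -> dict:
        out = {}
        for tr in self.tracks:
            if tr.pair_id is not None:
                out.setdefault(tr.pair_id, []).append(tr)
        return out

    def to_dataframe(self, cell_id: int = 0) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for f, p, g in zip(tr.frames, tr.positions, tr.gap_flags):
                rows.append((cell_id, tr.track_id,
                             -1 if tr.pair_id is None else tr.pair_id,
                             int(f), f * self.frame_interval_s,
                             p[0], p[1], p[2], bool(g)))
        return pd.DataFrame(rows, columns=[
            "cell_id", "track_id", "pair_id", "frame", "t_seconds",
            "x_um", "y_um", "z_um", "gap_flag"])


class _ActiveTrack:
    __slots__ = ("tid", "frames", "positions", "gaps", "missed")

    def __init__(self, tid, frame, pos):
        self.tid = tid
        self.frames = [frame]
        self.positions = [np.asarray(pos, dtype=float)]
        self.gaps = [False]
        self.missed = 0

    def predict(self, frame):
        if len(self.positions) >= 2:
            v = (self.positions[-1] - self.positions[-2]) / max(
                self.frames[-1] - self.frames[-2], 1)
            return self.positions[-1] + v * (frame - self.frames[-1])
        return self.positions[-1]

    def extend(self, frame, pos):
        prev_f = self.frames[-1]
        if frame > prev_f + 1:  # close the gap by linear interpolation
            prev_p = self.positions[-1]
            for f in range(prev_f + 1, frame):
                w = (f - prev_f) / (frame - prev_f)
                self.frames.append(f)
                self.positions.append(prev_p + w * (np.asarray(pos) - prev_p))
                self.gaps.append(True)
        self.frames.append(frame)
        self.positions.append(np.asarray(pos, dtype=float))
        self.gaps.append(False)
        self.missed = 0


def link_spots(spots_per_frame, frame_interval_s: float,
               search_radius_um: float = 1.8, max_gap: int = 3) -> TrackSet:
    """Link per-frame detections into tracks.

    ``spots_per_frame`` maps frame index to an (n, 3) array of x/y/z um
    positions (or a list of objects with ``position_um``).  Ties are
    broken deterministically (global minimum-cost assignment; equal
    costs resolved by lower track id).
    """
    if search_radius_um <= 0:
        raise ValueError("search radius must be strictly positive")
    frames = sorted(spots_per_frame)
    if len(frames) < 2:
        raise ValueError("need detections in at least two frames")

    def coords(f):
        items = spots_per_frame[f]
        if len(items) == 0:
            return np.empty((0, 3))
        if hasattr(items[0], "position_um"):
            return np.stack([s.position_um for s in items])
        return np.atleast_2d(np.asarray(items, dtype=float))

    active: list[_ActiveTrack] = []
    done: list[_ActiveTrack] = []
    next_id = 0
    for f in frames:
        det = coords(f)
        preds = np.stack([tr.predict(f) for tr in active]) if active \
            else np.empty((0, 3))
        n_tr, n_det = len(active), len(det)
        assigned_det = np.zeros(n_det, dtype=bool)
        assigned_tr = np.zeros(n_tr, dtype=bool)
        if n_tr and n_det:
            cost = np.linalg.norm(preds[:, None] - det[None, :], axis=-1)
            gate = np.array([search_radius_um * (tr.missed + 1)
                             for tr in active])
            big = 1e6
            gated = np.where(cost <= gate[:, None], cost, big)
            rows, cols = linear_sum_assignment(gated)
            for r, c in zip(rows, cols):
                if gated[r, c] >= big:
                    continue
                active[r].extend(f, det[c])
                assigned_det[c] = True
                assigned_tr[r] = True
        still = []
        for i, tr in enumerate(active):
            if assigned_tr[i]:
                still.append(tr)
            else:
                tr.missed += 1
                if tr.missed > max_gap:
                    done.append(tr)
                else:
                    still.append(tr)
        active = still
        for c in np.flatnonzero(~assigned_det):
            active.append(_ActiveTrack(next_id, f, det[c]))
            next_id += 1
    done.extend(active)
    done.sort(key=lambda tr: tr.tid)
    tracks = [Track(track_id=tr.tid, frames=np.asarray(tr.frames),
                    positions=np.stack(tr.positions),
                    gap_flags=np.asarray(tr.gaps)) for tr in done]
    return TrackSet(tracks=tracks, frame_interval_s=frame_interval_s)


# ---------------------------------------------------------------------------
# pair assignment


def _mean_pair_distance(t1: Track, t2: Track, frame_lo, frame_hi):
    common = np.intersect1d(t1.frames, t2.frames)
    common = common[(common >= frame_lo) & (common < frame_hi)]
    if common.size == 0:
        return np.inf
    i1 = np.searchsorted(t1.frames, common)
    i2 = np.searchsorted(t2.frames, common)
    return float(np.mean(np.linalg.norm(
        t1.positions[i1] - t2.positions[i2], axis=1)))


def enumerate_matchings(items):
    """All perfect matchings of an even-sized list (105 for 8 items)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for i, other in enumerate(rest):
        remaining = rest[:i] + rest[i + 1:]
        for sub in enumerate_matchings(remaining):
            yield [(first, other)] + sub


def assign_pairs(trackset: TrackSet, window=None, ground_truth=None,
                 expected_count: Optional[int] = None,
                 anaphase_frame: Optional[int] = None,
                 ambiguity_tol: float = 0.05) -> TrackSet:
    """Assign pair ids to tracks.

    In evaluation mode (``ground_truth`` is a kt_id->pair_id mapping and
    track ids coincide with KT ids) the simulator's pairing is copied.
    Otherwise pairing minimizes the summed mean within-pair distance
    over ``window = (frame_lo, frame_hi)`` (prometaphase--metaphase)
    under a perfect-matching constraint; near-ties within
    ``ambiguity_tol`` (relative) are flagged as warnings, and if
    ``anaphase_frame`` is given, paired tracks must diverge after it.
    """
    tracks = trackset.tracks
    if ground_truth is not None:
        for tr in tracks:
            tr.pair_id = int(ground_truth[tr.track_id])
        return trackset
    n = len(tracks)
    if expected_count is not None and n != expected_count:
        raise ValueError(
            f"expected {expected_count} tracks, got {n} "
            f"({expected_count - n} missing)")
    if n % 2:
        raise ValueError(f"cannot pair an odd number of tracks ({n})")
    if window is None:
        lo, hi = 0, max(tr.frames[-1] for tr in tracks) + 1
    else:
        lo, hi = window
    dist = {}
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            d = _mean_pair_distance(tracks[i], tracks[j], lo, hi)
            dist[(i, j)] = d
            g.add_edge(i, j, weight=d)
    matching = nx.min_weight_matching(g)
    matching = sorted(tuple(sorted(e)) for e in matching)

    # ambiguity: compare against the runner-up over all perfect matchings
    flagged = set()
    if n <= 10:
        costs = []
        for m in enumerate_matchings(list(range(n))):
            key = tuple(sorted(tuple(sorted(e)) for e in m))
            costs.append((sum(dist[e] for e in key), key))
        costs.sort()
        best_cost, best_key = costs[0]
        if len(costs) > 1:
            second_cost, second_key = costs[1]
            if best_cost > 0 and (second_cost - best_cost) / best_cost \
                    < ambiguity_tol:
                flagged = set(best_key) ^ set(second_key)
                trackset.warnings.append(
                    "ambiguous pairing: runner-up matching within "
                    f"{ambiguity_tol:.0%} on pairs {sorted(flagged)}")

    for pid, (i, j) in enumerate(matching):
        tracks[i].pair_id = pid
        tracks[j].pair_id = pid

    if anaphase_frame is not None:
        for (i, j) in matching:
            d_end = _mean_pair_distance(tracks[i], tracks[j],
                                        anaphase_frame + 6, hi)
            d_start = dist[(i, j)]
            if np.isfinite(d_end) and d_end < d_start:
                trackset.warnings.append(
                    f"pair ({i},{j}) does not diverge after anaphase")
    return trackset


def tracks_from_table(df: pd.DataFrame, frame_interval_s: float) -> TrackSet:
    """Build a TrackSet from a track table (track_id or kt_id keyed)."""
    key = "track_id" if "track_id" in df.columns else "kt_id"
    tracks = []
    for tid, sub in df.groupby(key):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            bad = int(np.flatnonzero(np.diff(frames) <= 0)[0])
            raise ValueError(
                f"non-monotone frames for track {tid} at row {sub.index[bad + 1]}")
        gap = sub["gap_flag"].to_numpy(dtype=bool) if "gap_flag" in sub \
            else np.zeros(len(sub), dtype=bool)
        pair = None
        if "pair_id" in sub.columns:
            pv = sub["pair_id"].iloc[0]
            pair = None if pd.isna(pv) or pv < 0 else int(pv)
        tracks.append(Track(
            track_id=int(tid), frames=frames,
            positions=sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            gap_flags=gap, pair_id=pair))
    return TrackSet(tracks=tracks, frame_interval_s=frame_interval_s)
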
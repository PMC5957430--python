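"""Readers/writers for track tables, ground truth, events and manifests.

All tabular interchange uses CSV with explicit units in the headers;
ground truth, phase annotations and event records round-trip through
JSON; configuration through YAML.  Every pipeline run writes a manifest
(config snapshot, seeds, package version, per-file SHA-256 digests,
timestamps) sufficient to re-run deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ("cell_id", "kt_id", "pair_id", "frame", "t_seconds",
                      "x_um", "y_um", "z_um")
TRACK_COLUMNS = ("cell_id", "track_id", "pair_id", "frame", "t_seconds",
                 "x_um", "y_um", "z_um", "gap_flag")
SPOT_COLUMNS = ("cell_id", "frame", "x_um", "y_um", "z_um", "intensity",
                "elongation")


def write_trajectories_csv(bundles, path) -> None:
    """Write one combined trajectory CSV for a list of bundles."""
    df = pd.concat([b.positions for b in bundles], ignore_index=True)
    df.to_csv(path, index=False)


def write_signals_csv(bundles, path) -> None:
    rows = []
    for b in bundles:
        s = b.signals.copy()
        s.insert(0, "cell_id", b.cell_id)
        rows.append(s)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_track_table(path, kind: str = "trajectory") -> pd.DataFrame:
    """Read and validate a trajectory or track CSV.

    Raises ValueError naming the first missing column or the first row
    with non-monotone frames within a track.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = TRAJECTORY_COLUMNS if kind == "trajectory" else TRACK_COLUMNS
    for col in required:
        if col not in df.columns:
            raise ValueError(f"track table {path}: missing column {col!r}")
    key = "kt_id" if kind == "trajectory" else "track_id"
    for (cell, tid), sub in df.groupby(["cell_id", key]):
        frames = sub["frame"].to_numpy()
        bad = np.flatnonzero(np.diff(frames) <= 0)
        if bad.size:
            row = int(sub.index[bad[0] + 1])
            raise ValueError(
                f"track table {path}: non-monotone frame for cell {cell} "
                f"{key} {tid} at row {row}")
    return df


def write_ground_truth_json(gts, path) -> None:
    payload = {str(i): gt.to_json_dict() for i, gt in enumerate(gts)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def phases_to_dict(result) -> dict:
    out = {
        "cell_id": result.cell_id,
        "genotype": result.genotype,
        "division": result.division,
        "boundaries_s": result.phases.boundaries_s if result.phases else None,
        "methods": result.phases.methods if result.phases else None,
        "jump_threshold_um_s": result.jump_threshold_um_s,
        "spindle_axis": None if result.spindle is None
        else [float(x) for x in result.spindle.axis],
        "spindle_method": None if result.spindle is None
        else result.spindle.method,
        "excursion_counts": {str(k): int(v)
                             for k, v in result.excursion_counts.items()},
        "events": [dataclasses.asdict(e) for e in result.events],
        "breathing_rate": result.breathing_rate,
        "univalent_classes": None if result.univalent_classes is None
        else [{"pair_id": u.pair_id, "label": u.label,
               "evidence": u.evidence} for u in result.univalent_classes],
        "mii_separation": result.mii_separation,
        "warnings": result.warnings,
    }
    return out


def write_results_json(results, path) -> None:
    with open(path, "w") as fh:
        json.dump([phases_to_dict(r) for r in results], fh, indent=1,
                  default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config_snapshot: dict, seed, files,
                   stage: str) -> Path:
    """Write a run manifest listing output digests and the exact config."""
    from . import __version__
    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "package": "meiotrack",
        "version": __version__,
        "seed": seed,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": config_snapshot,
        "outputs": {str(Path(f).name): sha256_of(f) for f in files},
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)
    return path
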
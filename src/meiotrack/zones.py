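"""Spindle-axis zone geometry shared by the simulator and event scoring.

Positions projected onto the spindle axis (plate centre at 0) are
partitioned into an equatorial band (the metaphase plate, default 3 um
wide), two polar zones (the outer quarter of each half axis) and the
unlabelled region in between.  An excursion is one completed transit
between the equatorial and a polar zone; entering the intermediate
region does not reset the transit.
"""

from __future__ import annotations

import numpy as np

EQUATORIAL = 1
POLAR = 2
NEITHER = 0


def zone_labels(s_axial: np.ndarray, plate_half_um: float,
                polar_inner_um: float) -> np.ndarray:
    """Label axial coordinates: 1 equatorial, 2 polar, 0 neither."""
    s = np.asarray(s_axial, dtype=float)
    if plate_half_um >= polar_inner_um:
        raise ValueError(
            "equatorial band and polar zone overlap: plate half-width "
            f"{plate_half_um} um >= polar inner edge {polar_inner_um} um")
    lab = np.zeros(s.shape, dtype=int)
    lab[np.abs(s) <= plate_half_um] = EQUATORIAL
    lab[np.abs(s) >= polar_inner_um] = POLAR
    return lab


def count_zone_transits(s_axial: np.ndarray, plate_half_um: float,
                        polar_inner_um: float):
    """Count completed polar<->equatorial transits along a projected track.

    Returns ``(count, transits)`` where each transit is a tuple
    ``(start_index, end_index, from_zone, to_zone)``; ``start_index`` is
    the last sample inside the origin zone and ``end_index`` the first
    sample inside the destination zone.
    """
    lab = zone_labels(s_axial, plate_half_um, polar_inner_um)
    transits = []
    last_zone = NEITHER
    last_idx = -1
    for i, z in enumerate(lab):
        if z == NEITHER:
            continue
        if last_zone != NEITHER and z != last_zone:
            transits.append((last_idx, i, last_zone, z))
        last_zone = z
        last_idx = i
    return len(transits), transits
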
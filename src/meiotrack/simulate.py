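"""Ground-truth kinetochore trajectory simulation.

A phase-switched stochastic model generates per-frame 3D positions for
the kinetochores (KTs) of a spermatocyte progressing through one meiotic
division (M I or M II) or through interkinesis (IK):

* prometaphase A -- concerted slow drift of all KT pairs with
  Ornstein-Uhlenbeck-like jitter, before any KT-MT interaction;
* prometaphase B -- Poisson-scheduled ballistic poleward jumps of one
  KT, partially followed by its partner, with excursions between the
  polar and equatorial zones, until each pair is captured and congresses
  into the metaphase plate band with its inter-KT axis aligned to the
  spindle axis;
* metaphase -- low-amplitude jitter around a plate slot;
* anaphase -- monotone separation of the two KTs of each pair towards
  opposite poles;
* telophase/interphase -- rest at the poles while a chromosome
  decondensation proxy signal ramps up.

Nuclear envelope breakdown (NEBD) is encoded in a diffuse nucleoplasmic
proxy signal that drops precipitously at the NEBD time.  All randomness
derives from a single integer seed; identical (config, seed) reproduce
identical outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import norm

from .config import SimulationConfig, PHASE_ORDER, default_phase_minutes
from .zones import count_zone_transits

UNIVALENT_CLASSES = ("I", "II", "III")


@dataclass
class BreathingEvent:
    dot_id: int
    t_start_s: float
    duration_s: float
    amplitude_nm: float


@dataclass
class GroundTruth:
    """Simulator oracle: true boundaries, positions, pairing and events."""

    division: str
    phase_boundaries_s: dict
    pairing: dict
    spindle_axis: Optional[np.ndarray]
    pole_positions: Optional[np.ndarray]
    kt_destination_sign: dict
    times_s: np.ndarray
    true_positions: np.ndarray  # (n_kt, n_frames, 3) um
    breathing_events: list = field(default_factory=list)
    excursion_counts: dict = field(default_factory=dict)
    reorientation_pairs: list = field(default_factory=list)
    univalent_classes: dict = field(default_factory=dict)
    pair_separations_nm: dict = field(default_factory=dict)

    def __post_init__(self):
        bounds = [v for v in self.phase_boundaries_s.values() if v is not None]
        order = [self.phase_boundaries_s[k] for k in _boundary_names(self.division)
                 if self.phase_boundaries_s.get(k) is not None]
        if any(b2 <= b1 for b1, b2 in zip(order, order[1:])):
            raise ValueError("phase boundaries must be strictly increasing")
        if bounds and (min(bounds) < 0 or max(bounds) > self.times_s[-1] + 1e-9):
            raise ValueError("phase boundaries must lie within the recording")
        for ev in self.breathing_events:
            if not (0 <= ev.t_start_s <= ev.t_start_s + ev.duration_s
                    <= self.times_s[-1] + 1e-9):
                raise ValueError("breathing event outside simulated interval")
        counts = np.bincount(np.fromiter(self.pairing.values(), dtype=int))
        if np.any(counts[counts > 0] != 2):
            raise ValueError("every KT must belong to exactly one pair of two")

    def to_json_dict(self) -> dict:
        return {
            "division": self.division,
            "phase_boundaries_s": self.phase_boundaries_s,
            "pairing": {str(k): int(v) for k, v in self.pairing.items()},
            "spindle_axis": None if self.spindle_axis is None
            else [float(x) for x in self.spindle_axis],
            "pole_positions": None if self.pole_positions is None
            else [[float(x) for x in p] for p in self.pole_positions],
            "kt_destination_sign": {str(k): int(v)
                                    for k, v in self.kt_destination_sign.items()},
            "breathing_events": [dataclasses.asdict(ev)
                                 for ev in self.breathing_events],
            "excursion_counts": {str(k): int(v)
                                 for k, v in self.excursion_counts.items()},
            "reorientation_pairs": [int(p) for p in self.reorientation_pairs],
            "univalent_classes": {str(k): v
                                  for k, v in self.univalent_classes.items()},
            "pair_separations_nm": self.pair_separations_nm,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


@dataclass
class TrajectoryBundle:
    """Observed output of one simulated cell.

    ``positions`` carries the exported track table (true positions plus
    configured localization noise); ``signals`` the per-frame
    nucleoplasmic and decondensation proxy channels.
    """

    cell_id: int
    positions: pd.DataFrame
    signals: pd.DataFrame
    frame_interval_s: float
    config: SimulationConfig


def _boundary_names(division: str):
    if division == "IK":
        return ("ik_start", "ik_end")
    return ("nebd", "prometaphase_b_onset", "metaphase_onset",
            "anaphase_onset", "telophase_onset", "interphase_onset")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _random_unit(rng, in_plane=False) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        if in_plane:
            v[2] = 0.0
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _ar1_noise(rng, n_frames: int, a: float, shape=(3,)) -> np.ndarray:
    """Stationary unit-variance AR(1) series, shape (n_frames, *shape)."""
    eps = rng.normal(size=(n_frames,) + shape)
    out = lfilter([np.sqrt(1 - a ** 2)], [1, -a], eps, axis=0)
    # start from the stationary distribution
    out[0] = rng.normal(size=shape)
    return out


class _PathBuilder:
    """Piecewise-linear anchor path for one pair centre."""

    def __init__(self, t0: float, p0: np.ndarray):
        self.knots_t = [t0]
        self.knots_p = [np.asarray(p0, dtype=float)]
        self.jumps = []  # (t_start, t_end, unit direction)

    @property
    def t_cur(self):
        return self.knots_t[-1]

    @property
    def p_cur(self):
        return self.knots_p[-1]

    def hold_until(self, t: float):
        if t > self.t_cur:
            self.knots_t.append(t)
            self.knots_p.append(self.p_cur.copy())

    def rewind_hold(self, t: float):
        """Shorten trailing dwells so the path is free from time ``t`` on."""
        while (len(self.knots_t) >= 2 and self.knots_t[-1] > t
               and np.array_equal(self.knots_p[-1], self.knots_p[-2])):
            if self.knots_t[-2] <= t:
                self.knots_t[-1] = t
                return
            self.knots_t.pop()
            self.knots_p.pop()

    def move_to(self, target: np.ndarray, speed: float, record_jump=True):
        target = np.asarray(target, dtype=float)
        dist = float(np.linalg.norm(target - self.p_cur))
        if dist < 1e-9:
            return self.t_cur
        t_arr = self.t_cur + dist / speed
        if record_jump:
            self.jumps.append((self.t_cur, t_arr, (target - self.p_cur) / dist))
        self.knots_t.append(t_arr)
        self.knots_p.append(target)
        return t_arr

    def sample(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(self.knots_t)
        p = np.stack(self.knots_p)
        out = np.empty((times.size, 3))
        for ax in range(3):
            out[:, ax] = np.interp(times, t, p[:, ax])
        return out


def _draw_phase_durations_s(config: SimulationConfig, rng,
                            overrides: Optional[dict] = None) -> dict:
    """Draw per-phase durations in seconds (floored at 20% of the mean)."""
    out = {}
    for phase, (mean, sd) in config.phase_minutes.items():
        if overrides is not None and phase in overrides:
            val = overrides[phase]
        else:
            val = rng.normal(mean, sd) if sd > 0 else mean
        out[phase] = max(0.2 * mean, val) * 60.0
    return out


def _sample_start_positions(rng, n: int, radius: float, min_dist: float):
    """Rejection-sample pair centres with a minimum mutual distance."""
    for _ in range(2000):
        pts = rng.uniform(-radius, radius, size=(8 * n, 3))
        pts = pts[np.linalg.norm(pts, axis=1) < radius]
        chosen = []
        for p in pts:
            if all(np.linalg.norm(p - q) >= min_dist for q in chosen):
                chosen.append(p)
            if len(chosen) == n:
                return np.stack(chosen)
    raise RuntimeError("could not place pair start positions")


def simulate_cell(config: SimulationConfig, seed: int,
                  phase_overrides: Optional[dict] = None,
                  cell_id: int = 0,
                  nebd_offset_s: float = 0.0):
    """Simulate one spermatocyte; returns ``(TrajectoryBundle, GroundTruth)``.

    ``phase_overrides`` maps phase name to an exact duration in minutes
    (used by :func:`simulate_cyst` for cyst-synchronized draws);
    ``nebd_offset_s`` shifts all boundaries by the cyst synchrony offset.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6b74]))
    if config.division == "IK":
        return _simulate_ik(config, rng, cell_id)
    return _simulate_division(config, rng, cell_id, phase_overrides,
                              nebd_offset_s)


def _simulate_division(config, rng, cell_id, phase_overrides, nebd_offset_s):
    dt = config.frame_interval_s
    geo, kin, sep = config.geometry, config.kinematics, config.separation
    durations = _draw_phase_durations_s(config, rng, phase_overrides)
    t_nebd = max(60.0, config.pre_nebd_min * 60.0 + nebd_offset_s)

    progression = config.progression_enabled
    if progression:
        t_b = t_nebd + durations["prometaphase_a"]
        t_m_target = t_b + durations["prometaphase_b"]
        t_a = t_m_target + durations["metaphase"]
        t_t = t_a + durations["anaphase"]
        t_i = t_t + durations["telophase"]
        t_end = t_i + config.tail_min * 60.0
    else:
        t_b = t_m_target = t_a = t_t = t_i = None
        t_end = t_nebd + 40.0 * 60.0
    n_frames = int(np.floor(t_end / dt)) + 1
    times = np.arange(n_frames) * dt

    n_pairs = 8 if config.univalent else 4
    axis = _random_unit(rng)
    half_l = geo.pole_distance_um / 2.0
    poles = np.stack([axis * half_l, -axis * half_l])
    plate_half = geo.plate_width_um / 2.0
    polar_inner = half_l * (1.0 - 2.0 * geo.polar_zone_fraction)

    starts = _sample_start_positions(rng, n_pairs, geo.nuclear_radius_um - 1.2,
                                     min_dist=3.2 if n_pairs <= 4 else 1.8)
    drift_dir = _random_unit(rng)
    drift_tau = 600.0

    v_jump = kin.jump_speed_um_s
    v_cong = kin.congression_speed_um_s or v_jump

    mii_like = config.division == "MII" or config.univalent

    # per-pair draws -------------------------------------------------
    pole_sign = rng.choice([-1, 1], size=n_pairs)       # preferred jump pole
    dest_sign = rng.choice([-1, 1], size=n_pairs)       # kt0 anaphase pole
    if config.univalent:
        classes = [UNIVALENT_CLASSES[i] for i in rng.choice(
            3, size=n_pairs, p=config.univalent_class_fractions)]
    else:
        classes = [None] * n_pairs

    if progression:
        # with tension-mediated stabilization pairs lock in as they
        # bi-orient; time-dependent stabilization (mnm/tef) locks all
        # pairs in close to the stabilization onset
        frac_lo = 0.3 if kin.tension_stabilization else 0.75
        stable = rng.uniform(t_b + frac_lo * (t_m_target - t_b), t_m_target,
                             size=n_pairs)
        stable[rng.integers(n_pairs)] = t_m_target  # last pair defines onset
    else:
        stable = np.full(n_pairs, np.inf)

    first_jumper = int(rng.integers(n_pairs)) if config.jumps_enabled else -1
    # the re-orienting pair needs the longest prometaphase-B budget
    reo_pair = (int(np.argmax(stable))
                if config.reorientations_per_cell > 0 and config.jumps_enabled
                and progression else -1)

    def polar_point(sign):
        perp = _random_unit(rng)
        perp -= perp @ axis * axis
        perp = _unit(perp) * rng.uniform(0.2, 1.4)
        return axis * sign * rng.uniform(polar_inner + 0.4, half_l - 0.9) + perp

    def plate_point(ax_max=1.0):
        perp = _random_unit(rng)
        perp -= perp @ axis * axis
        perp = _unit(perp) * rng.uniform(0.4, geo.spindle_radius_um)
        return axis * rng.uniform(-ax_max, ax_max) + perp

    kt_pos = np.empty((2 * n_pairs, n_frames, 3))
    arrivals = np.full(n_pairs, np.nan)
    class_iii_departed = np.full(n_pairs, np.nan)
    reo_done = False

    sep_records = {"rest_nm": {}, "stretch_nm": {}}

    for p in range(n_pairs):
        builder = _PathBuilder(0.0, starts[p])
        # pre-NEBD + prometaphase A: saturating concerted drift
        drift_end = t_b if progression else t_end
        n_sub = max(2, int(drift_end / 120.0))
        for ts in np.linspace(0.0, drift_end, n_sub + 1)[1:]:
            disp = kin.drift_speed_um_s * drift_tau * (1 - np.exp(-ts / drift_tau))
            builder.knots_t.append(ts)
            builder.knots_p.append(starts[p] + drift_dir * disp)

        cong_start = np.nan
        if progression:
            # --- prometaphase B itinerary ---
            start_b = t_b if p == first_jumper else t_b + rng.uniform(10.0, 90.0)
            builder.hold_until(start_b)
            if config.jumps_enabled:
                if p == reo_pair and start_b + 400.0 <= stable[p]:
                    # one re-orientation: poleward jump, then a jump
                    # towards the opposite pole, then capture; start with
                    # the far pole so both jumps are long-range
                    ax_cur = builder.p_cur @ axis
                    s = -int(np.sign(ax_cur)) if abs(ax_cur) >= 2.0 \
                        else pole_sign[p]
                    builder.move_to(polar_point(s), v_jump)
                    builder.hold_until(builder.t_cur + rng.uniform(30.0, 60.0))
                    builder.move_to(polar_point(-s), v_jump)
                    builder.hold_until(builder.t_cur + rng.uniform(30.0, 60.0))
                    reo_done = True
                else:
                    # each completed pole visit yields two transits, but
                    # the first poleward trip from a start outside the
                    # plate band is not a completed transit
                    lam = (config.excursions_per_pair + 1.0) / 2.0 \
                        if config.excursions_per_pair > 0 else 0.0
                    n_vis = int(rng.poisson(lam)) if lam > 0 else 0
                    if p == first_jumper:
                        n_vis = max(1, n_vis)
                    for v_i in range(n_vis):
                        if builder.t_cur > stable[p] - 260.0 \
                                and not (p == first_jumper and v_i == 0):
                            break
                        builder.move_to(polar_point(pole_sign[p]), v_jump)
                        builder.hold_until(builder.t_cur
                                           + rng.uniform(20.0, 60.0))
                        if builder.t_cur > stable[p] - 180.0:
                            break
                        builder.move_to(plate_point(), v_jump)
                        builder.hold_until(builder.t_cur
                                           + rng.uniform(20.0, 60.0))
            # --- congression into the plate ---
            if config.congression_enabled:
                slot = plate_point(ax_max=0.8)
                dist = np.linalg.norm(slot - builder.p_cur)
                t_dep = stable[p] - dist / v_cong
                builder.rewind_hold(t_dep)
                builder.hold_until(t_dep)
                arrivals[p] = builder.move_to(slot, v_cong,
                                              record_jump=config.jumps_enabled)
                if classes[p] == "III":
                    # KT-led poleward departure before the m/a transition
                    t_dep3 = rng.uniform(min(arrivals[p] + 120.0, t_a - 400.0),
                                         t_a - 200.0)
                    builder.hold_until(t_dep3)
                    builder.move_to(polar_point(pole_sign[p]), v_jump)
                    class_iii_departed[p] = t_dep3
                elif classes[p] == "II":
                    builder.hold_until(t_t)
                    drift3 = axis * pole_sign[p] * 0.012 * (t_end - t_t)
                    builder.knots_t.append(t_end)
                    builder.knots_p.append(builder.p_cur + drift3)
            else:
                # colcemid-like: keep drifting, no congression
                pass
        builder.hold_until(t_end + dt)
        center = builder.sample(times)

        # --- separation magnitude course m(t) (half separation, um) ---
        if config.univalent:
            base = sep.univalent_baseline_nm / 2000.0
            if classes[p] == "I":
                meta = sep.univalent_metaphase_nm / 2000.0
                peak = rng.uniform(*sep.univalent_split_nm) / 2000.0
                knots_t = [0.0, max(cong_start if cong_start == cong_start
                                    else arrivals[p] - 120.0, 1.0),
                           arrivals[p], t_a, t_a + 240.0, t_t + 180.0,
                           t_i, t_end + dt]
                knots_m = [base, base, meta, meta, peak, peak, base, base]
            else:
                knots_t = [0.0, t_end + dt]
                knots_m = [base, base]
            sep_records["rest_nm"][p] = base * 2000.0
        elif mii_like:
            nebd_nm = max(sep.sister_floor_nm,
                          rng.normal(*sep.sister_nebd_nm))
            plateau_nm = max(sep.sister_floor_nm,
                             rng.normal(*sep.sister_plateau_nm))
            risen = nebd_nm + sep.sister_rise_nm
            if progression:
                a0 = arrivals[p] if arrivals[p] == arrivals[p] else t_m_target
                knots_t = [0.0, t_nebd, t_b, max(a0 - 100.0, t_b + 1.0), a0,
                           t_end + dt]
                knots_m = np.array([nebd_nm, nebd_nm, risen, risen,
                                    plateau_nm, plateau_nm]) / 2000.0
            else:
                knots_t = [0.0, t_nebd, t_end + dt]
                knots_m = np.array([nebd_nm, nebd_nm, risen]) / 2000.0
            sep_records["rest_nm"][p] = nebd_nm
            sep_records["stretch_nm"][p] = plateau_nm
        else:
            rest = rng.uniform(*sep.bivalent_rest_um)
            stretch = rest * sep.bivalent_stretch_factor
            if progression and arrivals[p] == arrivals[p]:
                knots_t = [0.0, max(arrivals[p] - 100.0, 1.0), arrivals[p],
                           t_end + dt]
                knots_m = [rest / 2, rest / 2, stretch / 2, stretch / 2]
            else:
                knots_t = [0.0, t_end + dt]
                knots_m = [rest / 2, rest / 2]
            sep_records["rest_nm"][p] = rest * 1000.0
            sep_records["stretch_nm"][p] = stretch * 1000.0
        m_course = np.interp(times, knots_t, np.asarray(knots_m, dtype=float))

        # --- orientation course e(t) ---
        e0 = _random_unit(rng, in_plane=mii_like)
        e_final = axis * dest_sign[p]
        if e0 @ e_final < 0:  # avoid near-antipodal interpolation collapse
            e0 = -e0
        e_path = np.tile(e0, (n_frames, 1))
        align = progression and config.congression_enabled and (
            not config.univalent or classes[p] == "I")
        if align and arrivals[p] == arrivals[p]:
            i0 = np.searchsorted(times, arrivals[p] - 100.0)
            i1 = np.searchsorted(times, arrivals[p])
            i1 = max(i1, i0 + 1)
            w = np.linspace(0.0, 1.0, max(i1 - i0, 1))
            seg = (1 - w)[:, None] * e0[None, :] + w[:, None] * e_final[None, :]
            e_path[i0:i1] = seg
            e_path[i1:] = e_final
        ang_noise = _ar1_noise(rng, n_frames, 0.7) * 0.05
        e_path = e_path + ang_noise
        e_path /= np.linalg.norm(e_path, axis=1, keepdims=True)

        # --- jitter schedule ---
        jit = _ar1_noise(rng, n_frames, kin.jitter_ar)
        jit_kt = _ar1_noise(rng, n_frames, kin.jitter_ar, shape=(2, 3)) * 0.012
        sigma = np.full(n_frames, kin.jitter_sigma_um)
        if progression:
            i_arr = np.searchsorted(
                times, arrivals[p] if arrivals[p] == arrivals[p] else t_a)
            sigma[np.searchsorted(times, t_b):i_arr] = 0.04
            sigma[i_arr:] = kin.metaphase_jitter_sigma_um
            if not config.univalent:
                iA = np.searchsorted(times, t_a)
                iT = np.searchsorted(times, t_t)
                sigma[iA:iT] = 0.0
                jit_kt[iA:iT] = 0.0
        center = center + jit * sigma[:, None]

        kt0 = center + m_course[:, None] * e_path + jit_kt[:, 0]
        kt1 = center - m_course[:, None] * e_path + jit_kt[:, 1]

        # leading KT stretch during ballistic jumps; conjoined sister
        # dots (univalents, dyads) only elongate slightly
        lead_stretch = kin.jump_lead_stretch_um \
            if not (config.univalent or mii_like) else 0.15
        for (tj0, tj1, dirv) in builder.jumps:
            i0, i1 = np.searchsorted(times, [tj0, tj1])
            if i1 <= i0:
                continue
            prof = np.sin(np.linspace(0, np.pi, i1 - i0)) * lead_stretch
            kt0[i0:i1] += prof[:, None] * dirv[None, :]

        # anaphase override: monotone separation towards opposite poles
        if progression and not config.univalent:
            iA = np.searchsorted(times, t_a)
            iT = np.searchsorted(times, t_t)
            for k, arr, s in ((0, kt0, dest_sign[p]), (1, kt1, -dest_sign[p])):
                start = arr[iA].copy()
                perp = start - (start @ axis) * axis
                target = axis * s * (half_l - 0.6) + 0.3 * perp
                dvec = target - start
                dist = np.linalg.norm(dvec)
                dirv = dvec / dist if dist > 0 else np.zeros(3)
                trav = np.minimum(kin.anaphase_speed_um_s
                                  * (times[iA:] - t_a), dist)
                arr[iA:] = start[None, :] + trav[:, None] * dirv[None, :]
                # resume jitter after telophase onset
                arr[iT:] += jit_kt[iT:, k] + jit[iT:] \
                    * kin.metaphase_jitter_sigma_um

        kt_pos[2 * p] = kt0
        kt_pos[2 * p + 1] = kt1

    # ground-truth metaphase onset = scheduled stabilization of the last
    # pair; congression is timed to complete by then
    if progression:
        t_m_real = float(t_m_target) if config.congression_enabled else None
        boundaries = {
            "nebd": float(t_nebd),
            "prometaphase_b_onset": float(t_b) if config.jumps_enabled else None,
            "metaphase_onset": t_m_real,
            "anaphase_onset": float(t_a),
            "telophase_onset": float(t_t),
            "interphase_onset": float(t_i),
        }
    else:
        boundaries = {"nebd": float(t_nebd), "prometaphase_b_onset": None,
                      "metaphase_onset": None, "anaphase_onset": None,
                      "telophase_onset": None, "interphase_onset": None}

    pairing = {2 * p: p for p in range(n_pairs)}
    pairing.update({2 * p + 1: p for p in range(n_pairs)})
    dest = {}
    for p in range(n_pairs):
        dest[2 * p] = int(dest_sign[p])
        dest[2 * p + 1] = int(-dest_sign[p])

    # excursion ground truth from the projected true pair centres
    exc = {}
    if progression:
        i_lo = np.searchsorted(times, t_nebd)
        i_hi = np.searchsorted(times, t_a)
    else:
        i_lo, i_hi = 0, n_frames
    for p in range(n_pairs):
        c = 0.5 * (kt_pos[2 * p] + kt_pos[2 * p + 1])
        s_ax = c[i_lo:i_hi] @ axis
        exc[p], _ = count_zone_transits(s_ax, plate_half, polar_inner)

    gt = GroundTruth(
        division=config.division,
        phase_boundaries_s=boundaries,
        pairing=pairing,
        spindle_axis=axis,
        pole_positions=poles,
        kt_destination_sign=dest,
        times_s=times,
        true_positions=kt_pos,
        excursion_counts=exc,
        reorientation_pairs=[reo_pair] if reo_done else [],
        univalent_classes={p: classes[p] for p in range(n_pairs)
                           if classes[p] is not None},
        pair_separations_nm=sep_records,
    )

    bundle = _make_bundle(config, rng, cell_id, times, kt_pos, pairing,
                          boundaries)
    return bundle, gt


def _make_bundle(config, rng, cell_id, times, kt_pos, pairing, boundaries):
    dt = config.frame_interval_s
    n_kt, n_frames = kt_pos.shape[:2]
    noise = rng.normal(0.0, config.measurement_noise_nm / 1000.0,
                       size=kt_pos.shape)
    obs = kt_pos + noise
    frames = np.tile(np.arange(n_frames), n_kt)
    kt_ids = np.repeat(np.arange(n_kt), n_frames)
    positions = pd.DataFrame({
        "cell_id": cell_id,
        "kt_id": kt_ids,
        "pair_id": np.array([pairing[k] for k in kt_ids]),
        "frame": frames,
        "t_seconds": times[frames],
        "x_um": obs[:, :, 0].ravel(),
        "y_um": obs[:, :, 1].ravel(),
        "z_um": obs[:, :, 2].ravel(),
    })

    nucleo = np.full(n_frames, 0.2)
    t_nebd = boundaries.get("nebd")
    if t_nebd is not None:
        drop = np.clip((times - t_nebd) / 30.0, 0.0, 1.0)
        nucleo = 1.0 - 0.8 * drop
    decon = np.zeros(n_frames)
    t_t, t_i = boundaries.get("telophase_onset"), boundaries.get(
        "interphase_onset")
    if t_t is not None and t_i is not None:
        decon = np.clip((times - t_t) / (t_i - t_t), 0.0, 1.0)
    signals = pd.DataFrame({
        "frame": np.arange(n_frames),
        "t_seconds": times,
        "nucleoplasm": nucleo + rng.normal(0, 0.02, n_frames),
        "decondensation": decon + rng.normal(0, 0.02, n_frames),
    })
    return TrajectoryBundle(cell_id=cell_id, positions=positions,
                            signals=signals, frame_interval_s=dt,
                            config=config)


def _simulate_ik(config, rng, cell_id):
    """Interkinesis: four conjoined sister-KT dots with breathing events."""
    dt = config.frame_interval_s
    geo, kin, sep, br = (config.geometry, config.kinematics,
                         config.separation, config.breathing)
    mean, sd = config.phase_minutes["ik"]
    dur = max(0.2 * mean, rng.normal(mean, sd) if sd > 0 else mean) * 60.0
    n_frames = int(np.floor(dur / dt)) + 1
    times = np.arange(n_frames) * dt
    n_dots = 4

    starts = _sample_start_positions(rng, n_dots, geo.nuclear_radius_um - 1.2,
                                     min_dist=2.2)
    events = []
    kt_pos = np.empty((2 * n_dots, n_frames, 3))
    hours = dur / 3600.0
    for p in range(n_dots):
        n_ev = rng.poisson(br.rate_per_dot_hour * hours)
        ev_list = []
        for _ in range(n_ev):
            if rng.uniform() < br.long_fraction:
                d = rng.uniform(br.duration_range_s[1], br.long_max_s)
            else:
                d = rng.uniform(*br.duration_range_s)
            for _ in range(50):
                t0 = rng.uniform(0.0, max(times[-1] - d, 1.0))
                if all(t0 + d < e0 or t0 > e0 + ed for (e0, ed, _) in ev_list):
                    break
            else:
                continue
            amp = rng.uniform(*br.amplitude_range_nm)
            ev_list.append((t0, d, amp))
        for (t0, d, amp) in sorted(ev_list):
            events.append(BreathingEvent(dot_id=p, t_start_s=float(t0),
                                         duration_s=float(d),
                                         amplitude_nm=float(amp)))
        base = rng.uniform(*sep.ik_baseline_nm) / 2000.0
        m_course = np.full(n_frames, base)
        for (t0, d, amp) in ev_list:
            sel = (times >= t0) & (times < t0 + d)
            m_course[sel] = amp / 2000.0
        # slow in-plane wandering orientation
        phi0 = rng.uniform(0, 2 * np.pi)
        phi = phi0 + np.cumsum(rng.normal(0, 0.06, n_frames))
        e_path = np.stack([np.cos(phi), np.sin(phi),
                           np.zeros(n_frames)], axis=1)
        jit = _ar1_noise(rng, n_frames, kin.jitter_ar) \
            * kin.metaphase_jitter_sigma_um
        center = starts[p][None, :] + jit
        kt_pos[2 * p] = center + m_course[:, None] * e_path
        kt_pos[2 * p + 1] = center - m_course[:, None] * e_path

    boundaries = {"ik_start": 0.0, "ik_end": float(times[-1])}
    pairing = {}
    for p in range(n_dots):
        pairing[2 * p] = p
        pairing[2 * p + 1] = p
    gt = GroundTruth(
        division="IK", phase_boundaries_s=boundaries, pairing=pairing,
        spindle_axis=None, pole_positions=None, kt_destination_sign={},
        times_s=times, true_positions=kt_pos, breathing_events=events,
    )
    bundle = _make_bundle(config, rng, cell_id, times, kt_pos, pairing, {})
    return bundle, gt


# ---------------------------------------------------------------------------
# cysts and cohorts


def simulate_cyst(config: SimulationConfig, seed: int, cyst_id: int = 0,
                  phase_z: Optional[dict] = None):
    """Simulate one cyst of ``config.n_cells`` near-synchronous cells.

    Phase durations are drawn once per cyst; each cell shifts every
    boundary by an independent uniform offset within the configured
    synchrony bound, so the within-cyst duration dispersion implied by
    the bound is subtracted (in quadrature) from the cyst-level draw.
    ``phase_z`` optionally fixes the cyst-level standard-normal draw per
    phase (used for stratified cohorts).
    """
    config.validate()
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ss = np.random.SeedSequence([int(seed), 0x6379, cyst_id])
    rng = np.random.default_rng(ss)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(config.n_cells)]
    b = config.cyst_synchrony_bound_min
    sd_within = b * np.sqrt(2.0 / 3.0)

    cyst_means = {}
    for phase, (mean, sd) in config.phase_minutes.items():
        sd_c = np.sqrt(max(sd ** 2 - sd_within ** 2, 0.0))
        z = phase_z.get(phase) if phase_z else rng.normal()
        cyst_means[phase] = max(0.2 * mean, mean + sd_c * z)

    phase_names = [p for p in (("ik",) if config.division == "IK"
                               else PHASE_ORDER)
                   if p in config.phase_minutes]
    out = []
    for i in range(config.n_cells):
        offs = rng.uniform(-b, b, size=len(phase_names) + 1) if b > 0 \
            else np.zeros(len(phase_names) + 1)
        overrides = {}
        for j, phase in enumerate(phase_names):
            overrides[phase] = max(0.2 * config.phase_minutes[phase][0],
                                   cyst_means[phase] + offs[j + 1] - offs[j])
        bundle, gt = simulate_cell(config, child_seeds[i],
                                   phase_overrides=overrides,
                                   cell_id=cyst_id * 100 + i,
                                   nebd_offset_s=offs[0] * 60.0)
        out.append((bundle, gt))
    return out


def simulate_cohort(config: SimulationConfig, n_cysts: int, seed: int,
                    stratified: bool = False):
    """Simulate ``n_cysts`` cysts; optionally stratify cyst-level draws.

    With ``stratified=True`` the per-phase cyst-level standard-normal
    draws are symmetric stratified quantiles (a shuffled
    ``norm.ppf((k+0.5)/K)`` grid), a variance-reduction device for
    parameter-recovery experiments: marginals are unchanged but the
    cohort mean estimates the configured mean without cyst-sampling
    noise.
    """
    if n_cysts < 1:
        raise ValueError("n_cysts must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x636f]))
    zs = {}
    if stratified:
        grid = norm.ppf((np.arange(n_cysts) + 0.5) / n_cysts)
        for phase in config.phase_minutes:
            zs[phase] = rng.permutation(grid)
    cysts = []
    for c in range(n_cysts):
        phase_z = {ph: float(zs[ph][c]) for ph in zs} if stratified else None
        cysts.append(simulate_cyst(config, seed, cyst_id=c, phase_z=phase_z))
    return cysts
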
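"""Simulation, optics and analysis configuration with genotype presets.

The control preset encodes the published phenomenology of Drosophila
spermatocyte meiosis: M I / IK / M II each last close to one hour
(58 +/- 6, 54 +/- 8, 56 +/- 8 min at the cyst level), prometaphase A
(pre KT-MT interaction drift) lasts 5 +/- 1.5 min and prometaphase B
(rapid KT jumps until stable bi-orientation of the last chromosome)
9.75 +/- 3 min during M I and 7 +/- 2 min during M II.  Perturbed
presets differ from control only in the documented parameters (e.g.
*mad2* shortens the pre-anaphase timer, colcemid removes KT jumps and
congression).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

GENOTYPES = (
    "control",
    "mad2",
    "mnm",
    "tef",
    "spc105_rnai",
    "colcemid",
    "fzy_rnai",
)

DIVISIONS = ("MI", "IK", "MII")

#: order of division phases after NEBD within one meiotic division
PHASE_ORDER = (
    "prometaphase_a",
    "prometaphase_b",
    "metaphase",
    "anaphase",
    "telophase",
)


@dataclass
class GeometryConfig:
    """Spindle/cell geometry in micrometres.

    The metaphase plate band is 3 um wide, about one quarter of the
    pole-to-pole distance, hence a 12 um spindle by default.  The polar
    zone is the symmetric complement: the outer quarter of each half
    spindle axis.
    """

    nuclear_radius_um: float = 5.0
    pole_distance_um: float = 12.0
    plate_width_um: float = 3.0
    polar_zone_fraction: float = 0.25
    spindle_radius_um: float = 2.5

    def validate(self) -> None:
        for name in ("nuclear_radius_um", "pole_distance_um", "plate_width_um",
                     "spindle_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry.{name} must be strictly positive")
        if self.plate_width_um > self.pole_distance_um:
            raise ValueError(
                "plate band width must not exceed the pole-to-pole distance")
        if not 0 < self.polar_zone_fraction < 0.5:
            raise ValueError("polar_zone_fraction must lie in (0, 0.5)")


@dataclass
class KinematicsConfig:
    """Stochastic kinematics of the phase-switched trajectory model.

    Speeds in um/s, positions in um.  ``jump_speed_um_s`` is the ballistic
    speed of poleward KT jumps during prometaphase B; prometaphase A drift
    and jitter stay well below it.  ``jump_lead_stretch_um`` transiently
    stretches the pair along the jump direction so that the jumping KT
    leads and its partner only partially follows.
    """

    drift_speed_um_s: float = 0.004
    jitter_sigma_um: float = 0.08
    jitter_ar: float = 0.8
    metaphase_jitter_sigma_um: float = 0.035
    jump_speed_um_s: float = 0.10
    jump_lead_stretch_um: float = 0.5
    anaphase_speed_um_s: float = 0.03
    congression_speed_um_s: Optional[float] = None  # default: jump speed
    tension_stabilization: bool = True
    stabilization_onset_min: Optional[float] = None  # time-dependent fallback

    def validate(self) -> None:
        for name in ("drift_speed_um_s", "jitter_sigma_um",
                     "metaphase_jitter_sigma_um", "jump_speed_um_s",
                     "anaphase_speed_um_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinematics.{name} must be strictly positive")
        if not 0 <= self.jitter_ar < 1:
            raise ValueError("kinematics.jitter_ar must lie in [0, 1)")


@dataclass
class BreathingConfig:
    """Transient sister-centromere splitting ("breathing") during IK.

    Control rate 0.17 events per Cid-EGFP dot per hour; most events are
    resolved for 20-40 s, a minority for up to 3 min; maximal separation
    of the two fluorescence maxima is around 550 nm.
    """

    rate_per_dot_hour: float = 0.17
    duration_range_s: tuple[float, float] = (20.0, 40.0)
    long_fraction: float = 0.2
    long_max_s: float = 180.0
    amplitude_range_nm: tuple[float, float] = (420.0, 560.0)

    def validate(self) -> None:
        if self.rate_per_dot_hour < 0:
            raise ValueError("breathing.rate_per_dot_hour must be >= 0")
        lo, hi = self.duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("breathing.duration_range_s must be positive and ordered")
        if not 0 <= self.long_fraction <= 1:
            raise ValueError("breathing.long_fraction must lie in [0, 1]")
        alo, ahi = self.amplitude_range_nm
        if not 0 < alo <= ahi:
            raise ValueError("breathing.amplitude_range_nm must be positive and ordered")


@dataclass
class SeparationConfig:
    """Within-pair KT-KT separations (bivalent homolog KTs, sister KTs).

    M II sister separation follows the published course: ~300 +/- 160 nm
    at NEBD II, a small MT-independent rise within the first five
    minutes, then growth to the bi-oriented plateau of 950 +/- 100 nm.
    """

    bivalent_rest_um: tuple[float, float] = (1.6, 2.4)
    bivalent_stretch_factor: float = 1.15
    sister_nebd_nm: tuple[float, float] = (300.0, 160.0)
    sister_floor_nm: float = 50.0
    sister_rise_nm: float = 100.0
    sister_plateau_nm: tuple[float, float] = (950.0, 100.0)
    ik_baseline_nm: tuple[float, float] = (80.0, 140.0)
    univalent_baseline_nm: float = 200.0
    univalent_metaphase_nm: float = 330.0
    univalent_split_nm: tuple[float, float] = (700.0, 900.0)

    def validate(self) -> None:
        if self.bivalent_rest_um[0] <= 0:
            raise ValueError("separation.bivalent_rest_um must be positive")
        if self.sister_plateau_nm[0] <= 0 or self.sister_nebd_nm[0] <= 0:
            raise ValueError("separation means must be positive")


@dataclass
class SimulationConfig:
    """Full configuration of one simulated cyst of spermatocytes."""

    genotype: str = "control"
    division: str = "MI"
    #: per-phase duration (mean, s.d.) in minutes, keys from PHASE_ORDER;
    #: for division "IK" the single key "ik" is used instead.
    phase_minutes: dict = field(default_factory=dict)
    pre_nebd_min: float = 5.0
    tail_min: float = 3.0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    breathing: BreathingConfig = field(default_factory=BreathingConfig)
    separation: SeparationConfig = field(default_factory=SeparationConfig)
    excursions_per_pair: float = 2.0
    reorientations_per_cell: int = 1
    jumps_enabled: bool = True
    congression_enabled: bool = True
    progression_enabled: bool = True  # False: no metaphase/anaphase (colcemid)
    univalent: bool = False
    univalent_class_fractions: tuple[float, float, float] = (0.30, 0.38, 0.32)
    n_cells: int = 3
    cyst_synchrony_bound_min: float = 1.0
    frame_interval_s: float = 10.0
    measurement_noise_nm: float = 20.0

    def __post_init__(self) -> None:
        if not self.phase_minutes:
            self.phase_minutes = default_phase_minutes(self.division)

    def validate(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"unknown genotype {self.genotype!r}; valid: {', '.join(GENOTYPES)}")
        if self.division not in DIVISIONS:
            raise ValueError(
                f"unknown division {self.division!r}; valid: {', '.join(DIVISIONS)}")
        for phase, (mean, sd) in self.phase_minutes.items():
            if mean <= 0:
                raise ValueError(f"phase {phase!r} mean duration must be positive")
            if sd < 0:
                raise ValueError(f"phase {phase!r} duration s.d. must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be strictly positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.pre_nebd_min <= 0:
            raise ValueError("pre_nebd_min must be strictly positive")
        if self.cyst_synchrony_bound_min < 0:
            raise ValueError("cyst_synchrony_bound_min must be >= 0")
        if abs(sum(self.univalent_class_fractions) - 1.0) > 1e-9:
            raise ValueError("univalent_class_fractions must sum to 1")
        self.geometry.validate()
        self.kinematics.validate()
        self.breathing.validate()
        self.separation.validate()

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("geometry", GeometryConfig),
                         ("kinematics", KinematicsConfig),
                         ("breathing", BreathingConfig),
                         ("separation", SeparationConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**_tuplify(sub, d[key]))
        if "phase_minutes" in d and d["phase_minutes"]:
            d["phase_minutes"] = {k: tuple(v) for k, v in d["phase_minutes"].items()}
        if "univalent_class_fractions" in d:
            d["univalent_class_fractions"] = tuple(d["univalent_class_fractions"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(d)


def _tuplify(sub_cls, d: dict) -> dict:
    """Convert YAML lists back to tuples for tuple-typed dataclass fields."""
    out = dict(d)
    for f in dataclasses.fields(sub_cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


@dataclass
class OpticsConfig:
    """Rendering optics emulating spinning-disc acquisition.

    Defaults: 300 nm z spacing (as acquired, 40-45 sections), 100 nm
    lateral pixels, a Gaussian PSF and Poisson-Gaussian camera noise.
    """

    voxel_xy_nm: float = 100.0
    voxel_z_nm: float = 300.0
    psf_sigma_xy_nm: float = 120.0
    psf_sigma_z_nm: float = 350.0
    photon_scale: float = 1000.0
    background: float = 20.0
    read_noise_sigma: float = 2.0
    shape_zyx: tuple[int, int, int] = (41, 144, 144)

    def validate(self) -> None:
        for name in ("voxel_xy_nm", "voxel_z_nm", "psf_sigma_xy_nm",
                     "psf_sigma_z_nm", "photon_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"optics.{name} must be strictly positive")
        if any(s < 3 for s in self.shape_zyx):
            raise ValueError("optics.shape_zyx axes must be >= 3 voxels")

    @property
    def voxel_um_zyx(self) -> tuple[float, float, float]:
        return (self.voxel_z_nm / 1000.0,
                self.voxel_xy_nm / 1000.0,
                self.voxel_xy_nm / 1000.0)


@dataclass
class AnalysisConfig:
    """Thresholds of the scoring/event stages, logged into every report.

    The jump-speed threshold separating prometaphase A drift from the
    rapid prometaphase B jumps is adaptive: three times the 95th
    percentile of early post-NEBD speeds of the same cell, with an
    absolute floor.
    """

    spot_diameter_nm: float = 500.0
    detect_noise_factor: float = 10.0
    pair_floor_nm: float = 150.0
    pair_peak_fraction: float = 0.5
    baseline_window_frames: int = 12
    jump_factor: float = 3.0
    jump_speed_floor_um_s: float = 0.02
    min_jump_displacement_um: float = 1.0
    plate_width_um: float = 3.0
    pole_distance_um: float = 12.0
    polar_zone_fraction: float = 0.25
    angle_max_deg: float = 30.0
    mobility_max_um_s: float = 0.025
    persistence_frames: int = 6
    anaphase_step_um: float = 0.3
    spindle_window_frames: int = 35
    ma_offset_min: float = 10.0
    split_threshold_nm: float = 450.0
    breathing_min_frames: int = 2
    plate_residency_min: float = 0.7
    elongation_cutoff: float = 1.3
    link_search_radius_um: float = 1.8
    link_max_gap: int = 3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)


def default_phase_minutes(division: str) -> dict:
    """Published per-phase (mean, s.d.) durations in minutes for controls."""
    if division == "MI":
        # sums to 58 min NEBD -> interphase onset
        return {
            "prometaphase_a": (5.0, 1.5),
            "prometaphase_b": (9.75, 3.0),
            "metaphase": (18.0, 4.0),
            "anaphase": (10.0, 2.0),
            "telophase": (15.25, 3.0),
        }
    if division == "MII":
        # sums to 56 min
        return {
            "prometaphase_a": (5.0, 1.5),
            "prometaphase_b": (7.0, 2.0),
            "metaphase": (18.0, 4.0),
            "anaphase": (10.0, 2.0),
            "telophase": (16.0, 3.0),
        }
    if division == "IK":
        return {"ik": (54.0, 8.0)}
    raise ValueError(f"unknown division {division!r}")


def make_preset(genotype: str, division: str = "MI") -> SimulationConfig:
    """Build a fully populated :class:`SimulationConfig` for a genotype.

    Control defaults equal the published means/s.d.; each perturbed
    preset differs from control only in documented parameters:

    * ``mad2``       -- SAC loss: NEBD-to-anaphase shortened by ~10 min
      (metaphase mean 18 -> 8 min).
    * ``mnm``/``tef``-- univalents instead of bivalents; no
      tension-mediated attachment stabilization, time-dependent
      stabilization after ~25 min; ~7 excursions per KT pair; univalent
      classes I/II/III at 30/38/32%.
    * ``spc105_rnai``-- rapid KT jumps abolished; KT-independent (slow)
      congression retained.
    * ``colcemid``   -- no jumps and no congression/progression.
    * ``fzy_rnai``   -- APC/C co-activator depleted: metaphase arrest
      for more than four hours (mean 270 min).
    """
    if genotype not in GENOTYPES:
        raise ValueError(
            f"unknown genotype preset {genotype!r}; valid presets: "
            + ", ".join(GENOTYPES))
    cfg = SimulationConfig(genotype=genotype, division=division)
    if genotype == "mad2":
        cfg.phase_minutes = dict(cfg.phase_minutes)
        cfg.phase_minutes["metaphase"] = (8.0, 4.0)
    elif genotype in ("mnm", "tef"):
        cfg.univalent = True
        cfg.kinematics.tension_stabilization = False
        cfg.kinematics.stabilization_onset_min = 25.0
        cfg.excursions_per_pair = 7.0
        cfg.reorientations_per_cell = 0
        if division == "MI":
            cfg.phase_minutes = {
                "prometaphase_a": (5.0, 1.5),
                "prometaphase_b": (20.0, 3.0),
                "metaphase": (25.0, 5.0),
                # exit: m/a transition assumed 10 min before telophase onset
                "anaphase": (10.0, 0.0),
                "telophase": (15.0, 3.0),
            }
    elif genotype == "spc105_rnai":
        cfg.jumps_enabled = False
        cfg.excursions_per_pair = 0.0
        cfg.reorientations_per_cell = 0
        cfg.kinematics.congression_speed_um_s = 0.015
    elif genotype == "colcemid":
        cfg.jumps_enabled = False
        cfg.congression_enabled = False
        cfg.progression_enabled = False
        cfg.excursions_per_pair = 0.0
        cfg.reorientations_per_cell = 0
    elif genotype == "fzy_rnai":
        cfg.phase_minutes = dict(cfg.phase_minutes)
        cfg.phase_minutes["metaphase"] = (270.0, 30.0)
    cfg.validate()
    return cfg
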
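"""Configuration objects for the synthetic generator and analysis stages.

All tunables of the pipeline live in dataclasses that can be serialized to
and from YAML/JSON.  Unknown keys are rejected on load so that typos in a
config file fail loudly before any output is written.

Conventions
-----------
* Scalar subject parameters may be given either as a fixed number or as a
  ``(low, high)`` pair, in which case the generator draws uniformly from
  the closed interval.
* Times are seconds, forces newtons, stiffness N/mm, displacements mm,
  unless a field name says otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError

#: EMG channel order used throughout the package (two extrinsic flexors,
#: two extrinsic extensors, two intrinsic interossei).
CHANNELS = ("FDP", "FDS", "EIP", "ED", "FDI", "SDI")

#: Functional grouping of the six recorded muscles.
CHANNEL_GROUPS = {
    "extrinsic_flexor": ("FDP", "FDS"),
    "extrinsic_extensor": ("EIP", "ED"),
    "intrinsic": ("FDI", "SDI"),
}

RangeOrValue = float | tuple[float, float] | list[float]


def draw_value(rng, spec: RangeOrValue) -> float:
    """Draw a parameter: fixed scalars pass through, pairs draw uniformly."""
    if isinstance(spec, (int, float)):
        return float(spec)
    lo, hi = (float(spec[0]), float(spec[1]))
    if lo > hi:
        raise ConfigError(f"invalid range ({lo}, {hi}): min > max")
    if lo == hi:
        return lo
    return float(rng.uniform(lo, hi))


def _check_range(name: str, spec: RangeOrValue) -> None:
    if not isinstance(spec, (int, float)):
        lo, hi = spec
        if lo > hi:
            raise ConfigError(f"{name}: invalid range ({lo}, {hi}): min > max")


@dataclass
class GeneratorConfig:
    """Settings for the synthetic subject/trial generator.

    The defaults describe the study conditions emulated by the package: a
    seated pinch grip on a spring-loaded perturbator that elongates by
    7.5 mm within a few milliseconds, six surface EMG channels, and an
    optical marker set sampled at 400 Hz.
    """

    # ---- subject parameter distributions -------------------------------
    mvc_force: RangeOrValue = (40.0, 80.0)       # N, maximum voluntary pinch force
    k0: RangeOrValue = (0.2, 0.6)                # N/mm, stiffness at zero force
    slope: RangeOrValue = (0.04, 0.08)           # N/mm per N, force-stiffness gradient
    index_share: RangeOrValue = (0.60, 0.80)     # fraction of displacement at index
    emg_noise_sd: RangeOrValue = 0.01            # a.u., electrode baseline amplitude
    tremor_sd: RangeOrValue = 0.05               # N, force plateau noise
    oscillation_amp: RangeOrValue = 1.0          # N, post-perturbation ringing
    oscillation_freq: RangeOrValue = 150.0       # Hz
    oscillation_decay_s: RangeOrValue = 0.005    # s, exponential decay constant

    # Added normalized stiffness per commanded task-2 level (fraction of the
    # subject's maximum stiffness scale).
    cocon_offset_by_level: dict[float, float] = field(
        default_factory=lambda: {0.15: 0.15, 0.25: 0.14, 0.35: 0.21, 0.45: 0.21, 0.55: 0.26}
    )
    # Trial-to-trial lognormal CV of the cocontraction effort in task 2.
    cocon_cv: float = 0.4

    # ---- EMG coupling ---------------------------------------------------
    # Per-channel weight of the net-force drive and of the cocontraction
    # drive in the EMG amplitude envelope, plus a per-trial multiplicative
    # lognormal gain CV (electrode/skin variability).  Order: CHANNELS.
    force_weights: tuple[float, ...] = (0.55, 0.50, 0.20, 0.45, 0.45, 0.40)
    cocon_weights: tuple[float, ...] = (0.30, 0.30, 0.20, 0.25, 1.00, 0.95)
    emg_gain_cv: tuple[float, ...] = (0.55, 0.50, 0.60, 0.50, 0.18, 0.18)
    # Carrier under the amplitude envelope: "noise" is amplitude-modulated
    # band-limited noise; "sine" is a deterministic in-band sinusoid whose
    # ARV is exactly proportional to the envelope (noise-free limit).
    emg_carrier: str = "noise"

    # ---- waveform template ---------------------------------------------
    pre_s: float = 0.5        # pre-perturbation plateau (>= 250 ms required)
    rise_s: float = 0.003     # linear force rise during the release
    post_s: float = 0.3       # post-perturbation plateau
    relax_s: float = 5.0      # relaxation recording length (EMG base noise)

    # ---- acquisition ----------------------------------------------------
    fs_force: float = 10_000.0
    fs_emg: float = 4_000.0
    fs_markers: float = 400.0
    displacement_mm: float = 7.5
    sensor_range_n: float = 100.0

    # ---- protocol -------------------------------------------------------
    task1_levels: tuple[float, ...] = (0.15, 0.25, 0.35, 0.45, 0.55, 0.65)
    task2_levels: tuple[float, ...] = (0.15, 0.25, 0.35, 0.45, 0.55)
    task1_reps: int = 4
    task2_reps: int = 15

    # ---- marker realism -------------------------------------------------
    marker_noise_sd_mm: float = 0.05
    marker_dropout_prob: float = 0.01     # per-frame chance of an exact-zero frame
    marker_swap_prob: float = 0.005       # per-frame chance a label-swap segment starts
    marker_swap_mean_frames: int = 4
    wrist_drift_amp_mm: float = 2.0       # slow rigid drift of the whole scene
    wrist_drift_freq_hz: float = 0.5
    wrist_drift_rot_deg: float = 1.0
    wrist_pose_noise_deg: float = 0.1     # noise on the stored wrist orientation

    def __post_init__(self):
        for name in ("mvc_force", "k0", "slope", "index_share", "emg_noise_sd",
                     "tremor_sd", "oscillation_amp", "oscillation_freq",
                     "oscillation_decay_s"):
            _check_range(name, getattr(self, name))
        if self.pre_s < 0.25:
            raise ConfigError("pre_s must be >= 0.25 s (window detection support)")
        for w in (self.force_weights, self.cocon_weights, self.emg_gain_cv):
            if len(w) != len(CHANNELS):
                raise ConfigError("EMG weight vectors must have six entries")
        if self.emg_carrier not in ("noise", "sine"):
            raise ConfigError(f"unknown emg_carrier {self.emg_carrier!r}")
        if self.task1_reps < 1 or self.task2_reps < 1:
            raise ConfigError("trial repetition counts must be >= 1")


@dataclass
class WindowConfig:
    """Window-detection and stiffness-estimation settings.

    ``tap_len_ms``/``t_trust_offset_ms`` hold the currently configured
    optimum of the window-placement objective; the defaults are the grid
    points 55/3 and 100/3 ms (printed as 18.3 and 33.3 ms).
    """

    tbp_len_s: float = 0.010          # length of the pre-perturbation window
    sd_threshold_n: float = 5e-4      # quiet-window SD bound on the smoothed force
    ma_points: int = 21               # moving-average width (samples, odd)
    tap_len_range_ms: tuple[float, float] = (5.0, 20.0)
    trust_max_ms: float = 40.0        # reflex-free horizon after the onset
    tap_len_ms: float = 55.0 / 3.0
    t_trust_offset_ms: float = 100.0 / 3.0
    grid_resolution_ms: float = 1.0 / 3.0
    displacement_mm: float = 7.5
    sample_rate: float = 10_000.0
    sd_rescale_factor: float = 10.0   # fallback ladder when no quiet window is found
    sd_rescale_max_steps: int = 6
    # Ladder cap: a plateau whose SD exceeds the force-sensor accuracy is
    # not quiet in any meaningful sense, so rescaling stops there.
    sd_threshold_max_n: float = 0.1
    # A threshold rung is accepted only if it admits at least this fraction
    # of the candidate windows: the quiet criterion must identify the
    # pre-perturbation plateau, not a lucky noise fluctuation.  Smoothing
    # leaves few effective degrees of freedom per window, so the sample-SD
    # distribution is wide; a rung below the true noise floor still admits
    # a few percent of windows by chance, while a genuine rung admits most.
    sd_quiet_min_frac: float = 0.25

    def __post_init__(self):
        if self.ma_points % 2 == 0 or self.ma_points < 1:
            raise ConfigError("ma_points must be a positive odd integer")
        lo, hi = self.tap_len_range_ms
        if not (0 < lo <= hi <= self.trust_max_ms):
            raise ConfigError("tap_len_range_ms must lie within (0, trust_max_ms]")
        if self.displacement_mm <= 0:
            raise ConfigError("displacement_mm must be positive")


@dataclass
class EMGConfig:
    """EMG filtering and activation-feature settings."""

    band_low_hz: float = 25.0
    band_high_hz: float = 450.0
    order: int = 2
    sample_rate: float = 4_000.0
    arv_window_s: float = 0.200       # activation window before the perturbation
    electrode_delay_s: float = 0.048  # constant acquisition delay of the electrodes
    baseline_window_s: float = 0.500  # quiet window in the relaxation recording

    def __post_init__(self):
        if self.sample_rate <= 2 * self.band_high_hz:
            raise ConfigError("sample_rate must exceed twice the upper band edge")


@dataclass
class KinematicsConfig:
    """Marker cleaning and digit-displacement settings."""

    speed_bound_m_s: float = 5.0      # inter-frame jump bound for artifact masking
    max_masked_frac: float = 0.5      # trial unusable above this within the windows
    sample_rate: float = 400.0
    displacement_mm: float = 7.5


@dataclass
class RegressionConfig:
    """Regression and normalization options."""

    transform: str = "plain"                 # plain | sqrt | square
    intersubject_normalization: str = "max_sd"   # max_sd | sd
    min_trials_per_subject: int = 10

    def __post_init__(self):
        if self.transform not in ("plain", "sqrt", "square"):
            raise ConfigError(f"unknown EMG transform {self.transform!r}")
        if self.intersubject_normalization not in ("max_sd", "sd"):
            raise ConfigError(
                f"unknown normalization {self.intersubject_normalization!r}")


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration (serializable, echoed into manifests)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    emg: EMGConfig = field(default_factory=EMGConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    n_subjects: int = 10
    seed: int = 0

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        gen = d["generator"]
        # YAML/JSON mapping keys must be strings
        gen["cocon_offset_by_level"] = {
            str(k): v for k, v in gen["cocon_offset_by_level"].items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "generator": GeneratorConfig,
            "window": WindowConfig,
            "emg": EMGConfig,
            "kinematics": KinematicsConfig,
            "regression": RegressionConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, klass in sections.items():
            sub = data.pop(key, None)
            if sub is None:
                kwargs[key] = klass()
                continue
            if not isinstance(sub, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _dataclass_from_dict(klass, sub, key)
        for key in ("n_subjects", "seed"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ConfigError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def _dataclass_from_dict(klass, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(klass)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    kwargs = dict(data)
    if "cocon_offset_by_level" in kwargs and isinstance(kwargs["cocon_offset_by_level"], dict):
        kwargs["cocon_offset_by_level"] = {
            float(k): float(v) for k, v in kwargs["cocon_offset_by_level"].items()}
    for name in ("force_weights", "cocon_weights", "emg_gain_cv",
                 "task1_levels", "task2_levels", "tap_len_range_ms"):
        if name in kwargs and isinstance(kwargs[name], list):
            kwargs[name] = tuple(kwargs[name])
    for name in ("mvc_force", "k0", "slope", "index_share", "emg_noise_sd",
                 "tremor_sd", "oscillation_amp", "oscillation_freq",
                 "oscillation_decay_s"):
        if name in kwargs and isinstance(kwargs[name], list):
            kwargs[name] = tuple(kwargs[name])
    return klass(**kwargs)
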
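"""Synthetic pinch-grip perturbation trials.

This module generates subjects and trials with the statistical structure
the downstream analysis assumes, so that every stage — window detection,
stiffness estimation, EMG activation features, digit kinematics, and the
force/stiffness regressions — can be exercised and validated without any
recorded data.

The emulated experiment: a subject pinches a spring-loaded perturbator
between index finger and thumb while holding a commanded force level
(fraction of their maximum voluntary contraction, MVC).  Releasing the
spring elongates the device by 7.5 mm within a few milliseconds; the grip
force (10 kHz), six surface-EMG channels (4 kHz) and optical markers
(400 Hz) are recorded around the event.  Two tasks are simulated:

* task 1 — force only, stiffness follows the subject's linear
  force-stiffness coupling ``k = k0 + slope * f``;
* task 2 — the subject additionally cocontracts, adding a force-level
  dependent stiffness offset (expressed as a fraction of the subject's
  stiffness scale) with trial-to-trial lognormal effort variability.

EMG amplitude envelopes are a linear mix of the net-force drive and the
cocontraction drive through per-muscle weights; the intrinsic hand
muscles (FDI, SDI) load mostly on cocontraction, the four extrinsic
forearm muscles mostly on force.  Envelopes modulate band-limited
(25-450 Hz) noise carriers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .config import CHANNELS, GeneratorConfig, draw_value
from .exceptions import GenerationError, InputError

# Wrist-frame grip geometry (mm).  The perturbator marker sits off-centre
# towards the index side so the two digit markers have distinct distances
# to it, which is what the per-frame label reassignment relies on.
_GRIP_ORIGIN = np.array([150.0, 0.0, 50.0])
_INDEX_OFFSET = 27.0      # +x side
_THUMB_OFFSET = -20.0     # -x side
_PERT_OFFSET = 10.0
_FOREARM_OFFSET = np.array([-120.0, 0.0, 0.0])

ALL_CHANNELS = ("force", "emg", "markers")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SubjectProfile:
    """Ground-truth parameters of one synthetic subject."""

    subject_id: str
    mvc_force: float                    # N
    k0: float                           # N/mm, stiffness at zero force
    slope: float                        # N/mm per N
    cocon_offset_by_level: dict[float, float]   # fraction of stiffness scale
    index_share: float                  # fraction of displacement at the index
    force_weights: np.ndarray           # (6,) EMG envelope weight of force drive
    cocon_weights: np.ndarray           # (6,) EMG envelope weight of cocontraction
    emg_gain_cv: np.ndarray             # (6,) per-trial lognormal gain CV
    emg_noise_sd: float                 # a.u.
    tremor_sd: float                    # N
    oscillation_amp: float              # N
    oscillation_freq: float             # Hz
    oscillation_decay_s: float          # s
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.index_share < 1.0:
            raise GenerationError("index_share must lie strictly in (0, 1)")
        if self.slope <= 0:
            raise GenerationError("slope must be positive")
        if self.mvc_force <= 0:
            raise GenerationError("mvc_force must be positive")
        for name in ("emg_noise_sd", "tremor_sd", "oscillation_amp"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")
        self.force_weights = np.asarray(self.force_weights, dtype=float)
        self.cocon_weights = np.asarray(self.cocon_weights, dtype=float)
        self.emg_gain_cv = np.asarray(self.emg_gain_cv, dtype=float)

    @property
    def muscle_weights(self) -> np.ndarray:
        """6x2 coupling of each muscle to (net force, cocontraction) drive."""
        return np.column_stack([self.force_weights, self.cocon_weights])

    @property
    def stiffness_scale(self) -> float:
        """Subject stiffness scale: task-1 stiffness at the top force level.

        Normalized (fraction-of-max) cocontraction offsets are converted to
        N/mm with this scale.
        """
        return self.k0 + self.slope * 0.65 * self.mvc_force


@dataclass
class TrialSpec:
    """What to simulate for one trial.

    ``k_true``/``f_pre`` override the profile-derived ground truth; they are
    used by recovery studies that drive the generator with stiffness values
    drawn from published summary statistics.
    """

    task: int                      # 1 or 2
    force_level: float             # fraction of MVC
    trial_index: int
    seed: int
    k_true: float | None = None    # N/mm override
    f_pre: float | None = None     # N override

    def __post_init__(self):
        if self.task not in (1, 2):
            raise GenerationError(f"task must be 1 or 2, got {self.task}")


@dataclass
class MarkerSet:
    """World-frame marker trajectories and tracked body poses (400 Hz)."""

    t: np.ndarray                 # (n,), s
    index: np.ndarray             # (n, 3), mm
    thumb: np.ndarray             # (n, 3), mm
    perturbator: np.ndarray       # (n, 3), mm
    wrist_pos: np.ndarray         # (n, 3), mm
    wrist_rot: np.ndarray         # (n, 3, 3)
    forearm_pos: np.ndarray       # (n, 3), mm
    forearm_rot: np.ndarray       # (n, 3, 3)


@dataclass
class TrialRecording:
    """One simulated perturbation trial."""

    subject_id: str
    task: int
    force_level: float
    trial_index: int
    fs_force: float
    fs_emg: float
    force: np.ndarray | None = None          # (n,), N
    emg: np.ndarray | None = None            # (6, n), a.u.
    markers: MarkerSet | None = None
    true_params: dict | None = None          # testing-only ground truth

    @property
    def t_force(self) -> np.ndarray:
        return np.arange(len(self.force)) / self.fs_force

    @property
    def metadata(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "task": self.task,
            "force_level": self.force_level,
            "trial_index": self.trial_index,
        }


# --------------------------------------------------------------------------
# subject generation
# --------------------------------------------------------------------------

def generate_subject(seed: int, config: GeneratorConfig,
                     subject_id: str | None = None) -> SubjectProfile:
    """Draw one subject profile; reproducible from ``seed``.

    Fixed scalars in the config pass through unchanged; ``(low, high)``
    pairs draw uniformly.
    """
    rng = np.random.default_rng(seed)
    return SubjectProfile(
        subject_id=subject_id or f"S{seed}",
        mvc_force=draw_value(rng, config.mvc_force),
        k0=draw_value(rng, config.k0),
        slope=draw_value(rng, config.slope),
        cocon_offset_by_level=dict(config.cocon_offset_by_level),
        index_share=draw_value(rng, config.index_share),
        force_weights=np.asarray(config.force_weights, dtype=float),
        cocon_weights=np.asarray(config.cocon_weights, dtype=float),
        emg_gain_cv=np.asarray(config.emg_gain_cv, dtype=float),
        emg_noise_sd=draw_value(rng, config.emg_noise_sd),
        tremor_sd=draw_value(rng, config.tremor_sd),
        oscillation_amp=draw_value(rng, config.oscillation_amp),
        oscillation_freq=draw_value(rng, config.oscillation_freq),
        oscillation_decay_s=draw_value(rng, config.oscillation_decay_s),
        seed=int(seed),
    )


# --------------------------------------------------------------------------
# trial generation
# --------------------------------------------------------------------------

def _bandlimited_carrier(rng, n: int, fs: float, low: float, high: float) -> np.ndarray:
    """Unit-SD band-limited Gaussian noise carrier."""
    from scipy import signal

    white = rng.standard_normal(n)
    sos = signal.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _sine_carrier(n: int, fs: float, channel: int) -> np.ndarray:
    """Deterministic unit-SD in-band sinusoid (noise-free carrier mode);
    each channel gets its own frequency so channels stay distinguishable."""
    freq = 80.0 + 20.0 * channel
    t = np.arange(n) / fs
    return np.sqrt(2.0) * np.sin(2 * np.pi * freq * t)


def _rotation_matrix(axis: np.ndarray, angle_rad: float | np.ndarray) -> np.ndarray:
    """Rodrigues rotation about a unit axis; broadcasts over angle."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    angle = np.atleast_1d(np.asarray(angle_rad, dtype=float))
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    eye = np.eye(3)
    out = (eye[None, :, :]
           + np.sin(angle)[:, None, None] * K[None, :, :]
           + (1 - np.cos(angle))[:, None, None] * (K @ K)[None, :, :])
    return out if np.ndim(angle_rad) else out[0]


def trial_truth(profile: SubjectProfile, spec: TrialSpec,
                rng: np.random.Generator,
                cocon_cv: float = 0.4) -> tuple[float, float, float]:
    """Resolve (f_pre, k_true, cocon_drive) for a trial.

    Task 1: ``k = k0 + slope * f`` and zero cocontraction drive.  Task 2
    adds the commanded level's normalized offset, scaled by the subject's
    stiffness scale and a lognormal effort multiplier; the same multiplier
    feeds the EMG cocontraction drive so EMG and stiffness stay coupled.
    """
    f_pre = spec.f_pre if spec.f_pre is not None else spec.force_level * profile.mvc_force
    cocon = 0.0
    if spec.task == 2:
        offset = profile.cocon_offset_by_level.get(round(spec.force_level, 4))
        if offset is None:
            # nearest configured level
            key = min(profile.cocon_offset_by_level,
                      key=lambda L: abs(L - spec.force_level))
            offset = profile.cocon_offset_by_level[key]
        if cocon_cv > 0:
            sigma = np.sqrt(np.log(1 + cocon_cv ** 2))
            mult = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma)
        else:
            mult = 1.0
        cocon = offset * mult
    if spec.k_true is not None:
        k_true = spec.k_true
        if spec.task == 2:
            # keep the EMG drive consistent with the imposed stiffness
            cocon = max(0.0, (k_true - profile.k0 - profile.slope * f_pre)
                        / profile.stiffness_scale)
    else:
        k_true = profile.k0 + profile.slope * f_pre + cocon * profile.stiffness_scale
    return f_pre, k_true, cocon


def generate_trial(profile: SubjectProfile, spec: TrialSpec,
                   config: GeneratorConfig | None = None,
                   channels: Sequence[str] = ALL_CHANNELS) -> TrialRecording:
    """Simulate one perturbation trial.

    ``channels`` selects which data streams to synthesize (``force``,
    ``emg``, ``markers``); each stream has its own random substream, so a
    stream's samples do not depend on which other streams are requested.
    Bit-identical output for identical (profile, spec, config).
    """
    config = config or GeneratorConfig()
    ss = np.random.SeedSequence(spec.seed)
    rng_truth, rng_force, rng_emg, rng_markers = (
        np.random.default_rng(s) for s in ss.spawn(4))

    f_pre, k_true, cocon = trial_truth(profile, spec, rng_truth,
                                       cocon_cv=config.cocon_cv)
    if f_pre < 0:
        raise GenerationError("pre-perturbation force must be >= 0")
    df = k_true * config.displacement_mm
    f_post = f_pre + df
    if max(f_pre, f_post) > config.sensor_range_n:
        raise GenerationError(
            f"force {max(f_pre, f_post):.1f} N exceeds the "
            f"{config.sensor_range_n:.0f} N sensor range")

    fs = config.fs_force
    n_pre = round(config.pre_s * fs)
    n_rise = max(1, round(config.rise_s * fs))
    n_post = round(config.post_s * fs)
    onset_s = n_pre / fs
    rec = TrialRecording(
        subject_id=profile.subject_id, task=spec.task,
        force_level=spec.force_level, trial_index=spec.trial_index,
        fs_force=fs, fs_emg=config.fs_emg,
        true_params={"k_true": k_true, "f_pre": f_pre, "f_post": f_post,
                     "index_share": profile.index_share, "onset_s": onset_s,
                     "cocon_drive": cocon},
    )

    if "force" in channels:
        force = np.empty(n_pre + n_rise + n_post)
        force[:n_pre] = f_pre
        force[n_pre:n_pre + n_rise] = f_pre + df * np.arange(1, n_rise + 1) / n_rise
        t_post = np.arange(n_post) / fs
        osc = (profile.oscillation_amp
               * np.exp(-t_post / profile.oscillation_decay_s)
               * np.sin(2 * np.pi * profile.oscillation_freq * t_post))
        force[n_pre + n_rise:] = f_post + osc
        if profile.tremor_sd > 0:
            force = force + rng_force.normal(0.0, profile.tremor_sd, force.size)
        rec.force = np.clip(force, 0.0, None)

    if "emg" in channels:
        rec.emg = _synthesize_emg(profile, config, rng_emg,
                                  n_pre + n_rise + n_post, fs,
                                  f_pre / profile.mvc_force, cocon)

    if "markers" in channels:
        rec.markers = _synthesize_markers(profile, config, rng_markers,
                                          (n_pre + n_rise + n_post) / fs, onset_s)
    return rec


def _synthesize_emg(profile: SubjectProfile, config: GeneratorConfig,
                    rng: np.random.Generator, n_force: int, fs_force: float,
                    force_drive: float, cocon_drive: float) -> np.ndarray:
    """Amplitude-modulated band-limited noise for the six channels (4 kHz)."""
    n = round(n_force / fs_force * config.fs_emg)
    out = np.empty((len(CHANNELS), n))
    for c in range(len(CHANNELS)):
        cv = profile.emg_gain_cv[c]
        if cv > 0:
            sigma = np.sqrt(np.log(1 + cv ** 2))
            gain = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma)
        else:
            gain = 1.0
        envelope = profile.emg_noise_sd + gain * (
            profile.force_weights[c] * force_drive
            + profile.cocon_weights[c] * cocon_drive)
        if config.emg_carrier == "sine":
            carrier = _sine_carrier(n, config.fs_emg, c)
        else:
            carrier = _bandlimited_carrier(rng, n, config.fs_emg, 25.0, 450.0)
        out[c] = envelope * carrier
    return out


def generate_relaxation(profile: SubjectProfile, config: GeneratorConfig,
                        seed: int) -> np.ndarray:
    """Relaxation recording (base-noise only) used for EMG baseline estimation."""
    rng = np.random.default_rng(seed)
    n = round(config.relax_s * config.fs_emg)
    out = np.empty((len(CHANNELS), n))
    for c in range(len(CHANNELS)):
        if config.emg_carrier == "sine":
            carrier = _sine_carrier(n, config.fs_emg, c)
        else:
            carrier = _bandlimited_carrier(rng, n, config.fs_emg, 25.0, 450.0)
        out[c] = profile.emg_noise_sd * carrier
    return out


def _synthesize_markers(profile: SubjectProfile, config: GeneratorConfig,
                        rng: np.random.Generator, duration_s: float,
                        onset_s: float) -> MarkerSet:
    fs = config.fs_markers
    n = round(duration_s * fs)
    t = np.arange(n) / fs

    # displacement ramp, 0 -> 1 over the rise
    ramp = np.clip((t - onset_s) / max(config.rise_s, 1e-9), 0.0, 1.0)
    s_index = profile.index_share * config.displacement_mm * ramp
    s_thumb = (1.0 - profile.index_share) * config.displacement_mm * ramp

    # wrist-frame (local) positions
    ex = np.array([1.0, 0.0, 0.0])
    index_local = _GRIP_ORIGIN + np.outer(_INDEX_OFFSET + s_index, ex)
    thumb_local = _GRIP_ORIGIN + np.outer(_THUMB_OFFSET - s_thumb, ex)
    pert_local = np.tile(_GRIP_ORIGIN + _PERT_OFFSET * ex, (n, 1))

    # slow rigid drift of the whole scene (forearm not perfectly still)
    amp, freq = config.wrist_drift_amp_mm, config.wrist_drift_freq_hz
    phases = rng.uniform(0, 2 * np.pi, size=4)
    drift = amp * np.column_stack([
        np.sin(2 * np.pi * freq * t + phases[0]),
        np.sin(2 * np.pi * freq * t + phases[1]),
        0.5 * np.sin(2 * np.pi * freq * t + phases[2]),
    ])
    axis = rng.standard_normal(3)
    angle = np.deg2rad(config.wrist_drift_rot_deg) * np.sin(
        2 * np.pi * freq * t + phases[3])
    R = _rotation_matrix(axis, angle)                       # (n, 3, 3)

    def to_world(p_local):
        return np.einsum("nij,nj->ni", R, p_local) + drift

    noise = config.marker_noise_sd_mm

    def noisy(p):
        return p + rng.normal(0.0, noise, p.shape) if noise > 0 else p

    index_w = noisy(to_world(index_local))
    thumb_w = noisy(to_world(thumb_local))
    pert_w = noisy(to_world(pert_local))
    wrist_pos = noisy(drift.copy())
    forearm_pos = noisy(to_world(np.tile(_FOREARM_OFFSET, (n, 1))))

    # stored wrist orientation carries small angular noise (pose estimation)
    if config.wrist_pose_noise_deg > 0:
        noise_axis = rng.standard_normal(3)
        noise_angle = rng.normal(
            0.0, np.deg2rad(config.wrist_pose_noise_deg), size=n)
        wrist_rot = np.einsum("nij,njk->nik",
                              _rotation_matrix(noise_axis, noise_angle), R)
    else:
        wrist_rot = R.copy()

    # artifacts: exact-zero dropouts and short label-swap segments
    for track in (index_w, thumb_w):
        drop = rng.random(n) < config.marker_dropout_prob
        track[drop] = 0.0
    if config.marker_swap_prob > 0:
        starts = np.flatnonzero(rng.random(n) < config.marker_swap_prob)
        for s in starts:
            length = 1 + rng.geometric(1.0 / config.marker_swap_mean_frames)
            sl = slice(s, min(n, s + length))
            index_w[sl], thumb_w[sl] = thumb_w[sl].copy(), index_w[sl].copy()

    return MarkerSet(t=t, index=index_w, thumb=thumb_w, perturbator=pert_w,
                     wrist_pos=wrist_pos, wrist_rot=wrist_rot,
                     forearm_pos=forearm_pos, forearm_rot=R.copy())


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Lazy collection of trials for a cohort of synthetic subjects."""

    config: GeneratorConfig
    seed: int
    profiles: list[SubjectProfile]
    specs: dict[str, list[TrialSpec]]
    relax_seeds: dict[str, int] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return sum(len(v) for v in self.specs.values())

    def iter_trials(self, channels: Sequence[str] = ALL_CHANNELS
                    ) -> Iterator[tuple[SubjectProfile, TrialSpec, TrialRecording]]:
        for profile in self.profiles:
            for spec in self.specs[profile.subject_id]:
                yield profile, spec, generate_trial(profile, spec, self.config,
                                                    channels=channels)

    def relaxation(self, subject_id: str) -> np.ndarray:
        profile = next(p for p in self.profiles if p.subject_id == subject_id)
        return generate_relaxation(profile, self.config,
                                   self.relax_seeds[subject_id])

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "generator_config": _config_echo(self.config),
            "subjects": [
                {"subject_id": p.subject_id, "seed": p.seed,
                 "mvc_force": p.mvc_force}
                for p in self.profiles],
            "trials": [
                {"subject_id": sid, "task": s.task, "force_level": s.force_level,
                 "trial_index": s.trial_index, "seed": s.seed}
                for sid in (p.subject_id for p in self.profiles)
                for s in self.specs[sid]],
        }


def _config_echo(config: GeneratorConfig) -> dict:
    import dataclasses as _dc
    d = _dc.asdict(config)
    d["cocon_offset_by_level"] = {str(k): v
                                  for k, v in d["cocon_offset_by_level"].items()}
    # JSON-stable form (tuples become lists) so manifests round-trip exactly
    return json.loads(json.dumps(d))


def generate_dataset(n_subjects: int, config: GeneratorConfig | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Build the full two-task protocol for ``n_subjects`` subjects.

    Per subject: ``len(task1_levels) * task1_reps`` task-1 trials and
    ``len(task2_levels) * task2_reps`` task-2 trials, presented in
    seed-driven randomized order (24 + 75 = 99 with the defaults).
    """
    if n_subjects < 1:
        raise InputError("n_subjects must be >= 1")
    config = config or GeneratorConfig()
    root = np.random.default_rng(seed)
    profiles: list[SubjectProfile] = []
    specs: dict[str, list[TrialSpec]] = {}
    relax_seeds: dict[str, int] = {}
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        subject_seed = int(root.integers(2 ** 31))
        profile = generate_subject(subject_seed, config, subject_id=sid)
        profiles.append(profile)
        relax_seeds[sid] = int(root.integers(2 ** 31))
        trial_specs: list[TrialSpec] = []
        for task, levels, reps in ((1, config.task1_levels, config.task1_reps),
                                   (2, config.task2_levels, config.task2_reps)):
            order = [lvl for lvl in levels for _ in range(reps)]
            root.shuffle(order)
            for j, lvl in enumerate(order):
                trial_specs.append(TrialSpec(
                    task=task, force_level=lvl, trial_index=j,
                    seed=int(root.integers(2 ** 31))))
        specs[sid] = trial_specs
    return SyntheticDataset(config=config, seed=seed, profiles=profiles,
                            specs=specs, relax_seeds=relax_seeds)


# --------------------------------------------------------------------------
# file I/O (delimited text per trial, JSON manifest)
# --------------------------------------------------------------------------

def write_trial(rec: TrialRecording, out_dir: str | Path) -> dict:
    """Write one trial's force/EMG/marker CSVs; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    if rec.force is not None:
        df = pd.DataFrame({"time_s": rec.t_force, "force_N": rec.force})
        path = out_dir / "force.csv"
        df.to_csv(path, index=False, float_format="%.8g")
        files["force"] = path.name
    if rec.emg is not None:
        t = np.arange(rec.emg.shape[1]) / rec.fs_emg
        df = pd.DataFrame({"time_s": t})
        for c, name in enumerate(CHANNELS):
            df[name] = rec.emg[c]
        path = out_dir / "emg.csv"
        df.to_csv(path, index=False, float_format="%.8g")
        files["emg"] = path.name
    if rec.markers is not None:
        m = rec.markers
        df = pd.DataFrame({"time_s": m.t})
        for name, arr in (("index", m.index), ("thumb", m.thumb),
                          ("perturbator", m.perturbator),
                          ("wrist", m.wrist_pos), ("forearm", m.forearm_pos)):
            for ax, col in zip("xyz", arr.T):
                df[f"{name}_{ax}_mm"] = col
        for name, rot in (("wrist", m.wrist_rot), ("forearm", m.forearm_rot)):
            flat = rot.reshape(len(m.t), 9)
            for k in range(9):
                df[f"{name}_r{k // 3 + 1}{k % 3 + 1}"] = flat[:, k]
        path = out_dir / "markers.csv"
        df.to_csv(path, index=False, float_format="%.8g")
        files["markers"] = path.name
    return files


def read_trial(trial_dir: str | Path, meta: dict,
               fs_force: float = 10_000.0, fs_emg: float = 4_000.0) -> TrialRecording:
    """Read a trial written by :func:`write_trial`."""
    trial_dir = Path(trial_dir)
    rec = TrialRecording(
        subject_id=meta["subject_id"], task=int(meta["task"]),
        force_level=float(meta["force_level"]),
        trial_index=int(meta["trial_index"]),
        fs_force=fs_force, fs_emg=fs_emg)
    fpath = trial_dir / "force.csv"
    if fpath.exists():
        df = pd.read_csv(fpath)
        if "force_N" not in df.columns:
            raise InputError(f"{fpath}: missing force_N column")
        rec.force = df["force_N"].to_numpy()
    epath = trial_dir / "emg.csv"
    if epath.exists():
        df = pd.read_csv(epath)
        missing = [c for c in CHANNELS if c not in df.columns]
        if missing:
            raise InputError(f"{epath}: missing channels {missing}")
        rec.emg = np.vstack([df[c].to_numpy() for c in CHANNELS])
    mpath = trial_dir / "markers.csv"
    if mpath.exists():
        df = pd.read_csv(mpath)
        n = len(df)

        def pos(name):
            return np.column_stack([df[f"{name}_{ax}_mm"] for ax in "xyz"])

        def rot(name):
            cols = [df[f"{name}_r{i}{j}"] for i in (1, 2, 3) for j in (1, 2, 3)]
            return np.column_stack(cols).reshape(n, 3, 3)

        rec.markers = MarkerSet(
            t=df["time_s"].to_numpy(), index=pos("index"), thumb=pos("thumb"),
            perturbator=pos("perturbator"), wrist_pos=pos("wrist"),
            wrist_rot=rot("wrist"), forearm_pos=pos("forearm"),
            forearm_rot=rot("forearm"))
    return rec


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
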
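"""Perturbation windowing and intrinsic stiffness estimation.

The grip perturbator elongates by a constant 7.5 mm within a few
milliseconds, so the intrinsic (a-reflexive) stiffness of one trial is
the force change over that displacement,

    k = (E_TaP(f) - E_TbP(f)) / (x_aP - x_bP),

where E_TbP and E_TaP average the (smoothed) force over a 10 ms window
T_bP just before the perturbation and a short window T_aP after it.
T_bP is found by the quiet-window rule: the latest 10 ms stretch ending
at or before the post-perturbation force peak whose sample SD falls
below a threshold; its end defines the perturbation start t_pert.  T_aP
ends at t_trust <= t_pert + 40 ms, early enough that reflexive and
voluntary responses cannot contribute.

The placement of T_aP (its length and its end t_trust) is calibrated on
a whole dataset by exhaustively minimizing an objective Z that sums, per
subject and force level, the coefficient of standard error of the
repeated task-1 stiffnesses and of the force samples inside T_aP of
every trial of both tasks.  Only task 1 enters the stiffness term: the
cocontraction level of task-2 trials cannot be commanded, so repeated
task-2 trials are not replicates of one condition.

Note on the quiet-window rule: the centered moving-average filter
spreads the onset (ma_points - 1) / 2 samples backwards, so on a clean
trace the detected t_pert leads the mechanical onset by up to half the
filter width (1.05 ms at the defaults).  Both averaging windows sit on
constant plateaus regardless, so the stiffness quotient is unaffected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import WindowConfig
from .exceptions import DetectionError, InputError, ConfigError

__all__ = [
    "PerturbationWindows", "StiffnessEstimate", "WindowOptResult",
    "smooth_force", "detect_windows", "estimate_stiffness",
    "coefficient_of_standard_error", "optimize_windows", "analyze_recordings",
]


@dataclass
class PerturbationWindows:
    """Detected analysis windows of one trial (times in seconds)."""

    t_peak: float
    t_pert: float
    t_trust: float
    tbp: tuple[float, float]      # closed interval [t_pert - 10 ms, t_pert]
    tap: tuple[float, float]      # closed interval [t_trust - T_aP, t_trust]
    i_pert: int                   # sample index of t_pert (t_start-relative)
    quality_flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not (self.tbp[1] <= self.t_pert <= self.tap[0] < self.tap[1]):
            raise InputError("window ordering violated: T_bP < t_pert <= T_aP")


@dataclass
class StiffnessEstimate:
    """Pre-perturbation force and stiffness of one trial."""

    k: float                      # N/mm
    f_pre: float                  # N, mean over T_bP
    f_post: float                 # N, mean over T_aP
    windows: PerturbationWindows
    quality_flags: set[str] = field(default_factory=set)


@dataclass
class WindowOptResult:
    """Outcome of the exhaustive T_aP placement search."""

    tap_len_ms: float
    t_trust_offset_ms: float
    objective: float
    grid: pd.DataFrame            # columns tap_len_ms, t_trust_offset_ms, Z
    n_excluded_groups: int = 0


# --------------------------------------------------------------------------

def smooth_force(trace: np.ndarray, ma_points: int = 21) -> np.ndarray:
    """Centered moving average; edges use a shrinking symmetric window."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise InputError("force trace must be one-dimensional")
    if trace.size <= ma_points:
        raise InputError(
            f"trace length {trace.size} must exceed ma_points {ma_points}")
    if ma_points % 2 == 0:
        raise InputError("ma_points must be odd")
    half = ma_points // 2
    c = np.concatenate([[0.0], np.cumsum(trace)])
    out = np.empty_like(trace)
    n = trace.size
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h
    out = (c[hi + 1] - c[lo]) / (hi - lo + 1)
    return out


def _rolling_stats(trace: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample SD (ddof=1) of every length-``w`` window ending at
    index e >= w - 1; entries for e < w - 1 are NaN."""
    n = trace.size
    c1 = np.concatenate([[0.0], np.cumsum(trace)])
    c2 = np.concatenate([[0.0], np.cumsum(trace ** 2)])
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    e = np.arange(w - 1, n)
    s1 = c1[e + 1] - c1[e + 1 - w]
    s2 = c2[e + 1] - c2[e + 1 - w]
    m = s1 / w
    var = np.clip((s2 - s1 ** 2 / w) / (w - 1), 0.0, None)
    mean[e] = m
    sd[e] = np.sqrt(var)
    return mean, sd


def detect_windows(trace: np.ndarray, cfg: WindowConfig | None = None,
                   t_start: float = 0.0) -> PerturbationWindows:
    """Locate T_bP (quiet-window rule) and place T_aP at the configured optimum.

    ``trace`` must already be smoothed (smoothing is applied once, before
    both detection and averaging).  If no window satisfies the SD bound,
    the threshold is multiplied by ``sd_rescale_factor`` up to
    ``sd_rescale_max_steps`` times; a rescale is recorded in
    ``quality_flags``.  If the criterion is still unsatisfiable a
    :class:`DetectionError` carrying the minimal SD found is raised.
    """
    cfg = cfg or WindowConfig()
    trace = np.asarray(trace, dtype=float)
    fs = cfg.sample_rate
    w = round(cfg.tbp_len_s * fs)
    if trace.size <= w:
        raise InputError("trace shorter than the T_bP window")
    i_peak = int(np.argmax(trace))
    if i_peak < round(0.25 * fs):
        raise InputError(
            "trace must span >= 250 ms before its global maximum")

    _, sd = _rolling_stats(trace, w)
    valid = np.arange(w - 1, i_peak + 1)
    if valid.size == 0:
        raise InputError("no candidate T_bP windows before the force peak")
    sd_valid = sd[valid]

    flags: set[str] = set()
    threshold = cfg.sd_threshold_n
    i_pert = None
    min_count = max(1, int(np.ceil(cfg.sd_quiet_min_frac * sd_valid.size)))
    for step in range(cfg.sd_rescale_max_steps + 1):
        if threshold > cfg.sd_threshold_max_n:
            break
        below = np.flatnonzero(sd_valid < threshold)
        # demand that the rung admits a plateau's worth of quiet windows,
        # not a single noise fluctuation
        if below.size >= min_count:
            i_pert = int(valid[below[-1]])
            if step:
                flags.add(f"sd-threshold-rescaled:{step}")
            break
        threshold *= cfg.sd_rescale_factor
    if i_pert is None:
        raise DetectionError(
            "no 10 ms window satisfies the SD criterion "
            f"(min SD {np.nanmin(sd_valid):.3g} N)",
            min_sd=float(np.nanmin(sd_valid)))

    t_pert = t_start + i_pert / fs
    t_trust = t_pert + cfg.t_trust_offset_ms / 1e3
    tap_len = cfg.tap_len_ms / 1e3
    if cfg.t_trust_offset_ms > cfg.trust_max_ms:
        raise ConfigError("t_trust_offset_ms exceeds trust_max_ms")
    return PerturbationWindows(
        t_peak=t_start + i_peak / fs,
        t_pert=t_pert,
        t_trust=t_trust,
        tbp=(t_pert - cfg.tbp_len_s, t_pert),
        tap=(t_trust - tap_len, t_trust),
        i_pert=i_pert,
        quality_flags=flags,
    )


def _window_slice(trace_len: int, fs: float, t_start: float,
                  interval: tuple[float, float], end_inclusive: bool = True) -> slice:
    i0 = round((interval[0] - t_start) * fs)
    i1 = round((interval[1] - t_start) * fs)
    if end_inclusive:
        i1 += 1
    if i0 < 0 or i1 > trace_len or i1 <= i0:
        raise InputError("analysis window outside the trace support")
    return slice(i0, i1)


def estimate_stiffness(trace: np.ndarray, windows: PerturbationWindows,
                       cfg: WindowConfig | None = None,
                       t_start: float = 0.0) -> StiffnessEstimate:
    """Stiffness quotient over the detected windows (smoothed trace)."""
    cfg = cfg or WindowConfig()
    trace = np.asarray(trace, dtype=float)
    fs = cfg.sample_rate
    # T_bP averaged over tbp_len samples ending at i_pert, matching detection
    w = round(cfg.tbp_len_s * fs)
    sl_pre = slice(windows.i_pert - w + 1, windows.i_pert + 1)
    if sl_pre.start < 0:
        raise InputError("T_bP outside the trace support")
    sl_post = _window_slice(trace.size, fs, t_start, windows.tap)
    if sl_post.stop - sl_post.start < 1:
        raise InputError("empty T_aP window")
    f_pre = float(np.mean(trace[sl_pre]))
    f_post = float(np.mean(trace[sl_post]))
    k = (f_post - f_pre) / cfg.displacement_mm
    return StiffnessEstimate(k=k, f_pre=f_pre, f_post=f_post, windows=windows,
                             quality_flags=set(windows.quality_flags))


def coefficient_of_standard_error(samples) -> float:
    """Dimensionless dispersion: sample SD over (mean * sqrt(n)).

    Combines the coefficient of variation with the standard error, so that
    at equal CV a smaller sample scores worse.  Requires n >= 2 and a
    positive mean.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise InputError("coefficient of standard error needs n >= 2")
    mu = x.mean()
    if mu <= 0:
        raise InputError("coefficient of standard error needs a positive mean")
    return float(x.std(ddof=1) / (mu * np.sqrt(x.size)))


# --------------------------------------------------------------------------
# window-placement objective
# --------------------------------------------------------------------------

@dataclass
class _TrialArrays:
    subject: str
    task: int
    level: float
    f_pre: float
    mean0: float       # trace mean, the centering offset
    c1: np.ndarray     # cumsum of the centered smoothed trace
    c2: np.ndarray     # cumsum of its square
    i_pert: int
    n: int


def _prepare_trial(subject: str, task: int, level: float,
                   smoothed: np.ndarray, i_pert: int,
                   cfg: WindowConfig) -> _TrialArrays:
    w = round(cfg.tbp_len_s * cfg.sample_rate)
    f_pre = float(np.mean(smoothed[i_pert - w + 1: i_pert + 1]))
    mean0 = float(smoothed.mean())
    centered = smoothed - mean0     # centering tames cumsum cancellation
    return _TrialArrays(
        subject=subject, task=task, level=level, f_pre=f_pre, mean0=mean0,
        c1=np.concatenate([[0.0], np.cumsum(centered)]),
        c2=np.concatenate([[0.0], np.cumsum(centered ** 2)]),
        i_pert=i_pert, n=smoothed.size)


def _tap_stats(tr: _TrialArrays, i_lo: np.ndarray, i_hi: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and ẽ of the force samples in [i_lo, i_hi] (inclusive) for a
    vector of grid points."""
    w = i_hi - i_lo + 1
    s1 = tr.c1[i_hi + 1] - tr.c1[i_lo]
    s2 = tr.c2[i_hi + 1] - tr.c2[i_lo]
    mean = tr.mean0 + s1 / w
    var = np.clip((s2 - s1 ** 2 / w) / (w - 1), 0.0, None)
    e = np.sqrt(var) / (mean * np.sqrt(w))
    return mean, e


def optimize_windows(trials, cfg: WindowConfig | None = None,
                     grid_resolution_ms: float | None = None) -> WindowOptResult:
    """Exhaustive grid search for the T_aP placement minimizing Z.

    ``trials`` is an iterable of dicts (or objects with attributes)
    carrying ``subject``, ``task``, ``level``, ``smoothed`` (force trace
    after the moving average) and ``i_pert`` (detected perturbation start,
    sample index).  Ties in the argmin are broken towards the smallest
    t_trust offset, then the smallest T_aP length (earliest trusted data).

    Task-1 (subject, level) groups with fewer than two trials cannot
    contribute a stiffness ẽ and are excluded with a warning.
    """
    cfg = cfg or WindowConfig()
    res = grid_resolution_ms or cfg.grid_resolution_ms
    fs = cfg.sample_rate
    lo_ms, hi_ms = cfg.tap_len_range_ms

    n_tap = int(round((hi_ms - lo_ms) / res))
    tap_values = lo_ms + res * np.arange(n_tap + 1)
    pairs = []
    for tap in tap_values:
        n_off = int(round((cfg.trust_max_ms - tap) / res))
        for off in tap + res * np.arange(n_off + 1):
            pairs.append((tap, off))
    if not pairs:
        raise ConfigError("empty window-placement grid")
    pairs_arr = np.array(pairs)                                  # (G, 2)
    tap_n = np.round(pairs_arr[:, 0] / 1e3 * fs).astype(int)
    off_n = np.round(pairs_arr[:, 1] / 1e3 * fs).astype(int)

    prepared: list[_TrialArrays] = []
    for tr in trials:
        get = tr.get if isinstance(tr, dict) else lambda k, _t=tr: getattr(_t, k)
        prepared.append(_prepare_trial(
            get("subject"), get("task"), get("level"),
            np.asarray(get("smoothed"), dtype=float), int(get("i_pert")), cfg))

    G = len(pairs)
    groups: dict[tuple[str, float], dict] = {}
    for tr in prepared:
        i_hi = tr.i_pert + off_n
        i_lo = i_hi - tap_n + 1
        if i_hi.max() >= tr.n:
            raise InputError("trace too short for the largest t_trust offset")
        mean, e_force = _tap_stats(tr, i_lo, i_hi)
        g = groups.setdefault((tr.subject, tr.level), {
            "k1": [], "e1": [], "e2": []})
        if tr.task == 1:
            g["k1"].append((mean - tr.f_pre) / cfg.displacement_mm)   # (G,)
            g["e1"].append(e_force)
        else:
            g["e2"].append(e_force)

    per_subject: dict[str, list[np.ndarray]] = {}
    n_excluded = 0
    for (subject, level), g in groups.items():
        if len(g["k1"]) < 2:
            warnings.warn(
                f"subject {subject} level {level}: fewer than two task-1 "
                "trials; group excluded from the objective", stacklevel=2)
            n_excluded += 1
            continue
        k1 = np.vstack(g["k1"])                                   # (n1, G)
        mu = k1.mean(axis=0)
        sd = k1.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            e_k = sd / (mu * np.sqrt(k1.shape[0]))
        e_k = np.where(mu > 0, e_k, np.inf)
        term = e_k + np.mean(np.vstack(g["e1"]), axis=0)
        if g["e2"]:
            term = term + np.mean(np.vstack(g["e2"]), axis=0)
        per_subject.setdefault(subject, []).append(term)

    if not per_subject:
        raise InputError("no usable (subject, level) groups for the objective")
    Z = np.mean([np.mean(np.vstack(terms), axis=0)
                 for terms in per_subject.values()], axis=0)      # (G,)

    z_min = float(np.min(Z))
    # placements within 1e-6 of the minimum are practically equivalent
    # (and below the numerical floor of the cumsum evaluation); the
    # tie-break then prefers the earliest trusted data
    tol = 1e-6 * max(1.0, abs(z_min))
    tied = np.flatnonzero(Z <= z_min + tol)
    # smallest offset first, then smallest tap length
    order = np.lexsort((pairs_arr[tied, 0], pairs_arr[tied, 1]))
    best = tied[order[0]]
    grid = pd.DataFrame({"tap_len_ms": pairs_arr[:, 0],
                         "t_trust_offset_ms": pairs_arr[:, 1], "Z": Z})
    return WindowOptResult(
        tap_len_ms=float(pairs_arr[best, 0]),
        t_trust_offset_ms=float(pairs_arr[best, 1]),
        objective=float(Z[best]), grid=grid, n_excluded_groups=n_excluded)


# --------------------------------------------------------------------------
# batch driver
# --------------------------------------------------------------------------

def analyze_recordings(recordings, cfg: WindowConfig | None = None,
                       keep_traces: bool = False):
    """Smooth, detect and estimate for an iterable of TrialRecording.

    Returns ``(table, failures, trials)``: a per-trial DataFrame, a list of
    (metadata, error) pairs for trials where detection failed, and — when
    ``keep_traces`` — the per-trial dicts consumed by
    :func:`optimize_windows`.
    """
    cfg = cfg or WindowConfig()
    rows, failures, kept = [], [], []
    for rec in recordings:
        try:
            smoothed = smooth_force(rec.force, cfg.ma_points)
            win = detect_windows(smoothed, cfg)
            est = estimate_stiffness(smoothed, win, cfg)
        except (DetectionError, InputError) as err:
            failures.append((rec.metadata, err))
            continue
        rows.append({**rec.metadata, "f_pre_N": est.f_pre,
                     "k_N_per_mm": est.k, "t_pert_s": win.t_pert,
                     "flags": ";".join(sorted(est.quality_flags))})
        if keep_traces:
            kept.append({"subject": rec.subject_id, "task": rec.task,
                         "level": rec.force_level, "smoothed": smoothed,
                         "i_pert": win.i_pert})
    table = pd.DataFrame(rows)
    return table, failures, kept
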
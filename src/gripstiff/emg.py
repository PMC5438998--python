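"""Surface-EMG filtering and activation features.

The muscular activation feature is the average rectified value (ARV) of
the zero-phase band-passed (25-450 Hz, second-order Butterworth) EMG
over a 200 ms window that ends just before the perturbation.  The
electrodes deliver their signal with a constant 48 ms delay, so by
default the window ends at ``t_pert - 48 ms`` (configurable).

Per-electrode base noise, measured as the ARV of a quiet 500 ms stretch
of a relaxation recording, is subtracted subject-wise.  Features are
then normalized per subject and electrode: divide by the within-subject
maximum, then by the SD of the max-normalized values.  This two-step
normalization is deliberately invariant to any positive per-electrode
gain — the property that makes regression across subjects meaningful
despite arbitrary electrode placement and skin impedance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import CHANNELS, EMGConfig
from .exceptions import ConfigError, InputError, NormalizationError

__all__ = [
    "BaselineRecord", "bandpass_emg", "arv", "find_baseline_window",
    "subtract_baseline", "two_step_normalize", "normalize_subject",
    "collapse_duplicated", "to_acquisition_grid", "extract_features",
]


@dataclass
class BaselineRecord:
    """Per-electrode base-noise ARV from a quiet window of a relaxation
    recording (identical window across electrodes)."""

    arv: dict[str, float]                 # electrode -> base ARV (signal units)
    window: tuple[float, float]           # (start_s, end_s)


def bandpass_emg(trace: np.ndarray, cfg: EMGConfig | None = None) -> np.ndarray:
    """Zero-phase (forward-backward) second-order Butterworth bandpass."""
    cfg = cfg or EMGConfig()
    if cfg.sample_rate <= 2 * cfg.band_high_hz:
        raise ConfigError("sample rate must exceed twice the upper band edge")
    trace = np.asarray(trace, dtype=float)
    sos = signal.butter(cfg.order, [cfg.band_low_hz, cfg.band_high_hz],
                        btype="bandpass", fs=cfg.sample_rate, output="sos")
    return signal.sosfiltfilt(sos, trace, axis=-1)


def arv(trace: np.ndarray, fs: float, window: tuple[float, float]) -> float:
    """Average rectified value: mean of |x| over ``window`` (seconds,
    relative to the start of ``trace``)."""
    trace = np.asarray(trace, dtype=float)
    i0 = round(window[0] * fs)
    i1 = round(window[1] * fs)
    if i0 < 0 or i1 > trace.size or i1 <= i0:
        raise InputError(f"ARV window {window} outside the trace support")
    return float(np.mean(np.abs(trace[i0:i1])))


def find_baseline_window(relaxation: np.ndarray, cfg: EMGConfig | None = None
                         ) -> BaselineRecord:
    """Automated quiet-window pick: the 500 ms window with the minimal
    summed ARV across electrodes (identical window for all electrodes).

    ``relaxation`` is a (6, n) array in CHANNELS order.
    """
    cfg = cfg or EMGConfig()
    relaxation = np.asarray(relaxation, dtype=float)
    if relaxation.ndim != 2 or relaxation.shape[0] != len(CHANNELS):
        raise InputError("relaxation recording must be (6, n) in channel order")
    w = round(cfg.baseline_window_s * cfg.sample_rate)
    n = relaxation.shape[1]
    if n < w:
        raise InputError("relaxation recording shorter than the baseline window")
    filtered = bandpass_emg(relaxation, cfg)
    rect = np.abs(filtered)
    csum = np.concatenate([np.zeros((len(CHANNELS), 1)),
                           np.cumsum(rect, axis=1)], axis=1)
    window_arv = (csum[:, w:] - csum[:, :-w]) / w        # (6, n - w + 1)
    start = int(np.argmin(window_arv.sum(axis=0)))
    return BaselineRecord(
        arv={name: float(window_arv[c, start])
             for c, name in enumerate(CHANNELS)},
        window=(start / cfg.sample_rate, (start + w) / cfg.sample_rate))


def subtract_baseline(arv_raw: dict[str, float],
                      baseline: BaselineRecord) -> dict[str, float]:
    """Elementwise ``arv_raw - baseline``; negatives are kept (flagged by
    the caller) so the subsequent normalization stays affine."""
    if set(arv_raw) != set(baseline.arv):
        raise InputError(
            f"electrode mismatch: features {sorted(arv_raw)} vs "
            f"baseline {sorted(baseline.arv)}")
    return {name: arv_raw[name] - baseline.arv[name] for name in arv_raw}


def two_step_normalize(values: np.ndarray, label: str = "series") -> np.ndarray:
    """Divide by the maximum, then by the SD of the max-normalized values.

    Applied per electrode within subject to the ARV features and, with the
    same semantics, to the force and stiffness targets.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InputError(f"{label}: need >= 2 values to normalize")
    mx = x.max()
    if mx <= 0:
        raise NormalizationError(f"{label}: non-positive maximum {mx:.3g}")
    x = x / mx
    sd = x.std(ddof=1)
    if sd == 0:
        raise NormalizationError(f"{label}: zero SD after max-normalization")
    return x / sd


def normalize_subject(features: pd.DataFrame,
                      columns: tuple[str, ...] = CHANNELS) -> pd.DataFrame:
    """Two-step normalization of each electrode column across all trials of
    one subject.  Never pool across subjects."""
    if len(features) < 2:
        raise InputError("need >= 2 trials per subject to normalize")
    out = features.copy()
    for name in columns:
        out[name] = two_step_normalize(features[name].to_numpy(), label=name)
    return out


# --------------------------------------------------------------------------
# acquisition-grid helpers
# --------------------------------------------------------------------------

def to_acquisition_grid(trace: np.ndarray, fs_native: float,
                        fs_acq: float) -> np.ndarray:
    """Sample-and-hold upsampling of a native-rate signal onto the faster
    acquisition grid (e.g. 4 kHz electrode output read out at 10 kHz)."""
    n = np.asarray(trace).shape[-1]
    idx = np.minimum((np.arange(round(n * fs_acq / fs_native))
                      * fs_native / fs_acq).astype(int), n - 1)
    return np.asarray(trace)[..., idx]


def collapse_duplicated(trace: np.ndarray, fs_acq: float,
                        fs_native: float) -> np.ndarray:
    """Undo sample-and-hold oversampling: keep the first acquisition sample
    of each native-rate period, recovering the native-rate series before
    filtering."""
    n = np.asarray(trace).shape[-1]
    idx = np.ceil(np.arange(round(n * fs_native / fs_acq))
                  * fs_acq / fs_native - 1e-9).astype(int)
    idx = idx[idx < n]
    return np.asarray(trace)[..., idx]


# --------------------------------------------------------------------------
# batch feature extraction
# --------------------------------------------------------------------------

def extract_features(emg: np.ndarray, t_pert: float,
                     baseline: BaselineRecord | None = None,
                     cfg: EMGConfig | None = None) -> dict:
    """Raw and baseline-corrected ARV features for one trial.

    The activation window spans ``arv_window_s`` and ends at
    ``t_pert - electrode_delay_s``.  Returns a dict with per-channel
    ``arv_raw``/``arv_corrected`` and a ``flags`` set (negative corrected
    values are flagged, not clipped).
    """
    cfg = cfg or EMGConfig()
    emg = np.asarray(emg, dtype=float)
    if emg.ndim != 2 or emg.shape[0] != len(CHANNELS):
        raise InputError("EMG array must be (6, n) in channel order")
    end = t_pert - cfg.electrode_delay_s
    window = (end - cfg.arv_window_s, end)
    filtered = bandpass_emg(emg, cfg)
    raw = {name: arv(filtered[c], cfg.sample_rate, window)
           for c, name in enumerate(CHANNELS)}
    flags: set[str] = set()
    if baseline is not None:
        corrected = subtract_baseline(raw, baseline)
        for name, v in corrected.items():
            if v < 0:
                flags.add(f"negative-corrected-arv:{name}")
    else:
        corrected = dict(raw)
    return {"arv_raw": raw, "arv_corrected": corrected, "flags": flags}
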
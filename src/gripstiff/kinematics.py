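"""Marker-track cleaning and digit displacement partition.

The perturbator elongates by a constant 7.5 mm; optical markers on the
index and thumb tips reveal how that displacement is split between the
two digits — a direct readout of their relative stiffness (the stiffer
digit moves less).  Digit positions are expressed in the wrist frame so
slow forearm drift does not masquerade as grip displacement, and each
digit's displacement is the Euclidean norm of the difference between
its mean wrist-frame position over T_bP and over T_aP, divided by the
7.5 mm total.

Marker artifacts are handled as in practice with optical tracking of
small reflective markers: frames that are exactly zero (marker lost) or
that jump faster than a physiological speed bound are masked missing,
and the index/thumb identities — which cameras occasionally swap — are
reassigned per frame by each marker's distance to the perturbator body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import KinematicsConfig
from .exceptions import InputError

__all__ = [
    "DigitDisplacement", "angular_distance", "clean_marker_track",
    "assign_digit_labels", "digit_displacements",
]

_ROT_TOL = 1e-6


@dataclass
class DigitDisplacement:
    """Perturbation displacement split, as % of the 7.5 mm elongation."""

    index_pct: float
    thumb_pct: float
    total_pct: float
    masked_fraction: float
    flags: set[str]


def _check_rotation(r: np.ndarray, name: str) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise InputError(f"{name} must be a 3x3 matrix")
    if np.max(np.abs(r @ r.T - np.eye(3))) > _ROT_TOL * 10:
        raise InputError(f"{name} is not orthonormal within tolerance")
    if np.linalg.det(r) < 0:
        raise InputError(f"{name} is not a proper rotation (det < 0)")
    return r


def angular_distance(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle between two rotations, in degrees.

    ``arccos((trace(R2 @ R1^-1) - 1) / 2)``, with the argument clamped to
    [-1, 1] against round-off; result in [0, 180].
    """
    r1 = _check_rotation(r1, "r1")
    r2 = _check_rotation(r2, "r2")
    c = (np.trace(r2 @ r1.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def clean_marker_track(track: np.ndarray, fs: float,
                       speed_bound_m_s: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Mask artifact frames of one marker track.

    A frame is masked when it is exactly zero (lost marker), already NaN,
    or when its jump from the last unmasked frame exceeds the speed bound.
    Returns ``(cleaned, mask)`` where masked frames are NaN and ``mask`` is
    True for missing frames.  The input is not modified.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 3:
        raise InputError("marker track must be (n, 3)")
    n = track.shape[0]
    mask = np.all(track == 0.0, axis=1) | np.isnan(track).any(axis=1)
    bound_mm = speed_bound_m_s * 1000.0 / fs       # mm per frame
    last_valid: np.ndarray | None = None
    for i in range(n):
        if mask[i]:
            continue
        if last_valid is not None:
            if np.linalg.norm(track[i] - last_valid) > bound_mm:
                mask[i] = True
                continue
        last_valid = track[i]
    cleaned = track.copy()
    cleaned[mask] = np.nan
    return cleaned, mask


def assign_digit_labels(track_a: np.ndarray, track_b: np.ndarray,
                        perturbator: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reassign index/thumb identities per frame by proximity to the
    perturbator body (the index marker sits closer to it).

    Frames with NaN in either track are left as given.  Returns
    ``(index_track, thumb_track)``.
    """
    a = np.asarray(track_a, dtype=float).copy()
    b = np.asarray(track_b, dtype=float).copy()
    p = np.asarray(perturbator, dtype=float)
    if not (a.shape == b.shape == p.shape):
        raise InputError("digit and perturbator tracks must be time-aligned")
    da = np.linalg.norm(a - p, axis=1)
    db = np.linalg.norm(b - p, axis=1)
    with np.errstate(invalid="ignore"):
        swap = da > db
    swap &= ~(np.isnan(da) | np.isnan(db))
    a[swap], b[swap] = b[swap], a[swap].copy()
    return a, b


def _to_wrist_frame(points: np.ndarray, wrist_pos: np.ndarray,
                    wrist_rot: np.ndarray) -> np.ndarray:
    """World -> wrist-frame coordinates, per frame."""
    return np.einsum("nji,nj->ni", wrist_rot, points - wrist_pos)


def _frame_slice(n: int, fs: float, interval: tuple[float, float]) -> slice:
    i0 = int(np.ceil(interval[0] * fs - 1e-9))
    i1 = int(np.floor(interval[1] * fs + 1e-9)) + 1
    if i0 < 0 or i1 > n or i1 <= i0:
        raise InputError("analysis window outside the marker track support")
    return slice(i0, i1)


def digit_displacements(index: np.ndarray, thumb: np.ndarray,
                        wrist_pos: np.ndarray, wrist_rot: np.ndarray,
                        windows, cfg: KinematicsConfig | None = None,
                        masks: tuple[np.ndarray, np.ndarray] | None = None
                        ) -> DigitDisplacement:
    """Partition the perturbation displacement between the digits.

    ``windows`` provides the same T_bP/T_aP intervals used for the
    stiffness quotient (attribute access: ``tbp``, ``tap``).  Masked
    frames (NaN, or True in ``masks``) are excluded from the window means;
    a trial with more than ``max_masked_frac`` missing frames inside the
    windows is rejected.
    """
    cfg = cfg or KinematicsConfig()
    fs = cfg.sample_rate
    index = np.asarray(index, dtype=float)
    thumb = np.asarray(thumb, dtype=float)
    n = index.shape[0]
    idx_w = _to_wrist_frame(index, wrist_pos, wrist_rot)
    thm_w = _to_wrist_frame(thumb, wrist_pos, wrist_rot)

    missing = np.isnan(idx_w).any(axis=1) | np.isnan(thm_w).any(axis=1)
    if masks is not None:
        missing |= masks[0] | masks[1]

    sl_pre = _frame_slice(n, fs, windows.tbp)
    sl_post = _frame_slice(n, fs, windows.tap)
    in_windows = np.zeros(n, dtype=bool)
    in_windows[sl_pre] = True
    in_windows[sl_post] = True
    masked_fraction = float(missing[in_windows].mean())
    flags: set[str] = set()
    if masked_fraction > cfg.max_masked_frac:
        raise InputError(
            f"{masked_fraction:.0%} of frames masked inside the analysis "
            "windows; trial unusable")
    if masked_fraction > 0:
        flags.add("masked-frames-in-windows")

    def window_mean(points, sl):
        ok = ~missing[sl]
        if not ok.any():
            raise InputError("all frames masked inside an analysis window")
        return points[sl][ok].mean(axis=0)

    d_index = np.linalg.norm(window_mean(idx_w, sl_post)
                             - window_mean(idx_w, sl_pre))
    d_thumb = np.linalg.norm(window_mean(thm_w, sl_post)
                             - window_mean(thm_w, sl_pre))
    scale = 100.0 / cfg.displacement_mm
    return DigitDisplacement(
        index_pct=float(d_index * scale), thumb_pct=float(d_thumb * scale),
        total_pct=float((d_index + d_thumb) * scale),
        masked_fraction=masked_fraction, flags=flags)


def analyze_markers(markers, windows, cfg: KinematicsConfig | None = None
                    ) -> DigitDisplacement:
    """Full kinematic chain for one trial.

    Order matters: exact-zero dropouts are masked first (a zero frame would
    defeat the proximity rule), then index/thumb identities are restored
    per frame by perturbator proximity, then remaining implausible jumps
    are masked by the speed bound.
    """
    cfg = cfg or KinematicsConfig()
    idx, _ = clean_marker_track(markers.index, cfg.sample_rate, np.inf)
    thm, _ = clean_marker_track(markers.thumb, cfg.sample_rate, np.inf)
    idx, thm = assign_digit_labels(idx, thm, markers.perturbator)
    idx, m_idx = clean_marker_track(idx, cfg.sample_rate, cfg.speed_bound_m_s)
    thm, m_thm = clean_marker_track(thm, cfg.sample_rate, cfg.speed_bound_m_s)
    return digit_displacements(idx, thm, markers.wrist_pos, markers.wrist_rot,
                               windows, cfg, masks=(m_idx, m_thm))
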
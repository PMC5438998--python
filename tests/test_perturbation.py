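"""Window detection, the stiffness quotient, and the placement objective."""

import dataclasses

import numpy as np
import pytest

from gripstiff import (DetectionError, WindowConfig, coefficient_of_standard_error,
                       detect_windows, estimate_stiffness, generate_subject,
                       generate_trial, optimize_windows, smooth_force)
from gripstiff.exceptions import InputError
from gripstiff.perturbation import PerturbationWindows
from gripstiff.synth import TrialSpec


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def test_smooth_constant_is_identity():
    x = np.full(500, 3.7)
    np.testing.assert_allclose(smooth_force(x, 21), x)


def test_smooth_impulse_spreads_to_plateau():
    x = np.zeros(401)
    x[200] = 1.0
    out = smooth_force(x, 21)
    np.testing.assert_allclose(out[190:211], 1 / 21, atol=1e-15)
    assert out[189] == 0.0 and out[211] == 0.0


def test_smooth_matches_bruteforce_windowed_mean():
    rng = np.random.default_rng(0)
    x = rng.normal(size=2000)
    out = smooth_force(x, 21)
    for i in rng.integers(10, 1990, size=100):
        assert out[i] == pytest.approx(x[i - 10:i + 11].mean(), abs=1e-12)


def test_smooth_rejects_short_trace():
    with pytest.raises(InputError):
        smooth_force(np.ones(10), 21)


# --------------------------------------------------------------------------
# window detection
# --------------------------------------------------------------------------

def _analyzed_quiet_trial(quiet_cfg, k_true=2.0, f_pre=10.0, seed=5,
                          wcfg=None):
    profile = generate_subject(1, quiet_cfg)
    profile.tremor_sd = 0.0
    profile.oscillation_amp = 0.0
    spec = TrialSpec(task=1, force_level=0.25, trial_index=0, seed=seed,
                     k_true=k_true, f_pre=f_pre)
    rec = generate_trial(profile, spec, quiet_cfg, channels=("force",))
    wcfg = wcfg or WindowConfig()
    sm = smooth_force(rec.force, wcfg.ma_points)
    return rec, sm, wcfg


def test_detect_onset_on_noise_free_trial(quiet_cfg):
    """The quiet-window rule places t_pert within half the moving-average
    width (plus one sample) of the true onset."""
    rec, sm, wcfg = _analyzed_quiet_trial(quiet_cfg)
    win = detect_windows(sm, wcfg)
    lead = (wcfg.ma_points - 1) / 2 / wcfg.sample_rate + 1 / wcfg.sample_rate
    assert rec.true_params["onset_s"] - lead <= win.t_pert \
        <= rec.true_params["onset_s"]
    assert win.quality_flags == set()


def test_detect_fails_on_monotone_ramp():
    fs = 10_000.0
    t = np.arange(int(0.6 * fs)) / fs
    ramp = 1.0 + 30.0 * t
    with pytest.raises(DetectionError) as exc:
        detect_windows(smooth_force(ramp, 21), WindowConfig())
    assert exc.value.min_sd is not None and exc.value.min_sd > 0


def test_detect_translation_equivariance(quiet_cfg):
    rec, sm, wcfg = _analyzed_quiet_trial(quiet_cfg)
    a = detect_windows(sm, wcfg, t_start=0.0)
    b = detect_windows(sm, wcfg, t_start=0.05)
    for attr in ("t_peak", "t_pert", "t_trust"):
        assert getattr(b, attr) - getattr(a, attr) == pytest.approx(0.05)
    assert b.tbp[0] - a.tbp[0] == pytest.approx(0.05)
    assert b.tap[1] - a.tap[1] == pytest.approx(0.05)


def test_detect_requires_pre_peak_span():
    fs = 10_000.0
    x = np.concatenate([np.ones(500), np.full(2000, 5.0)])
    with pytest.raises(InputError):
        detect_windows(smooth_force(x, 21), WindowConfig())


def test_window_legality_on_noisy_trials(gen_cfg):
    """Every detected window set respects t_trust <= t_pert + 40 ms and the
    T_bP-before-T_aP ordering."""
    root = np.random.default_rng(11)
    wcfg = WindowConfig()
    for _ in range(20):
        profile = generate_subject(int(root.integers(2 ** 31)), gen_cfg)
        spec = TrialSpec(task=2, force_level=0.35, trial_index=0,
                         seed=int(root.integers(2 ** 31)))
        rec = generate_trial(profile, spec, gen_cfg, channels=("force",))
        win = detect_windows(smooth_force(rec.force, wcfg.ma_points), wcfg)
        assert win.t_trust <= win.t_pert + wcfg.trust_max_ms / 1e3 + 1e-12
        assert win.tbp[1] <= win.t_pert <= win.tap[0] < win.tap[1] == win.t_trust


# --------------------------------------------------------------------------
# stiffness quotient
# --------------------------------------------------------------------------

def _manual_windows(fs=10_000.0):
    t_pert = 0.5
    return PerturbationWindows(
        t_peak=0.52, t_pert=t_pert, t_trust=t_pert + 100 / 3 / 1e3,
        tbp=(t_pert - 0.01, t_pert),
        tap=(t_pert + 0.015, t_pert + 100 / 3 / 1e3),
        i_pert=int(t_pert * fs))


def test_stiffness_quotient_arithmetic():
    """10 N before, 25 N after, 7.5 mm displacement -> 2 N/mm."""
    trace = np.concatenate([np.full(5001, 10.0), np.full(2199, 25.0)])
    est = estimate_stiffness(trace, _manual_windows(), WindowConfig())
    assert est.k == pytest.approx(2.0, abs=1e-12)
    assert est.f_pre == pytest.approx(10.0)
    assert est.f_post == pytest.approx(25.0)


def test_stiffness_zero_when_no_force_step():
    trace = np.full(7200, 10.0)
    est = estimate_stiffness(trace, _manual_windows(), WindowConfig())
    assert est.k == 0.0


def test_stiffness_exact_on_noise_free_trials(quiet_cfg):
    """Eq-exactness invariant: the estimator returns k_true to numerical
    precision for every legal T_aP placement."""
    for tap_len, offset in ((5.0, 40.0), (10.0, 20.0), (55 / 3, 100 / 3),
                            (20.0, 25.0)):
        wcfg = WindowConfig(tap_len_ms=tap_len, t_trust_offset_ms=offset)
        for k_true in (0.5, 1.2, 3.3):
            rec, sm, _ = _analyzed_quiet_trial(quiet_cfg, k_true=k_true)
            win = detect_windows(sm, wcfg)
            est = estimate_stiffness(sm, win, wcfg)
            assert est.k == pytest.approx(k_true, abs=1e-10)
            assert est.f_pre == pytest.approx(10.0, abs=1e-10)


def test_stiffness_estimate_default_noise_mean(gen_cfg):
    """Mean estimate over 100 seeded trials at k_true = 1.2 N/mm stays
    within 2 % of the truth."""
    root = np.random.default_rng(3)
    wcfg = WindowConfig()
    ks = []
    for _ in range(100):
        profile = generate_subject(int(root.integers(2 ** 31)), gen_cfg)
        spec = TrialSpec(task=1, force_level=0.25, trial_index=0,
                         seed=int(root.integers(2 ** 31)), k_true=1.2)
        rec = generate_trial(profile, spec, gen_cfg, channels=("force",))
        sm = smooth_force(rec.force, wcfg.ma_points)
        est = estimate_stiffness(sm, detect_windows(sm, wcfg), wcfg)
        ks.append(est.k)
    assert np.mean(ks) == pytest.approx(1.2, rel=0.02)


# --------------------------------------------------------------------------
# coefficient of standard error
# --------------------------------------------------------------------------

def test_cse_zero_for_constant_samples():
    assert coefficient_of_standard_error([2.5, 2.5, 2.5]) == 0.0


def test_cse_hand_computed_value():
    # s = sqrt(2), mu = 2, n = 2 -> 0.5
    assert coefficient_of_standard_error([1.0, 3.0]) == pytest.approx(0.5)


def test_cse_duplication_scaling():
    rng = np.random.default_rng(4)
    x = rng.uniform(1, 2, size=13)
    e1 = coefficient_of_standard_error(x)
    e2 = coefficient_of_standard_error(np.repeat(x, 2))
    # doubling n leaves SD and mean (nearly) unchanged, halving by sqrt(2);
    # np.repeat changes ddof=1 SD slightly, hence the loose tolerance
    assert e2 == pytest.approx(e1 / np.sqrt(2), rel=0.05)


def test_cse_input_guards():
    with pytest.raises(InputError):
        coefficient_of_standard_error([1.0])
    with pytest.raises(InputError):
        coefficient_of_standard_error([-1.0, -3.0])


# --------------------------------------------------------------------------
# window-placement objective
# --------------------------------------------------------------------------

def _z_oracle(trials, tap_ms, off_ms, cfg):
    """Independent brute-force evaluation of the placement objective."""
    fs = cfg.sample_rate
    groups = {}
    for tr in trials:
        i_hi = tr["i_pert"] + round(off_ms * fs / 1e3)
        tap_n = round(tap_ms * fs / 1e3)
        seg = tr["smoothed"][i_hi - tap_n + 1: i_hi + 1]
        e_f = np.std(seg, ddof=1) / (np.mean(seg) * np.sqrt(len(seg)))
        w = round(cfg.tbp_len_s * fs)
        f_pre = np.mean(tr["smoothed"][tr["i_pert"] - w + 1: tr["i_pert"] + 1])
        k = (np.mean(seg) - f_pre) / cfg.displacement_mm
        groups.setdefault((tr["subject"], tr["level"]), []).append(
            (tr["task"], k, e_f))
    per_subject = {}
    for (sub, level), items in groups.items():
        k1 = [k for task, k, _ in items if task == 1]
        if len(k1) < 2:
            continue
        e_k = np.std(k1, ddof=1) / (np.mean(k1) * np.sqrt(len(k1)))
        e1 = [e for task, _, e in items if task == 1]
        e2 = [e for task, _, e in items if task == 2]
        term = e_k + np.mean(e1) + (np.mean(e2) if e2 else 0.0)
        per_subject.setdefault(sub, []).append(term)
    return np.mean([np.mean(v) for v in per_subject.values()])


def _small_cohort(cfg, seed=21, n_subjects=2, reps=3):
    root = np.random.default_rng(seed)
    wcfg = WindowConfig()
    trials = []
    for i in range(n_subjects):
        profile = generate_subject(int(root.integers(2 ** 31)), cfg)
        for task, levels in ((1, (0.25, 0.45)), (2, (0.25, 0.45))):
            for lvl in levels:
                for j in range(reps):
                    spec = TrialSpec(task=task, force_level=lvl,
                                     trial_index=j,
                                     seed=int(root.integers(2 ** 31)))
                    rec = generate_trial(profile, spec, cfg,
                                         channels=("force",))
                    sm = smooth_force(rec.force, wcfg.ma_points)
                    win = detect_windows(sm, wcfg)
                    trials.append({"subject": f"S{i}", "task": task,
                                   "level": lvl, "smoothed": sm,
                                   "i_pert": win.i_pert})
    return trials, wcfg


def test_objective_matches_bruteforce_oracle(gen_cfg):
    """The vectorized grid evaluation of Z agrees with an independent
    re-summation at every grid point, and so does the argmin."""
    trials, wcfg = _small_cohort(gen_cfg)
    res = optimize_windows(trials, wcfg, grid_resolution_ms=3.0)
    oracle = np.array([
        _z_oracle(trials, tap, off, wcfg)
        for tap, off in res.grid[["tap_len_ms", "t_trust_offset_ms"]].to_numpy()])
    np.testing.assert_allclose(res.grid["Z"].to_numpy(), oracle,
                               rtol=1e-7, atol=1e-12)
    assert res.objective == pytest.approx(oracle.min(), rel=1e-7)
    assert _z_oracle(trials, res.tap_len_ms, res.t_trust_offset_ms, wcfg) \
        == pytest.approx(oracle.min(), rel=1e-7)


def test_objective_degenerate_tie_breaking(quiet_cfg):
    """Noise-free, oscillation-free traces give Z = 0 on every placement
    that clears the force rise; among those ties the optimizer must pick
    the earliest trusted data (smallest offset, then smallest length)."""
    trials, wcfg = _small_cohort(quiet_cfg)
    res = optimize_windows(trials, wcfg, grid_resolution_ms=1.0)
    assert res.objective == pytest.approx(0.0, abs=1e-7)
    tied = res.grid[res.grid["Z"] <= res.objective + 1e-6]
    assert len(tied) > 10  # the degeneracy is real, not a unique minimum
    first = tied.sort_values(["t_trust_offset_ms", "tap_len_ms"]).iloc[0]
    assert res.t_trust_offset_ms == pytest.approx(first["t_trust_offset_ms"])
    assert res.tap_len_ms == pytest.approx(first["tap_len_ms"])


def test_longer_ringing_pushes_trust_later(gen_cfg):
    """Slower post-perturbation oscillation decay moves the optimal t_trust
    offset later (non-decreasing)."""
    offsets = []
    for decay in (0.002, 0.010):
        cfg = dataclasses.replace(gen_cfg, oscillation_decay_s=decay,
                                  oscillation_amp=2.0)
        trials, wcfg = _small_cohort(cfg, seed=33, n_subjects=2, reps=4)
        res = optimize_windows(trials, wcfg, grid_resolution_ms=1.0)
        offsets.append(res.t_trust_offset_ms)
    assert offsets[1] >= offsets[0]


def test_optimize_warns_on_underfilled_groups(gen_cfg):
    trials, wcfg = _small_cohort(gen_cfg, seed=5, n_subjects=1, reps=3)
    # leave one (subject, level) group with a single task-1 trial
    singles = [t for t in trials if not (t["task"] == 1 and t["level"] == 0.25)]
    singles.append(next(t for t in trials
                        if t["task"] == 1 and t["level"] == 0.25))
    with pytest.warns(UserWarning, match="fewer than two"):
        optimize_windows(singles, wcfg, grid_resolution_ms=5.0)
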
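"""Force/stiffness models, cross-validation, correlation comparisons."""

import numpy as np
import pandas as pd
import pytest

from gripstiff import (FitError,
                       ForceFromEMG, StiffnessFromEMG, correlation_table,
                       compare_transforms, crossval_intersubject,
                       crossval_intrasubject, decoupling_table,
                       prepare_subject_table, steiger_z)
from gripstiff.config import CHANNELS
from gripstiff.exceptions import InputError
from gripstiff.regression import LEVEL_BIN_MAP, significance_code


def _table(n=40, seed=0, n_subjects=1):
    """Random full-rank EMG design with linear targets."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        emg = rng.uniform(0.1, 2.0, size=(n, 6))
        f = 1.0 + emg @ rng.uniform(0.2, 1.0, 6) + 0.01 * rng.standard_normal(n)
        k = 0.5 + 0.4 * f + emg[:, 4] + 0.01 * rng.standard_normal(n)
        for i in range(n):
            rows.append({"subject_id": f"S{s}", "task": 1 + i % 2,
                         "force_level": 0.15 + 0.1 * (i % 5),
                         "trial_index": i, "f_pre": f[i], "k": k[i],
                         **dict(zip(CHANNELS, emg[i]))})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model objects
# --------------------------------------------------------------------------

def test_ols_recovers_exact_linear_law():
    """y = 1 + 2 * EMG_FDI exactly -> coefficients (1, 0,0,0,0, 2, 0)."""
    rng = np.random.default_rng(1)
    emg = rng.uniform(0, 1, size=(30, 6))
    y = 1.0 + 2.0 * emg[:, CHANNELS.index("FDI")]
    res = ForceFromEMG(y, emg).fit()
    want = pd.Series(0.0, index=res.params.index)
    want["const"], want["EMG_FDI"] = 1.0, 2.0
    pd.testing.assert_series_equal(res.params, want, atol=1e-9,
                                   check_names=False)
    assert res.rsquared == pytest.approx(1.0)


def test_stiffness_model_counts_coefficients(cohort_table):
    norm = prepare_subject_table(cohort_table)
    k_res = StiffnessFromEMG.from_trials(norm).fit()
    f_res = ForceFromEMG.from_trials(norm).fit()
    assert len(k_res.params) == 8
    assert len(f_res.params) == 7


def test_collinear_force_column_rejected():
    rng = np.random.default_rng(2)
    emg = rng.uniform(0, 1, size=(30, 6))
    f = rng.uniform(5, 30, 30)
    emg[:, 0] = f                 # duplicate the force regressor
    with pytest.raises(FitError, match="EMG_FDP|force"):
        StiffnessFromEMG(rng.uniform(1, 2, 30), emg, force=f).fit()


def test_ols_residuals_orthogonal_to_design(cohort_table):
    norm = prepare_subject_table(cohort_table)
    res = StiffnessFromEMG.from_trials(norm).fit()
    g = res.model.exog.T @ res.resid
    np.testing.assert_allclose(g, 0.0, atol=1e-8)


def test_significance_code_bands():
    assert [significance_code(p) for p in (1e-4, 5e-3, 0.03, 0.07, 0.5)] \
        == ["+++", "++", "+", ".", "-"]


def test_recovered_structure_matches_generating_coupling(cohort_table):
    """On generator data whose cocontraction drive loads the intrinsic
    muscles, the stiffness model must put its significant weights on FDI,
    SDI and force."""
    norm = prepare_subject_table(cohort_table)
    res = StiffnessFromEMG.from_trials(norm).fit()
    codes = res.significance_codes()
    # clearly significant at the reduced cohort size...
    assert codes["EMG_FDI"] in ("+++", "++")
    assert codes["EMG_SDI"] in ("+++", "++")
    assert codes["force"] == "+++"
    # ...and every extrinsic channel is weaker evidence than any of them
    p = res.pvalues
    strongest = max(p["EMG_FDI"], p["EMG_SDI"], p["force"])
    assert all(p[f"EMG_{c}"] > strongest for c in ("FDP", "FDS", "EIP", "ED"))


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def test_noiseless_crossvalidation_is_near_perfect(identical_law_table):
    """Identical noiseless law across subjects: leave-one-trial-out and
    leave-one-subject-out R^2 both exceed 0.999 for both targets."""
    norm = identical_law_table
    for target in ("stiffness", "force"):
        intra = crossval_intrasubject(norm, target=target)
        inter = crossval_intersubject(norm, target=target)
        assert (intra.r2_per_subject > 0.999).all(), intra.summary()
        assert (inter.r2_per_subject > 0.999).all(), inter.summary()


def test_crossval_fold_counts(cohort_table):
    norm = prepare_subject_table(cohort_table)
    intra = crossval_intrasubject(norm, target="stiffness")
    assert intra.n_models == len(norm)          # one model per perturbation
    inter = crossval_intersubject(norm, target="stiffness")
    assert inter.n_models == norm["subject_id"].nunique()


def test_permuted_targets_destroy_predictability(cohort_table):
    """Permuting the stiffness target within subject pushes the mean
    cross-validated R^2 to (at or below) chance."""
    norm = prepare_subject_table(cohort_table)
    rng = np.random.default_rng(7)
    shuffled = norm.copy()
    shuffled["k"] = (shuffled.groupby("subject_id")["k"]
                     .transform(lambda s: rng.permutation(s.to_numpy())))
    intra = crossval_intrasubject(shuffled, target="stiffness")
    inter = crossval_intersubject(shuffled, target="stiffness")
    assert intra.mean <= 0.05
    assert inter.mean <= 0.05


def test_crossval_below_insample(cohort_table):
    """Held-out R^2 should not beat the in-sample fit."""
    norm = prepare_subject_table(cohort_table)
    insample = StiffnessFromEMG.from_trials(norm).fit().rsquared
    inter = crossval_intersubject(norm, target="stiffness")
    assert inter.mean <= insample + 1e-9


def test_crossval_requires_enough_subjects(cohort_table):
    norm = prepare_subject_table(cohort_table)
    one = norm[norm["subject_id"] == norm["subject_id"].iloc[0]]
    with pytest.raises(InputError):
        crossval_intersubject(one)


# --------------------------------------------------------------------------
# Steiger's z and correlation tables
# --------------------------------------------------------------------------

def _steiger_oracle(r_jk, r_jh, r_kh, n):
    """Independent spelled-out evaluation of the dependent-correlation z."""
    import math

    z_jk = 0.5 * math.log((1 + r_jk) / (1 - r_jk))
    z_jh = 0.5 * math.log((1 + r_jh) / (1 - r_jh))
    rbar = 0.5 * (r_jk + r_jh)
    psi = (r_kh * (1 - 2 * rbar ** 2)
           - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r_kh ** 2))
    s = psi / (1 - rbar ** 2) ** 2
    return (z_jk - z_jh) * math.sqrt((n - 3) / (2 - 2 * s))


def test_steiger_identical_correlations():
    z, p = steiger_z(0.6, 0.6, 0.4, 50)
    assert z == 0.0 and p == pytest.approx(1.0)


def test_steiger_matches_formula_oracle():
    z, p = steiger_z(0.63, 0.41, 0.28, 37)
    assert z == pytest.approx(_steiger_oracle(0.63, 0.41, 0.28, 37), abs=1e-9)
    assert 0 < p < 1


def test_steiger_antisymmetry():
    z1, _ = steiger_z(0.7, 0.3, 0.5, 60)
    z2, _ = steiger_z(0.3, 0.7, 0.5, 60)
    assert z1 == pytest.approx(-z2, abs=1e-12)


def test_steiger_rejects_degenerate():
    with pytest.raises(InputError):
        steiger_z(1.0, 0.5, 0.2, 30)


def test_correlation_table_channel_equal_to_target():
    df = _table(n=30, seed=3, n_subjects=3)
    df["FDI"] = df["k"]
    out = correlation_table(df)
    fdi = out.per_subject[out.per_subject["item"] == "FDI"]
    np.testing.assert_allclose(fdi["r_stiffness"], 1.0, atol=1e-12)


def test_correlation_table_null_channel():
    df = _table(n=200, seed=4, n_subjects=3)
    rng = np.random.default_rng(11)
    df["EIP"] = rng.standard_normal(len(df))    # independent noise
    out = correlation_table(df)
    eip = out.per_subject[out.per_subject["item"] == "EIP"]
    assert abs(eip["r_stiffness"].mean()) < 2 / np.sqrt(200)


def test_correlation_ordering_on_generator_data(cohort_table):
    """Intrinsic channels correlate with stiffness more strongly than any
    extrinsic channel, mirroring the generator's coupling."""
    norm = prepare_subject_table(cohort_table)
    out = correlation_table(norm)
    means = (out.per_subject[out.per_subject["item"].isin(CHANNELS)]
             .groupby("item")["r_stiffness"].mean())
    assert min(means["FDI"], means["SDI"]) > max(
        means[c] for c in ("FDP", "FDS", "EIP", "ED"))


def test_transform_comparison_on_generator_data(cohort_table):
    norm = prepare_subject_table(cohort_table)
    out = compare_transforms(norm, target="force")
    assert set(out.tests["pair"]) == {"plain vs sqrt", "plain vs square",
                                      "sqrt vs square"}
    assert np.isfinite(out.tests["z_stouffer"]).all()


# --------------------------------------------------------------------------
# decoupling table
# --------------------------------------------------------------------------

def test_decoupling_null_when_tasks_identical():
    """Task 2 drawn from the task-1 distribution -> difference row ~ 0."""
    rng = np.random.default_rng(8)
    rows = []
    for s in range(6):
        for task in (1, 2):
            for lvl in (0.15, 0.35, 0.55):
                for i in range(20):
                    rows.append({"subject_id": f"S{s}", "task": task,
                                 "force_level": lvl, "trial_index": i,
                                 "k": 0.5 + 2 * lvl + 0.1 * rng.standard_normal()})
    table = decoupling_table(pd.DataFrame(rows))
    assert np.abs(table.difference.to_numpy()).max() < 2.0  # percent points


def test_decoupling_difference_row_is_mean_difference(cohort_table):
    table = decoupling_table(cohort_table).table
    np.testing.assert_allclose(
        table.loc["diff_pct"],
        table.loc["mean_task2_pct"] - table.loc["mean_task1_pct"],
        atol=1e-9)


def test_decoupling_excludes_single_task_subjects(cohort_table):
    partial = cohort_table[~((cohort_table["subject_id"] == "S01")
                             & (cohort_table["task"] == 2))]
    with pytest.warns(UserWarning, match="lacks one task"):
        table = decoupling_table(partial)
    assert table.excluded_subjects == ["S01"]


def test_level_bin_map_covers_protocol():
    assert {round(k, 2) for k in LEVEL_BIN_MAP} \
        >= {0.15, 0.25, 0.35, 0.45, 0.55}
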
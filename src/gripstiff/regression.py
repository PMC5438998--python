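"""Linear force and stiffness models from muscular activity.

Model class
-----------
Force is regressed on the six normalized EMG activations,

    f_i = b1 + b . EMG_i,

and stiffness on the activations plus the measured grip force,

    k_i = b1 + b . EMG_i + bn * f_i,

by ordinary least squares.  Models are built from a per-trial table with
:meth:`ForceFromEMG.from_trials` / :meth:`StiffnessFromEMG.from_trials`
and fitted with ``.fit()``, which returns an
:class:`EMGRegressionResults` carrying coefficients, their standard
errors and p values, and a ``summary()`` table.

Cross-validation
----------------
* intrasubject — leave-one-trial-out within each subject (one model per
  trial); the per-subject R^2 pools the held-out predictions against the
  subject's own mean.
* intersubject — leave-one-subject-out on subject-wise normalized data
  (one model per subject); R^2 per held-out subject.

Both report mean +/- SD of R^2 across subjects.  Cross-validated R^2 may
be negative: a model worse than the held-out mean.

Correlation comparisons
-----------------------
Pearson correlations of each electrode to stiffness and to force are
compared with a paired t-test on the Fisher-transformed coefficients
across subjects, and EMG amplitude transforms (plain vs sqrt vs square)
are compared with Steiger's z-test for dependent correlations sharing
one variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import CHANNELS, RegressionConfig
from .emg import two_step_normalize
from .exceptions import FitError, InputError

__all__ = [
    "ForceFromEMG", "StiffnessFromEMG", "EMGRegressionResults", "CVResult",
    "DecouplingTable", "CorrelationComparison", "prepare_subject_table",
    "crossval_intrasubject", "crossval_intersubject", "steiger_z",
    "compare_transforms", "correlation_table", "decoupling_table",
    "significance_code",
]

_TRANSFORMS = {
    "plain": lambda x: x,
    "sqrt": lambda x: np.sqrt(np.clip(x, 0.0, None)),
    "square": lambda x: np.square(x),
}

#: p-value bands for the compact significance codes used in the
#: coefficient tables.
_SIG_BANDS = ((0.001, "+++"), (0.01, "++"), (0.05, "+"), (0.1, "."))


def significance_code(p: float) -> str:
    for bound, code in _SIG_BANDS:
        if p <= bound:
            return code
    return "-"


def _apply_transform(emg: np.ndarray, transform: str) -> np.ndarray:
    try:
        return _TRANSFORMS[transform](emg)
    except KeyError:
        raise InputError(f"unknown EMG transform {transform!r}") from None


# --------------------------------------------------------------------------
# model objects
# --------------------------------------------------------------------------

class _EMGLinearModel:
    """Shared OLS machinery for the force and stiffness models."""

    target_name = ""
    _includes_force = False

    def __init__(self, endog: np.ndarray, emg: np.ndarray,
                 force: np.ndarray | None = None, transform: str = "plain",
                 channel_names: tuple[str, ...] = CHANNELS):
        endog = np.asarray(endog, dtype=float)
        emg = np.asarray(emg, dtype=float)
        if emg.ndim != 2 or emg.shape[1] != len(channel_names):
            raise InputError(
                f"EMG matrix must be (n, {len(channel_names)})")
        if emg.shape[0] != endog.size:
            raise InputError("EMG matrix and target length mismatch")
        if np.isnan(endog).any() or np.isnan(emg).any():
            raise InputError("missing values in the regression inputs")
        cols = [np.ones(endog.size)]
        names = ["const"]
        cols.extend(_apply_transform(emg, transform).T)
        names.extend(f"EMG_{c}" for c in channel_names)
        if self._includes_force:
            if force is None:
                raise InputError("the stiffness model requires a force column")
            force = np.asarray(force, dtype=float)
            if np.isnan(force).any():
                raise InputError("missing values in the force column")
            cols.append(force)
            names.append("force")
        self.exog = np.column_stack(cols)
        self.exog_names = names
        self.endog = endog
        self.transform = transform
        if endog.size < self.exog.shape[1] + 1:
            raise InputError(
                f"need >= {self.exog.shape[1] + 1} observations, "
                f"got {endog.size}")
        self._check_rank()

    def _check_rank(self) -> None:
        x = self.exog
        if np.linalg.matrix_rank(x) < x.shape[1]:
            # name the offending columns: those whose removal restores rank
            bad = []
            for j in range(1, x.shape[1]):
                others = np.delete(x, j, axis=1)
                if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(x):
                    bad.append(self.exog_names[j])
            raise FitError(
                f"rank-deficient design; collinear columns: {bad or 'unknown'}")

    @classmethod
    def from_trials(cls, table: pd.DataFrame, transform: str = "plain"):
        """Build the model from a per-trial table with columns ``k``,
        ``f_pre`` and the six EMG channel names."""
        emg = table[list(CHANNELS)].to_numpy()
        endog = table[cls._endog_column].to_numpy()
        force = table["f_pre"].to_numpy() if cls._includes_force else None
        return cls(endog, emg, force=force, transform=transform)

    def fit(self) -> "EMGRegressionResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return EMGRegressionResults(model=self, _sm_results=res)


class ForceFromEMG(_EMGLinearModel):
    """Grip force from the six EMG activations (7 coefficients)."""

    target_name = "force"
    _endog_column = "f_pre"
    _includes_force = False


class StiffnessFromEMG(_EMGLinearModel):
    """Grip stiffness from the six EMG activations plus force (8 coefficients)."""

    target_name = "stiffness"
    _endog_column = "k"
    _includes_force = True


@dataclass
class EMGRegressionResults:
    """Fitted coefficients with uncertainties and diagnostics."""

    model: _EMGLinearModel
    _sm_results: object

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._sm_results.params, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._sm_results.bse, index=self.model.exog_names)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self._sm_results.pvalues, index=self.model.exog_names)

    @property
    def rsquared(self) -> float:
        return float(self._sm_results.rsquared)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._sm_results.resid)

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        return np.asarray(self._sm_results.predict(
            self.model.exog if exog is None else exog))

    def significance_codes(self) -> pd.Series:
        return self.pvalues.map(significance_code)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, p, significance code."""
        return pd.DataFrame({
            "coef": self.params, "se": self.bse, "p": self.pvalues,
            "code": self.significance_codes(),
        })

    def to_dict(self) -> dict:
        return {
            "target": self.model.target_name,
            "transform": self.model.transform,
            "coefficients": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "rsquared": self.rsquared,
        }


# --------------------------------------------------------------------------
# subject-wise normalization of the merged trial table
# --------------------------------------------------------------------------

def prepare_subject_table(table: pd.DataFrame,
                          cfg: RegressionConfig | None = None) -> pd.DataFrame:
    """Normalize targets subject-wise on a merged per-trial table.

    EMG columns are assumed already normalized per subject/electrode (the
    emg module's two-step rule).  Force and stiffness targets are scaled
    per subject with the configured variant: ``max_sd`` divides by the
    maximum then by the SD of the result; ``sd`` divides by the SD only.
    """
    cfg = cfg or RegressionConfig()
    out = []
    for sid, grp in table.groupby("subject_id", sort=True):
        grp = grp.copy()
        for col in ("f_pre", "k"):
            x = grp[col].to_numpy(dtype=float)
            if cfg.intersubject_normalization == "max_sd":
                grp[col] = two_step_normalize(x, label=f"{sid}:{col}")
            else:
                sd = x.std(ddof=1)
                if sd == 0:
                    raise InputError(f"{sid}:{col}: zero SD")
                grp[col] = x / sd
        out.append(grp)
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    """Cross-validated fit quality per subject and its summary."""

    scheme: str                      # leave-one-trial-out | leave-one-subject-out
    target: str
    r2_per_subject: pd.Series        # indexed by subject_id
    n_models: int
    skipped_folds: int = 0

    @property
    def mean(self) -> float:
        return float(self.r2_per_subject.mean())

    @property
    def sd(self) -> float:
        return float(self.r2_per_subject.std(ddof=1))

    def summary(self) -> str:
        return (f"{self.target} [{self.scheme}]: "
                f"R^2 = {100 * self.mean:.1f} +/- {100 * self.sd:.1f} % "
                f"({self.n_models} models)")


def _design(table: pd.DataFrame, target: str, transform: str
            ) -> tuple[np.ndarray, np.ndarray]:
    emg = _apply_transform(table[list(CHANNELS)].to_numpy(dtype=float), transform)
    cols = [np.ones(len(table)), *emg.T]
    if target == "stiffness":
        cols.append(table["f_pre"].to_numpy(dtype=float))
        y = table["k"].to_numpy(dtype=float)
    elif target == "force":
        y = table["f_pre"].to_numpy(dtype=float)
    else:
        raise InputError(f"unknown target {target!r}")
    return np.column_stack(cols), y


def _lstsq_fit_predict(x_train, y_train, x_test) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x_train, y_train, rcond=None)
    return x_test @ beta


def crossval_intrasubject(table: pd.DataFrame, target: str = "stiffness",
                          transform: str = "plain",
                          cfg: RegressionConfig | None = None) -> CVResult:
    """Leave-one-trial-out within each subject.

    The number of fitted models per subject equals that subject's trial
    count; held-out predictions are pooled per subject and scored against
    the subject's own mean.
    """
    cfg = cfg or RegressionConfig()
    r2, n_models, skipped = {}, 0, 0
    for sid, grp in table.groupby("subject_id", sort=True):
        if len(grp) < cfg.min_trials_per_subject:
            raise InputError(
                f"subject {sid}: need >= {cfg.min_trials_per_subject} trials")
        x, y = _design(grp, target, transform)
        preds = np.empty(len(grp))
        ok = np.ones(len(grp), dtype=bool)
        for i in range(len(grp)):
            keep = np.arange(len(grp)) != i
            try:
                preds[i] = _lstsq_fit_predict(x[keep], y[keep], x[i])
                n_models += 1
            except np.linalg.LinAlgError:
                ok[i] = False
                skipped += 1
        sse = float(np.sum((y[ok] - preds[ok]) ** 2))
        sst = float(np.sum((y[ok] - y[ok].mean()) ** 2))
        r2[sid] = 1.0 - sse / sst
    return CVResult(scheme="leave-one-trial-out", target=target,
                    r2_per_subject=pd.Series(r2), n_models=n_models,
                    skipped_folds=skipped)


def crossval_intersubject(table: pd.DataFrame, target: str = "stiffness",
                          transform: str = "plain",
                          cfg: RegressionConfig | None = None) -> CVResult:
    """Leave-one-subject-out on subject-wise normalized data.

    One model per held-out subject; R^2 against the held-out subject's own
    mean, measuring subject-independent predictability.
    """
    cfg = cfg or RegressionConfig()
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 3:
        raise InputError("intersubject cross-validation needs >= 3 subjects")
    r2, skipped = {}, 0
    for sid in subjects:
        train = table[table["subject_id"] != sid]
        test = table[table["subject_id"] == sid]
        x_tr, y_tr = _design(train, target, transform)
        x_te, y_te = _design(test, target, transform)
        try:
            pred = _lstsq_fit_predict(x_tr, y_tr, x_te)
        except np.linalg.LinAlgError:
            skipped += 1
            continue
        sse = float(np.sum((y_te - pred) ** 2))
        sst = float(np.sum((y_te - y_te.mean()) ** 2))
        r2[sid] = 1.0 - sse / sst
    return CVResult(scheme="leave-one-subject-out", target=target,
                    r2_per_subject=pd.Series(r2), n_models=len(r2),
                    skipped_folds=skipped)


# --------------------------------------------------------------------------
# correlation comparisons
# --------------------------------------------------------------------------

def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int
              ) -> tuple[float, float]:
    """Steiger's z-test for two dependent correlations sharing variable j.

    Tests H0: rho_jk = rho_jh given the correlation r_kh between the two
    non-shared variables, using Fisher-transformed coefficients.  Returns
    ``(z, two-sided p)``.
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 <= r <= 1.0:
            raise InputError(f"{name} outside [-1, 1]")
    if abs(r_jk) == 1.0 or abs(r_jh) == 1.0:
        raise InputError("degenerate transform: |r| = 1 exactly")
    if n < 4:
        raise InputError("Steiger's z needs n >= 4")
    z1, z2 = np.arctanh(r_jk), np.arctanh(r_jh)
    rbar = (r_jk + r_jh) / 2.0
    psi = (r_kh * (1.0 - 2.0 * rbar ** 2)
           - 0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r_kh ** 2))
    cov = psi / (1.0 - rbar ** 2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * cov))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class CorrelationComparison:
    """Correlation structure and paired/dependent-correlation tests."""

    per_subject: pd.DataFrame        # long format, one row per (subject, item)
    summary: pd.DataFrame
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)


def correlation_table(table: pd.DataFrame) -> CorrelationComparison:
    """Per-electrode correlations to stiffness and force.

    For every subject and electrode the Pearson r of the normalized
    activation to the (normalized) stiffness and force targets; summary
    rows give mean +/- SD across subjects, the ``force`` row the
    force-stiffness correlation itself.  A paired t-test on the
    arctanh-transformed coefficients asks, per electrode, whether its
    correlation to stiffness differs from its correlation to force.
    """
    rows = []
    for sid, grp in table.groupby("subject_id", sort=True):
        if len(grp) < 10:
            raise InputError(f"subject {sid}: need >= 10 trials")
        k = grp["k"].to_numpy(dtype=float)
        f = grp["f_pre"].to_numpy(dtype=float)
        for name in CHANNELS:
            x = grp[name].to_numpy(dtype=float)
            if x.std() == 0 or k.std() == 0 or f.std() == 0:
                raise InputError(f"{sid}:{name}: constant series, "
                                 "correlation undefined")
            rows.append({"subject_id": sid, "item": name,
                         "r_stiffness": float(np.corrcoef(x, k)[0, 1]),
                         "r_force": float(np.corrcoef(x, f)[0, 1])})
        rows.append({"subject_id": sid, "item": "force",
                     "r_stiffness": float(np.corrcoef(f, k)[0, 1]),
                     "r_force": np.nan})
    per_subject = pd.DataFrame(rows)

    items = [*CHANNELS, "force"]
    summary = (per_subject.groupby("item")[["r_stiffness", "r_force"]]
               .agg(["mean", "std"]).reindex(items))
    tests = []
    eps = np.finfo(float).eps

    def _fisher(r):
        # keep the transform finite at |r| = 1 (degenerate but allowed input)
        return np.arctanh(np.clip(r, -1 + eps, 1 - eps))

    for name in CHANNELS:
        sub = per_subject[per_subject["item"] == name]
        zs = _fisher(sub["r_stiffness"].to_numpy())
        zf = _fisher(sub["r_force"].to_numpy())
        t, p = stats.ttest_rel(zs, zf)
        tests.append({"item": name, "t": float(t), "p": float(p),
                      "code": significance_code(float(p))})
    return CorrelationComparison(per_subject=per_subject, summary=summary,
                                 tests=pd.DataFrame(tests))


def compare_transforms(table: pd.DataFrame, target: str = "force"
                       ) -> CorrelationComparison:
    """Does a sqrt or square EMG transform improve the linear fit?

    Per subject, the quality of each transform's fit is the correlation
    between the in-sample OLS prediction and the target; transform pairs
    are compared with Steiger's z (the target is the shared variable, the
    two predictions the dependent non-shared ones).  Per-subject z values
    are combined across subjects with Stouffer's method.
    """
    names = list(_TRANSFORMS)
    rows, tests = [], []
    per_subject_z: dict[tuple[str, str], list[float]] = {}
    for sid, grp in table.groupby("subject_id", sort=True):
        preds = {}
        y = None
        for tf in names:
            x, y = _design(grp, target, tf)
            preds[tf] = _lstsq_fit_predict(x, y, x)
        n = len(grp)
        r = {tf: float(np.corrcoef(preds[tf], y)[0, 1]) for tf in names}
        rows.append({"subject_id": sid, **{f"r_{tf}": r[tf] for tf in names}})
        for a, b in (("plain", "sqrt"), ("plain", "square"), ("sqrt", "square")):
            r_ab = float(np.corrcoef(preds[a], preds[b])[0, 1])
            z, _ = steiger_z(r[a], r[b], r_ab, n)
            per_subject_z.setdefault((a, b), []).append(z)
    for (a, b), zs in per_subject_z.items():
        zs = np.asarray(zs)
        z_comb = float(zs.sum() / np.sqrt(zs.size))
        p_comb = 2.0 * float(stats.norm.sf(abs(z_comb)))
        tests.append({"pair": f"{a} vs {b}", "target": target,
                      "z_stouffer": z_comb, "p": p_comb,
                      "mean_z": float(zs.mean())})
    per_subject = pd.DataFrame(rows)
    summary = per_subject[[f"r_{tf}" for tf in names]].agg(["mean", "std"])
    return CorrelationComparison(per_subject=per_subject, summary=summary,
                                 tests=pd.DataFrame(tests))


# --------------------------------------------------------------------------
# decoupling table
# --------------------------------------------------------------------------

#: Commanded force level (fraction of MVC) -> reported bin label (% MVC).
#: The five task-2 levels map onto bins one notch lower because the
#: +/- 5 % MVC control band centres the produced force below the command.
LEVEL_BIN_MAP = {0.15: 10, 0.25: 20, 0.35: 30, 0.45: 40, 0.55: 50, 0.65: 60}


@dataclass
class DecouplingTable:
    """Normalized stiffness of both tasks per force-level bin."""

    table: pd.DataFrame              # rows: mean/sd per task, diff, ratio
    excluded_subjects: list[str]

    @property
    def difference(self) -> pd.Series:
        return self.table.loc["diff_pct"]


def decoupling_table(estimates: pd.DataFrame) -> DecouplingTable:
    """Cocontraction-driven stiffness increase per force level.

    Stiffness is normalized per subject by its maximum over all of that
    subject's trials (both tasks), trials are pooled across subjects and
    binned by commanded force level; the difference row
    mean(task 2) - mean(task 1) per bin is the average voluntary stiffness
    increase through cocontraction, in % of subject-maximum stiffness.

    The ratio row divides each task-2 trial's normalized stiffness by its
    subject's task-1 mean at the same bin and averages; this pairing rule
    is a documented convention, not a uniquely defined quantity.
    """
    required = {"subject_id", "task", "force_level", "k"}
    if not required.issubset(estimates.columns):
        raise InputError(f"estimates table needs columns {sorted(required)}")
    excluded = []
    parts = []
    for sid, grp in estimates.groupby("subject_id", sort=True):
        if set(grp["task"].unique()) != {1, 2}:
            warnings.warn(f"subject {sid} lacks one task; excluded from the "
                          "decoupling table", stacklevel=2)
            excluded.append(sid)
            continue
        grp = grp.copy()
        mx = grp["k"].max()
        if mx <= 0:
            raise InputError(f"subject {sid}: non-positive maximum stiffness")
        grp["k_norm"] = grp["k"] / mx
        parts.append(grp)
    if not parts:
        raise InputError("no subject has trials in both tasks")
    pooled = pd.concat(parts, ignore_index=True)
    pooled["bin"] = pooled["force_level"].map(
        lambda L: LEVEL_BIN_MAP.get(round(L, 4)))

    bins = sorted(b for b in pooled["bin"].unique()
                  if {(1, b), (2, b)} <= set(
                      zip(pooled["task"], pooled["bin"])))
    cols = {}
    for b in bins:
        t1 = pooled.loc[(pooled["task"] == 1) & (pooled["bin"] == b), "k_norm"]
        t2 = pooled.loc[(pooled["task"] == 2) & (pooled["bin"] == b), "k_norm"]
        ratios = []
        for sid, grp in pooled[pooled["bin"] == b].groupby("subject_id"):
            m1 = grp.loc[grp["task"] == 1, "k_norm"].mean()
            if m1 > 0:
                ratios.extend(grp.loc[grp["task"] == 2, "k_norm"] / m1)
        cols[b] = {
            "mean_task1_pct": 100 * t1.mean(), "mean_task2_pct": 100 * t2.mean(),
            "sd_task1_pct": 100 * t1.std(ddof=1),
            "sd_task2_pct": 100 * t2.std(ddof=1),
            "diff_pct": 100 * (t2.mean() - t1.mean()),
            "ratio": float(np.mean(ratios)) if ratios else np.nan,
        }
    table = pd.DataFrame(cols)
    table.columns.name = "bin_pct_mvc"
    return DecouplingTable(table=table, excluded_subjects=excluded)
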
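"""Pipeline orchestration: simulate -> analyze -> report.

Each stage reads and writes only the declared files (per-trial CSVs, a
JSON dataset manifest, per-stage output tables) so stages can be rerun
and audited independently.  All randomness flows from a single root
seed through named substreams, and every stage echoes its configuration
into its manifest: rerunning with identical config and seed reproduces
identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import CHANNELS, PipelineConfig
from .exceptions import DetectionError, GripstiffError, InputError
from . import emg as emg_mod
from . import kinematics as kin_mod
from . import perturbation as pert_mod
from . import regression as reg_mod
from . import synth

log = logging.getLogger("gripstiff")

__all__ = ["AnalysisResult", "analyze_dataset", "run_simulate",
           "run_analyze", "run_report"]


@dataclass
class AnalysisResult:
    """Per-trial outputs of the analysis stage."""

    estimates: pd.DataFrame
    features: pd.DataFrame
    displacements: pd.DataFrame
    merged: pd.DataFrame
    failures: list = field(default_factory=list)        # no stiffness estimate
    marker_failures: list = field(default_factory=list)  # stiffness ok, markers not
    warnings: dict = field(default_factory=dict)


def _analyze_trials(trial_iter, relaxation_by_subject, config: PipelineConfig
                    ) -> AnalysisResult:
    """Core per-trial loop shared by the in-memory and on-disk drivers."""
    wcfg, ecfg, kcfg = config.window, config.emg, config.kinematics
    baselines = {
        sid: emg_mod.find_baseline_window(rel, ecfg)
        for sid, rel in relaxation_by_subject.items()}
    est_rows, feat_rows, disp_rows = [], [], []
    failures, marker_failures = [], []
    warn_counts = {"detection_failures": 0, "masked_marker_trials": 0,
                   "unusable_marker_trials": 0}
    for rec in trial_iter:
        meta = rec.metadata
        try:
            smoothed = pert_mod.smooth_force(rec.force, wcfg.ma_points)
            win = pert_mod.detect_windows(smoothed, wcfg)
            est = pert_mod.estimate_stiffness(smoothed, win, wcfg)
        except (DetectionError, InputError) as err:
            failures.append({**meta, "error": str(err)})
            warn_counts["detection_failures"] += 1
            continue
        est_rows.append({**meta, "f_pre_N": est.f_pre, "k_N_per_mm": est.k,
                         "t_pert_s": win.t_pert,
                         "flags": ";".join(sorted(est.quality_flags))})
        if rec.emg is not None:
            feats = emg_mod.extract_features(
                rec.emg, win.t_pert, baselines.get(rec.subject_id), ecfg)
            feat_rows.append({**meta, **feats["arv_corrected"],
                              "flags": ";".join(sorted(feats["flags"]))})
        if rec.markers is not None:
            try:
                disp = kin_mod.analyze_markers(rec.markers, win, kcfg)
            except InputError as err:
                warn_counts["unusable_marker_trials"] += 1
                marker_failures.append({**meta, "error": str(err)})
                continue
            if disp.masked_fraction > 0:
                warn_counts["masked_marker_trials"] += 1
            disp_rows.append({**meta, "index_pct": disp.index_pct,
                              "thumb_pct": disp.thumb_pct,
                              "total_pct": disp.total_pct,
                              "masked_fraction": disp.masked_fraction})

    estimates = pd.DataFrame(est_rows)
    features = pd.DataFrame(feat_rows)
    displacements = pd.DataFrame(disp_rows)

    # subject-wise two-step normalization of the activation features
    if not features.empty:
        features = pd.concat(
            [emg_mod.normalize_subject(grp)
             for _, grp in features.groupby("subject_id", sort=True)],
            ignore_index=True)

    keys = ["subject_id", "task", "force_level", "trial_index"]
    merged = estimates.rename(
        columns={"f_pre_N": "f_pre", "k_N_per_mm": "k"})
    if not features.empty:
        merged = merged.merge(
            features.drop(columns=["flags"]), on=keys, how="left")
    if not displacements.empty:
        merged = merged.merge(displacements, on=keys, how="left")
    return AnalysisResult(estimates=estimates, features=features,
                          displacements=displacements, merged=merged,
                          failures=failures, marker_failures=marker_failures,
                          warnings=warn_counts)


def analyze_dataset(dataset: synth.SyntheticDataset, config: PipelineConfig,
                    channels=("force", "emg", "markers")) -> AnalysisResult:
    """In-memory analysis of a synthetic dataset (no files written)."""
    relax = {p.subject_id: dataset.relaxation(p.subject_id)
             for p in dataset.profiles} if "emg" in channels else {}
    return _analyze_trials(
        (rec for _, _, rec in dataset.iter_trials(channels)), relax, config)


# --------------------------------------------------------------------------
# disk stages
# --------------------------------------------------------------------------

def _write_manifest(path: Path, stage: str, config: PipelineConfig,
                    payload: dict, t0: float) -> None:
    manifest = {"stage": stage, "version": __version__,
                "config": config.to_dict(),
                "elapsed_s": round(time.time() - t0, 3), **payload}
    path.write_text(json.dumps(manifest, indent=2))


def _trial_dirname(meta: dict) -> str:
    level = round(100 * meta["force_level"])
    return (f"{meta['subject_id']}/task{meta['task']}"
            f"_l{level:02d}_t{meta['trial_index']:03d}")


def run_simulate(config: PipelineConfig, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Generate and write the synthetic dataset plus its manifest."""
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    ds = synth.generate_dataset(config.n_subjects, config.generator, seed)
    manifest = ds.manifest()
    for entry, (profile, spec, rec) in zip(manifest["trials"],
                                           ds.iter_trials()):
        rel = _trial_dirname(entry)
        files = synth.write_trial(rec, out_dir / rel)
        entry["path"] = rel
        entry["files"] = files
    for profile in ds.profiles:
        rel_emg = ds.relaxation(profile.subject_id)
        t = np.arange(rel_emg.shape[1]) / config.generator.fs_emg
        df = pd.DataFrame({"time_s": t})
        for c, name in enumerate(CHANNELS):
            df[name] = rel_emg[c]
        sub_dir = out_dir / profile.subject_id
        sub_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(sub_dir / "relaxation.csv", index=False, float_format="%.8g")
    synth.write_manifest(manifest, out_dir / "manifest.json")
    _write_manifest(out_dir / "run_manifest.json", "simulate", config,
                    {"n_subjects": config.n_subjects,
                     "n_trials": ds.n_trials,
                     "data_manifest": "manifest.json"}, t0)
    log.info("simulated %d trials for %d subjects", ds.n_trials,
             config.n_subjects)
    return manifest


def run_analyze(data_dir: str | Path, out_dir: str | Path,
                config: PipelineConfig) -> AnalysisResult:
    """Analyze a dataset directory written by :func:`run_simulate`."""
    t0 = time.time()
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = synth.read_manifest(data_dir / "manifest.json")
    missing = [e["path"] for e in manifest["trials"]
               if not (data_dir / e["path"]).is_dir()]
    if missing:
        raise InputError(f"missing trial directories: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")

    gen_cfg = config.generator
    read_failures: list[dict] = []

    def trials():
        for entry in manifest["trials"]:
            try:
                yield synth.read_trial(data_dir / entry["path"], entry,
                                       fs_force=gen_cfg.fs_force,
                                       fs_emg=gen_cfg.fs_emg)
            except (InputError, ValueError, KeyError) as err:
                read_failures.append(
                    {**{k: entry[k] for k in ("subject_id", "task",
                                              "force_level", "trial_index")},
                     "error": str(err)})

    relax = {}
    for sub in manifest["subjects"]:
        sid = sub["subject_id"]
        path = data_dir / sid / "relaxation.csv"
        if path.exists():
            df = pd.read_csv(path)
            relax[sid] = np.vstack([df[c].to_numpy() for c in CHANNELS])

    result = _analyze_trials(trials(), relax, config)
    result.failures.extend(read_failures)
    result.estimates.to_csv(out_dir / "estimates.csv", index=False)
    if not result.features.empty:
        result.features.to_csv(out_dir / "features.csv", index=False)
    if not result.displacements.empty:
        result.displacements.to_csv(out_dir / "displacements.csv", index=False)
    result.merged.to_csv(out_dir / "trials.csv", index=False)
    n_flagged = len(result.failures)
    if len(result.estimates) + n_flagged != len(manifest["trials"]):
        raise GripstiffError("trial count not conserved across analysis")
    _write_manifest(out_dir / "analysis_manifest.json", "analyze", config, {
        "n_trials_in": len(manifest["trials"]),
        "n_analyzed": len(result.estimates),
        "n_flagged": n_flagged,
        "flagged": result.failures,
        "marker_failures": result.marker_failures,
        "warnings": result.warnings,
    }, t0)
    log.info("analyzed %d/%d trials (%d flagged)", len(result.estimates),
             len(manifest["trials"]), n_flagged)
    return result


def run_report(analysis_dir: str | Path, out_dir: str | Path,
               config: PipelineConfig) -> dict:
    """Build summary tables, regression models and the force-stiffness figure."""
    t0 = time.time()
    analysis_dir, out_dir = Path(analysis_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials_path = analysis_dir / "trials.csv"
    if not trials_path.exists():
        raise InputError(f"no analysis tables found in {analysis_dir}")
    merged = pd.read_csv(trials_path)
    if merged.empty:
        raise InputError("analysis table is empty")
    outputs = {}

    # --- decoupling table (needs both tasks) ----------------------------
    if set(merged["task"].unique()) == {1, 2}:
        dec = reg_mod.decoupling_table(merged)
        dec.table.to_csv(out_dir / "decoupling.csv")
        outputs["decoupling"] = "decoupling.csv"
    else:
        warnings.warn("dataset lacks one task; decoupling table omitted")

    # --- displacement partition summary ---------------------------------
    if "index_pct" in merged.columns and merged["index_pct"].notna().any():
        disp = merged.dropna(subset=["index_pct"])
        per_subject = disp.groupby("subject_id")[
            ["index_pct", "thumb_pct", "total_pct"]].agg(["mean", "std"])
        grand = per_subject.xs("mean", axis=1, level=1).mean()
        summary = per_subject.copy()
        summary.loc["grand_mean"] = np.nan
        for col in ("index_pct", "thumb_pct", "total_pct"):
            summary.loc["grand_mean", (col, "mean")] = grand[col]
        summary.to_csv(out_dir / "displacements_summary.csv")
        outputs["displacements"] = "displacements_summary.csv"

    # --- regression, CV, correlations (needs EMG features) --------------
    models_payload = {}
    if all(c in merged.columns for c in CHANNELS):
        ok = merged.dropna(subset=list(CHANNELS))
        norm = reg_mod.prepare_subject_table(ok, config.regression)
        tf = config.regression.transform
        for klass in (reg_mod.ForceFromEMG, reg_mod.StiffnessFromEMG):
            res = klass.from_trials(norm, transform=tf).fit()
            models_payload[klass.target_name] = res.to_dict()
        cv_payload = {}
        for target in ("force", "stiffness"):
            for fn, key in ((reg_mod.crossval_intrasubject, "intrasubject"),
                            (reg_mod.crossval_intersubject, "intersubject")):
                try:
                    cv = fn(norm, target=target, transform=tf,
                            cfg=config.regression)
                except InputError as err:
                    warnings.warn(f"CV {key}/{target} skipped: {err}")
                    continue
                cv_payload[f"{key}_{target}"] = {
                    "scheme": cv.scheme, "mean_r2": cv.mean, "sd_r2": cv.sd,
                    "per_subject": cv.r2_per_subject.to_dict(),
                    "n_models": cv.n_models}
        corr = reg_mod.correlation_table(norm)
        corr.summary.to_csv(out_dir / "correlations.csv")
        corr.tests.to_csv(out_dir / "correlation_tests.csv", index=False)
        outputs["correlations"] = "correlations.csv"
        (out_dir / "models.json").write_text(json.dumps(
            {"models": models_payload, "cv": cv_payload}, indent=2))
        outputs["models"] = "models.json"

    # --- force-stiffness figure -----------------------------------------
    fig_payload = _force_stiffness_figure(merged, out_dir)
    outputs["figure"] = fig_payload

    _write_manifest(out_dir / "report_manifest.json", "report", config,
                    {"outputs": outputs}, t0)
    return outputs


def _force_stiffness_figure(merged: pd.DataFrame, out_dir: Path) -> dict:
    """Scatter of per-trial stiffness over force with per-task linear fits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    fits = {}
    colors = {1: "black", 2: "tab:red"}
    for task, grp in merged.groupby("task"):
        f = grp["f_pre"].to_numpy(dtype=float)
        k = grp["k"].to_numpy(dtype=float)
        ax.plot(f, k, ".", ms=3, color=colors.get(task, None),
                label=f"task {task}")
        if len(grp) >= 3:
            slope, intercept = np.polyfit(f, k, 1)
            r2 = float(np.corrcoef(f, k)[0, 1] ** 2)
            xs = np.linspace(f.min(), f.max(), 2)
            ax.plot(xs, intercept + slope * xs, "-",
                    color=colors.get(task, None))
            fits[str(task)] = {"slope": float(slope),
                               "intercept": float(intercept), "r2": r2}
    ax.set_xlabel("grip force [N]")
    ax.set_ylabel("grip stiffness [N/mm]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "force_stiffness.png", dpi=150)
    plt.close(fig)
    (out_dir / "force_stiffness_fits.json").write_text(
        json.dumps(fits, indent=2))
    return {"png": "force_stiffness.png",
            "fits": "force_stiffness_fits.json"}
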
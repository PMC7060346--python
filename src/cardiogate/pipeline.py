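"""End-to-end orchestration: simulate -> score -> analyze.

Each stage is a thin composition of the owning modules — every number in
every output table is reproducible by calling that module directly on the
same inputs.  The analysis stage applies the cohort exclusion rule
(NoGo commission errors more than 2 SD above the group mean) before any
statistics, mirrors the published table layout (descriptives,
systole-vs-diastole paired tests, interoception/impulsivity correlation
matrices, HRV regressions), and attaches the default-prior Bayes factor
to every cell.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, gating, hrv, interoception, io as cio, stats, synthetic
from .bayes import PriorSpec, DEFAULT_PRIOR
from .errors import InsufficientDataError, InvalidInputError

__all__ = ["score_dataset", "analyze", "run_all", "gate_sim_report"]

#: behaviour columns entering correlation/regression analyses
_BEHAV_MEASURES = ["go_rt_mean", "nogo_err_mean", "choose_go_mean",
                   "choose_go_rt_mean"]
_INTERO_INDICES = ["std_accuracy", "alt_accuracy", "insight", "awareness",
                   "confidence_mean", "sensibility", "tipe"]
_IMPULSIVITY = ["bis_attention", "bis_motor", "bis_planning", "bis_total",
                "caars_adhd", "upps_neg_urgency", "upps_premeditation",
                "upps_perseverance", "upps_sensation", "upps_pos_urgency"]
_PAIRED_TESTS = [("go_rt", "Go RT (ms)"),
                 ("nogo_err", "% NoGo errors"),
                 ("choose_go", "% Choose-Go"),
                 ("choose_go_rt", "Choose-Go RT (ms)")]


def score_dataset(data: dict, hrv_window_s: float | None = None) -> dict:
    """Per-subject summaries from a dataset bundle.

    Returns dict with ``behavior`` (one row per subject, all phase-split
    indices), ``profiles`` (the seven interoceptive indices), and ``hrv``
    (RMSSD/bpm per subject with artifact flag).
    """
    rows = []
    for sid, grp in data["task_trials"].groupby("subject_id", sort=True):
        rows.append({"subject_id": sid, **behavior.score_session(grp)})
    behav = pd.DataFrame(rows)

    profiles = interoception.profile_cohort(data["tracking_trials"],
                                            data.get("questionnaires"))

    hrows = []
    for sid, rr in sorted(data.get("rr", {}).items()):
        s = hrv.summarize_rr(rr, window_s=hrv_window_s)
        hrows.append({"subject_id": sid, "rmssd": s.rmssd, "bpm": s.bpm,
                      "n_beats": s.n_beats,
                      "flagged_artifact": s.flagged_artifact})
    return {"behavior": behav, "profiles": profiles,
            "hrv": pd.DataFrame(hrows)}


def _merged(scored: dict) -> pd.DataFrame:
    m = scored["behavior"].merge(scored["profiles"], on="subject_id", how="left")
    if not scored["hrv"].empty:
        m = m.merge(scored["hrv"], on="subject_id", how="left")
    return m


def analyze(scored: dict, questionnaires: pd.DataFrame | None = None,
            prior: PriorSpec = DEFAULT_PRIOR, apply_exclusions: bool = True) -> dict:
    """Cohort statistics from per-subject summaries.

    Applies the NoGo-error exclusion rule first (single pass), then builds
    the descriptive table, the four systole-vs-diastole paired tests (with
    a Wilcoxon alongside the NoGo comparison), the correlation matrices,
    and the four HRV regressions.
    """
    merged = _merged(scored)
    if questionnaires is not None:
        merged = merged.merge(questionnaires, on="subject_id", how="left")

    excluded = pd.DataFrame(columns=["subject_id", "nogo_err_mean"])
    if apply_exclusions and len(merged) >= 3:
        mask = behavior.exclusion_flags(merged["nogo_err_mean"])
        excluded = merged.loc[mask, ["subject_id", "nogo_err_mean"]].copy()
        merged = merged.loc[~mask].reset_index(drop=True)

    tables = {"excluded": excluded}
    tables["table2"] = behavior.cohort_table(merged)

    trows = []
    for base, label in _PAIRED_TESTS:
        x = merged[f"{base}_systole"].to_numpy(float)
        y = merged[f"{base}_diastole"].to_numpy(float)
        try:
            res = stats.paired_t(x, y, prior=prior)
            row = {"measure": label, **res.as_dict()}
        except (InvalidInputError, InsufficientDataError):
            row = {"measure": label, "method": "paired_t", "estimate": np.nan,
                   "statistic": np.nan, "p": np.nan, "n": int(len(merged))}
        if base == "nogo_err":
            try:
                w = stats.wilcoxon_signed_rank(x, y)
                row.update(wilcoxon_w=w.statistic, wilcoxon_p=w.p,
                           wilcoxon_z=w.extra["z_approx"])
            except (InvalidInputError, InsufficientDataError):
                row.update(wilcoxon_w=np.nan, wilcoxon_p=np.nan,
                           wilcoxon_z=np.nan)
        trows.append(row)
    tables["ttests"] = pd.DataFrame(trows)

    tables["corr_interoception"] = stats.correlation_matrix(
        merged, _INTERO_INDICES, _BEHAV_MEASURES, prior=prior)

    if questionnaires is not None:
        imp = [c for c in _IMPULSIVITY if c in merged.columns]
        tables["corr_impulsivity"] = stats.correlation_matrix(
            merged, imp, _BEHAV_MEASURES, prior=prior)
        subset = [c for c in ("bis_attention", "bis_motor", "bis_planning",
                              "bis_total", "caars_adhd") if c in merged.columns]
        tables["corr_intero_impulsivity"] = stats.correlation_matrix(
            merged, _INTERO_INDICES, subset, prior=prior)

    if "rmssd" in merged.columns and merged["rmssd"].notna().sum() > 4:
        rrows = []
        X = merged[["rmssd", "bpm"]].to_numpy(float)
        for dv in _BEHAV_MEASURES:
            res = stats.ols_enter(merged[dv].to_numpy(float), X, prior=prior)
            d = res.as_dict()
            d.pop("params", None)
            rrows.append({"dependent": dv, "r2": d.pop("estimate"), **d})
        tables["regressions"] = pd.DataFrame(rrows)

    return tables


def gate_sim_report(n_trials: int = 400, bpm: float = 75.0, rmssd: float = 54.0,
                    seed: int = 0, config: gating.GatingConfig = None,
                    gen_config: synthetic.GenConfig = None) -> dict:
    """Simulate one gated session and evaluate achieved cue timing.

    Builds a schedule (default 400-trial mix), an RR stream at the given
    rate/variability, schedules every trial, and returns the per-phase
    timing report plus a JSON-ready summary.
    """
    config = config or gating.GatingConfig()
    gen_config = gen_config or synthetic.GenConfig(
        n_trials=n_trials, mean_bpm=bpm, rmssd_target=rmssd, seed=seed)
    rng = np.random.default_rng(seed)
    schedule = synthetic.gen_session_schedule(gen_config, rng)
    ibi = 60000.0 / bpm
    n_beats = int(n_trials * (2 * ibi + config.cue_max_ms + config.fixation_ms)
                  / ibi * 1.2) + 20
    rr = synthetic.gen_rr_series(bpm, rmssd, n_beats, rng)
    sim = gating.simulate_gated_session(schedule, rr, config)
    report = gating.evaluate_timing(sim["onset_ms"], rr, sim["phase"], config,
                                    anchor_indices=sim["anchor_index"])
    summary = {
        "n_trials": int(sim["onset_ms"].size),
        "complete": sim["complete"],
        "bin_edges_ms": report.bin_edges.tolist(),
        "histograms": {ph: h.tolist() for ph, h in report.histograms.items()},
        "fraction_within_tolerance": report.fraction_within_tolerance,
    }
    return {"sim": sim, "rr": rr, "report": report, "summary": summary}


def run_all(config: synthetic.GenConfig, outdir,
            prior: PriorSpec = DEFAULT_PRIOR,
            hrv_window_s: float | None = None) -> dict:
    """Simulate a cohort, write it, score it, and write all analysis tables.

    Deterministic under a fixed config seed: two runs produce
    byte-identical files (no timestamps inside data files).
    """
    outdir = Path(outdir)
    data = synthetic.gen_dataset(config, outdir / "data")
    scored = score_dataset(data, hrv_window_s=hrv_window_s)
    tables = analyze(scored, questionnaires=data["questionnaires"], prior=prior)

    resdir = outdir / "results"
    resdir.mkdir(parents=True, exist_ok=True)
    scored["behavior"].to_csv(resdir / "behavior_summaries.csv", index=False)
    scored["profiles"].to_csv(resdir / "interoception_profiles.csv", index=False)
    scored["hrv"].to_csv(resdir / "hrv.csv", index=False)
    tables["excluded"].to_csv(resdir / "exclusions.csv", index=False)
    tables["table2"].to_csv(resdir / "table2.csv", index=False)
    tables["ttests"].to_csv(resdir / "ttests.csv", index=False)
    tables["corr_interoception"].to_csv(resdir / "corr_interoception.csv",
                                        index=False)
    if "corr_impulsivity" in tables:
        tables["corr_impulsivity"].to_csv(resdir / "corr_impulsivity.csv",
                                          index=False)
        tables["corr_intero_impulsivity"].to_csv(
            resdir / "corr_intero_impulsivity.csv", index=False)
    if "regressions" in tables:
        tables["regressions"].to_csv(resdir / "regressions.csv", index=False)

    run_manifest = {"config": asdict(config), "seed": config.seed,
                    "prior": asdict(prior),
                    "n_subjects_analyzed": int(
                        len(scored["behavior"]) - len(tables["excluded"]))}
    (resdir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True) + "\n")
    return {"data": data, "scored": scored, "tables": tables,
            "outdir": outdir}
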
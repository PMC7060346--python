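"""Synthetic cohort generator for the cardiac-gated inhibition pipeline.

Everything the analysis consumes can be generated here with known ground
truth: per-subject RR streams (independent Gaussian IBI jitter calibrated
so that the expected RMSSD equals the target exactly), gated 400-trial
Go/NoGo/Choose sessions scheduled on those streams, six heartbeat-counting
trials with confidence ratings, and impulsivity questionnaires.

The cohort-level latent structure is a stand-in for unobserved individual
differences, not a mechanistic claim: a metacognition latent drives the
accuracy-confidence coupling, a tracking-ability ratio drives reported
beat counts, and an impulsivity latent drives commission errors and
questionnaire scores.  The two behavioural effects the generator can
inject — a correlation between interoceptive awareness and %Choose-Go and
one between insight and Choose-Go reaction time — are calibrated against
the *realized* (scored) awareness/insight of the simulated subjects with
an analytic correction for binomial and trial-sampling attenuation, so a
requested cohort correlation is recovered by the scoring pipeline.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from math import log, sqrt

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import gating, interoception
from .errors import InvalidParameterError
from .rr import RRSeries

__all__ = [
    "GenConfig", "SubjectLatents",
    "gen_rr_series", "gen_session_schedule", "gen_behavior",
    "gen_tracking_trials", "gen_questionnaires", "gen_ecg_waveform",
    "gen_cohort", "gen_dataset",
]

# ---------------------------------------------------------------- config

@dataclass(frozen=True)
class GenConfig:
    """Study-condition parameters of the generator.

    Defaults reproduce the published cohort: 41 subjects, 75 bpm with
    RMSSD 54 ms, 400-trial sessions split 200/66/134 across Go/NoGo/Choose
    with half of each type at systole, ~1% Go omissions, and cohort
    correlations of -0.44 (awareness vs %Choose-Go) and -0.40 (insight vs
    Choose-Go RT).
    """

    n_subjects: int = 41
    mean_bpm: float = 75.0
    rmssd_target: float = 54.0
    n_trials: int = 400
    trial_mix: tuple = (0.50, 0.165, 0.335)     # Go, NoGo, Choose
    phase_split: float = 0.5                     # fraction systole per type
    effect_awareness_choosego: float = -0.44
    effect_insight_rt: float = -0.40
    omission_rate: float = 0.01
    overestimator_rate: float = 1.0 / 41.0
    count_noise_sd: float = 2.0                  # beats, on the report scale
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.trial_mix) - 1.0) > 1e-9:
            raise InvalidParameterError("trial_mix must sum to 1")
        if self.rmssd_target <= 0:
            raise InvalidParameterError("rmssd_target must be positive")
        if not (30 <= self.mean_bpm <= 180):
            raise InvalidParameterError("mean_bpm must lie in [30, 180]")
        if self.n_subjects < 1 or self.n_trials < 1:
            raise InvalidParameterError("counts must be positive")
        if not (0 <= self.phase_split <= 1):
            raise InvalidParameterError("phase_split must lie in [0, 1]")

    @property
    def type_counts(self) -> dict:
        """Exact per-type counts: Go and NoGo round, Choose absorbs the
        remainder (yields 200/66/134 at the 400-trial default)."""
        n_go = round(self.n_trials * self.trial_mix[0])
        n_nogo = round(self.n_trials * self.trial_mix[1])
        return {"go": n_go, "nogo": n_nogo, "choose": self.n_trials - n_go - n_nogo}


@dataclass(frozen=True)
class SubjectLatents:
    """Unobserved per-subject traits driving the generative model."""

    metacognition: float        # standardized; drives accuracy-confidence coupling
    tracking_ability: float     # expected reported/real beat ratio, > 0
    confidence_coupling: float  # per-trial accuracy<->confidence coupling, [-1, 1]
    impulsivity: float          # standardized; drives errors and questionnaires

    def __post_init__(self):
        if self.tracking_ability <= 0:
            raise InvalidParameterError("tracking_ability must be positive")


# Behavioural calibration constants (cohort-descriptive scale targets).
_GO_RT_MEAN = 482.0      # ms, subject-level mean
_GO_RT_SUBJ_SD = 55.0
_GO_RT_WITHIN_LOGSD = 0.17
_NOGO_ERR_BASE = 0.04
_NOGO_RT_MEAN = 405.0
_CHOOSE_BASE_P = 0.605
_CHOOSE_P_SD = 0.11
_CHOOSE_RT_MEAN = 520.0
_CHOOSE_RT_SUBJ_TAU = 0.158   # log-scale between-subject spread
_CHOOSE_RT_WITHIN_LOGSD = 0.17
_CONF_SPREAD = 1.6            # per-trial confidence spread around subject level


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ------------------------------------------------------------ primitives

def gen_rr_series(mean_bpm: float, rmssd_target: float, n_beats: int,
                  seed=None) -> RRSeries:
    """RR stream with iid Gaussian IBI jitter.

    IBIs are ``60000/mean_bpm + N(0, rmssd_target/sqrt(2))`` truncated to
    [300, 2000] ms, so the expected RMSSD of the series equals
    ``rmssd_target`` (successive differences of iid jitter have variance
    twice the jitter variance). Autocorrelated variability (respiratory
    arrhythmia, drift) is deliberately not modelled: RMSSD is the only
    HRV index consumed downstream and this model controls it exactly.
    """
    if rmssd_target <= 0:
        raise InvalidParameterError("rmssd_target must be positive")
    if n_beats < 4:
        raise InvalidParameterError("n_beats must be >= 4")
    rng = _rng(seed)
    base = 60000.0 / mean_bpm
    ibis = rng.normal(base, rmssd_target / sqrt(2.0), size=n_beats - 1)
    ibis = np.clip(ibis, 300.0, 2000.0)
    return RRSeries(np.concatenate([[0.0], np.cumsum(ibis)]))


def gen_ecg_waveform(rr: RRSeries, fs_hz: float = 1000.0,
                     r_width_ms: float = 12.0, noise_sd: float = 0.03,
                     seed=None):
    """Toy ECG-like trace: unit-height Gaussian R-bumps on noisy baseline.

    Exists solely to exercise threshold peak detection; it makes no claim
    to physiological waveform realism.
    """
    rng = _rng(seed)
    n = int(np.ceil((rr.r_times[-1] + 500.0) * fs_hz / 1000.0))
    t = np.arange(n) * (1000.0 / fs_hz)
    sig = rng.normal(0.0, noise_sd, size=n)
    for rt in rr.r_times:
        lo = max(0, int((rt - 5 * r_width_ms) * fs_hz / 1000.0))
        hi = min(n, int((rt + 5 * r_width_ms) * fs_hz / 1000.0) + 1)
        sig[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - rt) / r_width_ms) ** 2)
    return t, sig


def gen_session_schedule(config: GenConfig, seed=None) -> list:
    """Randomized trial order with exact type counts and per-type phase
    counts differing by at most one."""
    rng = _rng(seed)
    trials = []
    for ttype, count in config.type_counts.items():
        n_sys = int(round(count * config.phase_split))
        # a coin decides which phase absorbs the odd trial
        if count * config.phase_split % 1 == 0.5 and rng.random() < 0.5:
            n_sys = count - n_sys
        phases = [gating.SYSTOLE] * n_sys + [gating.DIASTOLE] * (count - n_sys)
        trials.extend((ttype, ph) for ph in phases)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def gen_tracking_trials(latents: SubjectLatents, mean_bpm: float, seed=None,
                        count_noise_sd: float = 2.0,
                        rmssd_target: float = 54.0,
                        confidence_level: float = 4.7) -> pd.DataFrame:
    """Six heartbeat-counting trials (25-50 s, randomized order).

    Real counts come from a generated RR stream; reported counts are
    ``round(tracking_ability * real + N(0, count_noise_sd))`` floored at
    zero; confidence is coupled to per-trial alternative accuracy with
    strength ``confidence_coupling`` on the standardized scale, mapped
    into [0, 10] and rounded to one decimal.
    """
    rng = _rng(seed)
    durations = rng.permutation(interoception.TRACKING_DURATIONS_S)
    total_s = float(np.sum(durations))
    n_beats = int(total_s / 60.0 * mean_bpm * 1.5) + 10
    rr = gen_rr_series(mean_bpm, rmssd_target, n_beats, rng)
    edges = np.concatenate([[0.0], np.cumsum(durations) * 1000.0])
    real = np.array([rr.beats_in_window(edges[i], edges[i + 1])
                     for i in range(len(durations))], dtype=float)
    real = np.maximum(real, 1)
    noise = rng.normal(0.0, count_noise_sd, size=real.size) if count_noise_sd > 0 else 0.0
    reported = np.maximum(np.round(latents.tracking_ability * real + noise), 0.0)

    acc = 1.0 - np.abs(real - reported) / ((real + reported) / 2.0)
    s = np.std(acc)
    z = (acc - np.mean(acc)) / s if s > 0 else np.zeros_like(acc)
    c = float(np.clip(latents.confidence_coupling, -1.0, 1.0))
    conf_raw = (confidence_level
                + _CONF_SPREAD * (c * z + sqrt(max(1 - c * c, 0.0))
                                  * rng.normal(size=acc.size)))
    confidence = np.round(np.clip(conf_raw, 0.0, 10.0), 1)
    return pd.DataFrame({
        "trial_index": np.arange(len(durations)),
        "duration_s": durations.astype(int),
        "nbeats_real": real.astype(int),
        "nbeats_reported": reported.astype(int),
        "confidence": confidence,
    })


def gen_behavior(latents: SubjectLatents, schedule, config: GenConfig,
                 seed=None, choose_logit: float | None = None,
                 choose_rt_mean: float | None = None) -> pd.DataFrame:
    """Per-trial responses and reaction times for one subject.

    Go trials are pressed with probability ``1 - omission_rate`` (a draw
    beyond the 1000 ms cue also counts as an omission); RTs are lognormal
    around a subject-level mean.  NoGo commission probability scales with
    impulsivity.  Choose presses are Bernoulli with the subject's
    choose-go propensity — by default logistic in the metacognition
    latent; cohort-calibrated pipelines pass ``choose_logit`` (and a
    ``choose_rt_mean``) computed against realized interoception scores.
    """
    rng = _rng(seed)
    if choose_logit is None:
        w = float(np.clip(config.effect_awareness_choosego, -1, 1))
        eta = w * latents.metacognition + sqrt(1 - w * w) * rng.normal()
        choose_logit = logit(_CHOOSE_BASE_P) + (_CHOOSE_P_SD / 0.239) * eta
    if choose_rt_mean is None:
        choose_rt_mean = _CHOOSE_RT_MEAN * np.exp(
            _CHOOSE_RT_SUBJ_TAU * rng.normal() - _CHOOSE_RT_SUBJ_TAU ** 2 / 2)

    go_rt_mean = max(rng.normal(_GO_RT_MEAN, _GO_RT_SUBJ_SD), 250.0)
    p_choose = float(expit(choose_logit))
    p_nogo = float(np.clip(
        _NOGO_ERR_BASE * np.exp(0.9 * latents.impulsivity - 0.405), 0.0, 0.6))

    rows = []
    for i, (ttype, phase) in enumerate(schedule):
        pressed, rt = 0, np.nan
        if ttype == "go":
            if rng.random() >= config.omission_rate:
                rt = go_rt_mean * np.exp(
                    rng.normal(0, _GO_RT_WITHIN_LOGSD) - _GO_RT_WITHIN_LOGSD ** 2 / 2)
                pressed = 1
        elif ttype == "nogo":
            if rng.random() < p_nogo:
                rt = _NOGO_RT_MEAN * np.exp(rng.normal(0, 0.15) - 0.15 ** 2 / 2)
                pressed = 1
        elif ttype == "choose":
            if rng.random() < p_choose:
                rt = choose_rt_mean * np.exp(
                    rng.normal(0, _CHOOSE_RT_WITHIN_LOGSD)
                    - _CHOOSE_RT_WITHIN_LOGSD ** 2 / 2)
                pressed = 1
        else:
            raise InvalidParameterError(f"unknown trial type {ttype!r}")
        if pressed and rt >= 1000.0:   # cue terminates: a slow press is an omission
            pressed, rt = 0, np.nan
        rows.append({"trial_index": i, "trial_type": ttype,
                     "intended_phase": phase, "pressed": pressed,
                     "rt_ms": round(rt, 1) if pressed else np.nan})
    return pd.DataFrame(rows)


# Questionnaire scales: (mean, sd, legal_min, legal_max), integer scores.
_SCALES = {
    "bis_attention": (18, 4, 8, 32),
    "bis_motor": (24, 4, 11, 44),
    "bis_planning": (24, 5, 11, 44),
    "caars_adhd": (13, 4, 0, 36),
    "upps_neg_urgency": (29, 7, 12, 48),
    "upps_premeditation": (23, 4, 11, 44),
    "upps_perseverance": (20, 3, 10, 40),
    "upps_sensation": (38, 7, 12, 48),
    "upps_pos_urgency": (29, 9, 14, 56),
}
_SCALE_LOADING = 0.6   # shared impulsivity-latent loading of every subscale


def gen_questionnaires(latents: SubjectLatents, seed=None) -> dict:
    """Integer questionnaire scores tied to the impulsivity latent.

    Each subscale loads 0.6 on the latent with independent residual, is
    rounded and clipped to its instrument-legal range; the BIS total is
    the sum of its three subscales. The 45 BPQ items (1-5) give the
    sensibility mean.
    """
    rng = _rng(seed)
    out = {}
    for name, (m, sd, lo, hi) in _SCALES.items():
        v = m + sd * (_SCALE_LOADING * latents.impulsivity
                      + sqrt(1 - _SCALE_LOADING ** 2) * rng.normal())
        out[name] = int(np.clip(round(v), lo, hi))
    out["bis_total"] = (out["bis_attention"] + out["bis_motor"]
                        + out["bis_planning"])
    base = np.clip(rng.normal(2.5, 0.6), 1.2, 4.3)
    items = np.clip(np.round(base + rng.normal(0, 0.9, size=45)), 1, 5)
    out["bpq_mean"] = float(np.round(np.mean(items), 4))
    return out


# ---------------------------------------------------------- cohort level

def _draw_latents(rng, config: GenConfig) -> SubjectLatents:
    m = rng.normal()
    if rng.random() < config.overestimator_rate:
        ability = rng.normal(2.4, 0.25)
    else:
        ability = max(rng.normal(0.72, 0.16), 0.05)
    coupling = float(np.clip(0.30 + 0.45 * m, -0.90, 0.98))
    return SubjectLatents(metacognition=m, tracking_ability=ability,
                          confidence_coupling=coupling,
                          impulsivity=rng.normal())


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    ok = np.isfinite(v)
    if ok.sum() >= 2 and np.nanstd(v[ok], ddof=1) > 0:
        out[ok] = (v[ok] - np.mean(v[ok])) / np.std(v[ok], ddof=1)
    return out


def gen_cohort(config: GenConfig) -> dict:
    """Full synthetic cohort, in memory.

    Returns a dict with DataFrames ``subjects``, ``task_trials``,
    ``tracking_trials``, ``questionnaires``, a ``rr`` mapping of
    subject_id to the rest-period :class:`RRSeries`, and the drawn
    ``latents``.  A single master seed spawns per-subject substreams
    (subject index in the spawn key), so cohorts are reproducible and
    order-independent.
    """
    subject_ids = [f"s{i + 1:03d}" for i in range(config.n_subjects)]
    sub_rngs = [np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(i,))) for i in range(config.n_subjects)]
    cohort_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(10 ** 6,)))

    latents = [_draw_latents(r, config) for r in sub_rngs]
    bpm = np.clip(cohort_rng.normal(config.mean_bpm, 10.0, config.n_subjects),
                  45.0, 110.0)
    sigma = sqrt(log(1 + (29.0 / 54.0) ** 2))
    rmssd = np.clip(config.rmssd_target / 54.0 * np.exp(
        cohort_rng.normal(log(54.0) - sigma ** 2 / 2, sigma, config.n_subjects)),
        8.0, 200.0)

    # tracking first: behavioural effects are calibrated on realized scores
    tracking_frames = []
    for sid, lat, r, b in zip(subject_ids, latents, sub_rngs, bpm):
        conf_level = float(np.clip(r.normal(4.7, 1.8), 0.5, 9.5))
        tf = gen_tracking_trials(lat, b, r, count_noise_sd=config.count_noise_sd,
                                 rmssd_target=config.rmssd_target,
                                 confidence_level=conf_level)
        tf.insert(0, "subject_id", sid)
        tracking_frames.append(tf)
    tracking = pd.concat(tracking_frames, ignore_index=True)
    profiles = interoception.profile_cohort(tracking)
    z_aw = _zscore(profiles.set_index("subject_id").loc[subject_ids, "awareness"])
    z_ins = _zscore(profiles.set_index("subject_id").loc[subject_ids, "insight"])

    n_choose = config.type_counts["choose"]
    lam_c = _CHOOSE_P_SD / sqrt(
        _CHOOSE_P_SD ** 2 + _CHOOSE_BASE_P * (1 - _CHOOSE_BASE_P) / max(n_choose, 1))
    w_aw = float(np.clip(config.effect_awareness_choosego / lam_c, -1, 1))
    w_ins = float(np.clip(config.effect_insight_rt / 0.99, -1, 1))
    s_logit = _CHOOSE_P_SD / (_CHOOSE_BASE_P * (1 - _CHOOSE_BASE_P))

    trial_frames = []
    rr_rest = {}
    subjects = []
    for i, (sid, lat, r, b, rm) in enumerate(
            zip(subject_ids, latents, sub_rngs, bpm, rmssd)):
        eta = w_aw * z_aw[i] + sqrt(1 - w_aw ** 2) * r.normal()
        cl = float(logit(_CHOOSE_BASE_P) + s_logit * eta)
        eta2 = w_ins * z_ins[i] + sqrt(1 - w_ins ** 2) * r.normal()
        crt = float(_CHOOSE_RT_MEAN * np.exp(
            _CHOOSE_RT_SUBJ_TAU * eta2 - _CHOOSE_RT_SUBJ_TAU ** 2 / 2))

        schedule = gen_session_schedule(config, r)
        beh = gen_behavior(lat, schedule, config, r,
                           choose_logit=cl, choose_rt_mean=crt)

        # gated onsets on a task-length RR stream
        ibi = 60000.0 / b
        n_beats = int(config.n_trials * (2 * ibi + 1000 + 1000) / ibi * 1.2) + 20
        task_rr = gen_rr_series(b, rm, n_beats, r)
        sim = gating.simulate_gated_session(
            schedule, task_rr, rts_ms=beh["rt_ms"].to_numpy())
        if not sim["complete"]:   # pragma: no cover - sized to never trigger
            raise RuntimeError("task RR stream exhausted; enlarge n_beats")
        beh["cue_onset_ms"] = np.round(sim["onset_ms"], 1)
        beh.insert(0, "subject_id", sid)
        trial_frames.append(beh)

        rest_beats = int(150.0 / 60.0 * b) + 40
        rr_rest[sid] = gen_rr_series(b, rm, rest_beats, r)
        subjects.append({"subject_id": sid,
                         "age": int(r.integers(18, 29)),
                         "sex": "m" if r.random() < 17 / 41 else "f"})

    quest = pd.DataFrame([{"subject_id": sid, **gen_questionnaires(lat, r)}
                          for sid, lat, r in zip(subject_ids, latents, sub_rngs)])
    cols = ["subject_id", "bis_attention", "bis_motor", "bis_planning",
            "bis_total", "caars_adhd", "upps_neg_urgency", "upps_premeditation",
            "upps_perseverance", "upps_sensation", "upps_pos_urgency", "bpq_mean"]
    return {
        "subjects": pd.DataFrame(subjects),
        "task_trials": pd.concat(trial_frames, ignore_index=True)[
            ["subject_id", "trial_index", "trial_type", "intended_phase",
             "cue_onset_ms", "pressed", "rt_ms"]],
        "tracking_trials": tracking,
        "questionnaires": quest[cols],
        "rr": rr_rest,
        "latents": dict(zip(subject_ids, latents)),
        "config": config,
    }


def gen_dataset(config: GenConfig, outdir) -> dict:
    """Generate a cohort and write it to ``outdir`` with a manifest.

    Files follow the documented CSV/plain-text schemas; the manifest
    records the config, the seed, and a sha256 checksum per file, making
    byte-identical regeneration checkable.
    """
    from . import io as cio
    cohort = gen_cohort(config)
    paths = cio.write_dataset(cohort, outdir)
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in sorted(paths)},
    }
    mpath = paths[0].parent / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    cohort["manifest"] = manifest
    return cohort
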
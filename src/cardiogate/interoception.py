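"""Heartbeat-tracking interoception scoring.

Seven per-subject indices summarize heartbeat-counting performance and
questionnaire self-report, spanning the accepted dimensions of
interoception:

* **standard accuracy** — mean over trials of ``1 - |real - reported| / real``;
  only meaningful when the subject does not report more than twice the real
  count (over-estimators get an absent value);
* **alternative accuracy** — mean of ``1 - |real - reported| /
  ((real + reported) / 2)``; bounded in [-1, 1] and robust to gross
  over-estimation;
* **insight** — mean per-trial signed discrepancy between standard accuracy
  and rescaled confidence (confidence / 10): 0 is optimal metacognition,
  negative = confident but inaccurate, positive = accurate but diffident;
* **awareness** — within-subject Pearson correlation between per-trial
  alternative accuracy and confidence (metacognitive coupling);
* **confidence** — mean 0-10 rating;
* **sensibility** — mean of the 45 Body Perception Questionnaire awareness
  items, each scored 1-5 (trait self-report);
* **TIPE** — trait interoceptive prediction error, cohort-z-scored
  sensibility minus cohort-z-scored alternative accuracy: positive values
  mark subjects who over-rate their own interoception.

Scoring functions take per-trial arrays; :func:`profile_cohort` assembles
the per-subject table from tidy trial/questionnaire frames with absent
values (over-estimators, degenerate correlations) left as NaN for pairwise
handling downstream.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "InteroceptionProfile",
    "std_accuracy", "alt_accuracy", "insight", "awareness",
    "confidence_mean", "sensibility", "tipe", "flag_overestimator",
    "profile_subject", "profile_cohort",
]

#: Standard trial durations (s) of the heartbeat tracking task.
TRACKING_DURATIONS_S = (25, 30, 35, 40, 45, 50)


@dataclass(frozen=True)
class InteroceptionProfile:
    subject_id: object
    std_accuracy: Optional[float]
    alt_accuracy: float
    insight: Optional[float]
    awareness: Optional[float]
    confidence_mean: float
    sensibility: Optional[float]
    tipe: Optional[float] = None    # cohort-level; filled by profile_cohort
    overestimator: bool = False


def _arrays(real, reported):
    real = np.asarray(real, dtype=float)
    reported = np.asarray(reported, dtype=float)
    if real.size == 0:
        raise InsufficientDataError("need at least one tracking trial")
    if real.shape != reported.shape:
        raise InvalidInputError("real and reported counts must be aligned")
    if np.any(real < 1):
        raise InvalidInputError("nbeats_real must be >= 1")
    if np.any(reported < 0):
        raise InvalidInputError("nbeats_reported must be >= 0")
    return real, reported


def _std_acc_per_trial(real, reported):
    return 1.0 - np.abs(real - reported) / real


def _alt_acc_per_trial(real, reported):
    denom = (real + reported) / 2.0
    if np.any(denom <= 0):
        raise InvalidInputError("real + reported must be positive")
    return 1.0 - np.abs(real - reported) / denom


def std_accuracy(real, reported) -> float:
    """Mean standard heartbeat-tracking accuracy; 1 = perfect, negative
    once reports exceed twice the real count."""
    real, reported = _arrays(real, reported)
    return float(np.mean(_std_acc_per_trial(real, reported)))


def alt_accuracy(real, reported) -> float:
    """Mean alternative accuracy, bounded in [-1, 1]."""
    real, reported = _arrays(real, reported)
    return float(np.mean(_alt_acc_per_trial(real, reported)))


def flag_overestimator(real, reported) -> bool:
    """True if total reported beats exceed twice the total real beats.

    Operationalized on totals across the trials (robust to one miscounted
    trial); flagged subjects keep only alternative-accuracy-based indices.
    """
    real, reported = _arrays(real, reported)
    return float(np.sum(reported)) > 2.0 * float(np.sum(real))


def insight(real, reported, confidence) -> float:
    """Mean signed per-trial discrepancy, standard accuracy - confidence/10.

    The per-trial standard accuracy is differenced against that trial's
    rescaled confidence, then averaged; the sign is kept (negative = low
    performance, high confidence). Not defined for over-estimators — the
    caller screens with :func:`flag_overestimator`.
    """
    real, reported = _arrays(real, reported)
    conf = np.asarray(confidence, dtype=float)
    if np.any((conf < 0) | (conf > 10)):
        raise InvalidInputError("confidence must lie in [0, 10]")
    return float(np.mean(_std_acc_per_trial(real, reported) - conf / 10.0))


def awareness(real, reported, confidence) -> Optional[float]:
    """Within-subject Pearson r between per-trial alternative accuracy and
    confidence. Returns None when either sequence is degenerate (zero
    variance) or fewer than 3 trials are available."""
    real, reported = _arrays(real, reported)
    conf = np.asarray(confidence, dtype=float)
    acc = _alt_acc_per_trial(real, reported)
    if acc.size < 3:
        return None
    if np.std(acc) == 0 or np.std(conf) == 0:
        return None
    return float(np.corrcoef(acc, conf)[0, 1])


def confidence_mean(confidence) -> float:
    conf = np.asarray(confidence, dtype=float)
    if conf.size == 0:
        raise InsufficientDataError("need at least one confidence rating")
    return float(np.mean(conf))


def sensibility(bpq) -> float:
    """Mean Body Perception Questionnaire score.

    Accepts either the 45 item responses (each 1-5) or a single
    precomputed mean in [1, 5].
    """
    x = np.atleast_1d(np.asarray(bpq, dtype=float))
    if np.any((x < 1) | (x > 5)):
        raise InvalidInputError("BPQ scores must lie in [1, 5]")
    return float(np.mean(x))


def tipe(alt_accuracies, sensibilities) -> np.ndarray:
    """Trait interoceptive prediction error across a cohort.

    z-scores each column with the sample SD (n-1 denominator) and returns
    z(sensibility) - z(accuracy) per subject. NaNs propagate (a subject
    missing either score gets NaN and does not enter the z-norms).
    """
    acc = np.asarray(alt_accuracies, dtype=float)
    sens = np.asarray(sensibilities, dtype=float)
    if acc.shape != sens.shape:
        raise InvalidInputError("cohort columns must be aligned")
    if np.sum(np.isfinite(acc)) < 3 or np.sum(np.isfinite(sens)) < 3:
        raise InsufficientDataError("TIPE needs a cohort of at least 3")

    def _z(v):
        m, s = np.nanmean(v), np.nanstd(v, ddof=1)
        if not np.isfinite(s) or s == 0:
            raise InvalidInputError("zero variance: z-scores undefined")
        return (v - m) / s

    return _z(sens) - _z(acc)


def profile_subject(subject_id, real, reported, confidence,
                    bpq=None) -> InteroceptionProfile:
    """All within-subject indices for one subject's tracking trials."""
    over = flag_overestimator(real, reported)
    aw = awareness(real, reported, confidence)
    return InteroceptionProfile(
        subject_id=subject_id,
        std_accuracy=None if over else std_accuracy(real, reported),
        alt_accuracy=alt_accuracy(real, reported),
        insight=None if over else insight(real, reported, confidence),
        awareness=aw,
        confidence_mean=confidence_mean(confidence),
        sensibility=None if bpq is None else sensibility(bpq),
        overestimator=over,
    )


def profile_cohort(tracking: pd.DataFrame,
                   questionnaires: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject index table from tidy trial data.

    ``tracking`` needs columns subject_id, nbeats_real, nbeats_reported,
    confidence; ``questionnaires`` (optional) supplies bpq_mean per
    subject_id. TIPE is filled cohort-wide when sensibility is available.
    Missing indices are NaN.
    """
    rows = []
    bpq_map = {}
    if questionnaires is not None and "bpq_mean" in questionnaires:
        bpq_map = dict(zip(questionnaires["subject_id"], questionnaires["bpq_mean"]))
    for sid, grp in tracking.groupby("subject_id", sort=True):
        p = profile_subject(sid, grp["nbeats_real"].to_numpy(),
                            grp["nbeats_reported"].to_numpy(),
                            grp["confidence"].to_numpy(),
                            bpq=bpq_map.get(sid))
        rows.append({
            "subject_id": sid,
            "std_accuracy": np.nan if p.std_accuracy is None else p.std_accuracy,
            "alt_accuracy": p.alt_accuracy,
            "insight": np.nan if p.insight is None else p.insight,
            "awareness": np.nan if p.awareness is None else p.awareness,
            "confidence_mean": p.confidence_mean,
            "sensibility": np.nan if p.sensibility is None else p.sensibility,
            "overestimator": p.overestimator,
        })
    out = pd.DataFrame(rows)
    if not out.empty and out["sensibility"].notna().sum() >= 3:
        out["tipe"] = tipe(out["alt_accuracy"].to_numpy(),
                           out["sensibility"].to_numpy())
    else:
        out["tipe"] = np.nan
    cols = ["subject_id", "std_accuracy", "alt_accuracy", "insight", "awareness",
            "confidence_mean", "sensibility", "tipe", "overestimator"]
    return out[cols]
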
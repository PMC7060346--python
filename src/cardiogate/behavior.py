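"""Go / NoGo / Choose behaviour scoring.

Four key indices per subject — Go reaction time, % NoGo commission errors,
% Choose-Go (how often the subject elects to act on free-choice trials),
and Choose-Go reaction time — plus Go omissions and the RT of NoGo error
presses, each computed per cardiac phase (systole / diastole) and pooled.
"Pooled" averages at the trial level, not across the two phase means, so
unequal phase counts are weighted naturally.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError

__all__ = ["score_session", "exclusion_flags", "cohort_table", "BEHAVIOR_COLUMNS"]

_PHASES = ("systole", "diastole")

BEHAVIOR_COLUMNS = [
    f"{base}_{suffix}"
    for base in ("go_rt", "go_omissions", "nogo_err", "nogo_rt",
                 "choose_go", "choose_go_rt")
    for suffix in ("systole", "diastole", "mean")
]


def _mean_or_nan(x) -> float:
    return float(np.mean(x)) if len(x) else np.nan


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else np.nan


def score_session(trials: pd.DataFrame) -> dict:
    """Behaviour indices for one subject's session.

    ``trials`` needs columns trial_type {go,nogo,choose}, intended_phase
    {systole,diastole}, pressed {0,1}, rt_ms (NaN when not pressed).
    Returns a flat dict over :data:`BEHAVIOR_COLUMNS`; cells whose
    denominator is empty (e.g. NoGo RT with no commission errors) are NaN.
    """
    required = {"trial_type", "intended_phase", "pressed", "rt_ms"}
    missing = required - set(trials.columns)
    if missing:
        raise InvalidInputError(f"trial table missing columns {sorted(missing)}")
    pressed = trials["pressed"].astype(bool)
    if (pressed & trials["rt_ms"].isna()).any():
        raise InvalidInputError("pressed trials must carry an rt_ms")

    out = {}
    subsets = {ph: trials["intended_phase"] == ph for ph in _PHASES}
    subsets["mean"] = pd.Series(True, index=trials.index)
    for key, sel in subsets.items():
        go = trials[sel & (trials["trial_type"] == "go")]
        nogo = trials[sel & (trials["trial_type"] == "nogo")]
        choose = trials[sel & (trials["trial_type"] == "choose")]
        out[f"go_rt_{key}"] = _mean_or_nan(go.loc[go["pressed"] == 1, "rt_ms"])
        out[f"go_omissions_{key}"] = _pct(int((go["pressed"] == 0).sum()), len(go))
        out[f"nogo_err_{key}"] = _pct(int((nogo["pressed"] == 1).sum()), len(nogo))
        out[f"nogo_rt_{key}"] = _mean_or_nan(nogo.loc[nogo["pressed"] == 1, "rt_ms"])
        out[f"choose_go_{key}"] = _pct(int((choose["pressed"] == 1).sum()), len(choose))
        out[f"choose_go_rt_{key}"] = _mean_or_nan(
            choose.loc[choose["pressed"] == 1, "rt_ms"])
    return out


def exclusion_flags(nogo_err: pd.Series | np.ndarray) -> np.ndarray:
    """Single-pass outlier rule on cohort NoGo commission-error rates.

    Flags subjects whose error rate exceeds the group mean plus two sample
    standard deviations (n-1). One-sided: low error rates never flag.
    Returns a boolean mask aligned with the input.
    """
    x = np.asarray(nogo_err, dtype=float)
    if np.sum(np.isfinite(x)) < 3:
        raise InsufficientDataError("exclusion rule needs a cohort of at least 3")
    m, s = np.nanmean(x), np.nanstd(x, ddof=1)
    if s == 0:
        return np.zeros(x.shape, dtype=bool)
    return x > m + 2.0 * s


def cohort_table(summaries: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Descriptive table (mean, SD, min, max) over per-subject summaries.

    SD uses the n-1 convention; missing cells are excluded column-wise.
    A column with a single observation gets SD = NaN.
    """
    if summaries.empty:
        raise InsufficientDataError("need at least one subject")
    cols = columns if columns is not None else [
        c for c in summaries.columns
        if c != "subject_id" and pd.api.types.is_numeric_dtype(summaries[c])]
    rows = []
    for c in cols:
        v = summaries[c].astype(float).dropna()
        rows.append({
            "variable": c,
            "mean": v.mean() if len(v) else np.nan,
            "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
            "min": v.min() if len(v) else np.nan,
            "max": v.max() if len(v) else np.nan,
            "n": len(v),
        })
    return pd.DataFrame(rows)
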
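"""Time-domain heart-rate-variability summaries.

Only RMSSD (root mean square of successive IBI differences, a
vagally-mediated index) and mean heart rate are computed; frequency-domain
and nonlinear indices are deliberately out of scope. An automated range
screen stands in for visual artifact inspection: suspect recordings are
flagged, never silently cleaned.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError
from .rr import RRSeries

__all__ = [
    "CardiacSummary",
    "ibis_from_rpeaks",
    "rmssd",
    "mean_bpm",
    "artifact_screen",
    "summarize_rr",
]

#: Physiological IBI plausibility bounds (ms); outside = suspected artifact.
DEFAULT_IBI_LOW_MS = 300.0
DEFAULT_IBI_HIGH_MS = 2000.0


@dataclass(frozen=True)
class CardiacSummary:
    rmssd: float          # ms
    bpm: float            # beats/min
    n_beats: int
    flagged_artifact: bool


def ibis_from_rpeaks(r_times) -> np.ndarray:
    """Successive differences of strictly increasing R-peak times (ms)."""
    t = np.asarray(r_times, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 R-peaks to form an IBI")
    if not np.all(np.diff(t) > 0):
        raise InvalidInputError("R-peak times must be strictly increasing")
    return np.diff(t)


def rmssd(ibis) -> float:
    """Root mean square of successive IBI differences, in ms."""
    x = np.asarray(ibis, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("RMSSD needs at least 2 IBIs")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def mean_bpm(r_times) -> float:
    """Mean heart rate, 60000 / mean IBI.

    Computed from the mean interval rather than beat count over duration:
    identical for full windows, stable for partial ones.
    """
    ibis = ibis_from_rpeaks(r_times)
    return 60000.0 / float(np.mean(ibis))


def artifact_screen(ibis, low_ms: float = DEFAULT_IBI_LOW_MS,
                    high_ms: float = DEFAULT_IBI_HIGH_MS):
    """Flag IBIs outside the plausible [low, high] ms range.

    Returns ``(flagged, ok_index)`` where *flagged* is True if any IBI is
    out of range and *ok_index* are the indices of in-range IBIs. The
    recording is reported, not cleaned.
    """
    if not (0 < low_ms < high_ms):
        raise InvalidParameterError("need 0 < low_ms < high_ms")
    x = np.asarray(ibis, dtype=float)
    ok = (x >= low_ms) & (x <= high_ms)
    return bool(np.any(~ok)), np.flatnonzero(ok)


def summarize_rr(rr: RRSeries, window_s: float | None = None,
                 low_ms: float = DEFAULT_IBI_LOW_MS,
                 high_ms: float = DEFAULT_IBI_HIGH_MS) -> CardiacSummary:
    """RMSSD + heart rate for a recording, optionally restricted to the
    first ``window_s`` seconds (default: whole recording)."""
    t = rr.r_times
    if window_s is not None:
        t = t[t <= t[0] + window_s * 1000.0]
    ibis = ibis_from_rpeaks(t)
    flagged, _ = artifact_screen(ibis, low_ms, high_ms)
    return CardiacSummary(rmssd=rmssd(ibis), bpm=mean_bpm(t),
                          n_beats=int(t.size), flagged_artifact=flagged)
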
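"""Cardiac-phase stimulus scheduling and its timing-precision evaluation.

The scheduler emulates online ECG-locked cue delivery: R-peaks are detected
from the incoming trace (or taken as given), the next R-wave is predicted as
the last detected R plus the median of the preceding inter-beat intervals,
and cues are timed either to systole (a fixed offset *after* a detected R,
default +290 ms, when baroreceptor firing peaks) or to diastole (a small
offset *before* the predicted next R, default 10 ms, when baroreceptors are
quiescent).

Systole needs no prediction — a forward offset is realizable reactively —
so its timing error is zero whenever detection is exact.  Diastole timing
error equals, trial by trial, the difference between the actual next IBI
and the median of the previous ones; the precision evaluation histograms
achieved onsets relative to the reference R-wave in fixed-width bins and
reports the fraction of trials within a tolerance of the intended offset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError
from .rr import RRSeries

__all__ = [
    "GatingConfig",
    "TimingReport",
    "detect_r_peaks",
    "predict_next_r",
    "schedule_trial_onset",
    "simulate_gated_session",
    "evaluate_timing",
]

SYSTOLE = "systole"
DIASTOLE = "diastole"


@dataclass(frozen=True)
class GatingConfig:
    """Scheduling and evaluation parameters (all times in ms)."""

    systole_offset: float = 290.0   # cue onset after the anchor R
    diastole_offset: float = 10.0   # cue onset before the predicted next R
    fixation_ms: float = 1000.0     # inter-trial fixation before ECG monitoring
    history: int = 3                # IBIs entering the median predictor
    bin_width: float = 50.0         # histogram resolution of the report
    tolerance: float = 200.0        # |error| bound counted as on-target
    cue_max_ms: float = 1000.0      # cue terminates at this duration or at the press
    hist_lo: float = -400.0         # histogram support relative to reference R
    hist_hi: float = 600.0

    def __post_init__(self):
        if min(self.systole_offset, self.diastole_offset, self.fixation_ms,
               self.bin_width, self.tolerance, self.cue_max_ms) <= 0:
            raise InvalidParameterError("all gating times must be positive")
        if self.history < 1:
            raise InvalidParameterError("history must be >= 1")


@dataclass(frozen=True)
class TimingReport:
    """Achieved-timing summary, per cardiac phase.

    ``offsets``/``errors`` are per-trial signed values (ms): the offset is
    relative to the reference R-wave, the error relative to the intended
    offset (+systole_offset or -diastole_offset).  Histograms are fractions
    over ``bin_edges`` (left edges, ``bin_width`` apart) and sum to 1.
    """

    bin_edges: np.ndarray
    histograms: dict            # phase -> fractions array, len(bin_edges)
    fraction_within_tolerance: dict  # phase -> float
    offsets: dict               # phase -> per-trial signed offsets (ms)
    errors: dict                # phase -> per-trial signed errors (ms)


def detect_r_peaks(signal, fs_hz: float, threshold: float,
                   refractory_ms: float = 250.0) -> RRSeries:
    """Threshold-crossing R-peak detection on a sampled trace.

    An upward crossing of ``threshold`` opens a candidate window that closes
    when the signal falls back below threshold; the local maximum within the
    window is the peak. Further crossings within ``refractory_ms`` of the
    last accepted peak are suppressed (default 250 ms, the physiological
    upper bound on heart rate).
    """
    x = np.asarray(signal, dtype=float)
    if fs_hz <= 0 or refractory_ms <= 0:
        raise InvalidParameterError("fs_hz and refractory_ms must be positive")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite samples")
    above = x >= threshold
    # rising edges: below -> at/above
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
    peaks = []
    last_peak_t = -np.inf
    dt = 1000.0 / fs_hz
    for i in rises:
        j = i
        while j + 1 < x.size and above[j + 1]:
            j += 1
        k = i + int(np.argmax(x[i:j + 1]))
        t = k * dt
        if t - last_peak_t >= refractory_ms:
            peaks.append(t)
            last_peak_t = t
    return RRSeries(np.asarray(peaks, dtype=float))


def predict_next_r(detected: RRSeries, history: int = 3) -> float:
    """Last detected R plus the median of the last ``history`` IBIs."""
    if len(detected) < history + 1:
        raise InsufficientDataError(
            f"need at least {history + 1} detected peaks for prediction")
    ibis = detected.ibis[-history:]
    return float(detected.r_times[-1] + np.median(ibis))


def _anchor_index(rr: RRSeries, earliest_allowed: float, history: int) -> int:
    """Index of the first usable R-peak at/after ``earliest_allowed``.

    The anchor must have ``history`` IBIs behind it for the predictor.
    Returns -1 if the stream is exhausted.
    """
    i = int(np.searchsorted(rr.r_times, earliest_allowed, side="left"))
    i = max(i, history)  # burn-in so the median predictor is defined
    return i if i < len(rr) else -1


def schedule_trial_onset(phase: str, detected: RRSeries, earliest_allowed: float,
                         config: GatingConfig = GatingConfig()):
    """Cue onset time for one trial.

    Waits for the first R-peak at/after ``earliest_allowed`` (the anchor
    R*).  Systole trials fire at R* + systole_offset.  Diastole trials fire
    at the predicted next R (R* + median of the ``history`` preceding IBIs)
    minus diastole_offset.

    Returns ``(onset_ms, anchor_index)``; raises ``InsufficientDataError``
    if the stream is exhausted before an anchor is found.
    """
    idx = _anchor_index(detected, earliest_allowed, config.history)
    if idx < 0:
        raise InsufficientDataError("R-peak stream exhausted before trial onset")
    r_star = detected.r_times[idx]
    if phase == SYSTOLE:
        return r_star + config.systole_offset, idx
    if phase == DIASTOLE:
        upto = RRSeries(detected.r_times[:idx + 1])
        predicted = predict_next_r(upto, config.history)
        return predicted - config.diastole_offset, idx
    raise InvalidInputError(f"unknown phase {phase!r}")


def simulate_gated_session(schedule, rr: RRSeries,
                           config: GatingConfig = GatingConfig(),
                           rts_ms=None, start_ms: float | None = None):
    """Sequentially schedule every trial of ``schedule`` on an RR stream.

    ``schedule`` is a sequence of ``(trial_type, phase)`` pairs (trial_type
    is carried through untouched).  Each trial consumes its cue duration —
    the response time if ``rts_ms`` provides one (the cue ends at the
    press), else the full ``cue_max_ms`` — plus the fixation period before
    the next trial's ECG monitoring starts.

    Returns a dict of aligned arrays: ``trial_index, trial_type, phase,
    onset_ms, anchor_index, complete``.  If the stream runs out, the
    session is truncated and ``complete`` is False.
    """
    phases, types, onsets, anchors = [], [], [], []
    cursor = float(rr.r_times[0]) if start_ms is None else float(start_ms)
    complete = True
    for i, (ttype, phase) in enumerate(schedule):
        earliest = cursor + config.fixation_ms
        try:
            onset, idx = schedule_trial_onset(phase, rr, earliest, config)
        except InsufficientDataError:
            complete = False
            break
        cue_ms = config.cue_max_ms
        if rts_ms is not None and rts_ms[i] is not None and np.isfinite(rts_ms[i]):
            cue_ms = min(float(rts_ms[i]), config.cue_max_ms)
        cursor = onset + cue_ms
        types.append(ttype)
        phases.append(phase)
        onsets.append(onset)
        anchors.append(idx)
    return {
        "trial_index": np.arange(len(onsets)),
        "trial_type": np.asarray(types, dtype=object),
        "phase": np.asarray(phases, dtype=object),
        "onset_ms": np.asarray(onsets, dtype=float),
        "anchor_index": np.asarray(anchors, dtype=int),
        "complete": complete,
    }


def _reference_r(rr: RRSeries, onset: float, phase: str,
                 config: GatingConfig, anchor: int | None) -> float:
    """Reference R-wave for an achieved onset.

    Systole: the R preceding the onset (its anchor, when known).  Diastole:
    the R the cue was aimed at — the anchor's successor when the anchor is
    known, otherwise the R nearest to (onset + diastole_offset).  Using the
    targeted R rather than "first R after onset" keeps a cue that lands a
    few ms past its target from being scored against the *following* beat
    (an error of a whole IBI for a miss of a few ms).
    """
    t = rr.r_times
    if phase == SYSTOLE:
        if anchor is not None:
            return t[anchor]
        i = int(np.searchsorted(t, onset, side="right")) - 1
        if i < 0:
            raise InvalidInputError("onset precedes the RR stream")
        return t[i]
    if phase == DIASTOLE:
        if anchor is not None:
            if anchor + 1 >= len(rr):
                raise InvalidInputError("anchor has no successor in the stream")
            return t[anchor + 1]
        target = onset + config.diastole_offset
        i = int(np.clip(np.searchsorted(t, target), 1, len(rr) - 1))
        return t[i] if abs(t[i] - target) < abs(t[i - 1] - target) else t[i - 1]
    raise InvalidInputError(f"unknown phase {phase!r}")


def evaluate_timing(onsets, rr: RRSeries, phases,
                    config: GatingConfig = GatingConfig(),
                    anchor_indices=None) -> TimingReport:
    """Achieved-timing report for a set of trials.

    Per trial: signed offset = onset - reference R; signed error = offset -
    intended offset (+systole_offset for systole, -diastole_offset for
    diastole).  Offsets are histogrammed in ``bin_width`` ms bins over
    [hist_lo, hist_hi), out-of-range values clipped to the end bins;
    fractions per phase sum to 1.
    """
    onsets = np.asarray(onsets, dtype=float)
    phases = np.asarray(phases, dtype=object)
    if onsets.size != phases.size:
        raise InvalidInputError("onsets and phases must be aligned")
    edges = np.arange(config.hist_lo, config.hist_hi, config.bin_width)
    intended = {SYSTOLE: config.systole_offset, DIASTOLE: -config.diastole_offset}
    offsets, errors, hists, fracs = {}, {}, {}, {}
    for phase in (SYSTOLE, DIASTOLE):
        sel = np.flatnonzero(phases == phase)
        offs = np.empty(sel.size)
        for k, i in enumerate(sel):
            anchor = None if anchor_indices is None else int(anchor_indices[i])
            offs[k] = onsets[i] - _reference_r(rr, onsets[i], phase, config, anchor)
        errs = offs - intended[phase]
        offsets[phase], errors[phase] = offs, errs
        fracs[phase] = float(np.mean(np.abs(errs) <= config.tolerance)) if sel.size else np.nan
        if sel.size:
            bins = np.clip(((offs - config.hist_lo) // config.bin_width).astype(int),
                           0, edges.size - 1)
            hists[phase] = np.bincount(bins, minlength=edges.size) / sel.size
        else:
            hists[phase] = np.zeros(edges.size)
    unknown = set(np.unique(phases)) - {SYSTOLE, DIASTOLE}
    if unknown:
        raise InvalidInputError(f"unknown phase labels: {sorted(unknown)}")
    return TimingReport(bin_edges=edges, histograms=hists,
                        fraction_within_tolerance=fracs,
                        offsets=offsets, errors=errors)
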
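"""R-peak time series and inter-beat intervals.

The :class:`RRSeries` is the cardiac ground truth shared by the gating
simulator, the HRV summaries, and the synthetic generator: a strictly
increasing sequence of R-peak times in milliseconds, with the successive
differences (inter-beat intervals, IBIs) derived on demand.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["RRSeries"]


@dataclass(frozen=True)
class RRSeries:
    """Strictly increasing R-peak event times in milliseconds."""

    r_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.r_times, dtype=float)
        if t.ndim != 1:
            raise InvalidInputError("r_times must be one-dimensional")
        if not np.all(np.isfinite(t)):
            raise InvalidInputError("r_times contains non-finite values")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("r_times must be strictly increasing")
        object.__setattr__(self, "r_times", t)

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals (ms), one fewer than the number of peaks."""
        return np.diff(self.r_times)

    def __len__(self) -> int:
        return self.r_times.size

    @property
    def duration_ms(self) -> float:
        return float(self.r_times[-1] - self.r_times[0]) if len(self) >= 2 else 0.0

    def beats_in_window(self, start_ms: float, end_ms: float) -> int:
        """Number of R-peaks with start <= t < end."""
        lo, hi = np.searchsorted(self.r_times, [start_ms, end_ms], side="left")
        return int(hi - lo)
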
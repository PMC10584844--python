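"""Interbeat-interval preprocessing: 10 Hz resampling and 1-s epoch means.

The IBI series is a step function of time: between two successive
R-peaks the interbeat interval is constant. Resampling samples that step
function on a fixed grid shared by both partners; epoch means then
average the samples within each 1-s epoch, giving the "epoch means"
series that enters the synchrony pipeline.

Conventions
-----------
* A sample at time ``t`` takes the value of the interval *containing*
  ``t``, where interval ``i`` covers the half-open span
  ``(t_i, t_{i+1}]`` (right-closed). Samples at or before the first
  peak, or after the last, are invalid.
* The grid is ``t_j = j / rate`` for ``j = 1 .. n_epochs * rate``, so
  epoch ``e`` (the second ``[e, e+1)``) averages the samples at
  ``e + 0.1 .. e + 1.0`` s at the default 10 Hz.
* An epoch containing any invalid sample is invalid as a whole; partial
  averages are never formed.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError
from .series import EpochMeanSeries, RPeakSeries


def resample_ibi(rpeaks: RPeakSeries, rate: int = 10,
                 start_s: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample the IBI step function on a fixed grid.

    Returns ``(values_ms, valid)`` of length ``n_epochs * rate`` where
    ``n_epochs = floor(duration / 1 s)``; the grid starts one step after
    ``start_s`` so that the samples of epoch ``e`` are those in
    ``(e, e+1]`` seconds.
    """
    t = rpeaks.times_s
    if t.size < 3:
        raise InsufficientDataError("need >= 2 interbeat intervals")
    n_epochs = int(np.floor((rpeaks.duration_s - start_s) + 1e-9))
    n = n_epochs * rate
    grid = start_s + (np.arange(n) + 1) / rate
    # first peak index >= grid time: the interval ending at that peak
    idx = np.searchsorted(t, grid, side="left")
    valid = (grid > t[0]) & (idx >= 1) & (idx <= t.size - 1)
    values = np.full(n, np.nan)
    safe = np.clip(idx, 1, t.size - 1)
    ibi = (t[safe] - t[safe - 1]) * 1000.0
    values[valid] = ibi[valid]
    return values, valid


def epoch_means(values: np.ndarray, valid: np.ndarray, rate: int = 10,
                epoch_s: float = 1.0, start_s: float = 0.0) -> EpochMeanSeries:
    """Average each epoch's samples into one IBI value per second.

    An epoch with any invalid constituent sample is invalid (NaN); this
    propagates missing-beat spans rather than forming partial averages.
    """
    per = int(round(rate * epoch_s))
    n_epochs = values.size // per
    v = values[: n_epochs * per].reshape(n_epochs, per)
    m = valid[: n_epochs * per].reshape(n_epochs, per)
    ok = m.all(axis=1)
    out = np.full(n_epochs, np.nan)
    out[ok] = v[ok].mean(axis=1)
    return EpochMeanSeries(values=out, valid=ok, epoch_s=epoch_s,
                           start_s=start_s)


def ibi_epoch_series(rpeaks: RPeakSeries, rate: int = 10,
                     epoch_s: float = 1.0) -> EpochMeanSeries:
    """R-peaks -> per-second IBI epoch means (the full preprocessing)."""
    values, valid = resample_ibi(rpeaks, rate=rate)
    return epoch_means(values, valid, rate=rate, epoch_s=epoch_s)
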
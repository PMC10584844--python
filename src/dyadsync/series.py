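"""Core in-memory containers for the synchrony pipeline.

All per-second series share one convention: epoch ``j`` is the half-open
interval ``[j, j+1)`` seconds from recording start, so mother and child
series recorded with a shared clock line up index-for-index, which is a
precondition for lagged alignment.

Lag sign convention (used everywhere): for a profile value ``r(k)``,
positive ``k`` means the mother's signal precedes the child's ("mother
leads"); negative ``k`` means the child leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InsufficientDataError

ROLES = ("mother", "child")
CONDITIONS = ("Rest", "Single", "La1", "La2")
#: conditions in which the partners interact (joint labyrinth games)
INTERACTIVE_CONDITIONS = ("La1", "La2")


@dataclass(frozen=True)
class RPeakSeries:
    """Ordered R-peak event times for one participant/condition.

    Parameters
    ----------
    times_s
        Strictly increasing peak times in seconds from recording start.
    duration_s
        Declared recording duration; defaults to the last peak time.
    """

    times_s: np.ndarray
    duration_s: float

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        if t.size < 3:
            raise InsufficientDataError(
                f"need >= 3 R-peaks, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise FormatError("R-peak times must be strictly increasing")
        if t[0] < 0:
            raise FormatError("negative R-peak time")
        if t[-1] > self.duration_s + 1e-9:
            raise FormatError(
                f"peak at {t[-1]:g}s exceeds declared duration "
                f"{self.duration_s:g}s")

    @property
    def n_peaks(self) -> int:
        return self.times_s.size

    @property
    def ibi_ms(self) -> np.ndarray:
        """Interbeat intervals in milliseconds (length ``n_peaks - 1``)."""
        return np.diff(self.times_s) * 1000.0


@dataclass
class EpochMeanSeries:
    """Per-epoch mean interbeat interval (ms) on a fixed 1-s grid."""

    values: np.ndarray          # ms; NaN where invalid
    valid: np.ndarray           # bool per epoch
    epoch_s: float = 1.0
    start_s: float = 0.0

    @property
    def n_epochs(self) -> int:
        return self.values.size


@dataclass
class RSASeries:
    """Second-by-second ln respiration-band power of the IBI series."""

    values: np.ndarray          # ln(ms^2); NaN where invalid
    valid: np.ndarray
    band_hz: tuple[float, float] = (0.12, 0.40)
    window_s: float = 32.0
    overlap_s: float = 31.0
    meta: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.values.size


@dataclass
class AffectSeries:
    """Binary per-second affect series (1 = positive affect present)."""

    values: np.ndarray          # int 0/1 per second
    role: str = "child"         # mother | child | shared
    code: str = "positive"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=int)
        if v.size and not np.isin(v, (0, 1)).all():
            raise FormatError("affect series must be binary 0/1")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def fraction(self) -> float:
        """Fraction of task time the code is present (Table-style M value)."""
        return float(self.values.mean()) if self.values.size else 0.0


def shared_affect(mother: AffectSeries, child: AffectSeries) -> AffectSeries:
    """Elementwise AND of the two partners' binary series."""
    n = min(mother.n, child.n)
    return AffectSeries(mother.values[:n] & child.values[:n], role="shared")


@dataclass
class ResidualSeries:
    """Pre-whitened residuals entering the cross-correlation.

    One sample is lost to differencing, so ``n = len(input) - 1``.
    ``report`` carries the detrend coefficients, ARIMA parameter
    estimates and a convergence/degeneracy flag.
    """

    values: np.ndarray
    source: str                  # ibi | rsa
    report: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class SynchronyProfile:
    """Cross-correlation per lag for one dyad/condition/signal.

    ``r[i]`` is the Pearson correlation of mother[t] with child[t + lags[i]],
    so positive lags quantify mother-precedes-child covariation.
    """

    lags: np.ndarray             # int seconds, ascending
    r: np.ndarray                # correlation per lag; NaN if undefined
    n_overlap: np.ndarray        # samples per lag
    dyad_id: str = ""
    condition: str = ""
    source: str = "ibi"

    def r_at(self, lag: int) -> float:
        idx = np.flatnonzero(self.lags == lag)
        if idx.size != 1:
            raise KeyError(f"lag {lag} not in profile")
        return float(self.r[idx[0]])

    def argmax_lag(self) -> int:
        """Lag with the highest correlation (NaNs ignored)."""
        return int(self.lags[np.nanargmax(self.r)])


@dataclass
class DyadRecord:
    """Paired mother+child data for one dyad and condition."""

    dyad_id: str
    condition: str
    mother_rpeaks: RPeakSeries | None = None
    child_rpeaks: RPeakSeries | None = None
    mother_affect: AffectSeries | None = None
    child_affect: AffectSeries | None = None

    def rpeaks(self, role: str) -> RPeakSeries | None:
        return self.mother_rpeaks if role == "mother" else self.child_rpeaks

    def affect(self, role: str) -> AffectSeries | None:
        if role == "shared":
            if self.mother_affect is None or self.child_affect is None:
                return None
            return shared_affect(self.mother_affect, self.child_affect)
        return self.mother_affect if role == "mother" else self.child_affect

    @property
    def complete(self) -> bool:
        return self.mother_rpeaks is not None and self.child_rpeaks is not None


@dataclass
class Cohort:
    """All dyads of a study, keyed by (dyad_id, condition)."""

    records: dict = field(default_factory=dict)   # (dyad_id, condition) -> DyadRecord

    def get(self, dyad_id: str, condition: str) -> DyadRecord | None:
        return self.records.get((dyad_id, condition))

    def add(self, rec: DyadRecord) -> None:
        self.records[(rec.dyad_id, rec.condition)] = rec

    @property
    def dyad_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for d, _ in self.records:
            seen.setdefault(d)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, c in self.records:
            seen.setdefault(c)
        return list(seen)

    def dyads_in(self, condition: str) -> list[DyadRecord]:
        return [r for (d, c), r in self.records.items()
                if c == condition and r.complete]
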
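"""Affect series construction and lagged regression-out ("cleaning").

The behavioral coding gives, per participant, a binary per-second
positive-affect series. Its contribution to physiological synchrony is
measured by removal: each participant's raw per-second ANS series (IBI
epoch means or ln RSA) is regressed on 21 lagged copies of an affect
series (shifts -10..+10 s, all jointly, plus intercept), the residuals
re-enter the unchanged synchrony pipeline, and the drop in synchrony
(uncleaned - cleaned) quantifies how much of the covariation the affect
carried.

Variants: *individual* uses the participant's own affect series,
*shared* the dyad's AND-series (same predictor set for both partners).
The shuffled-affect control substitutes, exhaustively, every other
same-role participant's affect series; own-affect cleaning should
reduce synchrony more than foreign-affect cleaning if the affect is
doing real work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import InsufficientDataError
from .series import AffectSeries, Cohort, DyadRecord, SynchronyProfile
from .synchrony import (cross_correlation_profile, prewhiten,
                        _common_valid_span)

VARIANTS = ("individual", "shared", "shuffled-individual",
            "shuffled-shared")


def affect_series(intervals, duration_s: float,
                  role: str = "child") -> AffectSeries:
    """Binarize annotation intervals onto the 1-s epoch grid.

    Second ``j`` is set iff the annotations cover at least 0.5 s of
    ``[j, j+1)``. Intervals are assumed pre-clipped to the recording.
    """
    n = int(np.floor(duration_s))
    coverage = np.zeros(n)
    for onset, offset in intervals:
        lo = int(np.floor(onset))
        hi = min(int(np.ceil(offset)), n)
        for j in range(max(lo, 0), hi):
            coverage[j] += max(0.0, min(offset, j + 1) - max(onset, j))
    return AffectSeries((coverage >= 0.5).astype(int), role=role)


def lagged_affect_design(affect: np.ndarray, lags=None) -> np.ndarray:
    """Design matrix of lagged affect copies plus intercept.

    Column for shift ``s`` holds ``affect[t - s]``; out-of-range entries
    are 0 (absence of affect is a meaningful value for a binary
    predictor, and padding preserves the series length). The intercept
    is the last column.
    """
    if lags is None:
        lags = range(-10, 11)
    lags = list(lags)
    a = np.asarray(affect, dtype=float)
    n = a.size
    if n <= len(lags) + 2:
        raise InsufficientDataError(
            f"series of {n} samples too short for {len(lags)} lagged "
            "predictors")
    X = np.zeros((n, len(lags) + 1))
    for j, s in enumerate(lags):
        if s == 0:
            X[:, j] = a
        elif s > 0:
            X[s:, j] = a[:-s]
        else:
            X[:s, j] = a[-s:]
    X[:, -1] = 1.0
    return X


def regress_out(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of ``values`` on ``design``.

    Rank deficiency (e.g. an all-zero affect series collapsing columns)
    is handled by the minimum-norm solution, which leaves the fitted
    projection — and hence the residuals — well defined.
    """
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


@dataclass
class CleaningResult:
    """Cleaned vs uncleaned synchrony for one dyad/condition/signal."""

    dyad_id: str
    condition: str
    source: str
    variant: str
    cleaned_profile: SynchronyProfile
    uncleaned_profile: SynchronyProfile
    r2_mother: float
    r2_child: float

    @property
    def delta(self) -> np.ndarray:
        """Per-lag synchrony reduction (uncleaned - cleaned)."""
        return self.uncleaned_profile.r - self.cleaned_profile.r


def _r_squared(values: np.ndarray, residuals: np.ndarray) -> float:
    tot = float(np.var(values))
    return 1.0 - float(np.var(residuals)) / tot if tot > 0 else 0.0


def _extract_series(rec: DyadRecord, role: str, source: str,
                    cfg: PipelineConfig):
    from .ibi import ibi_epoch_series
    from .rsa import rsa_from_rpeaks
    rp = rec.rpeaks(role)
    if rp is None:
        raise InsufficientDataError(
            f"dyad {rec.dyad_id}/{rec.condition} missing {role}")
    if source == "ibi":
        s = ibi_epoch_series(rp, rate=cfg.resample_hz, epoch_s=cfg.epoch_s)
    else:
        s = rsa_from_rpeaks(rp, cfg)
    return s.values, s.valid


def _affect_for(rec: DyadRecord, role: str, variant: str,
                override: np.ndarray | None = None) -> np.ndarray:
    if override is not None:
        return override
    key = "shared" if variant.endswith("shared") else role
    aff = rec.affect(key)
    if aff is None:
        raise InsufficientDataError(
            f"dyad {rec.dyad_id}/{rec.condition} has no affect series "
            f"for {key}")
    return aff.values


def cleaned_synchrony(rec: DyadRecord, source: str = "ibi",
                      variant: str = "individual",
                      config: PipelineConfig | None = None,
                      mother_affect: np.ndarray | None = None,
                      child_affect: np.ndarray | None = None
                      ) -> CleaningResult:
    """Synchrony before and after regressing affect out of both partners.

    The cleaning runs on the raw per-second series over the partners'
    common valid span, before detrending, so the downstream pipeline is
    identical for both branches. Explicit ``*_affect`` arrays override
    the dyad's own series (the shuffled-affect control passes foreign
    series here).
    """
    cfg = config or PipelineConfig()
    mv, mok = _extract_series(rec, "mother", source, cfg)
    cv, cok = _extract_series(rec, "child", source, cfg)
    span = _common_valid_span(mok, cok)
    mv, cv = mv[span], cv[span]

    m_aff = _affect_for(rec, "mother", variant, mother_affect)[span]
    c_aff = _affect_for(rec, "child", variant, child_affect)[span]
    if cfg.clean_use_both_individual and variant == "individual" \
            and mother_affect is None and child_affect is None:
        Xm = np.column_stack([
            lagged_affect_design(m_aff, cfg.clean_lags)[:, :-1],
            lagged_affect_design(c_aff, cfg.clean_lags)])
        Xc = Xm
    else:
        Xm = lagged_affect_design(m_aff, cfg.clean_lags)
        Xc = lagged_affect_design(c_aff, cfg.clean_lags)

    m_clean = regress_out(mv, Xm)
    c_clean = regress_out(cv, Xc)

    def profile(m, c):
        return cross_correlation_profile(
            prewhiten(m, cfg, source=source),
            prewhiten(c, cfg, source=source),
            lags=cfg.sync_lags, dyad_id=rec.dyad_id,
            condition=rec.condition)

    return CleaningResult(
        dyad_id=rec.dyad_id, condition=rec.condition, source=source,
        variant=variant,
        cleaned_profile=profile(m_clean, c_clean),
        uncleaned_profile=profile(mv, cv),
        r2_mother=_r_squared(mv, m_clean),
        r2_child=_r_squared(cv, c_clean))


def shuffled_affect_control(cohort: Cohort, dyad_id: str, condition: str,
                            source: str = "ibi",
                            variant: str = "individual",
                            config: PipelineConfig | None = None
                            ) -> CleaningResult | None:
    """Mean cleaned profile over the exhaustive foreign-affect set.

    For each other dyad with affect data in the condition, the child is
    cleaned with that dyad's child affect and the mother with that
    dyad's mother affect (the shared variant substitutes the foreign
    dyad's shared series for both); the resulting cleaned profiles are
    averaged per lag.
    """
    cfg = config or PipelineConfig()
    rec = cohort.get(dyad_id, condition)
    if rec is None or not rec.complete:
        return None
    mv, mok = _extract_series(rec, "mother", source, cfg)
    cv, cok = _extract_series(rec, "child", source, cfg)
    span = _common_valid_span(mok, cok)
    mv, cv = mv[span], cv[span]

    def profile(m, c):
        return cross_correlation_profile(
            prewhiten(m, cfg, source=source),
            prewhiten(c, cfg, source=source),
            lags=cfg.sync_lags, dyad_id=dyad_id, condition=condition)

    uncleaned = profile(mv, cv)
    cleaned_rs, r2m, r2c = [], [], []
    for other_id in cohort.dyad_ids:
        if other_id == dyad_id:
            continue
        other = cohort.get(other_id, condition)
        if other is None:
            continue
        if variant.endswith("shared"):
            foreign = other.affect("shared")
            if foreign is None:
                continue
            m_aff = c_aff = foreign.values
        else:
            fm, fc = other.affect("mother"), other.affect("child")
            if fm is None or fc is None:
                continue
            m_aff, c_aff = fm.values, fc.values
        if m_aff.size < span.stop or c_aff.size < span.stop:
            continue
        m_clean = regress_out(mv, lagged_affect_design(m_aff[span],
                                                       cfg.clean_lags))
        c_clean = regress_out(cv, lagged_affect_design(c_aff[span],
                                                       cfg.clean_lags))
        cleaned_rs.append(profile(m_clean, c_clean).r)
        r2m.append(_r_squared(mv, m_clean))
        r2c.append(_r_squared(cv, c_clean))
    if not cleaned_rs:
        return None
    mean_profile = SynchronyProfile(
        lags=uncleaned.lags.copy(), r=np.vstack(cleaned_rs).mean(axis=0),
        n_overlap=uncleaned.n_overlap.copy(),
        dyad_id=dyad_id, condition=condition, source=source)
    return CleaningResult(
        dyad_id=dyad_id, condition=condition, source=source,
        variant=f"shuffled-{variant}",
        cleaned_profile=mean_profile, uncleaned_profile=uncleaned,
        r2_mother=float(np.mean(r2m)), r2_child=float(np.mean(r2c)))
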
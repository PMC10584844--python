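"""Pre-whitening and lagged cross-correlation — the synchrony statistic.

Within-person autocorrelation inflates cross-correlations between two
independent but individually smooth series; each partner's series is
therefore pre-whitened before correlating:

1. quadratic (order-2 polynomial) detrend, removing linear and
   quadratic drift over the task;
2. ARIMA(1,1,1) fitted without constant on the detrend residuals; the
   one-step-ahead innovations are the whitened series (one sample is
   lost to differencing).

The synchrony profile is then the Pearson correlation of the two
innovation series at integer lags k in [-3, +3] s:

    r(k) = corr( mother[t], child[t+k] )

so positive k means the mother's signal precedes the child's ("mother
leads") and negative k means the child leads. Each lag is computed on
its own overlap with per-lag re-centering (no zero padding).
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import PipelineConfig
from .errors import InsufficientDataError
from .series import DyadRecord, ResidualSeries, SynchronyProfile

#: residual variance below this (relative to input) is treated as degenerate
_DEGENERATE_TOL = 1e-12


def detrend_poly(values: np.ndarray, order: int = 2) -> np.ndarray:
    """Least-squares polynomial detrend; returns the fit residuals.

    The design is (1, t, t^2, ...) on the sample index; residuals keep
    the input's length.
    """
    y = np.asarray(values, dtype=float)
    if y.size <= order + 1:
        raise InsufficientDataError(
            f"need more than {order + 1} samples for an order-{order} fit")
    t = np.arange(y.size, dtype=float)
    # scaled index keeps the Vandermonde well conditioned at n ~ 300
    coeffs = np.polynomial.polynomial.polyfit(t / y.size, y, order)
    fitted = np.polynomial.polynomial.polyval(t / y.size, coeffs)
    return y - fitted


def _ar1_innovations(d: np.ndarray) -> tuple[np.ndarray, float]:
    """AR(1) innovations of a differenced series via Yule-Walker."""
    v = d - d.mean()
    denom = float(v @ v)
    phi = float(v[1:] @ v[:-1]) / denom if denom > 0 else 0.0
    phi = float(np.clip(phi, -0.99, 0.99))
    resid = np.empty_like(d)
    resid[0] = d[0]
    resid[1:] = d[1:] - phi * d[:-1]
    return resid, phi


def arima_prewhiten(values: np.ndarray, order: tuple[int, int, int] = (1, 1, 1),
                    source: str = "ibi") -> ResidualSeries:
    """ARIMA innovation residuals of a (detrended) series.

    Maximum-likelihood ARIMA fit without constant (the input is already
    detrended, and differencing removes any remaining level). Returns
    the one-step-ahead innovations with the first (undefined) value
    dropped, so the output is one sample shorter than the input. On
    non-convergence the fallback is AR(1) on first differences, with
    the report flagging the downgrade; a series that is constant after
    differencing yields all-zero residuals flagged degenerate.
    """
    from statsmodels.tsa.arima.model import ARIMA

    y = np.asarray(values, dtype=float)
    d = int(order[1])
    diffed = np.diff(y, n=d) if d else y
    report: dict = {"order": order, "converged": False, "degenerate": False,
                    "fallback": None}
    if diffed.size == 0 or np.allclose(diffed, diffed[0], atol=1e-12):
        report["degenerate"] = True
        return ResidualSeries(np.zeros(max(y.size - max(d, 1), 0)),
                              source=source, report=report)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ARIMA(y, order=order, trend="n")
            res = model.fit()
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            raise RuntimeError("MLE did not converge")
        resid = np.asarray(res.resid)[max(d, 1):]
        report.update(converged=True,
                      phi=float(res.arparams[0]) if order[0] else 0.0,
                      theta=float(res.maparams[0]) if order[2] else 0.0)
        return ResidualSeries(resid, source=source, report=report)
    except Exception as exc:  # non-convergence or numerical failure
        resid, phi = _ar1_innovations(np.diff(y) if d == 0 else diffed)
        report.update(fallback="ar1-diff", phi=phi, theta=0.0,
                      error=str(exc))
        warnings.warn(f"ARIMA fit failed ({exc}); falling back to AR(1) "
                      "on first differences")
        return ResidualSeries(resid[1:] if d == 0 else resid,
                              source=source, report=report)


def prewhiten(values: np.ndarray, config: PipelineConfig | None = None,
              source: str = "ibi") -> ResidualSeries:
    """Quadratic detrend followed by ARIMA innovation filtering."""
    cfg = config or PipelineConfig()
    detrended = detrend_poly(values, order=cfg.detrend_order)
    rs = arima_prewhiten(detrended, order=cfg.arima_order, source=source)
    rs.report["detrend_order"] = cfg.detrend_order
    return rs


def lagged_pearson(mother: np.ndarray, child: np.ndarray, lag: int
                   ) -> tuple[float, int]:
    """Pearson r of mother[t] with child[t+lag] on the overlap.

    Returns ``(r, n_overlap)``; r is NaN when either slice has zero
    variance on the overlap.
    """
    n = min(mother.size, child.size)
    m, c = mother[:n], child[:n]
    if lag >= 0:
        a, b = m[: n - lag], c[lag:]
    else:
        a, b = m[-lag:], c[: n + lag]
    if a.size < 3:
        return np.nan, a.size
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom <= 0:
        return np.nan, a.size
    return float((a @ b) / denom), a.size


def cross_correlation_profile(mother: ResidualSeries, child: ResidualSeries,
                              lags=None, dyad_id: str = "",
                              condition: str = "") -> SynchronyProfile:
    """Synchrony profile r(k) for k in the given lag range (default -3..3)."""
    if lags is None:
        lags = range(-3, 4)
    lags = np.asarray(sorted(lags), dtype=int)
    if mother.source != child.source:
        raise ValueError("partners' series have different sources "
                         f"({mother.source} vs {child.source})")
    r = np.empty(lags.size)
    n_overlap = np.empty(lags.size, dtype=int)
    for i, k in enumerate(lags):
        r[i], n_overlap[i] = lagged_pearson(mother.values, child.values,
                                            int(k))
    return SynchronyProfile(lags=lags, r=r, n_overlap=n_overlap,
                            dyad_id=dyad_id, condition=condition,
                            source=mother.source)


def _common_valid_span(valid_a: np.ndarray, valid_b: np.ndarray) -> slice:
    """Largest contiguous run of seconds where both series are valid."""
    both = valid_a[: min(valid_a.size, valid_b.size)] \
        & valid_b[: min(valid_a.size, valid_b.size)]
    if not both.any():
        raise InsufficientDataError("no common valid span")
    idx = np.flatnonzero(both)
    # runs of consecutive indices; keep the longest
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    best = np.argmax(ends - starts)
    return slice(idx[starts[best]], idx[ends[best]] + 1)


def compute_synchrony(dyad: DyadRecord, source: str = "ibi",
                      config: PipelineConfig | None = None,
                      mother_values=None, child_values=None,
                      mother_valid=None, child_valid=None
                      ) -> SynchronyProfile:
    """Full synchrony statistic for one dyad/condition/signal.

    Composition detrend -> ARIMA -> lagged cross-correlation, applied
    identically to IBI epoch means and per-second ln RSA. Only the
    common valid span of the two partners (aligned on the shared epoch
    grid) enters the pipeline. Pass precomputed per-second
    ``*_values``/``*_valid`` arrays to skip the signal extraction; the
    usual entry point extracts them from the dyad's R-peak series.
    """
    cfg = config or PipelineConfig()
    if mother_values is None or child_values is None:
        from .ibi import ibi_epoch_series
        from .rsa import rsa_from_rpeaks
        if not dyad.complete:
            raise InsufficientDataError(
                f"dyad {dyad.dyad_id}/{dyad.condition} missing a partner")
        if source == "ibi":
            ms = ibi_epoch_series(dyad.mother_rpeaks, rate=cfg.resample_hz,
                                  epoch_s=cfg.epoch_s)
            cs = ibi_epoch_series(dyad.child_rpeaks, rate=cfg.resample_hz,
                                  epoch_s=cfg.epoch_s)
        elif source == "rsa":
            ms = rsa_from_rpeaks(dyad.mother_rpeaks, cfg)
            cs = rsa_from_rpeaks(dyad.child_rpeaks, cfg)
        else:
            raise ValueError(f"unknown source {source!r}")
        mother_values, mother_valid = ms.values, ms.valid
        child_values, child_valid = cs.values, cs.valid
    if mother_valid is None:
        mother_valid = np.isfinite(mother_values)
    if child_valid is None:
        child_valid = np.isfinite(child_values)
    span = _common_valid_span(np.asarray(mother_valid),
                              np.asarray(child_valid))
    m_res = prewhiten(np.asarray(mother_values)[span], cfg, source=source)
    c_res = prewhiten(np.asarray(child_values)[span], cfg, source=source)
    return cross_correlation_profile(m_res, c_res, lags=cfg.sync_lags,
                                     dyad_id=dyad.dyad_id,
                                     condition=dyad.condition)
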
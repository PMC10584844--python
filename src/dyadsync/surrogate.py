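"""Shuffled-pair surrogate synchrony: the task-similarity null.

Two people doing the same task can covary simply because the task
drives both. The surrogate for a dyad pairs its child with every other
dyad's mother and its mother with every other dyad's child — same
condition, never the own partner — computes the same pre-whitened
cross-correlation for each pairing, and averages the profiles
(arithmetic mean of correlations over the pooled child-side and
adult-side sets; optionally on the Fisher-z scale). The set is
exhaustive, so the surrogate is deterministic.

Pre-whitening is per participant, so each participant's residual series
is computed once and reused across all pairings; unequal valid spans
are aligned from each span's start and truncated to the shorter length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .series import Cohort, ResidualSeries, SynchronyProfile
from .synchrony import cross_correlation_profile, prewhiten


@dataclass
class SurrogateResult:
    """Mean shuffled-pair profile for one dyad/condition/signal."""

    dyad_id: str
    condition: str
    source: str
    mean_profile: SynchronyProfile
    set_size: int


class ResidualCache:
    """Per-participant pre-whitened residuals, computed lazily once."""

    def __init__(self, cohort: Cohort, source: str = "ibi",
                 config: PipelineConfig | None = None):
        self.cohort = cohort
        self.source = source
        self.cfg = config or PipelineConfig()
        self._store: dict = {}

    def _extract(self, rpeaks):
        from .ibi import ibi_epoch_series
        from .rsa import rsa_from_rpeaks
        if self.source == "ibi":
            s = ibi_epoch_series(rpeaks, rate=self.cfg.resample_hz,
                                 epoch_s=self.cfg.epoch_s)
        else:
            s = rsa_from_rpeaks(rpeaks, self.cfg)
        return s.values[s.valid]

    def residuals(self, dyad_id: str, role: str,
                  condition: str) -> ResidualSeries | None:
        key = (dyad_id, role, condition)
        if key not in self._store:
            rec = self.cohort.get(dyad_id, condition)
            rp = rec.rpeaks(role) if rec is not None else None
            if rp is None:
                self._store[key] = None
            else:
                vals = self._extract(rp)
                self._store[key] = prewhiten(vals, self.cfg,
                                             source=self.source)
        return self._store[key]


def _mean_profiles(profiles: list[SynchronyProfile], fisher_z: bool,
                   dyad_id: str, condition: str,
                   source: str) -> SynchronyProfile:
    lags = profiles[0].lags
    stack = np.vstack([p.r for p in profiles])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
        mean_r = np.tanh(np.nanmean(z, axis=0))
    else:
        mean_r = np.nanmean(stack, axis=0)
    n_overlap = np.vstack([p.n_overlap for p in profiles]).min(axis=0)
    return SynchronyProfile(lags=lags.copy(), r=mean_r, n_overlap=n_overlap,
                            dyad_id=dyad_id, condition=condition,
                            source=source)


def shuffled_pair_profiles(cohort: Cohort, dyad_id: str, condition: str,
                           source: str = "ibi",
                           config: PipelineConfig | None = None,
                           cache: ResidualCache | None = None
                           ) -> SurrogateResult | None:
    """Mean synchrony of the dyad's exhaustive shuffled-pair set.

    Pairings with a missing series are skipped (reducing ``set_size``);
    a dyad with no valid pairing at all yields ``None``.
    """
    cfg = config or PipelineConfig()
    if cache is None:
        cache = ResidualCache(cohort, source=source, config=cfg)
    own_child = cache.residuals(dyad_id, "child", condition)
    own_mother = cache.residuals(dyad_id, "mother", condition)
    profiles: list[SynchronyProfile] = []
    for other_id in cohort.dyad_ids:
        if other_id == dyad_id:
            continue
        # child of this dyad x mother of the other
        other_mother = cache.residuals(other_id, "mother", condition)
        if own_child is not None and other_mother is not None:
            profiles.append(cross_correlation_profile(
                other_mother, own_child, lags=cfg.sync_lags,
                dyad_id=f"{dyad_id}~{other_id}", condition=condition))
        # mother of this dyad x child of the other
        other_child = cache.residuals(other_id, "child", condition)
        if own_mother is not None and other_child is not None:
            profiles.append(cross_correlation_profile(
                own_mother, other_child, lags=cfg.sync_lags,
                dyad_id=f"{dyad_id}~{other_id}", condition=condition))
    if not profiles:
        return None
    mean_profile = _mean_profiles(profiles, cfg.fisher_z_average,
                                  dyad_id, condition, source)
    return SurrogateResult(dyad_id=dyad_id, condition=condition,
                           source=source, mean_profile=mean_profile,
                           set_size=len(profiles))


def cohort_surrogates(cohort: Cohort, condition: str, source: str = "ibi",
                      config: PipelineConfig | None = None
                      ) -> dict[str, SurrogateResult]:
    """Surrogate results for every dyad of a condition, sharing one
    residual cache."""
    cfg = config or PipelineConfig()
    cache = ResidualCache(cohort, source=source, config=cfg)
    out: dict[str, SurrogateResult] = {}
    for dyad_id in cohort.dyad_ids:
        res = shuffled_pair_profiles(cohort, dyad_id, condition,
                                     source=source, config=cfg, cache=cache)
        if res is not None:
            out[dyad_id] = res
    return out
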
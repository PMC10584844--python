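"""End-to-end pipeline: manifest in, result tables out.

Stages: per-dyad synchrony profiles (IBI and RSA), exhaustive
shuffled-pair surrogates, affect-cleaned profiles with shuffled-affect
controls, and the cohort statistics (actual-vs-surrogate paired tests,
mirrored-lag tests, condition mixed models, across-dyad correlations).
Any stage failure excludes that (dyad, condition) from group statistics
with a logged reason — never a silent imputation. Everything on disk is
CSV; the effective configuration (with seed) is echoed to the output
directory for provenance.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .affect import cleaned_synchrony, shuffled_affect_control
from .config import PipelineConfig
from .io import CohortManifest, load_cohort, profiles_to_frame
from .series import Cohort, INTERACTIVE_CONDITIONS
from .stats import (attach_fdr, compare_lag_signs, condition_lmm, fdr_adjust,
                    paired_t, across_dyad_correlations)
from .surrogate import cohort_surrogates
from .synchrony import compute_synchrony

log = logging.getLogger("dyadsync")

SOURCES = ("ibi", "rsa")
_FLOAT_FMT = "%.10g"


def actual_profiles(cohort: Cohort, source: str, cfg: PipelineConfig,
                    conditions=None) -> tuple[list, list]:
    """Per-dyad synchrony profiles; returns (profiles, exclusions)."""
    profiles, excluded = [], []
    for condition in conditions or cohort.conditions:
        for rec in cohort.dyads_in(condition):
            try:
                profiles.append(compute_synchrony(rec, source, cfg))
            except Exception as exc:
                log.error("excluding %s/%s from %s synchrony: %s",
                          rec.dyad_id, condition, source, exc)
                excluded.append((rec.dyad_id, condition, source, str(exc)))
    return profiles, excluded


def surrogate_table(cohort: Cohort, source: str, cfg: PipelineConfig,
                    profiles: list, conditions=None) -> pd.DataFrame:
    """Actual and mean-surrogate r side by side, one row per lag."""
    actual = {(p.dyad_id, p.condition): p for p in profiles}
    rows = []
    for condition in conditions or cohort.conditions:
        surr = cohort_surrogates(cohort, condition, source, cfg)
        for dyad_id, res in surr.items():
            act = actual.get((dyad_id, condition))
            for i, lag in enumerate(res.mean_profile.lags):
                rows.append({
                    "dyad_id": dyad_id, "condition": condition,
                    "source": source, "lag": int(lag),
                    "r_actual": float(act.r[i]) if act is not None
                    else np.nan,
                    "r_surrogate": float(res.mean_profile.r[i]),
                    "set_size": res.set_size})
    return pd.DataFrame(rows)


def cleaned_table(cohort: Cohort, source: str, cfg: PipelineConfig,
                  variants=("individual", "shared"),
                  with_shuffled: bool = True,
                  conditions=INTERACTIVE_CONDITIONS) -> pd.DataFrame:
    """Cleaned vs uncleaned r per dyad/condition/lag/variant."""
    rows = []
    for condition in conditions:
        for variant in variants:
            for rec in cohort.dyads_in(condition):
                try:
                    cr = cleaned_synchrony(rec, source, variant, cfg)
                except Exception as exc:
                    log.error("cleaning failed for %s/%s (%s): %s",
                              rec.dyad_id, condition, variant, exc)
                    continue
                for i, lag in enumerate(cr.cleaned_profile.lags):
                    rows.append({
                        "dyad_id": rec.dyad_id, "condition": condition,
                        "source": source, "variant": variant,
                        "lag": int(lag),
                        "r_uncleaned": float(cr.uncleaned_profile.r[i]),
                        "r_cleaned": float(cr.cleaned_profile.r[i]),
                        "r2_mother": cr.r2_mother,
                        "r2_child": cr.r2_child})
            if with_shuffled:
                for rec in cohort.dyads_in(condition):
                    sc = shuffled_affect_control(cohort, rec.dyad_id,
                                                 condition, source,
                                                 variant, cfg)
                    if sc is None:
                        continue
                    for i, lag in enumerate(sc.cleaned_profile.lags):
                        rows.append({
                            "dyad_id": rec.dyad_id, "condition": condition,
                            "source": source, "variant": sc.variant,
                            "lag": int(lag),
                            "r_uncleaned": float(sc.uncleaned_profile.r[i]),
                            "r_cleaned": float(sc.cleaned_profile.r[i]),
                            "r2_mother": sc.r2_mother,
                            "r2_child": sc.r2_child})
    return pd.DataFrame(rows)


def _paired_rows(results) -> list[dict]:
    return [{"family_id": r.family_id, "label": r.label, "t": r.t,
             "df": r.df, "p": r.p, "p_adj": r.p_adj, "d": r.d, "n": r.n,
             "degenerate": r.degenerate} for r in results]


def group_statistics(profiles_by_source: dict, surrogate_frames: dict,
                     cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """All cohort-level tests from precomputed profile tables."""
    out: dict[str, pd.DataFrame] = {}

    # actual vs surrogate, per condition x source, FDR across lags
    rows = []
    for source, frame in surrogate_frames.items():
        for condition, sub in frame.groupby("condition"):
            family = f"t:{source}:{condition}"
            results = []
            for lag, lagsub in sub.groupby("lag"):
                ok = lagsub.dropna(subset=["r_actual", "r_surrogate"])
                if len(ok) < 3:
                    continue
                results.append(paired_t(ok["r_actual"], ok["r_surrogate"],
                                        effect_size=cfg.effect_size,
                                        family_id=family,
                                        label=f"lag {lag:+d}"))
            rows.extend(_paired_rows(attach_fdr(results)))
    out["actual_vs_surrogate"] = pd.DataFrame(rows)

    # mirrored-lag comparisons, per condition x source
    rows = []
    for source, profiles in profiles_by_source.items():
        by_cond: dict[str, list] = {}
        for p in profiles:
            by_cond.setdefault(p.condition, []).append(p)
        for condition, plist in by_cond.items():
            if len(plist) < 3:
                continue
            res = compare_lag_signs(plist, max_lag=cfg.sync_max_lag_s,
                                    effect_size=cfg.effect_size,
                                    family_id=f"lagsign:{source}:{condition}")
            rows.extend(_paired_rows(res))
    out["lag_sign_tests"] = pd.DataFrame(rows)

    # condition mixed models per source x lag, FDR across lags per source
    rows = []
    for source, profiles in profiles_by_source.items():
        frame = profiles_to_frame(profiles)
        lag_results = []
        for lag, sub in frame[frame["r"].notna()].groupby("lag"):
            try:
                res = condition_lmm(sub)
            except Exception as exc:
                log.warning("LMM failed for %s lag %+d: %s",
                            source, lag, exc)
                continue
            lag_results.append((lag, res))
        if lag_results:
            adj = fdr_adjust([r.p for _, r in lag_results])
            for (lag, res), pa in zip(lag_results, adj):
                res.p_adj = float(pa)
                rows.append({"source": source, "lag": int(lag),
                             "F": res.F, "df_num": res.df_num,
                             "df_den": res.df_den, "p": res.p,
                             "p_adj": res.p_adj, "R2": res.R2,
                             "singular": res.singular})
    out["condition_lmm"] = pd.DataFrame(rows)
    return out


def run_pipeline(manifest: CohortManifest, cfg: PipelineConfig,
                 out_dir, sources=SOURCES) -> dict:
    """Execute every stage and write the results bundle to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(cfg.to_yaml())
    log.info("pipeline start: %d manifest entries, seed %d",
             len(manifest.entries), cfg.seed)

    cohort, excluded = load_cohort(manifest)
    results: dict = {"excluded": excluded}

    profiles_by_source: dict[str, list] = {}
    surrogate_frames: dict[str, pd.DataFrame] = {}
    for source in sources:
        profiles, exc = actual_profiles(cohort, source, cfg)
        excluded.extend(exc)
        profiles_by_source[source] = profiles
        frame = profiles_to_frame(profiles)
        frame.to_csv(out_dir / f"profiles_{source}.csv", index=False,
                     float_format=_FLOAT_FMT)
        surr = surrogate_table(cohort, source, cfg, profiles)
        surrogate_frames[source] = surr
        surr.to_csv(out_dir / f"surrogate_{source}.csv", index=False,
                    float_format=_FLOAT_FMT)
        has_affect = any(
            rec.mother_affect is not None and rec.child_affect is not None
            for rec in cohort.records.values())
        if has_affect:
            cleaned = cleaned_table(cohort, source, cfg)
            cleaned.to_csv(out_dir / f"cleaned_{source}.csv", index=False,
                           float_format=_FLOAT_FMT)
            results[f"cleaned_{source}"] = cleaned

    stats_tables = group_statistics(profiles_by_source, surrogate_frames,
                                    cfg)
    for name, table in stats_tables.items():
        table.to_csv(out_dir / f"stats_{name}.csv", index=False,
                     float_format=_FLOAT_FMT)

    # across-dyad correlations at lag 0 (La conditions), with affect
    corr_input = {}
    for source, profiles in profiles_by_source.items():
        for p in profiles:
            if p.condition in INTERACTIVE_CONDITIONS:
                corr_input.setdefault(
                    f"{p.source}_{p.condition}", {})[p.dyad_id] = p.r_at(0)
    for condition in INTERACTIVE_CONDITIONS:
        for role in ("mother", "child", "shared"):
            col = {}
            for rec in cohort.dyads_in(condition):
                aff = rec.affect(role)
                if aff is not None:
                    col[rec.dyad_id] = aff.fraction
            if col:
                corr_input[f"affect_{role}_{condition}"] = col
    if corr_input:
        table = pd.DataFrame(corr_input)
        r, p = across_dyad_correlations(table)
        r.to_csv(out_dir / "correlations_r.csv", float_format=_FLOAT_FMT)
        p.to_csv(out_dir / "correlations_p.csv", float_format=_FLOAT_FMT)
        results["correlations"] = (r, p)

    excl_rows = [{"dyad_id": e[0], "condition": e[1],
                  "reason": "; ".join(str(x) for x in e[2:])}
                 for e in excluded]
    pd.DataFrame(excl_rows, columns=["dyad_id", "condition", "reason"]
                 ).to_csv(out_dir / "excluded.csv", index=False)

    results.update(profiles=profiles_by_source,
                   surrogates=surrogate_frames, stats=stats_tables)
    log.info("pipeline done: outputs in %s", out_dir)
    return results
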
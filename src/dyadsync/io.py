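"""On-disk formats: R-peak CSVs, affect annotation CSVs, cohort manifest.

All series are plain CSV with explicit headers and times in seconds —
inspectable and language-neutral. The manifest is one CSV linking
mother/child recordings per dyad and condition:

    dyad_id,role,condition,rpeak_path,affect_path
    d000,mother,La1,d000_mother_La1_rpeaks.csv,d000_mother_La1_affect.csv

Relative paths resolve against the manifest's directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .affect import affect_series
from .errors import FormatError, InsufficientDataError
from .series import (AffectSeries, Cohort, CONDITIONS, DyadRecord, ROLES,
                     RPeakSeries)

log = logging.getLogger("dyadsync")


def read_rpeaks(path) -> RPeakSeries:
    """Load an R-peak series from CSV (column ``t_rpeak_s``).

    Duplicate consecutive times are collapsed; nonmonotonic input (after
    collapsing) is a format error, fewer than 3 peaks an
    insufficient-data error. The recording duration is the optional
    ``duration_s`` column's first value, else the last peak time.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if "t_rpeak_s" not in df.columns:
        raise FormatError(f"{path}: missing column t_rpeak_s")
    t = df["t_rpeak_s"].to_numpy(dtype=float)
    if t.size and (np.any(~np.isfinite(t)) or t.min() < 0):
        raise FormatError(f"{path}: R-peak times must be finite and >= 0")
    if np.any(np.diff(t) < 0):
        raise FormatError(f"{path}: R-peak times must be nondecreasing")
    t = np.unique(t)
    if t.size < 3:
        raise InsufficientDataError(f"{path}: fewer than 3 distinct peaks")
    if "duration_s" in df.columns and df["duration_s"].notna().any():
        duration = float(df["duration_s"].dropna().iloc[0])
    else:
        duration = float(t[-1])
    return RPeakSeries(times_s=t, duration_s=duration)


def write_rpeaks(rpeaks: RPeakSeries, path) -> None:
    df = pd.DataFrame({"t_rpeak_s": rpeaks.times_s})
    df["duration_s"] = np.nan
    df.loc[0, "duration_s"] = rpeaks.duration_s
    df.to_csv(path, index=False, float_format="%.6f")


def read_affect_annotations(path, duration_s: float
                            ) -> list[tuple[str, float, float]]:
    """Load annotation intervals (columns code, onset_s, offset_s).

    Intervals running past the recording are clipped with a warning;
    a negative onset is an error. An empty file means the participant
    showed no coded affect. All codes are returned; downstream
    consumers select ``positive``.
    """
    df = pd.read_csv(path)
    if df.empty:
        return []
    for col in ("code", "onset_s", "offset_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    out = []
    for _, row in df.iterrows():
        onset, offset = float(row["onset_s"]), float(row["offset_s"])
        if onset < 0:
            raise FormatError(f"{path}: negative onset {onset}")
        if not onset < offset:
            raise FormatError(f"{path}: empty interval ({onset}, {offset})")
        if offset > duration_s:
            log.warning("%s: interval (%g, %g) exceeds duration %g; "
                        "clipped", path, onset, offset, duration_s)
            offset = duration_s
            if not onset < offset:
                continue
        code = str(row["code"])
        if code != "positive":
            log.warning("%s: retaining non-positive code %r", path, code)
        out.append((code, onset, offset))
    return out


def write_affect_annotations(affect: AffectSeries, path) -> None:
    """Write a binary series as positive-code onset/offset intervals."""
    v = np.concatenate(([0], affect.values, [0]))
    onsets = np.flatnonzero(np.diff(v) == 1)
    offsets = np.flatnonzero(np.diff(v) == -1)
    df = pd.DataFrame({"code": "positive",
                       "onset_s": onsets.astype(float),
                       "offset_s": offsets.astype(float)})
    df.to_csv(path, index=False, float_format="%.6f")


def load_affect(path, duration_s: float, role: str) -> AffectSeries:
    """Annotations -> binary per-second series for one participant."""
    intervals = read_affect_annotations(path, duration_s)
    pos = [(a, b) for code, a, b in intervals if code == "positive"]
    return affect_series(pos, duration_s, role=role)


@dataclass
class ManifestEntry:
    dyad_id: str
    role: str
    condition: str
    rpeak_path: Path
    affect_path: Path | None = None


@dataclass
class CohortManifest:
    entries: list

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.role not in ROLES:
                raise FormatError(f"unknown role {e.role!r}")
            if e.condition not in CONDITIONS:
                raise FormatError(f"unknown condition {e.condition!r}")
            key = (e.dyad_id, e.role, e.condition)
            if key in seen:
                raise FormatError(f"duplicate manifest entry {key}")
            seen.add(key)
            if not Path(e.rpeak_path).exists():
                raise FormatError(f"missing file {e.rpeak_path}")
            if e.affect_path is not None and not Path(e.affect_path).exists():
                raise FormatError(f"missing file {e.affect_path}")

    @classmethod
    def load(cls, path) -> "CohortManifest":
        path = Path(path)
        df = pd.read_csv(path)
        needed = {"dyad_id", "role", "condition", "rpeak_path"}
        if not needed <= set(df.columns):
            raise FormatError(
                f"{path}: manifest needs columns {sorted(needed)}")
        entries = []
        for _, row in df.iterrows():
            affect = row.get("affect_path")
            affect_path = None
            if isinstance(affect, str) and affect.strip():
                affect_path = path.parent / affect
            entries.append(ManifestEntry(
                dyad_id=str(row["dyad_id"]), role=str(row["role"]),
                condition=str(row["condition"]),
                rpeak_path=path.parent / str(row["rpeak_path"]),
                affect_path=affect_path))
        return cls(entries)


def load_cohort(manifest: CohortManifest
                ) -> tuple[Cohort, list[tuple[str, str, str]]]:
    """Materialise a cohort from a manifest.

    Any (dyad, condition) whose files fail to load is excluded as a
    whole — never partially imputed — and returned in the exclusion
    list; remaining conditions of the same dyad are kept.
    """
    cohort = Cohort()
    failures: dict[tuple[str, str], str] = {}
    for e in manifest.entries:
        key = (e.dyad_id, e.condition)
        rec = cohort.records.get(key)
        if rec is None:
            rec = DyadRecord(dyad_id=e.dyad_id, condition=e.condition)
            cohort.records[key] = rec
        try:
            rp = read_rpeaks(e.rpeak_path)
            aff = None
            if e.affect_path is not None:
                aff = load_affect(e.affect_path, rp.duration_s, e.role)
        except Exception as exc:
            failures[key] = f"{e.role}: {exc}"
            log.error("excluding dyad %s condition %s (%s: %s)",
                      e.dyad_id, e.condition, e.role, exc)
            continue
        if e.role == "mother":
            rec.mother_rpeaks, rec.mother_affect = rp, aff
        else:
            rec.child_rpeaks, rec.child_affect = rp, aff
    excluded = []
    for key, reason in failures.items():
        rec = cohort.records.pop(key, None)
        excluded.append((key[0], key[1], reason))
    return cohort, excluded


def write_cohort(cohort: Cohort, out_dir, manifest_name: str = "manifest.csv"
                 ) -> Path:
    """Write every recording of a cohort plus its manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (dyad_id, condition), rec in sorted(cohort.records.items()):
        for role in ROLES:
            rp = rec.rpeaks(role)
            if rp is None:
                continue
            stem = f"{dyad_id}_{role}_{condition}"
            write_rpeaks(rp, out_dir / f"{stem}_rpeaks.csv")
            aff = rec.mother_affect if role == "mother" else rec.child_affect
            affect_name = ""
            if aff is not None:
                affect_name = f"{stem}_affect.csv"
                write_affect_annotations(aff, out_dir / affect_name)
            rows.append({"dyad_id": dyad_id, "role": role,
                         "condition": condition,
                         "rpeak_path": f"{stem}_rpeaks.csv",
                         "affect_path": affect_name})
    manifest_path = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Long-format table: one row per (dyad, condition, source, lag)."""
    rows = []
    for p in profiles:
        for lag, r, n in zip(p.lags, p.r, p.n_overlap):
            rows.append({"dyad_id": p.dyad_id, "condition": p.condition,
                         "source": p.source, "lag": int(lag),
                         "r": float(r), "n_overlap": int(n)})
    return pd.DataFrame(rows)
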
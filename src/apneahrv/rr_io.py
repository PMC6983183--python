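"""Readers and writers for beat-to-beat (RR) interval recordings and cohort manifests.

The native RR text format stores one recording per file:

* optional header lines ``# key=value`` (keys: ``subject``, ``sensor``,
  ``filtered``, ``columns``),
* one beat per line, either a single RR duration in milliseconds
  (``columns=rr``, onsets reconstructed by cumulative sum) or
  ``onset_s<TAB>rr_ms`` pairs (``columns=onset_rr``, used for filtered
  series whose onsets are no longer the cumulative sum of durations).

Cohort manifests are plain CSV with one row per subject carrying the
clinical variables (AHI, ODI, ESS, BMI, age, sex, apnea type) and optional
per-sensor RR file paths.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SENSORS = ("belt", "patch")
APNEA_TYPES = ("obstructive", "central", "mixed", "none")
SEXES = ("female", "male")

#: tolerance for the onset/duration consistency invariant, seconds
ONSET_TOL_S = 1e-6

MANIFEST_REQUIRED_COLUMNS = (
    "subject_id", "ahi", "odi", "ess", "bmi", "age", "sex", "apnea_type",
)
MANIFEST_PATH_COLUMNS = ("rr_belt", "rr_patch")


class RRParseError(ValueError):
    """Raised when an RR text file cannot be parsed."""


@dataclass
class RRSeries:
    """One night of beat-to-beat intervals from one sensor.

    ``onsets_s`` are beat times in seconds from recording start, strictly
    increasing; ``rr_ms[i]`` is the duration of the interval ending at
    ``onsets_s[i]``.  For an unfiltered series the onsets are exactly the
    cumulative sum of the durations (within :data:`ONSET_TOL_S`); a filtered
    series may contain timing gaps where beats were excluded.
    """

    subject_id: str
    sensor: str
    onsets_s: np.ndarray
    rr_ms: np.ndarray
    filtered: bool = False

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor {self.sensor!r}; expected one of {SENSORS}")
        if self.onsets_s.ndim != 1 or self.onsets_s.shape != self.rr_ms.shape:
            raise ValueError("onsets_s and rr_ms must be 1-d arrays of equal length")
        if self.n_beats == 0:
            return  # an empty series can result from aggressive filtering
        if not np.all(np.isfinite(self.rr_ms)) or np.any(self.rr_ms <= 0):
            raise ValueError("rr_ms must be finite and strictly positive")
        if not np.all(np.isfinite(self.onsets_s)):
            raise ValueError("onsets_s must be finite")
        if self.n_beats > 1 and not np.all(np.diff(self.onsets_s) > 0):
            raise ValueError("onsets_s must be strictly increasing")
        if not self.filtered and self.n_beats > 1:
            gap = np.diff(self.onsets_s) - self.rr_ms[1:] / 1000.0
            worst = float(np.max(np.abs(gap)))
            if worst > ONSET_TOL_S:
                raise ValueError(
                    f"onset/duration mismatch of {worst:.3e} s in unfiltered series"
                )

    @property
    def n_beats(self) -> int:
        return int(self.rr_ms.size)

    @property
    def span_s(self) -> float:
        """Elapsed time between the first and the last beat, seconds."""
        if self.n_beats < 2:
            return 0.0
        return float(self.onsets_s[-1] - self.onsets_s[0])

    def equals(self, other: "RRSeries") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.sensor == other.sensor
            and self.filtered == other.filtered
            and np.array_equal(self.onsets_s, other.onsets_s)
            and np.array_equal(self.rr_ms, other.rr_ms)
        )

    def with_sensor(self, sensor: str) -> "RRSeries":
        return replace(self, sensor=sensor)


@dataclass
class CohortManifest:
    """Clinical table for a cohort, one row per subject.

    Wraps a :class:`pandas.DataFrame` with the required columns
    ``subject_id, ahi, odi, ess, bmi, age, sex, apnea_type`` and optional
    ``rr_belt`` / ``rr_patch`` path columns.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing required column(s): {missing}")
        t = self.table
        if t["subject_id"].duplicated().any():
            dupes = t.loc[t["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject_id(s): {dupes}")
        for col, lo, hi in (("ahi", 0, None), ("odi", 0, None), ("ess", 0, 24)):
            v = t[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in column {col!r}")
            if np.any(v < lo) or (hi is not None and np.any(v > hi)):
                rng = f">= {lo}" if hi is None else f"in [{lo}, {hi}]"
                raise ValueError(f"column {col!r} must be {rng}")
        bad = set(t["apnea_type"]) - set(APNEA_TYPES)
        if bad:
            raise ValueError(f"unknown apnea_type value(s): {sorted(bad)}")
        bad = set(t["sex"]) - set(SEXES)
        if bad:
            raise ValueError(f"unknown sex value(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def response(self, name: str) -> np.ndarray:
        """Per-subject values of a clinical response variable (e.g. ``ahi``)."""
        return self.table[name].to_numpy(dtype=float)


def _parse_bool(text: str) -> bool:
    if text.lower() in ("true", "1", "yes"):
        return True
    if text.lower() in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def read_rr(path: str | Path, format: str = "auto", strict: bool = True) -> RRSeries:
    """Read an RR series from a text file.

    Parameters
    ----------
    path:
        File in the native RR text format.
    format:
        ``"durations"`` (one RR in ms per line), ``"onset_rr"``
        (two columns: onset seconds, RR ms) or ``"auto"`` to infer from the
        header / first data line.
    strict:
        If True (default), non-positive or non-finite intervals raise a
        :class:`RRParseError` naming the offending line; otherwise such rows
        are dropped and counted in the log.
    """
    path = Path(path)
    header: dict[str, str] = {}
    onsets: list[float] = []
    durations: list[float] = []
    n_rejected = 0
    inferred: str | None = None if format == "auto" else format
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    header[key.strip()] = val.strip()
                continue
            fields = line.split()
            if inferred is None:
                cols = header.get("columns")
                if cols == "rr":
                    inferred = "durations"
                elif cols == "onset_rr":
                    inferred = "onset_rr"
                else:
                    inferred = "onset_rr" if len(fields) == 2 else "durations"
            expected = 2 if inferred == "onset_rr" else 1
            if len(fields) != expected:
                raise RRParseError(
                    f"{path}:{lineno}: expected {expected} value(s), got {len(fields)}"
                )
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise RRParseError(f"{path}:{lineno}: {exc}") from None
            rr = values[-1]
            if not np.isfinite(rr) or rr <= 0:
                if strict:
                    raise RRParseError(
                        f"{path}:{lineno}: non-positive or non-finite RR interval {rr!r}"
                    )
                n_rejected += 1
                continue
            if inferred == "onset_rr":
                onsets.append(values[0])
            durations.append(rr)
    if not durations:
        raise RRParseError(f"{path}: no RR intervals found")
    if n_rejected:
        logger.info("read_rr(%s): rejected %d invalid row(s)", path, n_rejected)
    rr_ms = np.asarray(durations)
    if inferred == "onset_rr":
        onsets_arr = np.asarray(onsets)
    else:
        onsets_arr = np.cumsum(rr_ms) / 1000.0
    return RRSeries(
        subject_id=header.get("subject", path.stem),
        sensor=header.get("sensor", "patch"),
        onsets_s=onsets_arr,
        rr_ms=rr_ms,
        filtered=_parse_bool(header.get("filtered", "false")),
    )


def write_rr(series: RRSeries, path: str | Path) -> None:
    """Write a series in the native RR text format; round-trips bit-exactly.

    Unfiltered series whose onsets equal the cumulative sum of durations are
    written in the compact durations-only dialect; anything else is written
    with explicit ``onset_s  rr_ms`` columns.
    """
    path = Path(path)
    compact = series.n_beats > 0 and np.array_equal(
        series.onsets_s, np.cumsum(series.rr_ms) / 1000.0
    )
    lines = [
        f"# subject={series.subject_id}",
        f"# sensor={series.sensor}",
        f"# filtered={'true' if series.filtered else 'false'}",
        f"# columns={'rr' if compact else 'onset_rr'}",
    ]
    if compact:
        lines += [repr(float(v)) for v in series.rr_ms]
    else:
        lines += [
            f"{float(t)!r}\t{float(v)!r}"
            for t, v in zip(series.onsets_s, series.rr_ms)
        ]
    path.write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV; validates columns and clinical ranges."""
    table = pd.read_csv(path)
    return CohortManifest(table=table)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)


def read_rr_from_edf(path: str | Path, annotation_pattern: str = "beat",
                     subject_id: str | None = None, sensor: str = "patch") -> RRSeries:
    """Extract an RR series from the annotation channel of an EDF(+) file.

    Beat annotations whose description contains ``annotation_pattern``
    (case-insensitive) are taken as R-peak times; RR intervals are their
    successive differences.  Requires the optional ``mne`` dependency
    (``pip install apneahrv[edf]``).  Raw-waveform R-peak detection is out of
    scope: input begins at annotated beats.
    """
    try:
        import mne  # noqa: PLC0415 (optional heavy dependency)
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "EDF support requires the optional 'mne' package (apneahrv[edf])"
        ) from exc
    ann = mne.read_annotations(str(path))
    pat = annotation_pattern.lower()
    times = np.asarray(
        [on for on, desc in zip(ann.onset, ann.description) if pat in desc.lower()]
    )
    if times.size < 2:
        raise RRParseError(f"{path}: fewer than two {annotation_pattern!r} annotations")
    rr_ms = np.diff(times) * 1000.0
    return RRSeries(
        subject_id=subject_id or Path(path).stem,
        sensor=sensor,
        onsets_s=times[1:],
        rr_ms=rr_ms,
        filtered=False,
    )
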
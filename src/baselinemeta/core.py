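"""Domain types and I/O for trial-level baseline summary data.

A :class:`Corpus` holds the trials of one meta-analysis.  Each
:class:`TrialRecord` carries the two randomized arms' summaries of the
primary outcome *measured at baseline* (mean/SD, or median/IQR when that
is all the trial published), the randomized and analyzed headcounts, the
population the baseline summary describes, and the outcome orientation
(whether lower or higher raw values mean a healthier patient).  These are
exactly the fields a reviewer extracts by hand from trial reports, so the
CSV/JSON schema is deliberately flat and hand-editable: UTF-8, comma
separated, header mandatory, an empty cell meaning "not reported".

Unknown extra columns (extraction notes and the like) survive a
read/write round-trip untouched but are ignored by every computation.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import hashlib
import io
import json
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = [
    "ArmSummary",
    "BaselinePopulation",
    "Corpus",
    "Orientation",
    "ReportingCategory",
    "ReportingStatus",
    "SchemaError",
    "SummaryType",
    "TrialRecord",
    "ValidationError",
    "corpus_digest",
    "file_digest",
    "read_corpus",
    "write_corpus",
    "write_report",
]


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


class SummaryType(str, enum.Enum):
    MEAN_SD = "mean_sd"
    MEDIAN_IQR = "median_iqr"
    NONE = "none"


class Orientation(str, enum.Enum):
    """Which direction of the raw outcome scale means a better condition.

    Pain or symptom scores are ``lower_is_better``; function or activity
    scores are ``higher_is_better``.  The orientation fixes the sign
    convention of the baseline standardized mean difference: after
    direction coding, a negative value always means the intervention arm
    was better off at baseline.
    """

    LOWER_IS_BETTER = "lower_is_better"
    HIGHER_IS_BETTER = "higher_is_better"


class BaselinePopulation(str, enum.Enum):
    """Whose baseline values the trial reported."""

    RANDOMIZED = "randomized"
    ANALYZED_ONLY = "analyzed_only"
    UNKNOWN = "unknown"


class ReportingCategory(str, enum.Enum):
    REPORTED_RANDOMIZED = "reported_randomized"
    REPORTED_ANALYZED_HIGH_DROPOUT = "reported_analyzed_high_dropout"
    REPORTED_MEDIAN_EXCLUDED = "reported_median_excluded"
    NOT_REPORTED = "not_reported"


@dataclass(frozen=True)
class ReportingStatus:
    """Outcome of the reporting-status triage for one trial."""

    status: ReportingCategory
    dropout_rate: float | None = None


@dataclass(frozen=True)
class ArmSummary:
    """Baseline summary statistics for one randomized arm."""

    n_randomized: int
    n_analyzed: int | None = None
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    iqr_low: float | None = None
    iqr_high: float | None = None
    summary_type: SummaryType = SummaryType.NONE

    def __post_init__(self) -> None:
        if self.n_randomized < 1:
            raise ValidationError(f"n_randomized must be >= 1, got {self.n_randomized}")
        if self.n_analyzed is not None and not (0 <= self.n_analyzed <= self.n_randomized):
            raise ValidationError(
                f"n_analyzed ({self.n_analyzed}) must lie in [0, n_randomized={self.n_randomized}]"
            )
        if self.summary_type is SummaryType.MEAN_SD:
            if self.mean is None or self.sd is None:
                raise ValidationError("summary_type=mean_sd requires both mean and sd")
            if not self.sd > 0:
                raise ValidationError(f"sd must be > 0, got {self.sd}")
            if self.n_randomized < 2:
                raise ValidationError("summary_type=mean_sd requires n_randomized >= 2")
        elif self.summary_type is SummaryType.MEDIAN_IQR:
            if self.median is None or self.iqr_low is None or self.iqr_high is None:
                raise ValidationError("summary_type=median_iqr requires median, iqr_low, iqr_high")
            if not (self.iqr_low <= self.median <= self.iqr_high):
                raise ValidationError(
                    f"IQR must bracket the median: {self.iqr_low} <= {self.median} <= {self.iqr_high}"
                )


@dataclass(frozen=True)
class TrialRecord:
    """One randomized trial's baseline data within a meta-analysis."""

    trial_id: str
    meta_id: str
    treatment: ArmSummary
    control: ArmSummary
    baseline_population: BaselinePopulation = BaselinePopulation.UNKNOWN
    orientation: Orientation | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_mean_sd = SummaryType.MEAN_SD in (
            self.treatment.summary_type,
            self.control.summary_type,
        )
        if has_mean_sd and self.orientation is None:
            raise ValidationError(
                f"trial {self.trial_id!r}: orientation is mandatory when an arm reports mean/sd"
            )


@dataclass(frozen=True)
class Corpus:
    """All trials of one meta-analysis, in extraction order."""

    meta_id: str
    trials: tuple[TrialRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValidationError(f"corpus {self.meta_id!r} is empty")
        seen: set[str] = set()
        for t in self.trials:
            if t.meta_id != self.meta_id:
                raise ValidationError(
                    f"trial {t.trial_id!r} has meta_id {t.meta_id!r}, expected {self.meta_id!r}"
                )
            if t.trial_id in seen:
                raise ValidationError(
                    f"duplicate trial_id {t.trial_id!r} within meta_id {self.meta_id!r}"
                )
            seen.add(t.trial_id)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


# ---------------------------------------------------------------------------
# Tabular schema

_ARM_FIELDS = ("n_rand", "n_anal", "mean", "sd", "median", "iqr_low", "iqr_high", "summary_type")
_META_COLUMNS = ("meta_id", "trial_id", "orientation", "baseline_population")
SCHEMA_COLUMNS: tuple[str, ...] = _META_COLUMNS + tuple(
    f"{f}_{arm}" for arm in ("t", "c") for f in _ARM_FIELDS
)

_COUNT_FIELDS = {"n_rand", "n_anal"}
_REAL_FIELDS = {"mean", "sd", "median", "iqr_low", "iqr_high"}


def _parse_count(value: str, column: str, trial_id: str) -> int | None:
    if value == "":
        return None
    try:
        x = float(value)
    except ValueError as exc:
        raise ValidationError(f"trial {trial_id!r}: column {column!r} is not a number: {value!r}") from exc
    if x != int(x):
        raise ValidationError(f"trial {trial_id!r}: column {column!r} must be an integer, got {value!r}")
    return int(x)


def _parse_real(value: str, column: str, trial_id: str) -> float | None:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(f"trial {trial_id!r}: column {column!r} is not a number: {value!r}") from exc


def _parse_enum(enum_cls, value: str, column: str, trial_id: str):
    try:
        return enum_cls(value)
    except ValueError as exc:
        valid = ", ".join(m.value for m in enum_cls)
        raise ValidationError(
            f"trial {trial_id!r}: column {column!r} has invalid value {value!r} (expected one of: {valid})"
        ) from exc


def _arm_from_row(row: Mapping[str, str], arm: str, trial_id: str) -> ArmSummary:
    vals: dict[str, Any] = {}
    for f in _ARM_FIELDS[:-1]:
        col = f"{f}_{arm}"
        raw = row[col]
        if f in _COUNT_FIELDS:
            vals[f] = _parse_count(raw, col, trial_id)
        else:
            vals[f] = _parse_real(raw, col, trial_id)
    st_raw = row[f"summary_type_{arm}"]
    if st_raw == "":
        # infer from which summaries are present
        if vals["mean"] is not None and vals["sd"] is not None:
            st = SummaryType.MEAN_SD
        elif vals["median"] is not None:
            st = SummaryType.MEDIAN_IQR
        else:
            st = SummaryType.NONE
    else:
        st = _parse_enum(SummaryType, st_raw, f"summary_type_{arm}", trial_id)
    if vals["n_rand"] is None:
        raise ValidationError(f"trial {trial_id!r}: column 'n_rand_{arm}' is mandatory")
    return ArmSummary(
        n_randomized=vals["n_rand"],
        n_analyzed=vals["n_anal"],
        mean=vals["mean"],
        sd=vals["sd"],
        median=vals["median"],
        iqr_low=vals["iqr_low"],
        iqr_high=vals["iqr_high"],
        summary_type=st,
    )


def _trial_from_row(row: Mapping[str, str], extra_cols: Sequence[str]) -> TrialRecord:
    trial_id = row["trial_id"]
    meta_id = row["meta_id"]
    if trial_id == "" or meta_id == "":
        raise ValidationError(f"row with empty meta_id/trial_id: {dict(row)!r}")
    try:
        treatment = _arm_from_row(row, "t", trial_id)
        control = _arm_from_row(row, "c", trial_id)
        orientation = (
            _parse_enum(Orientation, row["orientation"], "orientation", trial_id)
            if row["orientation"] != ""
            else None
        )
        population = (
            _parse_enum(BaselinePopulation, row["baseline_population"], "baseline_population", trial_id)
            if row["baseline_population"] != ""
            else BaselinePopulation.UNKNOWN
        )
        return TrialRecord(
            trial_id=trial_id,
            meta_id=meta_id,
            treatment=treatment,
            control=control,
            baseline_population=population,
            orientation=orientation,
            extra={c: row[c] for c in extra_cols},
        )
    except ValidationError as exc:
        if trial_id not in str(exc):
            raise ValidationError(f"trial {trial_id!r}: {exc}") from exc
        raise


def _trial_to_row(trial: TrialRecord) -> dict[str, str]:
    def fmt(x: Any) -> str:
        if x is None:
            return ""
        if isinstance(x, float):
            return repr(x)
        return str(x)

    row = {
        "meta_id": trial.meta_id,
        "trial_id": trial.trial_id,
        "orientation": trial.orientation.value if trial.orientation else "",
        "baseline_population": trial.baseline_population.value,
    }
    for arm_key, arm in (("t", trial.treatment), ("c", trial.control)):
        row[f"n_rand_{arm_key}"] = fmt(arm.n_randomized)
        row[f"n_anal_{arm_key}"] = fmt(arm.n_analyzed)
        row[f"mean_{arm_key}"] = fmt(arm.mean)
        row[f"sd_{arm_key}"] = fmt(arm.sd)
        row[f"median_{arm_key}"] = fmt(arm.median)
        row[f"iqr_low_{arm_key}"] = fmt(arm.iqr_low)
        row[f"iqr_high_{arm_key}"] = fmt(arm.iqr_high)
        row[f"summary_type_{arm_key}"] = arm.summary_type.value
    row.update({k: str(v) for k, v in trial.extra.items()})
    return row


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_corpus(path: str | Path, format: str | None = None) -> list[Corpus]:
    """Read trial records from CSV or JSON and group them into corpora.

    Returns one :class:`Corpus` per distinct ``meta_id``, preserving row
    order.  Every domain invariant is validated; a violating row raises
    :class:`ValidationError` naming the trial, a missing mandatory column
    raises :class:`SchemaError` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        rows = frame.to_dict(orient="records")
        columns = list(frame.columns)
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError("JSON input must be an array of row objects")
        rows = [{k: ("" if v is None else str(v)) for k, v in obj.items()} for obj in data]
        columns = sorted({c for r in rows for c in r}) if rows else []
        rows = [{c: r.get(c, "") for c in columns} for r in rows]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    missing = [c for c in SCHEMA_COLUMNS if c not in columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    extra_cols = [c for c in columns if c not in SCHEMA_COLUMNS]

    grouped: dict[str, list[TrialRecord]] = {}
    for row in rows:
        trial = _trial_from_row(row, extra_cols)
        grouped.setdefault(trial.meta_id, []).append(trial)
    return [Corpus(meta_id=mid, trials=tuple(trials)) for mid, trials in grouped.items()]


def write_corpus(corpora: Iterable[Corpus], path: str | Path, format: str | None = None) -> None:
    """Write corpora back to the flat CSV/JSON schema (round-trip safe)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    corpora = list(corpora)
    rows = [_trial_to_row(t) for c in corpora for t in c.trials]
    extra_cols = sorted({k for r in rows for k in r if k not in SCHEMA_COLUMNS})
    columns = list(SCHEMA_COLUMNS) + extra_cols
    if fmt == "csv":
        frame = pd.DataFrame(rows, columns=columns).fillna("")
        frame.to_csv(path, index=False, encoding="utf-8")
    elif fmt == "json":
        payload = [{c: r.get(c, "") for c in columns} for r in rows]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Report serialization


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def corpus_digest(corpus: Corpus) -> str:
    """SHA-256 digest of a corpus's canonical CSV serialization."""
    buf = io.StringIO()
    rows = [_trial_to_row(t) for t in corpus.trials]
    extra_cols = sorted({k for r in rows for k in r if k not in SCHEMA_COLUMNS})
    cols = list(SCHEMA_COLUMNS) + extra_cols
    buf.write(",".join(cols) + "\n")
    for r in rows:
        buf.write(",".join(r.get(c, "") for c in cols) + "\n")
    return hashlib.sha256(buf.getvalue().encode("utf-8")).hexdigest()


def _jsonify(obj: Any) -> Any:
    """Convert dataclasses/enums/numpy scalars to plain JSON-safe values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonify(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):  # numpy scalar
        return obj.item()
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return None
    return obj


def write_report(report: Mapping[str, Any], path: str | Path, timestamp: str | None = None) -> None:
    """Serialize an analysis report to JSON at full float precision.

    The file is byte-deterministic for a given report apart from the
    ``provenance.timestamp`` field (pass ``timestamp`` to pin it).
    """
    payload = _jsonify(dict(report))
    prov = dict(payload.get("provenance") or {})
    prov["timestamp"] = timestamp or datetime.datetime.now(datetime.timezone.utc).isoformat()
    payload["provenance"] = prov
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
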
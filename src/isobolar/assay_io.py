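"""File formats and report serialisation.

CSV schemas for plate-assay wells and caliper tumor measurements, plus a
versioned JSON report.  Readers are strict: every malformed input raises a
diagnosable error naming the offending column or row; no partial datasets
are ever returned.  No science lives here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

PLATE_COLUMNS = [
    "plate_id",
    "condition_id",
    "agent1",
    "dose1",
    "agent2",
    "dose2",
    "dose_units",
    "absorbance",
    "replicate",
    "is_control",
]

TUMOR_COLUMNS = ["animal_id", "group", "day", "length_mm", "width_mm"]


class SchemaError(ValueError):
    """A file does not conform to the documented CSV schema."""


class RowValidationError(ValueError):
    """A row violates a record invariant; the message cites the row."""


@dataclass(frozen=True)
class WellRecord:
    """One well of a viability plate: agent doses plus raw OD450 absorbance.

    ``is_control`` must hold exactly when both doses are zero; absorbance
    must be finite and strictly positive (raw optical density).
    """

    plate_id: str
    condition_id: str
    agent1: str
    dose1: float
    agent2: str
    dose2: float
    absorbance: float
    replicate: int
    is_control: bool
    dose_units: str = "uM"

    def __post_init__(self) -> None:
        for name, dose in (("dose1", self.dose1), ("dose2", self.dose2)):
            if not math.isfinite(dose) or dose < 0:
                raise RowValidationError(
                    f"{name} must be finite and >= 0, got {dose!r}"
                )
        if not math.isfinite(self.absorbance) or self.absorbance <= 0:
            raise RowValidationError(
                f"absorbance must be finite and > 0, got {self.absorbance!r}"
            )
        if int(self.replicate) < 1:
            raise RowValidationError(
                f"replicate must be >= 1, got {self.replicate!r}"
            )
        both_zero = self.dose1 == 0 and self.dose2 == 0
        if self.is_control != both_zero:
            raise RowValidationError(
                "is_control must hold exactly when dose1 == dose2 == 0 "
                f"(is_control={self.is_control}, dose1={self.dose1}, "
                f"dose2={self.dose2})"
            )


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement of one animal on one day (mm).

    By convention length >= width; violating inputs are swapped with a
    logged warning rather than rejected, since the two calipers are
    interchangeable in the volume formula's sense.
    """

    animal_id: str
    group: str
    day: int
    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if int(self.day) < 0:
            raise RowValidationError(f"day must be >= 0, got {self.day!r}")
        for name, v in (("length_mm", self.length_mm), ("width_mm", self.width_mm)):
            if not math.isfinite(v) or v <= 0:
                raise RowValidationError(
                    f"{name} must be finite and > 0, got {v!r}"
                )
        if self.width_mm > self.length_mm:
            logger.warning(
                "animal %s day %s: width %.3f > length %.3f; swapping by "
                "convention",
                self.animal_id,
                self.day,
                self.width_mm,
                self.length_mm,
            )
            length, width = float(self.width_mm), float(self.length_mm)
            object.__setattr__(self, "length_mm", length)
            object.__setattr__(self, "width_mm", width)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def read_plate_csv(path: str | Path) -> list[WellRecord]:
    """Read a plate-assay CSV into validated :class:`WellRecord` objects.

    Row numbers (1-based, excluding the header) are cited in validation
    errors.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PLATE_COLUMNS, path)
    records: list[WellRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                WellRecord(
                    plate_id=str(row.plate_id),
                    condition_id=str(row.condition_id),
                    agent1="" if pd.isna(row.agent1) else str(row.agent1),
                    dose1=float(row.dose1),
                    agent2="" if pd.isna(row.agent2) else str(row.agent2),
                    dose2=float(row.dose2),
                    absorbance=float(row.absorbance),
                    replicate=int(row.replicate),
                    is_control=_parse_bool(row.is_control),
                    dose_units=str(row.dose_units),
                )
            )
        except (RowValidationError, ValueError, TypeError) as exc:
            raise RowValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def _parse_bool(value: Any) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def write_plate_csv(records: Iterable[WellRecord], path: str | Path) -> None:
    """Write :class:`WellRecord` objects to CSV with the documented header."""
    rows = [
        {
            "plate_id": r.plate_id,
            "condition_id": r.condition_id,
            "agent1": r.agent1,
            "dose1": repr(r.dose1),
            "agent2": r.agent2,
            "dose2": repr(r.dose2),
            "dose_units": r.dose_units,
            "absorbance": repr(r.absorbance),
            "replicate": r.replicate,
            "is_control": r.is_control,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_tumor_csv(path: str | Path) -> list[TumorMeasurement]:
    """Read caliper measurements; width > length rows are swapped with a
    logged warning (see :class:`TumorMeasurement`)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TUMOR_COLUMNS, path)
    out: list[TumorMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            length, width = float(row.length_mm), float(row.width_mm)
            if width > length:
                logger.warning(
                    "%s: row %d: width %.3f > length %.3f; swapped by "
                    "convention",
                    path,
                    i,
                    width,
                    length,
                )
                length, width = width, length
            out.append(
                TumorMeasurement(
                    animal_id=str(row.animal_id),
                    group=str(row.group),
                    day=int(row.day),
                    length_mm=length,
                    width_mm=width,
                )
            )
        except (RowValidationError, ValueError, TypeError) as exc:
            raise RowValidationError(f"{path}: row {i}: {exc}") from exc
    return out


def write_tumor_csv(measurements: Iterable[TumorMeasurement], path: str | Path) -> None:
    rows = [
        {
            "animal_id": m.animal_id,
            "group": m.group,
            "day": m.day,
            "length_mm": repr(m.length_mm),
            "width_mm": repr(m.width_mm),
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=TUMOR_COLUMNS).to_csv(path, index=False)


def _jsonify(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays and NaN to JSON-safe values."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(results: dict[str, Any], path: str | Path) -> None:
    """Write a versioned, machine-readable JSON report.

    ``results`` is a mapping of named analysis products (estimates with
    CIs, test statistics with p-values, verdicts); non-finite floats are
    serialised as null.
    """
    doc = {"schema_version": REPORT_SCHEMA_VERSION, "results": _jsonify(results)}
    Path(path).write_text(json.dumps(doc, indent=2, allow_nan=False) + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    """Read a report written by :func:`write_report`; returns the results
    mapping and checks the schema version."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != REPORT_SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported report schema version {version!r}; "
            f"expected {REPORT_SCHEMA_VERSION!r}"
        )
    return doc["results"]
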
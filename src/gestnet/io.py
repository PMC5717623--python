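"""CSV readers and writers for scans, gestures, individuals, kin pairs and
dyadic matrices.

All files are UTF-8 CSV with a header row. The numeric code 999 in any
numeric column denotes a missing value (never data); id-set columns are
semicolon-joined; empty cells in optional string columns mean missing.
Matrix files are labelled square CSVs: first row and first column hold the
node ids and the diagonal is left blank.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .network import DyadMatrix
from .types import (
    MISSING_CODE,
    GestureEvent,
    Individual,
    ScanRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

ID_SET_SEP = ";"

SCAN_COLUMNS = [
    "follow_id",
    "focal_id",
    "scan_index",
    "within_10m_ids",
    "party_ids",
    "nn_id",
    "nn_distance_m",
    "attention_present",
    "focal_activity",
    "nn_activity",
]

GESTURE_COLUMNS = [
    "event_id",
    "sequence_id",
    "follow_id",
    "time_s",
    "signaller_id",
    "recipient_id",
    "gesture_type",
    "modality",
    "context",
    "panthoot",
    "response_present",
    "response_type",
    "vocal_response",
    "audience_10m_ids",
]

INDIVIDUAL_COLUMNS = [
    "id",
    "sex",
    "birth_year",
    "reproductive_status",
    "pantgrunt_indegree",
    "pantgrunt_outdegree",
]


def _parse_float(raw: str, row: int, column: str) -> Optional[float]:
    """Parse a numeric cell, mapping the 999 sentinel and blanks to missing."""
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise ValidationError(
            f"row {row}, column {column!r}: cannot parse {raw!r} as a number"
        ) from exc
    if value == MISSING_CODE:
        return None
    return value


def _parse_flag(raw: str, row: int, column: str) -> Optional[bool]:
    raw = raw.strip()
    if raw == "" or raw == str(MISSING_CODE):
        return None
    if raw in ("0", "1"):
        return raw == "1"
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    raise ValidationError(
        f"row {row}, column {column!r}: cannot parse {raw!r} as a 0/1 flag"
    )


def _parse_id_set(raw: str) -> FrozenSet[str]:
    raw = raw.strip()
    if not raw:
        return frozenset()
    return frozenset(part for part in raw.split(ID_SET_SEP) if part)


def _fmt_id_set(ids: FrozenSet[str]) -> str:
    return ID_SET_SEP.join(sorted(ids))


def _fmt_flag(value: Optional[bool]) -> str:
    if value is None:
        return str(MISSING_CODE)
    return "1" if value else "0"


def _fmt_num(value: Optional[float]) -> str:
    if value is None:
        return str(MISSING_CODE)
    return repr(value) if value != int(value) else str(int(value))


def _check_header(header: Sequence[str], expected: Sequence[str], path: Path) -> None:
    missing = [c for c in expected if c not in header]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_scans(
    path: str | Path,
    known_ids: Optional[Set[str]] = None,
    max_scan_index: int = 9,
) -> List[ScanRecord]:
    """Read scan records, validating invariants row by row.

    ``known_ids`` (when given) restricts every id field to the population;
    an unknown id raises a :class:`ValidationError` naming the row.
    """
    path = Path(path)
    records: List[ScanRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or [], SCAN_COLUMNS, path)
        for rownum, row in enumerate(reader, start=2):
            try:
                scan_index_f = _parse_float(row["scan_index"], rownum, "scan_index")
                if scan_index_f is None:
                    raise ValidationError(
                        f"row {rownum}, column 'scan_index': missing"
                    )
                scan_index = int(scan_index_f)
                if not 1 <= scan_index <= max_scan_index:
                    raise ValidationError(
                        f"row {rownum}, column 'scan_index': {scan_index} "
                        f"outside [1, {max_scan_index}]"
                    )
                nn_id = row["nn_id"].strip() or None
                if nn_id == str(MISSING_CODE):
                    nn_id = None
                record = ScanRecord(
                    follow_id=row["follow_id"].strip(),
                    focal_id=row["focal_id"].strip(),
                    scan_index=scan_index,
                    within_10m_ids=_parse_id_set(row["within_10m_ids"]),
                    party_ids=_parse_id_set(row["party_ids"]),
                    nn_id=nn_id,
                    nn_distance_m=_parse_float(
                        row["nn_distance_m"], rownum, "nn_distance_m"
                    ),
                    attention_present=_parse_flag(
                        row["attention_present"], rownum, "attention_present"
                    ),
                    focal_activity=row["focal_activity"].strip() or None,
                    nn_activity=row["nn_activity"].strip() or None,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: {exc}") from None
            if known_ids is not None:
                ids_used = (
                    {record.focal_id}
                    | record.party_ids
                    | ({record.nn_id} if record.nn_id else set())
                )
                unknown = ids_used - known_ids
                if unknown:
                    raise ValidationError(
                        f"{path}: row {rownum}: unknown id(s) {sorted(unknown)}"
                    )
            records.append(record)
    return records


def write_scans(records: Iterable[ScanRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCAN_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.follow_id,
                    r.focal_id,
                    r.scan_index,
                    _fmt_id_set(r.within_10m_ids),
                    _fmt_id_set(r.party_ids),
                    r.nn_id or "",
                    _fmt_num(r.nn_distance_m),
                    _fmt_flag(r.attention_present),
                    r.focal_activity or "",
                    r.nn_activity or "",
                ]
            )


def read_gestures(
    path: str | Path, known_ids: Optional[Set[str]] = None
) -> List[GestureEvent]:
    """Read gesture events; the ``context`` column is optional."""
    path = Path(path)
    required = [c for c in GESTURE_COLUMNS if c not in ("context", "sequence_id")]
    events: List[GestureEvent] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or [], required, path)
        has_context = "context" in (reader.fieldnames or [])
        if not has_context:
            logger.info("%s: no 'context' column; sequence grouping will ignore context", path)
        for rownum, row in enumerate(reader, start=2):
            try:
                time_s = _parse_float(row["time_s"], rownum, "time_s")
                if time_s is None:
                    raise ValidationError(f"row {rownum}, column 'time_s': missing")
                response_present = _parse_flag(
                    row["response_present"], rownum, "response_present"
                )
                event = GestureEvent(
                    event_id=row["event_id"].strip(),
                    sequence_id=(row.get("sequence_id") or "").strip() or None,
                    follow_id=row["follow_id"].strip(),
                    time_s=time_s,
                    signaller_id=row["signaller_id"].strip(),
                    recipient_id=row["recipient_id"].strip(),
                    gesture_type=row["gesture_type"].strip(),
                    modality=row["modality"].strip(),
                    context=(row.get("context") or "").strip() or None,
                    panthoot=bool(_parse_flag(row["panthoot"], rownum, "panthoot")),
                    response_present=bool(response_present),
                    response_type=row["response_type"].strip() or "none",
                    vocal_response=bool(
                        _parse_flag(row["vocal_response"], rownum, "vocal_response")
                    ),
                    audience_10m_ids=_parse_id_set(row["audience_10m_ids"]),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: {exc}") from None
            if known_ids is not None:
                ids_used = (
                    {event.signaller_id, event.recipient_id} | event.audience_10m_ids
                )
                unknown = ids_used - known_ids
                if unknown:
                    raise ValidationError(
                        f"{path}: row {rownum}: unknown id(s) {sorted(unknown)}"
                    )
            events.append(event)
    return events


def write_gestures(events: Iterable[GestureEvent], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(GESTURE_COLUMNS)
        for e in events:
            writer.writerow(
                [
                    e.event_id,
                    e.sequence_id or "",
                    e.follow_id,
                    _fmt_num(e.time_s),
                    e.signaller_id,
                    e.recipient_id,
                    e.gesture_type,
                    e.modality,
                    e.context or "",
                    _fmt_flag(e.panthoot),
                    _fmt_flag(e.response_present),
                    e.response_type,
                    _fmt_flag(e.vocal_response),
                    _fmt_id_set(e.audience_10m_ids),
                ]
            )


def read_individuals(path: str | Path) -> List[Individual]:
    path = Path(path)
    individuals: List[Individual] = []
    seen: Set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or [], INDIVIDUAL_COLUMNS, path)
        for rownum, row in enumerate(reader, start=2):
            try:
                ind = Individual(
                    id=row["id"].strip(),
                    sex=row["sex"].strip(),
                    birth_year=_parse_float(row["birth_year"], rownum, "birth_year"),
                    reproductive_status=row["reproductive_status"].strip()
                    or "not_applicable",
                    pantgrunt_indegree=_parse_float(
                        row["pantgrunt_indegree"], rownum, "pantgrunt_indegree"
                    )
                    or 0.0,
                    pantgrunt_outdegree=_parse_float(
                        row["pantgrunt_outdegree"], rownum, "pantgrunt_outdegree"
                    )
                    or 0.0,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: {exc}") from None
            if ind.id in seen:
                raise ValidationError(f"{path}: row {rownum}: duplicate id {ind.id}")
            seen.add(ind.id)
            individuals.append(ind)
    return individuals


def write_individuals(individuals: Iterable[Individual], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(INDIVIDUAL_COLUMNS)
        for ind in individuals:
            writer.writerow(
                [
                    ind.id,
                    ind.sex,
                    _fmt_num(ind.birth_year),
                    ind.reproductive_status,
                    _fmt_num(ind.pantgrunt_indegree),
                    _fmt_num(ind.pantgrunt_outdegree),
                ]
            )


def read_kin_pairs(path: str | Path) -> Set[FrozenSet[str]]:
    """Read unordered maternal-kin pairs from a two-column CSV."""
    path = Path(path)
    pairs: Set[FrozenSet[str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or [], ["id_a", "id_b"], path)
        for rownum, row in enumerate(reader, start=2):
            a, b = row["id_a"].strip(), row["id_b"].strip()
            if not a or not b or a == b:
                raise ValidationError(f"{path}: row {rownum}: invalid kin pair")
            pairs.add(frozenset((a, b)))
    return pairs


def write_kin_pairs(pairs: Iterable[FrozenSet[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_a", "id_b"])
        for pair in sorted(tuple(sorted(p)) for p in pairs):
            writer.writerow(pair)


def read_matrix(path: str | Path, directed: bool = True) -> DyadMatrix:
    """Read a labelled square matrix CSV (blank diagonal and missing cells)."""
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise ValidationError(f"{path}: row and column labels differ")
    return DyadMatrix(tuple(frame.index), frame.to_numpy(dtype=float), directed=directed)


def write_matrix(matrix: DyadMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.to_csv(Path(path), na_rep="")
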
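"""Delimited-text I/O for result streams and event logs.

CSV with ISO-8601 timestamps is the canonical interchange format; writing
then reading any valid table is the identity.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .core import FLAGS, QCEvent, ResultPoint, check_time_order

RESULT_COLUMNS = ["timestamp", "center_id", "analyte", "value",
                  "flags", "stream", "qc_level"]
EVENT_COLUMNS = ["kind", "classification", "analyte", "center_id",
                 "t_trigger", "t_confirmed", "confirmed_by", "action", "note"]

#: Tokens accepted in the flags column without an explicit flag_map.
DEFAULT_FLAG_MAP = {f: f for f in FLAGS}
DEFAULT_FLAG_MAP.update({"": None, "none": None})


class SchemaError(ValueError):
    """A required column is missing or a token cannot be mapped."""


def _parse_flags(token, flag_map: dict, line_no: int) -> frozenset:
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return frozenset()
    out = set()
    for part in str(token).split(";"):
        part = part.strip()
        if part.lower() in ("", "none", "nan"):
            continue
        mapped = flag_map.get(part, flag_map.get(part.lower(), "__missing__"))
        if mapped == "__missing__":
            raise SchemaError(f"line {line_no}: unknown flag token {part!r}")
        if mapped is not None:
            out.add(mapped)
    return frozenset(out)


def read_results(path, schema: Optional[dict] = None,
                 enforce_order: bool = True) -> list:
    """Read a result-stream CSV into ``ResultPoint`` rows in file order.

    Parameters
    ----------
    path : path-like
    schema : dict, optional
        ``{"columns": {canonical: actual}, "flag_map": {token: flag|None}}``.
        Unknown flag tokens are rejected with the offending line number.
    enforce_order : bool
        Reject timestamp regressions within one (center, analyte, stream).
    """
    schema = schema or {}
    colmap = {c: schema.get("columns", {}).get(c, c) for c in RESULT_COLUMNS}
    flag_map = dict(DEFAULT_FLAG_MAP)
    flag_map.update(schema.get("flag_map", {}))

    df = pd.read_csv(path, dtype={colmap["flags"]: str,
                                  colmap["qc_level"]: str})
    required = ["timestamp", "center_id", "analyte", "value"]
    for canon in required:
        if colmap[canon] not in df.columns:
            raise SchemaError(f"missing required column {colmap[canon]!r}")

    points = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        line_no = i + 2  # header is line 1
        try:
            ts = pd.Timestamp(row[colmap["timestamp"]]).to_pydatetime()
            value = float(row[colmap["value"]])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {line_no}: unparseable row: {exc}") from exc
        flags = _parse_flags(row.get(colmap["flags"]), flag_map, line_no)
        stream = row.get(colmap["stream"], "patient")
        if stream is None or pd.isna(stream):
            stream = "patient"
        qc_level = row.get(colmap["qc_level"])
        if qc_level is not None and pd.isna(qc_level):
            qc_level = None
        points.append(ResultPoint(
            timestamp=ts,
            center_id=str(row[colmap["center_id"]]),
            analyte=str(row[colmap["analyte"]]),
            value=value,
            flags=flags,
            stream=str(stream),
            qc_level=qc_level,
        ))
    if enforce_order:
        check_time_order(points)
    return points


def write_results(points: Sequence[ResultPoint], path) -> None:
    """Write a result stream as CSV (round-trips through read_results)."""
    rows = [{
        "timestamp": p.timestamp.isoformat(),
        "center_id": p.center_id,
        "analyte": p.analyte,
        "value": repr(p.value),
        "flags": ";".join(sorted(p.flags)),
        "stream": p.stream,
        "qc_level": p.qc_level if p.qc_level is not None else "",
    } for p in points]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def write_events(events: Sequence[QCEvent], path) -> None:
    """Write an event log as CSV with stable column order.

    Dual-classified events keep both labels in one row, joined by ``|``.
    """
    rows = [{
        "kind": e.kind,
        "classification": "|".join(e.classification),
        "analyte": e.analyte,
        "center_id": e.center_id,
        "t_trigger": e.t_trigger.isoformat(),
        "t_confirmed": e.t_confirmed.isoformat() if e.t_confirmed else "",
        "confirmed_by": e.confirmed_by or "",
        "action": e.action,
        "note": e.note,
    } for e in events]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> list:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing event columns: {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        events.append(QCEvent(
            kind=row["kind"],
            classification=tuple(row["classification"].split("|")),
            analyte=row["analyte"],
            center_id=row["center_id"],
            t_trigger=pd.Timestamp(row["t_trigger"]).to_pydatetime(),
            t_confirmed=(pd.Timestamp(row["t_confirmed"]).to_pydatetime()
                         if row["t_confirmed"] else None),
            confirmed_by=row["confirmed_by"] or None,
            action=row["action"] or "none",
            note=row["note"],
        ))
    return events
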
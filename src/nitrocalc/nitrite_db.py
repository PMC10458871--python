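"""Excipient nitrite-statistics database: load, validate, query, write.

The database maps an excipient name (optionally qualified by a supplier
label) to its min/mean/max nitrite level in ppm w/w. A bare excipient name
refers to the aggregate record across suppliers; supplier change is then
modeled by querying the min or max statistic of the aggregate.

File formats: CSV with columns ``excipient,supplier,min_ppm,mean_ppm,
max_ppm,n,source`` (supplier/n/source optional) and a YAML mirror. An
import helper reads a nitrite sheet from a calculation-toolkit XLSX
workbook, tolerating header variations and failing informatively on a
layout it cannot recognize.
"""

from __future__ import annotations

import csv
import difflib
import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import yaml

from .errors import NitriteLookupError, SchemaError
from .model import STATISTICS, NitriteStats, normalize_key

RecordKey = tuple[str, str | None]  # (normalized excipient, normalized supplier)

_REQUIRED_COLUMNS = ("excipient", "min_ppm", "mean_ppm", "max_ppm")
_OPTIONAL_COLUMNS = ("supplier", "n", "source")


@dataclass
class NitriteDatabase:
    """Validated collection of :class:`NitriteStats` records."""

    records: dict[RecordKey, NitriteStats] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def add(self, stats: NitriteStats, supplier: str | None = None) -> None:
        key = (normalize_key(stats.excipient), normalize_key(supplier) if supplier else None)
        if key in self.records:
            raise SchemaError(
                f"duplicate nitrite record for excipient {stats.excipient!r}"
                + (f" supplier {supplier!r}" if supplier else "")
            )
        self.records[key] = stats

    def get(self, excipient: str, supplier: str | None = None) -> NitriteStats:
        key = (normalize_key(excipient), normalize_key(supplier) if supplier else None)
        try:
            return self.records[key]
        except KeyError:
            names = sorted({k[0] for k in self.records})
            near = difflib.get_close_matches(key[0], names, n=3, cutoff=0.5)
            hint = f"; nearest matches: {near}" if near else f"; known: {names}"
            raise NitriteLookupError(
                f"no nitrite record for excipient {excipient!r}"
                + (f" supplier {supplier!r}" if supplier else "")
                + hint
            ) from None

    def __contains__(self, excipient: str) -> bool:
        return (normalize_key(excipient), None) in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NitriteStats]:
        return iter(self.records.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NitriteDatabase):
            return NotImplemented
        return self.records == other.records


def select_nitrite(
    db: NitriteDatabase,
    excipient: str,
    statistic: str = "mean",
    supplier: str | None = None,
) -> float:
    """Nitrite level (ppm w/w) of an excipient under one supplier scenario:
    ``min`` best case, ``mean`` average case, ``max`` worst case."""
    return db.get(excipient, supplier).statistic(statistic)


# --------------------------------------------------------------------------
# Parsing helpers


def _parse_float(raw: object, column: str, rowno: int) -> float:
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        raise SchemaError(f"row {rowno}: missing value in column {column!r}")
    try:
        val = float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {rowno}: non-numeric value {raw!r} in column {column!r}"
        ) from None
    if not math.isfinite(val):
        raise SchemaError(f"row {rowno}: non-finite value in column {column!r}")
    return val


def _record_from_row(row: Mapping[str, object], rowno: int) -> tuple[NitriteStats, str | None]:
    name = str(row.get("excipient") or "").strip()
    if not name:
        raise SchemaError(f"row {rowno}: empty excipient name")
    vals = {c: _parse_float(row.get(c), c, rowno) for c in ("min_ppm", "mean_ppm", "max_ppm")}
    if not vals["min_ppm"] <= vals["mean_ppm"] <= vals["max_ppm"]:
        raise SchemaError(
            f"row {rowno} ({name}): statistics must satisfy min <= mean <= max, "
            f"got ({vals['min_ppm']}, {vals['mean_ppm']}, {vals['max_ppm']})"
        )
    n_raw = row.get("n")
    n = None
    if n_raw not in (None, ""):
        n = int(_parse_float(n_raw, "n", rowno))
    stats = NitriteStats(
        excipient=name,
        min_ppm=vals["min_ppm"],
        mean_ppm=vals["mean_ppm"],
        max_ppm=vals["max_ppm"],
        n_samples=n,
        source=str(row.get("source") or "").strip(),
    )
    supplier_raw = str(row.get("supplier") or "").strip()
    return stats, supplier_raw or None


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        return "yaml"
    if suffix == ".csv":
        return "csv"
    raise SchemaError(f"cannot infer format from {path.name!r}; pass format='csv'|'yaml'")


def load_nitrite_db(path: str | Path, fmt: str | None = None) -> NitriteDatabase:
    """Read and validate a nitrite database from CSV or YAML.

    Schema errors cite the offending row number; duplicate
    (excipient, supplier) keys are rejected.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    db = NitriteDatabase()
    if fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames
            if header is None:
                raise SchemaError(f"{path.name}: empty file")
            missing = [c for c in _REQUIRED_COLUMNS if c not in header]
            if missing:
                raise SchemaError(f"{path.name}: missing required columns {missing}")
            rows = list(reader)
        if not rows:
            raise SchemaError(f"{path.name}: no data rows")
        for idx, row in enumerate(rows, start=2):  # header is row 1
            try:
                stats, supplier = _record_from_row(row, idx)
                db.add(stats, supplier)
            except SchemaError:
                raise
        db.metadata = {"path": str(path), "units": "ppm w/w"}
    elif fmt == "yaml":
        doc = yaml.safe_load(path.read_text())
        if not isinstance(doc, dict) or "records" not in doc:
            raise SchemaError(f"{path.name}: expected a mapping with a 'records' list")
        records = doc["records"]
        if not records:
            raise SchemaError(f"{path.name}: no records")
        for idx, row in enumerate(records, start=1):
            if not isinstance(row, dict):
                raise SchemaError(f"record {idx}: expected a mapping")
            stats, supplier = _record_from_row(row, idx)
            db.add(stats, supplier)
        meta = doc.get("metadata") or {}
        db.metadata = {**{str(k): str(v) for k, v in meta.items()}, "path": str(path),
                       "units": "ppm w/w"}
    else:
        raise SchemaError(f"unsupported format {fmt!r}; expected 'csv' or 'yaml'")
    return db


def _format_number(value: float) -> str:
    # repr keeps '6.5' as '6.5' (shortest round-tripping decimal)
    return repr(int(value)) if float(value).is_integer() else repr(float(value))


def write_nitrite_db(db: NitriteDatabase, path: str | Path, fmt: str | None = None) -> Path:
    """Serialize a database so that loading it back reproduces it exactly.

    Numbers are written as their shortest round-tripping decimal strings,
    so 6.5 stays 6.5 in the text file.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    rows = []
    for (_, supplier), stats in db.records.items():
        rows.append(
            {
                "excipient": stats.excipient,
                "supplier": supplier or "",
                "min_ppm": _format_number(stats.min_ppm),
                "mean_ppm": _format_number(stats.mean_ppm),
                "max_ppm": _format_number(stats.max_ppm),
                "n": "" if stats.n_samples is None else str(stats.n_samples),
                "source": stats.source,
            }
        )
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=list(_REQUIRED_COLUMNS[:1] + _OPTIONAL_COLUMNS[:1])
                + list(_REQUIRED_COLUMNS[1:]) + list(_OPTIONAL_COLUMNS[1:])
            )
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "yaml":
        records = []
        for row in rows:
            rec: dict[str, object] = {
                "excipient": row["excipient"],
                "min_ppm": float(row["min_ppm"]),
                "mean_ppm": float(row["mean_ppm"]),
                "max_ppm": float(row["max_ppm"]),
            }
            if row["supplier"]:
                rec["supplier"] = row["supplier"]
            if row["n"]:
                rec["n"] = int(row["n"])
            if row["source"]:
                rec["source"] = row["source"]
            records.append(rec)
        doc = {"metadata": {"units": "ppm w/w"}, "records": records}
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        raise SchemaError(f"unsupported format {fmt!r}; expected 'csv' or 'yaml'")
    return path


# --------------------------------------------------------------------------
# Packaged reference data


def packaged_db_path(name: str = "nitrite_printed.csv") -> Path:
    """Path to a packaged reference database file."""
    return Path(importlib.resources.files("nitrocalc").joinpath("data", name))  # type: ignore[arg-type]


def load_packaged_db() -> NitriteDatabase:
    """The bundled tier-A database: only excipient nitrite values that are
    individually documented (crospovidone, croscarmellose sodium, and the
    lowest-on-the-market filler band); everything else must come from the
    user's own data or the toolkit import."""
    return load_nitrite_db(packaged_db_path())


# --------------------------------------------------------------------------
# Toolkit XLSX import

_HEADER_ALIASES = {
    "excipient": ("excipient", "ingredient", "material", "name"),
    "min_ppm": ("min", "minimum", "lowest", "best"),
    "mean_ppm": ("mean", "average", "avg"),
    "max_ppm": ("max", "maximum", "highest", "worst"),
}


def _match_header(cells: list[object]) -> dict[str, int] | None:
    found: dict[str, int] = {}
    for idx, cell in enumerate(cells):
        text = normalize_key(str(cell)) if cell is not None else ""
        if not text:
            continue
        for column, aliases in _HEADER_ALIASES.items():
            if column not in found and any(text.startswith(a) for a in aliases):
                found[column] = idx
                break
    return found if set(found) >= set(_REQUIRED_COLUMNS) else None


def import_toolkit_xlsx(path: str | Path, sheet: str | None = None) -> NitriteDatabase:
    """Read a nitrite sheet from a calculation-toolkit Excel workbook.

    Scans for a header row containing excipient/min/mean/max columns
    (tolerating common alias spellings such as "average" or "highest") and
    reads records until the first blank excipient cell. Raises a
    :class:`SchemaError` naming the sheets scanned when no recognizable
    layout is found.
    """
    import openpyxl

    path = Path(path)
    if not path.exists():
        raise SchemaError(f"toolkit workbook not found: {path}")
    wb = openpyxl.load_workbook(path, data_only=True, read_only=True)
    sheets = [wb[sheet]] if sheet else wb.worksheets
    for ws in sheets:
        rows = list(ws.iter_rows(values_only=True))
        for header_idx, row in enumerate(rows):
            cols = _match_header(list(row))
            if cols is None:
                continue
            db = NitriteDatabase(metadata={"path": str(path), "sheet": ws.title,
                                           "units": "ppm w/w"})
            for rowno, data in enumerate(rows[header_idx + 1:], start=header_idx + 2):
                name = data[cols["excipient"]] if cols["excipient"] < len(data) else None
                if name is None or not str(name).strip():
                    break
                record = {
                    "excipient": str(name),
                    "min_ppm": data[cols["min_ppm"]],
                    "mean_ppm": data[cols["mean_ppm"]],
                    "max_ppm": data[cols["max_ppm"]],
                }
                stats, _ = _record_from_row(record, rowno)
                db.add(stats)
            if len(db):
                return db
    raise SchemaError(
        f"{path.name}: no sheet with a recognizable nitrite table "
        f"(need excipient/min/mean/max headers); scanned sheets: "
        f"{[ws.title for ws in sheets]}"
    )
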
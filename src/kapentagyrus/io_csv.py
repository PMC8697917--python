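"""CSV input/output in the specimen-table dialect.

One row is one specimen.  Columns, in order: ``specimen_id, species_label,
host_species, locality, country, da_total, da_ltn, da_inner, da_outer,
da_point, va_total, va_ltn, va_inner, va_outer, va_point, db_len, db_width,
vb_len, vb_width, hI..hVII, mco_tube, mco_ap, ap_side`` plus the optional
qualitative column ``broad_roots``.  An empty cell is a missing value —
never zero.  Floats are written at full precision; rounding is a display
concern only.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

from .morphometry import (
    HOOK_PAIRS,
    AnchorMeasurements,
    BarMeasurements,
    HookMeasurements,
    McoMeasurements,
    SpecimenRecord,
    ValidationError,
)

__all__ = ["CSV_COLUMNS", "read_specimens", "write_specimens", "SpecimenCSVError"]

_META_COLUMNS = ("specimen_id", "species_label", "host_species", "locality", "country")
_NUMERIC_COLUMNS = (
    "da_total", "da_ltn", "da_inner", "da_outer", "da_point",
    "va_total", "va_ltn", "va_inner", "va_outer", "va_point",
    "db_len", "db_width", "vb_len", "vb_width",
    "hI", "hII", "hIII", "hIV", "hV", "hVI", "hVII",
    "mco_tube", "mco_ap",
)
CSV_COLUMNS = _META_COLUMNS + _NUMERIC_COLUMNS + ("ap_side", "broad_roots")


class SpecimenCSVError(ValueError):
    """One or more rows violate the specimen-CSV dialect."""


def _parse_float(cell: str, column: str, line: int, errors: List[str]) -> Optional[float]:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        errors.append(f"line {line}: column {column}: not a number: {cell!r}")
        return None


def read_specimens(path: Union[str, Path]) -> List[SpecimenRecord]:
    """Read and validate a specimen CSV; raises with every offending row named."""
    path = Path(path)
    errors: List[str] = []
    records: List[SpecimenRecord] = []
    seen: dict = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        unknown = [c for c in header if c not in CSV_COLUMNS]
        if unknown:
            raise SpecimenCSVError(f"unknown columns: {', '.join(unknown)}")
        missing_cols = [c for c in _META_COLUMNS if c not in header]
        if missing_cols:
            raise SpecimenCSVError(f"missing required columns: {', '.join(missing_cols)}")
        for line_no, row in enumerate(reader, start=2):
            sid = (row.get("specimen_id") or "").strip()
            if not sid:
                errors.append(f"line {line_no}: empty specimen_id")
                continue
            if sid in seen:
                errors.append(
                    f"duplicate specimen_id {sid!r} on lines {seen[sid]} and {line_no}"
                )
                continue
            seen[sid] = line_no
            values = {
                c: _parse_float(row.get(c, ""), c, line_no, errors)
                for c in _NUMERIC_COLUMNS
            }
            ap = (row.get("ap_side") or "").strip() or "unknown"
            broad_cell = (row.get("broad_roots") or "").strip().lower()
            broad = {"": None, "true": True, "false": False}.get(broad_cell)
            if broad_cell and broad is None:
                errors.append(f"line {line_no}: broad_roots must be true/false/empty")
            record = SpecimenRecord(
                specimen_id=sid,
                species_label=(row.get("species_label") or "").strip() or None,
                host_species=(row.get("host_species") or "").strip() or None,
                locality=(row.get("locality") or "").strip(),
                country=(row.get("country") or "").strip(),
                dorsal_anchor=AnchorMeasurements(
                    values["da_total"], values["da_ltn"], values["da_inner"],
                    values["da_outer"], values["da_point"],
                ),
                ventral_anchor=AnchorMeasurements(
                    values["va_total"], values["va_ltn"], values["va_inner"],
                    values["va_outer"], values["va_point"],
                ),
                dorsal_bar=BarMeasurements(values["db_len"], values["db_width"]),
                ventral_bar=BarMeasurements(values["vb_len"], values["vb_width"]),
                hooks=HookMeasurements(
                    {p: v for p in HOOK_PAIRS if (v := values[f"h{p}"]) is not None}
                ),
                mco=McoMeasurements(values["mco_tube"], values["mco_ap"], ap),
                broad_inner_roots=broad,
            )
            try:
                record.validate()
            except ValidationError as exc:
                errors.append(f"line {line_no}: {exc}")
                continue
            records.append(record)
    if errors:
        raise SpecimenCSVError("; ".join(errors))
    if not records:
        warnings.warn(f"{path}: no specimen rows (header only?)", stacklevel=2)
    return records


def write_specimens(records: Sequence[SpecimenRecord], path: Union[str, Path]) -> None:
    """Write records in the standard dialect; round-trips losslessly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            m = rec.measurements()
            row: List[str] = [
                rec.specimen_id,
                rec.species_label or "",
                rec.host_species or "",
                rec.locality,
                rec.country,
            ]
            row += ["" if m[c] is None else repr(m[c]) for c in _NUMERIC_COLUMNS]
            row.append("" if rec.mco.ap_loop_side == "unknown" else rec.mco.ap_loop_side)
            row.append("" if rec.broad_inner_roots is None else str(rec.broad_inner_roots).lower())
            writer.writerow(row)


def export_fixture_records() -> Iterable[SpecimenRecord]:
    """The mean specimens of the embedded profile columns (13 records)."""
    from .reference import profile_mean_records

    return profile_mean_records()
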
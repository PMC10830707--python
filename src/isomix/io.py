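"""CSV readers and writers for consumer and diet-source isotope tables.

Dialect: comma-separated, UTF-8, ``.`` decimal, header row required, missing
values as empty strings.  Floats are written to 6 decimals, which round-trips
delta values well below analytical precision (~0.1-0.2 per mil).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import pandas as pd

from .records import IsotopeRecord, LizardRecord

__all__ = [
    "SchemaError",
    "RowParseError",
    "CONSUMER_COLUMNS",
    "SOURCE_COLUMNS",
    "read_isotope_table",
    "write_isotope_table",
]

CONSUMER_COLUMNS = [
    "sample_id", "site", "habitat", "tissue", "sex",
    "svl_mm", "mass_g", "d13C", "d15N", "cn_ratio",
]
SOURCE_COLUMNS = ["sample_id", "site", "environment", "taxon", "d13C", "d15N", "cn_ratio"]

_REQUIRED = {
    "consumer": CONSUMER_COLUMNS,
    "source": SOURCE_COLUMNS,
    "plant": SOURCE_COLUMNS,
}


class SchemaError(ValueError):
    """The CSV is missing required columns for the requested schema."""


class RowParseError(ValueError):
    """One or more rows failed type coercion; ``rows`` holds (row number, message)."""

    def __init__(self, rows: Sequence[tuple]):
        self.rows = list(rows)
        detail = "; ".join(f"row {i}: {msg}" for i, msg in self.rows)
        super().__init__(f"{len(self.rows)} row(s) failed to parse: {detail}")


def _opt_float(value, column: str):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"non-numeric {column}: {s!r}")


def _req_float(value, column: str) -> float:
    out = _opt_float(value, column)
    if out is None:
        raise ValueError(f"missing {column}")
    return out


def _opt_str(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_isotope_table(
    path: Union[str, Path], schema: str
) -> List[IsotopeRecord]:
    """Read a consumer, source, or plant CSV into typed records.

    ``schema='consumer'`` yields :class:`LizardRecord`; ``'source'`` and
    ``'plant'`` yield :class:`IsotopeRecord` with ``environment`` set.  Rows
    that fail coercion are collected and raised together as
    :class:`RowParseError` with their 1-based data row numbers.
    """
    if schema not in _REQUIRED:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for schema {schema!r}")

    records: List[IsotopeRecord] = []
    errors: List[tuple] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            if schema == "consumer":
                rec: IsotopeRecord = LizardRecord(
                    sample_id=str(row["sample_id"]).strip(),
                    site=str(row["site"]).strip(),
                    habitat=str(row["habitat"]).strip(),
                    tissue=str(row["tissue"]).strip() or "lizard_tail",
                    sex=_opt_str(row["sex"]),
                    svl=_opt_float(row["svl_mm"], "svl_mm"),
                    mass=_opt_float(row["mass_g"], "mass_g"),
                    d13C=_req_float(row["d13C"], "d13C"),
                    d15N=_req_float(row["d15N"], "d15N"),
                    cn_ratio=_opt_float(row["cn_ratio"], "cn_ratio"),
                )
            else:
                taxon = _opt_str(row["taxon"])
                tissue = taxon if taxon in {"plant", "algae"} else "arthropod"
                rec = IsotopeRecord(
                    sample_id=str(row["sample_id"]).strip(),
                    site=str(row["site"]).strip(),
                    habitat="beach",
                    tissue=tissue,
                    environment=_opt_str(row["environment"]),
                    taxon=taxon,
                    d13C=_req_float(row["d13C"], "d13C"),
                    d15N=_req_float(row["d15N"], "d15N"),
                    cn_ratio=_opt_float(row["cn_ratio"], "cn_ratio"),
                )
            records.append(rec)
        except ValueError as exc:
            errors.append((i, str(exc)))
    if errors:
        raise RowParseError(errors)
    return records


def _fmt(x) -> str:
    return "" if x is None else f"{x:.6f}"


def write_isotope_table(
    records: Iterable[IsotopeRecord], path: Union[str, Path], schema: str = "consumer"
) -> None:
    """Write records back to CSV using the same column layout the readers expect."""
    rows = []
    for r in records:
        if schema == "consumer":
            rows.append({
                "sample_id": r.sample_id, "site": r.site, "habitat": r.habitat,
                "tissue": r.tissue, "sex": getattr(r, "sex", None) or "",
                "svl_mm": _fmt(getattr(r, "svl", None)),
                "mass_g": _fmt(getattr(r, "mass", None)),
                "d13C": _fmt(r.d13C), "d15N": _fmt(r.d15N),
                "cn_ratio": _fmt(r.cn_ratio),
            })
        else:
            rows.append({
                "sample_id": r.sample_id, "site": r.site,
                "environment": r.environment or "",
                "taxon": r.taxon or r.tissue,
                "d13C": _fmt(r.d13C), "d15N": _fmt(r.d15N),
                "cn_ratio": _fmt(r.cn_ratio),
            })
    cols = CONSUMER_COLUMNS if schema == "consumer" else SOURCE_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
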
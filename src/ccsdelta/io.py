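"""Tab-separated table I/O with a configurable column mapping.

The pipeline consumes MaxQuant-style "evidence" tables (one row per
detected peptide feature per run). Canonical field names are fixed;
a :class:`ColumnMap` translates them to whatever headers a source file
uses. All output tables are TSV, UTF-8, "." decimal, with a mandatory
header row; comment lines starting with ``#`` carry run metadata and
are skipped on read.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ColumnMap",
    "MAXQUANT_COLUMN_MAP",
    "RejectedRow",
    "read_evidence_table",
    "read_reference_table",
    "read_mod_masses",
    "write_table",
    "read_table",
    "annotate_sites",
]

#: canonical evidence fields -> dtype kind ("num" fields must parse as floats)
REQUIRED_FIELDS = {
    "run_id": "str",
    "sequence": "str",
    "modified_sequence": "str",
    "modification_name": "str",
    "charge": "num",
    "mz": "num",
    "inv_k0": "num",
    "rt": "num",
    "intensity": "num",
}
OPTIONAL_FIELDS = {"mod_position": "num", "n_mod_sites": "num", "pool": "str"}

#: 1/K0 acquisition window of the TIMS ramp, Vs cm^-2
INV_K0_WINDOW = (0.6, 1.5)


class ConfigError(ValueError):
    """Bad configuration (missing column mapping, invalid option)."""


class DataError(ValueError):
    """Input data violates a contract (duplicates, empty reference set)."""


@dataclass(frozen=True)
class ColumnMap:
    """Map canonical field names to source column headers.

    Unmapped optional fields default to absent; mapped required fields
    must exist in the file header.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def source(self, canonical: str) -> str:
        return self.mapping.get(canonical, canonical)

    def validate(self, header: Sequence[str]) -> None:
        for canonical in REQUIRED_FIELDS:
            src = self.source(canonical)
            if src not in header:
                raise ConfigError(
                    f"evidence table is missing mapped column {src!r} "
                    f"(canonical field {canonical!r})"
                )


#: mapping for MaxQuant evidence.txt headers
MAXQUANT_COLUMN_MAP = ColumnMap(
    {
        "run_id": "Raw file",
        "sequence": "Sequence",
        "modified_sequence": "Modified sequence",
        "modification_name": "Modifications",
        "charge": "Charge",
        "mz": "m/z",
        "inv_k0": "1/K0",
        "rt": "Retention time",
        "intensity": "Intensity",
    }
)


@dataclass(frozen=True)
class RejectedRow:
    row_number: int  # 1-based data row index
    reason: str


_SITE_RE = re.compile(r"\(")


def _parse_sites(modified_sequence: str):
    """Locate bracket-style modification annotations.

    Returns (n_sites, position) where position is the 1-based residue
    index of the single site (NaN if zero or multiple sites). Only site
    location is needed, not the modification chemistry.
    """
    s = modified_sequence.strip("_")
    n_sites = 0
    position = float("nan")
    residue_idx = 0
    depth = 0
    for ch in s:
        if ch == "(":
            if depth == 0:
                n_sites += 1
                position = residue_idx
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        elif depth == 0:
            residue_idx += 1
    if n_sites != 1:
        position = float("nan")
    return n_sites, position


def annotate_sites(features: pd.DataFrame) -> pd.DataFrame:
    """Fill ``mod_position`` / ``n_mod_sites`` from ``modified_sequence``.

    Rows whose modification_name is "Unmodified" get 0 sites. Existing
    columns are preserved.
    """
    out = features.copy()
    need_pos = "mod_position" not in out.columns
    need_n = "n_mod_sites" not in out.columns
    if not (need_pos or need_n):
        return out
    parsed = [_parse_sites(ms) for ms in out["modified_sequence"]]
    if need_n:
        out["n_mod_sites"] = [p[0] for p in parsed]
    if need_pos:
        out["mod_position"] = [p[1] for p in parsed]
    return out


def read_evidence_table(path, column_map: ColumnMap | None = None):
    """Read an evidence TSV into a canonical-column DataFrame.

    Returns ``(features, rejects)``: rows with unparseable numeric fields
    are collected as :class:`RejectedRow` objects rather than raised or
    silently dropped. Row order is preserved and never deduplicated.
    """
    column_map = column_map or ColumnMap()
    try:
        raw = pd.read_csv(
            path, sep="\t", dtype=str, comment="#", keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        warnings.warn(f"evidence table {path} is empty")
        return pd.DataFrame(columns=list(REQUIRED_FIELDS)), []
    column_map.validate(list(raw.columns))

    rename = {column_map.source(c): c for c in REQUIRED_FIELDS}
    for c in OPTIONAL_FIELDS:
        src = column_map.source(c)
        if src in raw.columns:
            rename[src] = c
    df = raw[list(rename)].rename(columns=rename)

    rejects: list[RejectedRow] = []
    numeric = [c for c, kind in {**REQUIRED_FIELDS, **OPTIONAL_FIELDS}.items()
               if kind == "num" and c in df.columns]
    converted = {}
    bad = pd.Series(False, index=df.index)
    for col in numeric:
        vals = pd.to_numeric(df[col].replace("", "nan"), errors="coerce")
        required = col in REQUIRED_FIELDS
        invalid = vals.isna() & (df[col] != "") & (df[col].str.lower() != "nan")
        if required:
            invalid |= vals.isna()
        for idx in df.index[invalid & ~bad]:
            rejects.append(
                RejectedRow(int(idx) + 1, f"unparseable {col}: {df.at[idx, col]!r}")
            )
        bad |= invalid
        converted[col] = vals
    for col, vals in converted.items():
        df[col] = vals
    df = df.loc[~bad].reset_index(drop=True)
    if not df.empty:
        df["charge"] = df["charge"].astype(int)
    if df.empty and not rejects:
        warnings.warn(f"evidence table {path} has no data rows")
    df = annotate_sites(df) if not df.empty else df
    return df, rejects


def read_reference_table(path) -> pd.DataFrame:
    """Read the reference-peptide table (sequence, ref_inv_k0, ref_rt[, charge]).

    Sequences must be unique; an empty table is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise DataError("reference set empty")
    for col in ("sequence", "ref_inv_k0", "ref_rt"):
        if col not in df.columns:
            raise ConfigError(f"reference table is missing column {col!r}")
    if "charge" not in df.columns:
        df["charge"] = 2  # iRT peptides fly doubly protonated
    dup = df["sequence"][df["sequence"].duplicated()]
    if len(dup):
        raise DataError(f"duplicate reference sequence(s): {sorted(set(dup))}")
    if (df["ref_inv_k0"] <= 0).any():
        raise DataError("reference ref_inv_k0 must be > 0")
    return df.reset_index(drop=True)


def read_mod_masses(path) -> pd.DataFrame:
    """Read the modification mass table (modification_name, delta_mass, target_residue)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("modification_name", "delta_mass"):
        if col not in df.columns:
            raise ConfigError(f"modification mass table is missing column {col!r}")
    dup = df["modification_name"][df["modification_name"].duplicated()]
    if len(dup):
        raise DataError(f"duplicate modification(s) in mass table: {sorted(set(dup))}")
    return df


def write_table(records, path, header_comments: Iterable[str] = ()) -> None:
    """Write any tabular result as TSV (UTF-8, header row, '.' decimal).

    ``header_comments`` become ``#``-prefixed lines above the header so
    physical assumptions travel with every output table. Reals are
    written with enough digits to round-trip to 1e-6 relative.
    """
    df = pd.DataFrame(records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
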
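"""Matching modified peptides to unmodified counterparts.

A pair couples the aggregated record of a modified peptide with the
record of its base sequence at the same charge and carries the relative
and absolute CCS differences, the RT difference, and the modification
mass. delta_ccs_rel is stored as a fraction:
(ccs_modified - ccs_unmodified) / ccs_unmodified.
"""

from __future__ import annotations

import pandas as pd

from .io import DataError

__all__ = ["match_pairs", "compute_deltas"]

PAIR_COLUMNS = [
    "sequence",
    "modification_name",
    "mod_position",
    "charge",
    "ccs_modified",
    "ccs_unmodified",
    "rt_modified",
    "rt_unmodified",
    "mz_unmodified",
]


def match_pairs(
    modified: pd.DataFrame, unmodified: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Pair each modified record with its (sequence, charge) counterpart.

    Both inputs are aggregated records (one row per modified_sequence x
    charge). The unmodified set must be unique by (sequence, charge);
    duplicates mean the aggregation contract was violated. Returns the
    pair table, deterministically sorted, and the number of modified
    records with no counterpart.
    """
    dup = unmodified.duplicated(subset=["sequence", "charge"])
    if dup.any():
        keys = unmodified.loc[dup, ["sequence", "charge"]].itertuples(index=False)
        raise DataError(
            "duplicate unmodified record(s) for key(s): "
            + ", ".join(f"({s}, {z})" for s, z in keys)
        )
    base = unmodified.rename(
        columns={
            "ccs_mean": "ccs_unmodified",
            "rt_mean": "rt_unmodified",
            "mz": "mz_unmodified",
        }
    )[["sequence", "charge", "ccs_unmodified", "rt_unmodified"]
      + (["mz_unmodified"] if "mz" in unmodified.columns else [])]
    mod = modified.rename(
        columns={"ccs_mean": "ccs_modified", "rt_mean": "rt_modified"}
    )
    merged = mod.merge(base, on=["sequence", "charge"], how="left")
    matched = merged["ccs_unmodified"].notna()
    n_unmatched = int((~matched).sum())
    cols = [c for c in PAIR_COLUMNS if c in merged.columns]
    pairs = (
        merged.loc[matched, cols]
        .sort_values(["modification_name", "sequence", "charge"], kind="stable")
        .reset_index(drop=True)
    )
    return pairs, n_unmatched


def compute_deltas(pairs: pd.DataFrame, mod_masses: pd.DataFrame) -> pd.DataFrame:
    """Populate delta_ccs_rel, delta_ccs_abs, delta_rt, delta_mass.

    ``mod_masses`` maps modification_name to delta_mass (Da); every
    modification present in ``pairs`` must be listed.
    """
    if (pairs["ccs_unmodified"] <= 0).any():
        raise DataError("ccs_unmodified must be > 0 for all pairs")
    mass_of = dict(
        zip(mod_masses["modification_name"], mod_masses["delta_mass"])
    )
    unknown = sorted(set(pairs["modification_name"]) - set(mass_of))
    if unknown:
        raise DataError(f"modification(s) missing from mass table: {unknown}")
    out = pairs.copy()
    out["delta_ccs_abs"] = out["ccs_modified"] - out["ccs_unmodified"]
    out["delta_ccs_rel"] = out["delta_ccs_abs"] / out["ccs_unmodified"]
    out["delta_rt"] = out["rt_modified"] - out["rt_unmodified"]
    out["delta_mass"] = out["modification_name"].map(mass_of)
    return out
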
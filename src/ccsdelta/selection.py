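"""Filtering and replicate aggregation of evidence features.

Reduces evidence rows to one record per (modified sequence, charge):
charge filter, single-internal-site rule, oxidation exclusion, per-run
top-intensity selection, then cross-run averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterRules",
    "filter_features",
    "select_top_evidence",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class FilterRules:
    allowed_charges: frozenset = field(default_factory=lambda: frozenset({2, 3}))
    exclude_cterm_mod: bool = True
    exclude_oxidized: bool = True
    require_single_site: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_charges:
            raise ValueError("allowed_charges must be non-empty")


def _is_oxidized(features: pd.DataFrame) -> pd.Series:
    name = features["modification_name"].astype(str).str.lower()
    mseq = features["modified_sequence"].astype(str).str.lower()
    return name.str.contains("oxid") | mseq.str.contains(r"\(ox", regex=True)


def filter_features(
    features: pd.DataFrame, rules: FilterRules = FilterRules()
) -> tuple[pd.DataFrame, dict]:
    """Apply the charge / single-site / C-terminus / oxidation rules.

    Returns the surviving rows (order preserved) and per-rule drop
    counts. Each dropped row is counted under the first rule it fails,
    in the fixed order charge, multisite, cterm, oxidized, so that
    survivors + counts always sum to the input size. Unmodified rows are
    only subject to the charge rule.
    """
    counts = {"charge": 0, "multisite": 0, "cterm": 0, "oxidized": 0}
    if features.empty:
        return features.copy(), counts

    modified = features["modification_name"].astype(str) != "Unmodified"
    n_sites = features.get("n_mod_sites")
    if n_sites is None:
        n_sites = modified.astype(int)
    pos = features.get("mod_position")
    if pos is None:
        pos = pd.Series(np.nan, index=features.index)
    seq_len = features["sequence"].astype(str).str.len()

    fail_charge = ~features["charge"].isin(list(rules.allowed_charges))
    fail_multi = rules.require_single_site & modified & (n_sites != 1)
    fail_cterm = rules.exclude_cterm_mod & modified & (pos == seq_len)
    fail_ox = rules.exclude_oxidized & _is_oxidized(features)

    reason = np.select(
        [fail_charge, fail_multi, fail_cterm, fail_ox],
        ["charge", "multisite", "cterm", "oxidized"],
        default="",
    )
    for key in counts:
        counts[key] = int((reason == key).sum())
    kept = features.loc[reason == ""].copy()
    return kept, counts


def select_top_evidence(features: pd.DataFrame) -> pd.DataFrame:
    """Keep the most intense row per (run_id, modified_sequence, charge).

    Ties are broken by earliest RT, then first occurrence in the input.
    Output preserves the input's relative row order; idempotent.
    """
    if features.empty:
        return features.copy()
    order = np.arange(len(features))
    ranked = features.assign(_order=order).sort_values(
        ["intensity", "rt", "_order"],
        ascending=[False, True, True],
        kind="stable",
    )
    top = ranked.drop_duplicates(
        subset=["run_id", "modified_sequence", "charge"], keep="first"
    )
    return top.sort_values("_order").drop(columns="_order").reset_index(drop=True)


def aggregate_replicates(features: pd.DataFrame) -> pd.DataFrame:
    """Mean CCS and RT per (modified_sequence, charge) across runs.

    Expects aligned, CCS-converted, top-selected features. Intensity is
    aggregated as the maximum; n_replicates counts distinct runs.
    Carried identity columns (sequence, modification_name, mod_position,
    pool) are taken from the first occurrence within each group.
    """
    if features.empty:
        return pd.DataFrame(
            columns=[
                "modified_sequence", "charge", "sequence", "modification_name",
                "mod_position", "mz", "ccs_mean", "rt_mean", "intensity_max",
                "n_replicates",
            ]
        )
    carry = [
        c for c in ("sequence", "modification_name", "mod_position", "pool", "mz")
        if c in features.columns
    ]
    agg = {c: (c, "first") for c in carry}
    agg.update(
        ccs_mean=("ccs", "mean"),
        rt_mean=("rt", "mean"),
        intensity_max=("intensity", "max"),
        n_replicates=("run_id", "nunique"),
    )
    out = (
        features.groupby(["modified_sequence", "charge"], sort=True)
        .agg(**agg)
        .reset_index()
    )
    return out
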
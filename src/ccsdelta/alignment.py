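"""Run-wise mobility and retention-time alignment from spiked references.

Each run's correction is the median deviation (measured - reference) of
its spiked reference peptides, computed on the 1/K0 scale; CCS is always
recomputed after alignment, never corrected directly. Precision is
quantified as per-peptide coefficients of variation across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataError

__all__ = [
    "RunCorrection",
    "PrecisionMetrics",
    "compute_run_correction",
    "compute_corrections",
    "apply_corrections",
    "precision_summary",
]

DEFAULT_MIN_REFS = 3


@dataclass(frozen=True)
class RunCorrection:
    """Additive per-run offsets; ``alignable=False`` flags failed runs."""

    run_id: str
    delta_inv_k0: float
    delta_rt: float
    n_refs_used: int
    alignable: bool = True


@dataclass(frozen=True)
class PrecisionMetrics:
    median_cv: float  # % (sd/mean, n-1)
    n_peptides: int
    completeness_fraction: float
    per_peptide: pd.DataFrame  # modified_sequence, charge, n_runs, ccs_mean, cv


def compute_run_correction(
    run_features: pd.DataFrame,
    refs: pd.DataFrame,
    min_refs: int = DEFAULT_MIN_REFS,
) -> RunCorrection:
    """Median deviation of matched reference peptides in one run.

    References are matched by (sequence, charge); if a reference appears
    multiple times in the run, the most intense occurrence is used. With
    fewer than ``min_refs`` matches the run is flagged unalignable.
    """
    run_ids = run_features["run_id"].unique()
    if len(run_ids) != 1:
        raise ValueError(f"expected features of one run, got {list(run_ids)}")
    run_id = str(run_ids[0])

    matched = run_features.merge(
        refs[["sequence", "charge", "ref_inv_k0", "ref_rt"]],
        on=["sequence", "charge"],
        how="inner",
    )
    if not matched.empty:
        matched = (
            matched.sort_values("intensity", ascending=False, kind="stable")
            .drop_duplicates(subset=["sequence", "charge"], keep="first")
        )
    n = len(matched)
    if n < min_refs:
        return RunCorrection(run_id, float("nan"), float("nan"), n, alignable=False)
    d_ik0 = float(np.median(matched["inv_k0"] - matched["ref_inv_k0"]))
    d_rt = float(np.median(matched["rt"] - matched["ref_rt"]))
    if not (np.isfinite(d_ik0) and np.isfinite(d_rt)):
        return RunCorrection(run_id, float("nan"), float("nan"), n, alignable=False)
    return RunCorrection(run_id, d_ik0, d_rt, n)


def compute_corrections(
    features: pd.DataFrame,
    refs: pd.DataFrame,
    min_refs: int = DEFAULT_MIN_REFS,
) -> list[RunCorrection]:
    """One :class:`RunCorrection` per run present in ``features``."""
    return [
        compute_run_correction(group, refs, min_refs)
        for _, group in features.groupby("run_id", sort=True)
    ]


def apply_corrections(
    features: pd.DataFrame, corrections: list[RunCorrection]
) -> tuple[pd.DataFrame, int]:
    """Subtract per-run offsets from 1/K0 and RT.

    Features from unalignable runs are dropped; the drop count is
    returned alongside the aligned table. Every run in ``features`` must
    have a correction (alignable or flagged).
    """
    by_run = {c.run_id: c for c in corrections}
    missing = set(features["run_id"].astype(str)) - set(by_run)
    if missing:
        raise DataError(f"no correction for run(s): {sorted(missing)}")

    alignable = features["run_id"].astype(str).map(lambda r: by_run[r].alignable)
    n_dropped = int((~alignable).sum())
    if n_dropped:
        dropped_runs = sorted(set(features.loc[~alignable, "run_id"].astype(str)))
        warnings.warn(
            f"dropping {n_dropped} features from {len(dropped_runs)} "
            f"unalignable run(s): {dropped_runs}"
        )
    out = features.loc[alignable].copy()
    out["inv_k0"] = out["inv_k0"] - out["run_id"].astype(str).map(
        lambda r: by_run[r].delta_inv_k0
    )
    out["rt"] = out["rt"] - out["run_id"].astype(str).map(
        lambda r: by_run[r].delta_rt
    )
    return out, n_dropped


def precision_summary(
    features: pd.DataFrame, require_complete: bool = True
) -> PrecisionMetrics:
    """Per-peptide CV of CCS across replicate runs.

    CV uses the sample standard deviation (n-1) over runs, per
    (modified_sequence, charge), in percent. ``require_complete``
    restricts to peptides observed in every run; otherwise peptides in
    at least two runs enter. Completeness is the fraction of peptides
    seen in all runs among those seen at all.
    """
    if "ccs" not in features.columns:
        raise ValueError("precision_summary needs a 'ccs' column")
    n_runs = features["run_id"].nunique()
    if n_runs < 2:
        raise DataError("precision_summary needs >= 2 runs")

    per = (
        features.groupby(["modified_sequence", "charge"])
        .agg(
            n_runs=("run_id", "nunique"),
            ccs_mean=("ccs", "mean"),
            ccs_sd=("ccs", lambda x: x.std(ddof=1)),
        )
        .reset_index()
    )
    complete = per["n_runs"] == n_runs
    completeness = float(complete.mean()) if len(per) else float("nan")

    kept = per[complete] if require_complete else per[per["n_runs"] >= 2]
    kept = kept.copy()
    if kept.empty:
        raise DataError("no peptides for CV")
    kept["cv"] = 100.0 * kept["ccs_sd"] / kept["ccs_mean"]
    return PrecisionMetrics(
        median_cv=float(kept["cv"].median()),
        n_peptides=int(len(kept)),
        completeness_fraction=completeness,
        per_peptide=kept.reset_index(drop=True),
    )
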
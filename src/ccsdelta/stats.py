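"""Modification-level statistics on matched CCS pairs.

Implements the headline analyses: per-modification median relative CCS
shift (MED) with one-sample Wilcoxon significance and Benjamini-
Hochberg adjustment, charge-state profiles, CCS-vs-m/z ion-cloud fits
with per-peptide residuals, the regression of pairwise CCS shifts on
those residuals ("shift gradients"), mass/retention-time correlations,
and rank concordance of per-sequence shifts between modifications.

The Wilcoxon and Benjamini-Hochberg primitives are implemented here
(exact signed-rank null by enumeration over sign assignments for small
n) rather than delegated, because their exact conventions — zeros
dropped, two-sided exact p for n <= 25, continuity-corrected normal
approximation above — are part of the artifact's contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import DataError

__all__ = [
    "wilcoxon_one_sample",
    "benjamini_hochberg",
    "summarize_modifications",
    "charge_state_profile",
    "CloudFit",
    "fit_ion_cloud",
    "attach_residuals",
    "GradientResult",
    "deltaccs_gradient",
    "CorrelationResult",
    "deltaccs_mass_correlation",
    "rank_concordance",
]

EXACT_WILCOXON_MAX_N = 25


def _signed_rank_statistic(values: np.ndarray) -> tuple[float, np.ndarray, int]:
    """W+ (sum of ranks of positive deviations), ranks, and n after zero removal."""
    nz = values[values != 0]
    n = nz.size
    if n == 0:
        return 0.0, np.empty(0), 0
    ranks = sps.rankdata(np.abs(nz))  # average ranks for ties
    w_plus = float(ranks[nz > 0].sum())
    return w_plus, ranks, n


def _exact_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by dynamic programming over all sign assignments.

    Works with tied (average) ranks: doubling makes all ranks integral,
    and the DP counts, over all 2^n equiprobable sign vectors, how many
    achieve each possible doubled W+.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_approx_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided normal approximation with tie correction and continuity correction."""
    n = ranks.size
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    d = w_plus - mu
    # continuity correction shrinks |d| by 0.5
    d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    z = d / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_one_sample(values, mu0: float = 0.0) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value against ``mu0``.

    Exact zeros (values equal to mu0) are dropped, classic-Wilcoxon
    style. For n <= 25 remaining deviations the exact null distribution
    is enumerated; above, a continuity-corrected normal approximation
    with tie correction is used. If nothing remains after zero removal,
    returns 1 with a warning.
    """
    values = np.asarray(values, dtype=float) - mu0
    w_plus, ranks, n = _signed_rank_statistic(values)
    if n == 0:
        warnings.warn("all values equal mu0; Wilcoxon p set to 1")
        return 1.0
    if n <= EXACT_WILCOXON_MAX_N:
        return _exact_two_sided_p(w_plus, ranks)
    return _normal_approx_p(w_plus, ranks)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def summarize_modifications(
    pairs: pd.DataFrame, mod_masses: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-modification summary over charge-2 and charge-3 pairs pooled.

    Columns: n_pairs_total, n_pairs_z2/n_pairs_z3, med (median relative
    CCS shift, percent), p_value (one-sample Wilcoxon of the pooled
    relative shifts against 0), q_value (BH across the modifications
    summarized in this call), median_delta_rt, and delta_mass when a
    mass table is given.
    """
    if pairs.empty:
        raise DataError("no pairs to summarize")
    rows = []
    for name, grp in pairs.groupby("modification_name", sort=True):
        deltas = grp["delta_ccs_rel"].to_numpy(dtype=float)
        by_charge = grp.groupby("charge").size()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = wilcoxon_one_sample(deltas)
        rows.append(
            {
                "modification_name": name,
                "n_pairs_total": int(len(grp)),
                "n_pairs_z2": int(by_charge.get(2, 0)),
                "n_pairs_z3": int(by_charge.get(3, 0)),
                "med": 100.0 * float(np.median(deltas)),
                "p_value": p,
                "median_delta_rt": float(grp["delta_rt"].median())
                if "delta_rt" in grp.columns
                else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    if mod_masses is not None:
        out["delta_mass"] = out["modification_name"].map(
            dict(zip(mod_masses["modification_name"], mod_masses["delta_mass"]))
        )
    elif "delta_mass" in pairs.columns:
        out["delta_mass"] = out["modification_name"].map(
            pairs.groupby("modification_name")["delta_mass"].first()
        )
    return out


def _has_internal_residue(sequence: str, residues: frozenset) -> bool:
    return any(ch in residues for ch in sequence[1:-1])


def charge_state_profile(
    records: pd.DataFrame,
    internal_residue_filter=None,
    weight_by_intensity: bool = False,
) -> pd.DataFrame:
    """Charge-state counts and fractions per modification.

    Consumes records before any charge filter. Fractions are count-based
    by default (``weight_by_intensity`` switches to intensity weights).
    ``internal_residue_filter`` keeps only sequences with at least one
    residue from the given set at a non-terminal position. Predominant
    charge is the argmax count; ties go to the lower charge.
    """
    df = records
    if internal_residue_filter:
        resset = frozenset(internal_residue_filter)
        df = df[df["sequence"].map(lambda s: _has_internal_residue(str(s), resset))]
    if df.empty:
        return pd.DataFrame(
            columns=["modification_name", "charge", "count", "fraction",
                     "predominant_charge"]
        )
    out = []
    for name, grp in df.groupby("modification_name", sort=True):
        if weight_by_intensity:
            counts = grp.groupby("charge")["intensity_max"].sum()
        else:
            counts = grp.groupby("charge").size().astype(float)
        total = counts.sum()
        # argmax with ties broken toward the lower charge
        best = counts.max()
        predominant = int(min(z for z in counts.index if counts[z] == best))
        for z in sorted(counts.index):
            out.append(
                {
                    "modification_name": name,
                    "charge": int(z),
                    "count": float(counts[z]),
                    "fraction": float(counts[z] / total),
                    "predominant_charge": predominant,
                }
            )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class CloudFit:
    """Per-charge linear CCS ~ m/z fit over unmodified peptides."""

    pool: str
    charge: int
    slope: float  # A^2 per Th
    intercept: float  # A^2
    residuals: pd.DataFrame  # sequence, residual (observed - fitted)


def fit_ion_cloud(
    unmodified: pd.DataFrame, charge: int, pool: str = "all"
) -> CloudFit:
    """OLS of mean CCS on m/z for unmodified records at one charge."""
    sub = unmodified[unmodified["charge"] == charge]
    if len(sub) < 3:
        raise DataError(
            f"ion-cloud fit for charge {charge} needs >= 3 records, got {len(sub)}"
        )
    mz = sub["mz"].to_numpy(dtype=float)
    ccs = sub["ccs_mean"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(mz, ccs, 1)
    resid = ccs - (intercept + slope * mz)
    residuals = pd.DataFrame({"sequence": sub["sequence"].to_numpy(), "residual": resid})
    return CloudFit(pool, int(charge), float(slope), float(intercept), residuals)


def attach_residuals(pairs: pd.DataFrame, clouds: list[CloudFit]) -> pd.DataFrame:
    """Add ``residual_unmodified`` to pairs from per-charge cloud fits."""
    lookup: dict[tuple[str, int], float] = {}
    for cloud in clouds:
        for seq, res in zip(cloud.residuals["sequence"], cloud.residuals["residual"]):
            lookup[(str(seq), cloud.charge)] = float(res)
    out = pairs.copy()
    out["residual_unmodified"] = [
        lookup.get((str(s), int(z)), float("nan"))
        for s, z in zip(out["sequence"], out["charge"])
    ]
    return out


@dataclass(frozen=True)
class GradientResult:
    modification_name: str
    charge: int
    gradient_slope: float
    intercept: float
    n_pairs: int
    standard_error: float


def deltaccs_gradient(
    pairs: pd.DataFrame, mode: str = "absolute"
) -> GradientResult | None:
    """Regress pairwise CCS shift on the unmodified peptide's cloud residual.

    ``pairs`` holds one modification at one charge with
    ``residual_unmodified`` filled in. By default the ABSOLUTE shift
    (A^2) is regressed on the residual (A^2), making the slope
    dimensionless; ``mode="relative"`` regresses the relative shift.
    Returns None (with a warning) below 3 usable pairs.
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"unknown gradient mode {mode!r}")
    ycol = "delta_ccs_abs" if mode == "absolute" else "delta_ccs_rel"
    sub = pairs.dropna(subset=["residual_unmodified", ycol])
    names = sub["modification_name"].unique() if len(sub) else []
    charges = sub["charge"].unique() if len(sub) else []
    if len(names) > 1 or len(charges) > 1:
        raise ValueError("deltaccs_gradient expects one modification at one charge")
    if len(sub) < 3:
        warnings.warn("fewer than 3 pairs with residuals; gradient not reported")
        return None
    x = sub["residual_unmodified"].to_numpy(dtype=float)
    y = sub[ycol].to_numpy(dtype=float)
    fit = sps.linregress(x, y)
    return GradientResult(
        modification_name=str(names[0]),
        charge=int(charges[0]),
        gradient_slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=int(len(sub)),
        standard_error=float(fit.stderr),
    )


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    r_squared: float
    n_modifications: int
    exclusions: tuple


def deltaccs_mass_correlation(
    summaries: pd.DataFrame, x: str = "delta_mass", exclude=()
) -> CorrelationResult:
    """Squared Pearson correlation of MED with delta-mass or median delta-RT."""
    if x not in summaries.columns:
        raise ValueError(f"column {x!r} not in summaries")
    sub = summaries[~summaries["modification_name"].isin(set(exclude))]
    sub = sub.dropna(subset=[x, "med"])
    if len(sub) < 3:
        raise DataError("correlation needs >= 3 modifications after exclusion")
    r, _ = sps.pearsonr(sub["med"], sub[x])
    return CorrelationResult(
        x_name=x,
        r_squared=float(r**2),
        n_modifications=int(len(sub)),
        exclusions=tuple(exclude),
    )


def rank_concordance(
    pairs_a: pd.DataFrame, pairs_b: pd.DataFrame
) -> tuple[float, int] | None:
    """Spearman rho of per-sequence absolute CCS shifts between two modifications.

    Computed on the intersection of sequences; returns (rho, n) or None
    with a warning when fewer than 3 sequences are shared.
    """
    a = pairs_a.set_index("sequence")["delta_ccs_abs"]
    b = pairs_b.set_index("sequence")["delta_ccs_abs"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        warnings.warn("fewer than 3 shared sequences; concordance not reported")
        return None
    rho, _ = sps.spearmanr(a.loc[shared], b.loc[shared])
    return float(rho), int(len(shared))
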
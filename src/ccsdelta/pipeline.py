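"""End-to-end orchestration: align -> convert -> filter -> pair -> stats.

The stage order is fixed: run-wise 1/K0 and RT alignment happens on the
mobility scale, CCS conversion strictly afterwards, then filtering,
per-run top-evidence selection, replicate aggregation, pair matching and
the modification-level statistics. Disabling alignment (for before/after
precision comparisons) is the only permitted deviation. All randomness
lives in the synthetic generator; given identical inputs and config the
pipeline is deterministic.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import alignment, pairs as pairing, selection, stats
from .io import (
    ColumnMap,
    ConfigError,
    MAXQUANT_COLUMN_MAP,
    read_evidence_table,
    read_mod_masses,
    read_reference_table,
    write_table,
)
from .physics import DEFAULT_CONSTANTS, PhysicalConstants, ccs_from_inverse_mobility

__all__ = ["PipelineConfig", "run_pipeline", "run_frames"]


@dataclass(frozen=True)
class PipelineConfig:
    evidence: tuple = ()  # one or more evidence TSV paths
    references: str = ""
    mod_masses: str = ""
    out_dir: str = "ccsdelta_out"
    column_map: ColumnMap = field(default_factory=ColumnMap)
    align: bool = True
    min_refs: int = 3
    constants: PhysicalConstants = DEFAULT_CONSTANTS
    filter_rules: selection.FilterRules = field(default_factory=selection.FilterRules)
    gradient_mode: str = "absolute"
    intensity_weighted_profile: bool = False
    drop_reference_pool: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cmap = raw.get("column_map", {})
            if cmap == "maxquant":
                column_map = MAXQUANT_COLUMN_MAP
            else:
                column_map = ColumnMap(dict(cmap))
            fr = raw.get("filter", {})
            rules = selection.FilterRules(
                allowed_charges=frozenset(fr.get("allowed_charges", [2, 3])),
                exclude_cterm_mod=bool(fr.get("exclude_cterm_mod", True)),
                exclude_oxidized=bool(fr.get("exclude_oxidized", True)),
                require_single_site=bool(fr.get("require_single_site", True)),
            )
            constants = PhysicalConstants(
                temperature=float(raw.get("temperature", 305.0)),
                gas_mass=float(raw.get("gas_mass", 28.013406)),
            )
            evidence = raw.get("evidence", [])
            if isinstance(evidence, str):
                evidence = [evidence]
            return cls(
                evidence=tuple(evidence),
                references=raw.get("references", ""),
                mod_masses=raw.get("mod_masses", ""),
                out_dir=raw.get("out_dir", "ccsdelta_out"),
                column_map=column_map,
                align=bool(raw.get("align", True)),
                min_refs=int(raw.get("min_refs", 3)),
                constants=constants,
                filter_rules=rules,
                gradient_mode=str(raw.get("gradient_mode", "absolute")),
                intensity_weighted_profile=bool(
                    raw.get("intensity_weighted_profile", False)
                ),
            )
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


def _header_comments(constants: PhysicalConstants) -> list[str]:
    return [
        f"temperature_K={constants.temperature}",
        f"gas_mass_Da={constants.gas_mass}",
        "gas=N2 loschmidt_density=273.15K/1atm",
    ]


def run_frames(
    evidence: pd.DataFrame,
    refs: pd.DataFrame,
    mod_masses: pd.DataFrame,
    *,
    align: bool = True,
    min_refs: int = 3,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    filter_rules: selection.FilterRules | None = None,
    gradient_mode: str = "absolute",
    intensity_weighted_profile: bool = False,
    drop_reference_pool: bool = True,
) -> dict:
    """Run all stages on in-memory tables; returns a result-bundle dict.

    This is the programmatic core used by both the CLI and the tests;
    :func:`run_pipeline` wraps it with file I/O.
    """
    filter_rules = filter_rules or selection.FilterRules()
    report: dict = {"n_rows_in": int(len(evidence))}

    # stage 1: run-wise alignment on the 1/K0 and RT scales
    if align:
        corrections = alignment.compute_corrections(evidence, refs, min_refs)
        aligned, n_dropped = alignment.apply_corrections(evidence, corrections)
        report["n_unalignable_runs"] = sum(not c.alignable for c in corrections)
        report["n_features_dropped_unalignable"] = n_dropped
    else:
        corrections = []
        aligned = evidence.copy()
    report["n_runs"] = int(aligned["run_id"].nunique())

    # stage 2: CCS conversion (always after alignment, never before)
    aligned = aligned.copy()
    aligned["ccs"] = ccs_from_inverse_mobility(
        aligned["inv_k0"].to_numpy(),
        aligned["charge"].to_numpy(),
        aligned["mz"].to_numpy(),
        constants,
    )

    if drop_reference_pool and "pool" in aligned.columns:
        analysis = aligned[aligned["pool"] != "reference"]
    else:
        analysis = aligned

    # stage 3+4: filters, then per-run top-evidence selection
    filtered, drop_counts = selection.filter_features(analysis, filter_rules)
    report["filter_drop_counts"] = drop_counts
    top = selection.select_top_evidence(filtered)
    report["n_after_top_selection"] = int(len(top))

    # precision on replicate runs (complete peptides), when possible
    precision = None
    if report["n_runs"] >= 2:
        try:
            precision = alignment.precision_summary(top, require_complete=True)
            report["median_cv_pct"] = precision.median_cv
            report["completeness_fraction"] = precision.completeness_fraction
        except Exception as exc:  # small fixtures may have no complete peptide
            warnings.warn(f"precision summary unavailable: {exc}")

    # stage 5: replicate aggregation
    records = selection.aggregate_replicates(top)
    report["n_records"] = int(len(records))

    # charge profile consumes pre-charge-filter data
    wide_rules = dataclasses.replace(
        filter_rules,
        allowed_charges=frozenset(analysis["charge"].unique().tolist() or [2]),
    )
    prof_feats, _ = selection.filter_features(analysis, wide_rules)
    prof_records = selection.aggregate_replicates(
        selection.select_top_evidence(prof_feats)
    )
    profile = stats.charge_state_profile(
        prof_records, weight_by_intensity=intensity_weighted_profile
    )

    # stage 6: pair matching
    is_mod = records["modification_name"] != "Unmodified"
    modified, unmodified = records[is_mod], records[~is_mod]
    pairs, n_unmatched = pairing.match_pairs(modified, unmodified)
    report["n_pairs"] = int(len(pairs))
    report["n_unmatched_modified"] = int(n_unmatched)
    if not pairs.empty:
        pairs = pairing.compute_deltas(pairs, mod_masses)

    # stage 7: statistics
    summary = stats.summarize_modifications(pairs, mod_masses) if len(pairs) else None

    clouds = []
    for charge in sorted(unmodified["charge"].unique()):
        try:
            clouds.append(stats.fit_ion_cloud(unmodified, int(charge)))
        except Exception as exc:
            warnings.warn(f"cloud fit skipped for charge {charge}: {exc}")
    if len(pairs) and clouds:
        pairs = stats.attach_residuals(pairs, clouds)

    gradients = []
    if len(pairs) and clouds:
        for (name, charge), grp in pairs.groupby(["modification_name", "charge"]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g = stats.deltaccs_gradient(grp, mode=gradient_mode)
            if g is not None:
                gradients.append(g)

    correlations = []
    if summary is not None and len(summary) >= 3:
        for x in ("delta_mass", "median_delta_rt"):
            if x in summary.columns and summary[x].notna().all():
                correlations.append(stats.deltaccs_mass_correlation(summary, x=x))
        if "delta_mass" in summary.columns and len(summary) >= 5:
            heavy = summary.nlargest(2, "delta_mass")["modification_name"]
            correlations.append(
                stats.deltaccs_mass_correlation(
                    summary, x="delta_mass", exclude=tuple(heavy)
                )
            )

    concordance = []
    if len(pairs):
        for charge, grp in pairs.groupby("charge"):
            by_mod = dict(tuple(grp.groupby("modification_name")))
            for a, b in itertools.combinations(sorted(by_mod), 2):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = stats.rank_concordance(by_mod[a], by_mod[b])
                if res is not None:
                    concordance.append(
                        {
                            "modification_a": a,
                            "modification_b": b,
                            "charge": int(charge),
                            "spearman_rho": res[0],
                            "n_shared": res[1],
                        }
                    )

    return {
        "corrections": corrections,
        "aligned": aligned,
        "records": records,
        "precision": precision,
        "pairs": pairs,
        "summary": summary,
        "charge_profile": profile,
        "clouds": clouds,
        "gradients": gradients,
        "correlations": correlations,
        "concordance": pd.DataFrame(concordance),
        "report": report,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline run; writes all result tables into ``out_dir``."""
    if not config.evidence:
        raise ConfigError("pipeline config lists no evidence tables")
    frames = []
    all_rejects = []
    for path in config.evidence:
        df, rejects = read_evidence_table(path, config.column_map)
        frames.append(df)
        all_rejects.extend((path, r) for r in rejects)
    evidence = pd.concat(frames, ignore_index=True)
    refs = read_reference_table(config.references)
    masses = read_mod_masses(config.mod_masses)

    results = run_frames(
        evidence,
        refs,
        masses,
        align=config.align,
        min_refs=config.min_refs,
        constants=config.constants,
        filter_rules=config.filter_rules,
        gradient_mode=config.gradient_mode,
        intensity_weighted_profile=config.intensity_weighted_profile,
        drop_reference_pool=config.drop_reference_pool,
    )
    results["report"]["n_rejected_rows"] = len(all_rejects)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comments = _header_comments(config.constants)

    def emit(name: str, obj) -> None:
        if obj is None or (hasattr(obj, "empty") and obj.empty):
            return
        write_table(obj, out / f"{name}.tsv", header_comments=comments)

    emit("records", results["records"])
    emit("pairs", results["pairs"])
    emit("summary", results["summary"])
    emit("charge_profile", results["charge_profile"])
    emit("concordance", results["concordance"])
    if results["corrections"]:
        emit(
            "run_corrections",
            pd.DataFrame([dataclasses.asdict(c) for c in results["corrections"]]),
        )
    if results["gradients"]:
        emit(
            "gradients",
            pd.DataFrame([dataclasses.asdict(g) for g in results["gradients"]]),
        )
    if results["correlations"]:
        emit(
            "correlations",
            pd.DataFrame(
                [
                    {
                        "x_name": c.x_name,
                        "r_squared": c.r_squared,
                        "n_modifications": c.n_modifications,
                        "exclusions": ";".join(c.exclusions),
                    }
                    for c in results["correlations"]
                ]
            ),
        )
    if results["clouds"]:
        emit(
            "cloud_fits",
            pd.DataFrame(
                [
                    {
                        "pool": c.pool,
                        "charge": c.charge,
                        "slope": c.slope,
                        "intercept": c.intercept,
                        "n_peptides": len(c.residuals),
                    }
                    for c in results["clouds"]
                ]
            ),
        )
    if results["precision"] is not None:
        emit("precision_per_peptide", results["precision"].per_peptide)

    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(results["report"], fh, indent=2, sort_keys=True)
    with open(out / "config_used.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "evidence": list(config.evidence),
                "references": config.references,
                "mod_masses": config.mod_masses,
                "align": config.align,
                "min_refs": config.min_refs,
                "temperature": config.constants.temperature,
                "gas_mass": config.constants.gas_mass,
                "filter": {
                    "allowed_charges": sorted(config.filter_rules.allowed_charges),
                    "exclude_cterm_mod": config.filter_rules.exclude_cterm_mod,
                    "exclude_oxidized": config.filter_rules.exclude_oxidized,
                    "require_single_site": config.filter_rules.require_single_site,
                },
                "gradient_mode": config.gradient_mode,
                "intensity_weighted_profile": config.intensity_weighted_profile,
            },
            fh,
            sort_keys=False,
        )
    return results
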
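"""Synthetic evidence-table generator with retrievable ground truth.

Emulates the statistical structure the pipeline assumes: per-charge
CCS-vs-m/z ion clouds, per-sequence residual structure shared across
modifications, modification-specific median CCS shifts and
residual-correlated gradients, additive per-run drift on 1/K0 and RT,
multiplicative (CV-style) measurement noise on CCS, replicate
missingness, and spiked reference peptides in every run.

The generative model per sequence and charge z:

    ccs_unmod = intercept_z + slope_z * mz + residual(seq, z)
    ccs_mod   = ccs_unmod * (1 + shift_mod) + gradient_mod * residual + eta

and per run: observed ccs = true ccs * (1 + eps), eps ~ N(0, noise_cv);
observed 1/K0 = mason_schamp_inverse(observed ccs) + drift_run.

Everything is deterministic given (config, seed); latent draws and
observation noise use independent seeded streams so `ground_truth`
can reproduce the latents without generating observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import INV_K0_WINDOW
from .physics import DEFAULT_CONSTANTS, PhysicalConstants, inverse_mobility_from_ccs

__all__ = [
    "ModSpec",
    "CloudSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_pools",
    "ground_truth",
    "mod_mass_table",
    "reference_table",
]

PROTON_MASS = 1.00727646688  # Da
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ModSpec:
    """Ground-truth parameters for one modification."""

    name: str
    delta_mass: float  # Da
    target_residue: str  # single letter; the site residue in generated sequences
    shift: float  # true median relative CCS shift (fraction)
    gradient: float = 0.0  # true slope of absolute shift vs cloud residual
    extra_sd: float = 2.0  # per-(sequence, mod) scatter on modified CCS, A^2
    charge2_prob: float = 0.6
    rt_shift: float = 0.0  # minutes


@dataclass(frozen=True)
class CloudSpec:
    """Per-charge linear CCS-vs-m/z cloud."""

    slope: float  # A^2 per Th
    intercept: float  # A^2
    residual_sd: float  # A^2


# Plausible truth values spanning the observed shift range (about -1 to +5 %)
# and both gradient signs; these are generator defaults, not measurements.
DEFAULT_MODS: tuple = (
    ModSpec("Methyl (K)", 14.01565, "K", 0.000, -0.05, charge2_prob=0.45),
    ModSpec("Dimethyl (K)", 28.03130, "K", 0.002, -0.05, charge2_prob=0.40),
    ModSpec("Trimethyl (K)", 42.04695, "K", 0.004, 0.10, charge2_prob=0.40),
    ModSpec("Acetyl (K)", 42.01057, "K", -0.002, -0.20, charge2_prob=0.90),
    ModSpec("Formyl (K)", 27.99491, "K", -0.012, -0.25, charge2_prob=0.90),
    ModSpec("Propionyl (K)", 56.02621, "K", 0.003, -0.22, charge2_prob=0.90),
    ModSpec("Butyryl (K)", 70.04186, "K", 0.008, -0.20, charge2_prob=0.90),
    ModSpec("Crotonyl (K)", 68.02621, "K", 0.006, -0.20, charge2_prob=0.90),
    ModSpec("Malonyl (K)", 86.00039, "K", -0.005, -0.30, charge2_prob=0.92),
    ModSpec("Succinyl (K)", 100.01604, "K", 0.000, -0.30, charge2_prob=0.92),
    ModSpec("Glutaryl (K)", 114.03169, "K", 0.005, -0.28, charge2_prob=0.92),
    ModSpec("Hydroxyisobutyryl (K)", 86.03678, "K", 0.014, -0.18, charge2_prob=0.90),
    ModSpec("Biotinyl (K)", 226.07760, "K", 0.043, -0.10, charge2_prob=0.92),
    ModSpec("GlyGly (K)", 114.04293, "K", 0.015, 0.12, charge2_prob=0.35),
    ModSpec("Methyl (R)", 14.01565, "R", 0.001, 0.05, charge2_prob=0.50),
    ModSpec("Dimethyl sym (R)", 28.03130, "R", 0.002, 0.05, charge2_prob=0.50),
    ModSpec("Dimethyl asym (R)", 28.03130, "R", 0.003, 0.05, charge2_prob=0.50),
    ModSpec("Citrullination (R)", 0.98402, "R", -0.008, -0.15, charge2_prob=0.85),
    ModSpec("Phospho (Y)", 79.96633, "Y", -0.010, -0.10, charge2_prob=0.60),
    ModSpec("Nitro (Y)", 44.98508, "Y", 0.002, -0.05, charge2_prob=0.60),
    ModSpec("Hydroxyproline (P)", 15.99491, "P", 0.001, 0.00, charge2_prob=0.60),
    ModSpec("O-GlcNAc (S)", 203.07937, "S", 0.045, -0.05, charge2_prob=0.60),
)

# Biognosys-style 11-peptide reference standard (doubly protonated),
# mobilities spread over the cloud and elution over the gradient.
DEFAULT_REFERENCES: tuple = (
    ("LGGNEQVTR", 0.780, 10.0),
    ("GAGSSEPVTGLDAK", 0.820, 20.0),
    ("VEATFGVDESNAK", 0.850, 30.0),
    ("YILAGVENSK", 0.875, 40.0),
    ("TPVISGGPYEYR", 0.905, 50.0),
    ("TPVITGAPYEYR", 0.930, 60.0),
    ("DGLDAASYYAPVR", 0.955, 70.0),
    ("ADVTPADFSEWSK", 0.985, 80.0),
    ("GTFIIDPGGVIR", 1.010, 90.0),
    ("GTFIIDPAAVIR", 1.040, 100.0),
    ("LFLQFGAQGSPFLK", 1.080, 110.0),
)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_sequences: int = 25  # per target-residue group
    n_runs: int = 3
    mods: Sequence[ModSpec] = DEFAULT_MODS
    clouds: dict = field(
        default_factory=lambda: {
            2: CloudSpec(slope=0.45, intercept=140.0, residual_sd=15.0),
            3: CloudSpec(slope=0.50, intercept=320.0, residual_sd=15.0),
        }
    )
    mass_range: tuple = (850.0, 1300.0)  # Da, unmodified monoisotopic-like mass
    drift_inv_k0_sd: float = 0.01  # Vs cm^-2
    drift_rt_sd: float = 0.3  # min
    noise_cv: float = 0.0025  # multiplicative CCS noise, fraction
    rt_noise_sd: float = 0.05  # min
    missing_prob: float = 0.1
    references: Sequence = DEFAULT_REFERENCES
    intensity_log_mean: float = 12.0
    intensity_log_sd: float = 1.0
    constants: PhysicalConstants = DEFAULT_CONSTANTS
    pool: str = "pool1"

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValueError("SyntheticConfig.n_runs must be >= 1")
        if self.n_sequences < 1:
            raise ValueError("SyntheticConfig.n_sequences must be >= 1")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("SyntheticConfig.missing_prob must be in [0, 1]")
        for name in ("drift_inv_k0_sd", "drift_rt_sd", "noise_cv", "rt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"SyntheticConfig.{name} must be >= 0")
        for m in self.mods:
            if not 0.0 <= m.charge2_prob <= 1.0:
                raise ValueError(f"charge2_prob out of [0, 1] for {m.name}")
            if m.extra_sd < 0:
                raise ValueError(f"extra_sd must be >= 0 for {m.name}")
        for z, cloud in self.clouds.items():
            if cloud.residual_sd < 0:
                raise ValueError(f"residual_sd must be >= 0 for charge {z}")
        if len(self.references) < 1:
            raise ValueError("SyntheticConfig.references must be non-empty")


@dataclass(frozen=True)
class GroundTruth:
    run_drifts: pd.DataFrame  # run_id, drift_inv_k0, drift_rt
    sequence_residuals: pd.DataFrame  # sequence, charge, residual
    mod_truth: pd.DataFrame  # modification_name, shift, gradient, ...
    true_ccs: pd.DataFrame  # sequence, modification_name, charge, mz, ccs_true, rt_true


def mod_mass_table(config: SyntheticConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "modification_name": [m.name for m in config.mods],
            "delta_mass": [m.delta_mass for m in config.mods],
            "target_residue": [m.target_residue for m in config.mods],
        }
    )


def reference_table(config: SyntheticConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sequence": seq, "ref_inv_k0": ik0, "ref_rt": rt, "charge": 2}
            for seq, ik0, rt in config.references
        ]
    )


def _random_sequences(rng, n, residue):
    """Tryptic-looking sequences with the target residue at an internal site."""
    seqs = {}
    while len(seqs) < n:
        length = int(rng.integers(8, 15))
        letters = rng.choice(list(AMINO_ACIDS), size=length)
        site = int(rng.integers(2, length))  # 1-based, internal (never terminal)
        letters[site - 1] = residue
        letters[-1] = "K" if rng.random() < 0.5 else "R"
        seq = "".join(letters)
        if seq not in seqs:
            seqs[seq] = site
    return list(seqs.items())


def _latents(config: SyntheticConfig):
    """All latent draws, from a stream independent of observation noise."""
    rng = np.random.default_rng([int(config.seed), 0])
    charges = sorted(config.clouds)

    groups = sorted({m.target_residue for m in config.mods})
    seq_rows = []
    for residue in groups:
        for seq, site in _random_sequences(rng, config.n_sequences, residue):
            seq_rows.append({"sequence": seq, "site": site, "group": residue})
    sequences = pd.DataFrame(seq_rows)
    lo, hi = config.mass_range
    sequences["mass"] = rng.uniform(lo, hi, size=len(sequences))
    sequences["rt_true"] = rng.uniform(10.0, 110.0, size=len(sequences))

    resid_rows = []
    for z in charges:
        sd = config.clouds[z].residual_sd
        for seq in sequences["sequence"]:
            resid_rows.append(
                {"sequence": seq, "charge": z, "residual": rng.normal(0.0, sd)}
            )
    residuals = pd.DataFrame(resid_rows)
    resid_of = {(r.sequence, r.charge): r.residual for r in residuals.itertuples()}

    # per (mod, sequence): observed charge state and idiosyncratic scatter
    entity_rows = []
    for m in config.mods:
        members = sequences[sequences["group"] == m.target_residue]
        for row in members.itertuples():
            z = 2 if rng.random() < m.charge2_prob else 3
            eta = rng.normal(0.0, m.extra_sd)
            entity_rows.append(
                {
                    "sequence": row.sequence,
                    "modification_name": m.name,
                    "mod_position": row.site,
                    "charge": z,
                    "eta": eta,
                }
            )
    mod_entities = pd.DataFrame(entity_rows)

    run_ids = [f"run{str(i + 1).zfill(2)}" for i in range(config.n_runs)]
    drifts = pd.DataFrame(
        {
            "run_id": run_ids,
            "drift_inv_k0": rng.normal(0.0, config.drift_inv_k0_sd, config.n_runs),
            "drift_rt": rng.normal(0.0, config.drift_rt_sd, config.n_runs),
        }
    )
    return sequences, residuals, resid_of, mod_entities, drifts


def _true_tables(config: SyntheticConfig, sequences, resid_of, mod_entities):
    """True CCS / m/z / RT for every (sequence, modification, charge) entity."""
    mods_by_name = {m.name: m for m in config.mods}
    charges = sorted(config.clouds)
    rows = []
    for row in sequences.itertuples():
        for z in charges:
            mz = (row.mass + z * PROTON_MASS) / z
            cloud = config.clouds[z]
            ccs = cloud.intercept + cloud.slope * mz + resid_of[(row.sequence, z)]
            rows.append(
                {
                    "sequence": row.sequence,
                    "modification_name": "Unmodified",
                    "mod_position": np.nan,
                    "charge": z,
                    "mz": mz,
                    "ccs_true": ccs,
                    "rt_true": row.rt_true,
                }
            )
    unmod = pd.DataFrame(rows)
    unmod_ccs = {
        (r.sequence, r.charge): r.ccs_true for r in unmod.itertuples()
    }

    seq_info = sequences.set_index("sequence")
    rows = []
    for e in mod_entities.itertuples():
        m = mods_by_name[e.modification_name]
        mass = seq_info.at[e.sequence, "mass"]
        mz = (mass + m.delta_mass + e.charge * PROTON_MASS) / e.charge
        base = unmod_ccs[(e.sequence, e.charge)]
        resid = resid_of[(e.sequence, e.charge)]
        ccs = base * (1.0 + m.shift) + m.gradient * resid + e.eta
        rows.append(
            {
                "sequence": e.sequence,
                "modification_name": m.name,
                "mod_position": e.mod_position,
                "charge": e.charge,
                "mz": mz,
                "ccs_true": ccs,
                "rt_true": seq_info.at[e.sequence, "rt_true"] + m.rt_shift,
            }
        )
    modified = pd.DataFrame(rows)
    return pd.concat([unmod, modified], ignore_index=True)


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Every latent used by :func:`generate_pools` for the same config."""
    config.validate()
    sequences, residuals, resid_of, mod_entities, drifts = _latents(config)
    true_ccs = _true_tables(config, sequences, resid_of, mod_entities)
    mod_truth = pd.DataFrame(
        {
            "modification_name": [m.name for m in config.mods],
            "target_residue": [m.target_residue for m in config.mods],
            "delta_mass": [m.delta_mass for m in config.mods],
            "shift": [m.shift for m in config.mods],
            "gradient": [m.gradient for m in config.mods],
            "extra_sd": [m.extra_sd for m in config.mods],
            "charge2_prob": [m.charge2_prob for m in config.mods],
            "rt_shift": [m.rt_shift for m in config.mods],
        }
    )
    return GroundTruth(
        run_drifts=drifts,
        sequence_residuals=residuals,
        mod_truth=mod_truth,
        true_ccs=true_ccs,
    )


def _modified_sequence(sequence: str, mod_name: str, position) -> str:
    if mod_name == "Unmodified" or not np.isfinite(position):
        return sequence
    p = int(position)
    return f"{sequence[:p]}({mod_name}){sequence[p:]}"


def generate_pools(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the full multi-run evidence table and its ground truth.

    The returned evidence DataFrame uses the canonical column names and
    passes ``read_evidence_table`` unchanged after a write/read cycle.
    Generated 1/K0 values are checked against the acquisition window;
    out-of-window values raise instead of being clipped.
    """
    config.validate()
    truth = ground_truth(config)
    rng = np.random.default_rng([int(config.seed), 1])

    entities = truth.true_ccs.reset_index(drop=True)
    n_ent = len(entities)
    n_runs = config.n_runs
    drifts = truth.run_drifts

    mod_seq = [
        _modified_sequence(s, m, p)
        for s, m, p in zip(
            entities["sequence"], entities["modification_name"],
            entities["mod_position"],
        )
    ]

    rows = []
    # observation noise drawn entity-major so the stream is reproducible
    eps = rng.normal(0.0, config.noise_cv, size=(n_ent, n_runs))
    rt_eps = rng.normal(0.0, config.rt_noise_sd, size=(n_ent, n_runs))
    present = rng.random(size=(n_ent, n_runs)) >= config.missing_prob
    log_int = rng.normal(
        config.intensity_log_mean, config.intensity_log_sd, size=(n_ent, n_runs)
    )
    for i, e in enumerate(entities.itertuples()):
        for j in range(n_runs):
            if not present[i, j]:
                continue
            ccs_obs = e.ccs_true * (1.0 + eps[i, j])
            inv_k0 = (
                inverse_mobility_from_ccs(ccs_obs, e.charge, e.mz, config.constants)
                + drifts.at[j, "drift_inv_k0"]
            )
            rows.append(
                {
                    "run_id": drifts.at[j, "run_id"],
                    "sequence": e.sequence,
                    "modified_sequence": mod_seq[i],
                    "modification_name": e.modification_name,
                    "mod_position": e.mod_position,
                    "n_mod_sites": 0 if e.modification_name == "Unmodified" else 1,
                    "charge": int(e.charge),
                    "mz": e.mz,
                    "inv_k0": inv_k0,
                    "rt": e.rt_true + drifts.at[j, "drift_rt"] + rt_eps[i, j],
                    "intensity": float(np.exp(log_int[i, j])),
                    "pool": config.pool,
                }
            )

    # reference peptides present in every run
    ref_eps = rng.normal(0.0, config.noise_cv, size=(len(config.references), n_runs))
    ref_rt_eps = rng.normal(
        0.0, config.rt_noise_sd, size=(len(config.references), n_runs)
    )
    ref_int = rng.normal(
        config.intensity_log_mean, config.intensity_log_sd,
        size=(len(config.references), n_runs),
    )
    for i, (seq, ref_ik0, ref_rt) in enumerate(config.references):
        mz = 450.0 + 30.0 * i  # nominal; refs are matched by sequence, not m/z
        for j in range(n_runs):
            rows.append(
                {
                    "run_id": drifts.at[j, "run_id"],
                    "sequence": seq,
                    "modified_sequence": seq,
                    "modification_name": "Unmodified",
                    "mod_position": np.nan,
                    "n_mod_sites": 0,
                    "charge": 2,
                    "mz": mz,
                    "inv_k0": ref_ik0 * (1.0 + ref_eps[i, j])
                    + drifts.at[j, "drift_inv_k0"],
                    "rt": ref_rt + drifts.at[j, "drift_rt"] + ref_rt_eps[i, j],
                    "intensity": float(np.exp(ref_int[i, j])),
                    "pool": "reference",
                }
            )

    evidence = pd.DataFrame(rows)
    lo, hi = INV_K0_WINDOW
    bad = (evidence["inv_k0"] < lo) | (evidence["inv_k0"] > hi)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} generated 1/K0 values fall outside the "
            f"acquisition window [{lo}, {hi}] "
            f"(range {evidence['inv_k0'].min():.3f}-{evidence['inv_k0'].max():.3f}); "
            "adjust cloud/mass/drift settings instead of clipping"
        )
    return evidence, truth
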
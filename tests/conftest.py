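import numpy as np
import pandas as pd
import pytest

from ccsdelta.simulate import (
    CloudSpec,
    ModSpec,
    SyntheticConfig,
    generate_pools,
    mod_mass_table,
    reference_table,
)


def make_features(rows):
    """Build a canonical evidence frame from a list of dicts with defaults."""
    defaults = {
        "run_id": "run01",
        "sequence": "PEPTIKDER",
        "modified_sequence": "PEPTIKDER",
        "modification_name": "Unmodified",
        "mod_position": np.nan,
        "n_mod_sites": 0,
        "charge": 2,
        "mz": 500.0,
        "inv_k0": 0.9,
        "rt": 30.0,
        "intensity": 1000.0,
    }
    return pd.DataFrame([{**defaults, **row} for row in rows])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


TWO_MODS = (
    ModSpec("Formyl (K)", 27.99491, "K", -0.012, -0.25, charge2_prob=0.9),
    ModSpec("Succinyl (K)", 100.01604, "K", 0.0, -0.30, charge2_prob=0.9),
)


def small_config(**overrides):
    base = dict(seed=7, n_sequences=15, n_runs=3, mods=TWO_MODS)
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    cfg = SyntheticConfig(seed=7, n_sequences=15, n_runs=3, mods=TWO_MODS)
    evidence, truth = generate_pools(cfg)
    return cfg, evidence, truth, reference_table(cfg), mod_mass_table(cfg)


def noise_free_config(shift=0.04, **overrides):
    mods = (
        ModSpec("Formyl (K)", 27.99491, "K", shift, 0.0, extra_sd=0.0),
    )
    base = dict(
        seed=3,
        n_sequences=10,
        n_runs=2,
        mods=mods,
        drift_inv_k0_sd=0.0,
        drift_rt_sd=0.0,
        noise_cv=0.0,
        rt_noise_sd=0.0,
        missing_prob=0.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
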
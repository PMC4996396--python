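"""Shared fixtures: tiny toys for oracle tests, bigger simulations reused
across the stochastic checks (session-scoped so each is generated once)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lungsig import SimulationConfig, combat_adjust, preprocess_spot_table, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_sim():
    """Six-run dataset under the planted-effect study conditions
    (2000 features, batch effects 0.5, session 0.5, 2% reactive at 1.0)."""
    cfg = SimulationConfig(n_features=2000, effect_log2=1.0, seed=20260926)
    spots, annotation, truth = simulate_dataset(cfg)
    matrix, _ = preprocess_spot_table(spots)
    return {"spots": spots, "annotation": annotation, "truth": truth, "matrix": matrix}


@pytest.fixture(scope="session")
def study_sim_combat(study_sim):
    return combat_adjust(study_sim["matrix"], study_sim["annotation"]["run"])


@pytest.fixture(scope="session")
def ordering_sim():
    """Dataset for the method-ordering checks: the study's assumed class
    difference log2(1.5) (so classification is not saturated) under strong
    batch effects (additive SD 1.0, ~2.4x the residual SD) — the regime the
    concordance criterion is about."""
    cfg = SimulationConfig(n_features=1500, batch_add_sd=1.0, seed=20260926)
    spots, annotation, truth = simulate_dataset(cfg)
    matrix, _ = preprocess_spot_table(spots)
    adjusted = combat_adjust(matrix, annotation["run"])
    return {"annotation": annotation, "truth": truth,
            "matrix": matrix, "combat": adjusted}


@pytest.fixture
def toy_matrix():
    """8 features x 6 arrays with visible class structure (first 3 arrays case)."""
    rng = np.random.default_rng(7)
    base = rng.normal(8, 1, (8, 6))
    base[0, :3] += 3.0
    base[1, :3] += 2.0
    return pd.DataFrame(
        base,
        index=[f"Ag{i:02d}" for i in range(8)],
        columns=[f"a{j}" for j in range(6)],
    )


@pytest.fixture
def toy_labels(toy_matrix):
    return pd.Series(
        ["case"] * 3 + ["control"] * 3, index=toy_matrix.columns
    )
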
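"""Shared fixtures: small pedigrees and a session-scoped social-model fit."""

from __future__ import annotations

import numpy as np
import pytest

from penmates.model import (GibbsConfig, ModelSpec, VarianceComponents,
                            build_design, gibbs_sampler)
from penmates.pedigree import build_pedigree, inverse_relationship_matrix
from penmates.simulate import SimulationParams, simulate_dataset


def random_pedigree(rng, n_founders=10, n_generations=3, per_gen=30):
    """Random discrete-generation pedigree records for property tests."""
    records = [(f"f{i}", 0, 0) for i in range(n_founders)]
    prev = [f"f{i}" for i in range(n_founders)]
    for g in range(1, n_generations):
        cur = []
        for i in range(per_gen):
            s, d = rng.choice(len(prev), size=2, replace=False)
            a = f"g{g}_{i}"
            records.append((a, prev[s], prev[d]))
            cur.append(a)
        prev = cur + prev[: n_founders // 2]
    return records


@pytest.fixture(scope="session")
def trio_pedigree():
    """Sire, dam (unrelated) and one offspring."""
    return build_pedigree([("S", 0, 0), ("D", 0, 0), ("O", "S", "D")])


def strong_ige_params(seed: int) -> SimulationParams:
    """Small study with a social variance large enough to matter:
    24 pens of ~10, sigma2_S about an eighth of sigma2_D."""
    vc = VarianceComponents(0.40, 0.05, -0.39 * np.sqrt(0.40 * 0.05),
                            0.10, 0.40)
    return SimulationParams(
        n_phenotyped=240, n_pens=24, pen_size_range=(9, 11), n_founders=40,
        n_generations=2, n_sires=12, n_dams=28, vc_true=vc,
        interaction_mode="OT", seed=seed)


@pytest.fixture(scope="session")
def small_ige_fit():
    """One strong-IGE dataset with a fitted pair-specific social model.

    Session-scoped: several evaluation tests read the same chains.
    """
    data = simulate_dataset(strong_ige_params(seed=81))
    ped = data.pedigree
    Ainv = inverse_relationship_matrix(ped)
    design = build_design(data.phenotypes, ModelSpec("AM_IGE_i", "OT"),
                          ped, data.C)
    chains = gibbs_sampler(design, Ainv,
                           GibbsConfig(8000, 2000, 5, seed=4))
    return {"data": data, "ped": ped, "Ainv": Ainv, "design": design,
            "chains": chains}
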
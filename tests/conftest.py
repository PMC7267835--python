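"""Shared fixtures: the canonical toy network and random branched fixtures.

All networks are generated programmatically; nothing is read from disk except
temporary files written by the IO tests themselves.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from nihba.fba import solve_fba
from nihba.model import make_toy_network

logging.getLogger("nihba").setLevel(logging.ERROR)
logging.getLogger("cobra").setLevel(logging.ERROR)

TOY5_FORMULAS = ["C3H4O3", "C3H7NO2", "C40H56"]  # A: pyruvate-like, C: lycopene-like


@pytest.fixture
def toy5():
    model = make_toy_network("toy5")
    model.formulas = list(TOY5_FORMULAS)
    return model


@pytest.fixture
def toy5_candidates(toy5):
    return (toy5.index("R1"), toy5.index("R3"))


def random_case(seed: int) -> dict:
    """Deterministic random fixture: model, candidate set, target, growth
    floor (10% of wild type) and knockout budget."""
    rng = np.random.default_rng(seed + 1000)
    n_branches = int(rng.integers(3, 6))
    coupled_fraction = float(rng.choice([0.25, 0.5, 0.75]))
    K = int(rng.integers(1, 4))
    model = make_toy_network(
        "random_branched",
        n_branches=n_branches,
        coupled_fraction=coupled_fraction,
        seed=seed,
    )
    candidates = tuple(
        j for j, r in enumerate(model.reaction_ids)
        if r not in ("UP", "BIO", "PRD")
    )
    wild = solve_fba(model)
    return {
        "model": model,
        "candidates": candidates,
        "target": model.index("PRD"),
        "growth_floor": 0.1 * wild.objective_value,
        "K": K,
        "wild_type_growth": float(wild.objective_value),
        "seed": seed,
    }


@pytest.fixture(params=range(5))
def random_fixture(request):
    return random_case(request.param)
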
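"""Shared fixtures: hand-built pedigrees and simulated populations."""

import numpy as np
import pytest

import tierblup as tb


@pytest.fixture
def trio():
    """Unrelated sire and dam with one offspring."""
    return tb.build_pedigree([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])


@pytest.fixture
def three_tier():
    """Grandparents g1..g4, parents p1, p2, offspring k1, k2."""
    return tb.build_pedigree(
        [
            ("g1", "0", "0"), ("g2", "0", "0"), ("g3", "0", "0"), ("g4", "0", "0"),
            ("p1", "g1", "g2"), ("p2", "g3", "g4"),
            ("k1", "p1", "p2"), ("k2", "p1", "p2"),
        ]
    )


def random_pedigree(rng, n_founders=10, n_offspring=40):
    """Random acyclic pedigree; later animals pick parents among earlier ones."""
    recs = [(f"f{i}", "0", "0") for i in range(n_founders)]
    labels = [r[0] for r in recs]
    for i in range(n_offspring):
        k = len(labels)
        s = labels[rng.integers(k)]
        d = labels[rng.integers(k)]
        if s == d:
            d = "0"
        lab = f"x{i}"
        recs.append((lab, s, d))
        labels.append(lab)
    return tb.build_pedigree(recs)


@pytest.fixture(scope="session")
def small_pop():
    """Small closed-nucleus population (≈150 animals) reused across tests."""
    cfg = tb.SimulationConfig(
        n_founders=16, generations_nucleus=2, n_matings_nucleus=12,
        n_matings_commercial=10, offspring_per_mating=2,
        offspring_per_mating_commercial=3, seed=11,
    )
    return tb.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_pop_cov():
    """Small population with a shared covariate in both tiers' models."""
    cfg = tb.SimulationConfig(
        n_founders=16, generations_nucleus=2, n_matings_nucleus=12,
        n_matings_commercial=10, offspring_per_mating=2,
        offspring_per_mating_commercial=3, covariate_coef=1.2, seed=13,
    )
    return tb.simulate_population(cfg)


def simulated_partitions(n, max_seed_offset=0):
    """Yield n (pedigree, partition) pairs from varied small simulations."""
    out = []
    for s in range(n):
        cfg = tb.SimulationConfig(
            n_founders=8 + (s % 5), generations_nucleus=1 + (s % 3),
            n_matings_nucleus=6 + (s % 4), n_matings_commercial=5,
            offspring_per_mating=2, offspring_per_mating_commercial=2,
            generations_commercial=1 + (s % 2),
            selection="none" if s % 2 else "phenotype",
            seed=1000 + s,
        )
        pop = tb.simulate_population(cfg)
        assert pop.ped.n <= 200
        out.append(pop)
    return out
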
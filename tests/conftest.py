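"""Shared fixtures: the worked example graph, small tables, random graphs."""

from __future__ import annotations

import numpy as np
import pytest

from trajkg import DirectionalityTable, KnowledgeGraph, Triple


@pytest.fixture(scope="session")
def small_table() -> DirectionalityTable:
    """Minimal directionality table covering the worked-example predicates."""
    return DirectionalityTable({
        "binds with": "undirected",
        "interacts with": "undirected",
        "inhibits": "directed",
        "stimulates": "directed",
        "catalysis precedes": "directed",
    })


@pytest.fixture(scope="session")
def default_table() -> DirectionalityTable:
    return DirectionalityTable.default()


@pytest.fixture
def example_kg() -> KnowledgeGraph:
    """The schematic two-disease example: a shared homodimerizing protein,
    one direct inhibition, and one two-step inhibition chain through an
    intermediate protein."""
    return KnowledgeGraph([
        Triple("DP1", "binds with", "DP1"),
        Triple("DP2", "inhibits", "DP4"),
        Triple("DP3", "inhibits", "IP"),
        Triple("IP", "inhibits", "DP5"),
    ])


@pytest.fixture
def example_sets() -> tuple[set, set]:
    return {"DP1", "DP2", "DP3"}, {"DP1", "DP4", "DP5"}


def random_graph(
    rng: np.random.Generator,
    n_proteins: int = 20,
    n_triples: int = 60,
    predicates: tuple[str, ...] = ("inhibits", "binds with", "stimulates"),
    self_loop_frac: float = 0.1,
) -> KnowledgeGraph:
    """A random triple set (duplicates possible on purpose)."""
    proteins = [f"P{i}" for i in range(n_proteins)]
    triples = []
    for _ in range(n_triples):
        s = proteins[rng.integers(n_proteins)]
        o = s if rng.random() < self_loop_frac else \
            proteins[rng.integers(n_proteins)]
        triples.append(Triple(s, predicates[rng.integers(len(predicates))], o))
    return KnowledgeGraph(triples)
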
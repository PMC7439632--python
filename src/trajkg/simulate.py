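"""Synthetic benchmark generator with a planted orientation signal.

The generator emulates the statistical shape of the real inputs — a protein
knowledge graph with a 47-predicate vocabulary (35 directed / 12 undirected),
skewed disease protein-set sizes, labelled ordered disease pairs with
reversal negatives — while planting a tunable association between trajectory
direction and predicate orientation.

The planted signal lives in *orientation only*: the unordered edge skeleton
(which protein pairs are connected, and by which predicate) is sampled
independently of the labels, so edge existence carries no class information
and the undirected feature variants form a proper chance baseline.  For each
positive pair (A, B), every directed-predicate edge lying on an A-B path of
length <= 2 is oriented with its subject on the A side with probability
1/2 + beta/2; all other directed edges, and all undirected-predicate edges,
are oriented uniformly.  Because every reversal negative (B, A) shares its
paths with its positive, a classifier must read the orientation of directed
predicates relative to the candidate's temporal order to separate the
classes — the signal the mixed variants can use and the undirected variants
cannot.

Orientation draws consume one uniform variate per edge in a fixed order
regardless of beta, so runs that differ only in beta share an identical
skeleton and identical undirected feature matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .kg import DIRECTED, DirectionalityTable, KnowledgeGraph, Triple
from .mapping import (
    NEGATIVE,
    POSITIVE,
    CandidatePair,
    ConceptMapping,
    GeneDiseaseAssociations,
    SubclassHierarchy,
    save_pairs,
)

PRESETS = ("jensen_like", "vandenakker_like")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Parameters of one synthetic benchmark.

    ``proteins_per_disease`` are inclusive log-uniform bounds for disease
    protein-set sizes (log-uniform emulates the heavily skewed set sizes of
    curated gene-disease associations).  ``beta`` in [0, 1] is the excess
    probability that a directed edge on a positive pair's path is oriented
    with its subject on the first-disease side; beta=0 is the null.
    ``n_negatives`` includes one reversal negative per positive when
    ``reversal_negatives`` is set, topped up with random non-trajectory
    pairs.
    """

    n_proteins: int = 500
    n_diseases: int = 50
    proteins_per_disease: tuple[int, int] = (4, 25)
    n_positives: int = 200
    n_negatives: int = 200
    reversal_negatives: bool = True
    background_edge_prob: float = 0.016
    self_loop_rate: float = 0.05
    beta: float = 0.8
    degree_matched_negatives: bool = False
    subclass_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.proteins_per_disease
        if not (1 <= lo <= hi):
            raise ValueError("proteins_per_disease bounds must satisfy "
                             "1 <= lo <= hi")
        if hi > self.n_proteins:
            raise ValueError("more proteins per disease than proteins")
        for name in ("background_edge_prob", "self_loop_rate", "beta",
                     "subclass_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        max_unordered = self.n_diseases * (self.n_diseases - 1) // 2
        if self.n_positives > max_unordered:
            raise ValueError(
                f"{self.n_positives} positives exceed the "
                f"{max_unordered} unordered disease pairs available"
            )
        n_rev = self.n_positives if self.reversal_negatives else 0
        if self.n_negatives < n_rev:
            raise ValueError("n_negatives smaller than the reversal negatives")
        total = self.n_positives + self.n_negatives
        if total > self.n_diseases * (self.n_diseases - 1):
            raise ValueError("more candidate pairs than ordered disease pairs")


@dataclass
class Benchmark:
    """A generated benchmark: graph, tables and labelled candidates."""

    config: BenchmarkConfig
    kg: KnowledgeGraph
    directionality: DirectionalityTable
    mapping: ConceptMapping
    hierarchy: SubclassHierarchy
    associations: GeneDiseaseAssociations
    candidates: list[CandidatePair]

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if c.label == POSITIVE else 0
                         for c in self.candidates])

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the five input TSVs; returns the file map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "triples": out / "triples.tsv",
            "directionality": out / "directionality.tsv",
            "mapping": out / "concept_mapping.tsv",
            "hierarchy": out / "concept_hierarchy.tsv",
            "associations": out / "gene_disease_associations.tsv",
            "pairs": out / "candidate_pairs.tsv",
        }
        self.kg.to_tsv(files["triples"])
        self.directionality.to_tsv(files["directionality"])
        self.mapping.to_tsv(files["mapping"])
        self.hierarchy.to_tsv(files["hierarchy"])
        self.associations.to_tsv(files["associations"])
        save_pairs(self.candidates, files["pairs"])
        return files


def _log_uniform_sizes(rng: np.random.Generator, bounds: tuple[int, int],
                       n: int) -> np.ndarray:
    lo, hi = bounds
    sizes = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    return np.clip(np.rint(sizes).astype(int), lo, hi)


def _sample_disease_pairs(
    rng: np.random.Generator, config: BenchmarkConfig, codes: list[str]
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Positive ordered pairs (unordered-distinct) and negative ordered pairs.

    A latent temporal rank over diseases decides the orientation of every
    positive: trajectories run from lower to higher rank, so each disease
    occupies a consistent side across all its trajectories (as in staged
    disease progression), which keeps the planted edge orientations of
    different positive pairs from contradicting each other.
    """
    d = len(codes)
    rank = rng.permutation(d)
    unordered = [(i, j) for i in range(d) for j in range(i + 1, d)]
    pick = rng.choice(len(unordered), size=config.n_positives, replace=False)
    positives = []
    for idx in pick:
        i, j = unordered[idx]
        if rank[i] > rank[j]:
            i, j = j, i
        positives.append((codes[i], codes[j]))

    used = set(positives)
    # reversals of positives are never sampled as "random" negatives: an
    # accidental exact reversal would duplicate a positive's undirected
    # feature row under the opposite label
    blocked = {(b, a) for a, b in positives}
    negatives: list[tuple[str, str]] = []
    if config.reversal_negatives:
        for a, b in positives:
            negatives.append((b, a))
            used.add((b, a))
    n_random = config.n_negatives - len(negatives)

    if n_random > 0 and not config.degree_matched_negatives:
        # uniform rejection sampling over unused, non-reversal ordered pairs
        placed = 0
        while placed < n_random:
            i, j = rng.integers(0, d, size=2)
            pair = (codes[i], codes[j])
            if i == j or pair in used or pair in blocked:
                continue
            negatives.append(pair)
            used.add(pair)
            placed += 1
    elif n_random > 0:
        # degree-matched option: recombine the positives' own disease
        # multisets so disease marginals — and hence protein-set-size
        # distributions — carry no label information
        reps = -(-n_random // len(positives))  # ceil
        firsts = [a for a, _ in positives] * reps
        seconds = [b for _, b in positives] * reps
        rng.shuffle(firsts)
        rng.shuffle(seconds)
        firsts, seconds = firsts[:n_random], seconds[:n_random]
        placed = 0
        attempts = 0
        max_attempts = 200 * n_random + 1000
        while placed < n_random and attempts < max_attempts:
            attempts += 1
            a, b = firsts[placed], seconds[placed]
            pair = (a, b)
            if a == b or pair in used or pair in blocked:
                # repair by swapping the second element with a random slot
                j = int(rng.integers(placed, n_random))
                seconds[placed], seconds[j] = seconds[j], seconds[placed]
                continue
            negatives.append(pair)
            used.add(pair)
            placed += 1
        while placed < n_random:  # fallback: uniform rejection sampling
            i, j = rng.integers(0, d, size=2)
            pair = (codes[i], codes[j])
            if i == j or pair in used or pair in blocked:
                continue
            negatives.append(pair)
            used.add(pair)
            placed += 1
    return positives, negatives


def _desired_orientations(
    adjacency: dict[str, set[str]],
    positives: Sequence[tuple[str, str]],
    protein_sets: dict[str, frozenset[str]],
) -> dict[tuple[str, str], str]:
    """Preferred subject per unordered edge, from positive pairs' paths.

    For each positive (A, B), edges on direct A-B links and on A-m-B
    two-step paths prefer the subject nearer the A side.  Conflicting
    preferences within one pair cancel; across pairs each edge takes the
    majority preference (ties stay unclaimed, i.e. uniformly oriented).
    """
    votes: dict[tuple[str, str], dict[str, int]] = {}
    for first, second in positives:
        pa, pb = protein_sets[first], protein_sets[second]
        desired: dict[tuple[str, str], str | None] = {}

        def want(u: str, v: str, subject: str) -> None:
            key = (u, v) if u <= v else (v, u)
            if key in desired and desired[key] != subject:
                desired[key] = None  # conflicting preference within the pair
            else:
                desired[key] = subject

        for a in pa:
            for m in adjacency.get(a, ()):
                if m == a:
                    continue
                if m in pb:  # direct leg, subject on the A side
                    if a in pb and m in pa:
                        continue  # both endpoints on both sides: ambiguous
                    want(a, m, a)
                for b in adjacency.get(m, ()):
                    if b == m or b == a or b not in pb:
                        continue
                    want(a, m, a)
                    want(m, b, m)
        for key, subject in desired.items():
            if subject is not None:
                votes.setdefault(key, {})[subject] = (
                    votes.setdefault(key, {}).get(subject, 0) + 1
                )
    claimed: dict[tuple[str, str], str] = {}
    for key, tally in votes.items():
        best = max(tally.values())
        winners = [s for s, n in tally.items() if n == best]
        if len(winners) == 1:
            claimed[key] = winners[0]
    return claimed


def generate_benchmark(config: BenchmarkConfig) -> Benchmark:
    """Generate a complete benchmark; deterministic given ``config.seed``."""
    config.validate()
    rng_struct = np.random.default_rng([config.seed, 0])
    rng_orient = np.random.default_rng([config.seed, 1])

    table = DirectionalityTable.default()
    vocab = table.predicates
    directed = {p for p in vocab if table.category(p) == DIRECTED}

    width = len(str(config.n_proteins - 1))
    proteins = [f"P{i:0{width}d}" for i in range(config.n_proteins)]
    dwidth = len(str(config.n_diseases - 1))
    codes = [f"D{i:0{dwidth}d}" for i in range(config.n_diseases)]
    concepts = {c: c.replace("D", "C", 1) for c in codes}

    # disease protein sets, log-uniform sizes
    sizes = _log_uniform_sizes(rng_struct, config.proteins_per_disease,
                               config.n_diseases)
    protein_sets: dict[str, frozenset[str]] = {}
    for code, size in zip(codes, sizes):
        members = rng_struct.choice(config.n_proteins, size=size,
                                    replace=False)
        protein_sets[code] = frozenset(proteins[i] for i in members)

    # mapping / hierarchy / associations: each concept keeps most proteins,
    # a "narrower" subclass concept holds the rest, so subclass expansion is
    # exercised end to end
    mapping_records, hierarchy_edges, assoc_records = [], [], []
    for code in codes:
        concept = concepts[code]
        child = concept + ".1"
        mapping_records.append((code, "ICD10", concept))
        members = sorted(protein_sets[code])
        to_child = rng_struct.random(len(members)) < config.subclass_fraction
        child_members = [p for p, flag in zip(members, to_child) if flag]
        parent_members = [p for p, flag in zip(members, to_child) if not flag]
        if not parent_members:  # keep the parent concept non-empty
            parent_members, child_members = child_members, []
        for p in parent_members:
            assoc_records.append((concept, p))
        if child_members:
            hierarchy_edges.append((concept, child, "narrower"))
            for p in child_members:
                assoc_records.append((child, p))

    # unordered background edge skeleton, label-independent
    n_pairs = config.n_proteins * (config.n_proteins - 1) // 2
    n_edges = rng_struct.binomial(n_pairs, config.background_edge_prob)
    iu, ju = np.triu_indices(config.n_proteins, k=1)
    pick = rng_struct.choice(n_pairs, size=n_edges, replace=False)
    pick.sort()
    edges = [(proteins[iu[k]], proteins[ju[k]]) for k in pick]
    edge_pred = {e: vocab[i] for e, i in
                 zip(edges, rng_struct.integers(0, len(vocab), size=n_edges))}
    loops = [p for p, u in zip(proteins, rng_struct.random(config.n_proteins))
             if u < config.self_loop_rate]
    loop_pred = {p: vocab[i] for p, i in
                 zip(loops, rng_struct.integers(0, len(vocab), size=len(loops)))}

    # labelled ordered pairs
    positives, negatives = _sample_disease_pairs(rng_struct, config, codes)

    # orientation preferences from positive pairs' paths
    adjacency: dict[str, set[str]] = {}
    for u, v in edges:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)
    claimed = _desired_orientations(adjacency, positives, protein_sets)

    # orient every edge with one uniform draw, in fixed order: identical
    # skeletons across beta values
    p_keep = 0.5 + config.beta / 2.0
    triples = []
    for u, v in edges:  # (u, v) already canonical (u < v by construction)
        pred = edge_pred[(u, v)]
        draw = rng_orient.random()
        preferred = claimed.get((u, v))
        if pred in directed and preferred is not None:
            subject = preferred if draw < p_keep else (
                v if preferred == u else u)
        else:
            subject = u if draw < 0.5 else v
        obj = v if subject == u else u
        triples.append(Triple(subject, pred, obj, "synthetic"))
    for p in loops:
        rng_orient.random()  # consume for stream alignment
        triples.append(Triple(p, loop_pred[p], p, "synthetic"))

    candidates = [
        CandidatePair(a, b, POSITIVE, protein_sets[a], protein_sets[b])
        for a, b in positives
    ] + [
        CandidatePair(a, b, NEGATIVE, protein_sets[a], protein_sets[b])
        for a, b in negatives
    ]

    return Benchmark(
        config=config,
        kg=KnowledgeGraph(triples),
        directionality=table,
        mapping=ConceptMapping(mapping_records),
        hierarchy=SubclassHierarchy(hierarchy_edges),
        associations=GeneDiseaseAssociations(assoc_records),
        candidates=candidates,
    )


def null_benchmark_config(seed: int = 0, **overrides) -> BenchmarkConfig:
    """A no-signal (beta=0) evaluation design.

    Compared with the default planted-signal shape, the null design spreads
    the candidate pairs over many diseases, uses homogeneous protein-set
    sizes and uniform (non-reversal) negatives: chance disease-multiplicity
    imbalance and set-size differences between the classes are then too
    small for a classifier to exploit, so any AUC away from 0.5 reflects a
    defect rather than nuisance structure.  Because a single finite dataset
    still shows chance feature-label association, null AUC estimates should
    be averaged over a few generator replicates (distinct seeds).
    """
    cfg = BenchmarkConfig(
        n_proteins=2000,
        n_diseases=200,
        proteins_per_disease=(12, 12),
        n_positives=200,
        n_negatives=200,
        reversal_negatives=False,
        background_edge_prob=8 / 2000,
        self_loop_rate=0.05,
        beta=0.0,
        degree_matched_negatives=False,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def emulate_reference_shape(preset: str, *, seed: int = 0,
                        **overrides) -> BenchmarkConfig:
    """A config approximating one of the two reference-set shapes at
    reduced scale.

    ``jensen_like``: many negatives per positive (default 50:1) and skewed
    protein-set sizes with median near 29 (log-uniform 7-94).
    ``vandenakker_like``: 55 positives / 370 negatives (reversal negatives
    included) with set-size median near 49 (log-uniform 17-167).
    """
    if preset == "jensen_like":
        cfg = BenchmarkConfig(
            n_proteins=1200,
            n_diseases=60,
            proteins_per_disease=(7, 94),
            n_positives=30,
            n_negatives=1500,
            reversal_negatives=True,
            background_edge_prob=8 / 1200,
            self_loop_rate=0.05,
            seed=seed,
        )
    elif preset == "vandenakker_like":
        cfg = BenchmarkConfig(
            n_proteins=2000,
            n_diseases=45,
            proteins_per_disease=(17, 167),
            n_positives=55,
            n_negatives=370,
            reversal_negatives=True,
            background_edge_prob=8 / 2000,
            self_loop_rate=0.05,
            seed=seed,
        )
    else:
        raise ValueError(
            f"unknown preset {preset!r}; expected one of {PRESETS}"
        )
    return replace(cfg, **overrides) if overrides else cfg
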
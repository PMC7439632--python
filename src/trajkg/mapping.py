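"""Disease codes -> concepts -> disease proteins, and candidate-pair sets.

Diseases arrive as source-vocabulary codes (ICD-10 / ICPC style).  A concept
mapping table links codes to concept identifiers, a subclass hierarchy
("narrower"/"child" relations) expands each concept with its descendants, and
a curated gene-disease association table assigns proteins to concepts.  A
disease is represented by the union of the proteins of all its mapped
concepts and their subclasses; diseases to which no protein can be assigned
are excluded from candidate pairs.

A candidate pair is an *ordered* pair of diseases: (A, B) asks whether A is
commonly followed in time by B, so (A, B) and (B, A) are distinct candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

SUBCLASS_RELATIONS = ("narrower", "child")


def _read_tsv(path: str | Path, min_cols: int) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least {min_cols} "
                    f"tab-separated columns, got {len(parts)}"
                )
            yield lineno, parts


class ConceptMapping:
    """Source code -> concept identifiers (one code may map to many concepts)."""

    def __init__(self, records: Iterable[tuple[str, str, str]] = ()):
        # (code, vocabulary, concept)
        self._by_code: dict[str, set[str]] = {}
        self._records: set[tuple[str, str, str]] = set()
        for code, vocab, concept in records:
            self._records.add((code, vocab, concept))
            self._by_code.setdefault(code, set()).add(concept)

    def concepts(self, code: str) -> set[str]:
        return set(self._by_code.get(code, ()))

    def __len__(self) -> int:
        return len(self._records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConceptMapping":
        """Load ``code<TAB>vocabulary<TAB>concept_id`` records."""
        return cls((p[0], p[1], p[2]) for _, p in _read_tsv(path, 3))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# code<TAB>vocabulary<TAB>concept_id\n")
            for rec in sorted(self._records):
                fh.write("\t".join(rec) + "\n")


class SubclassHierarchy:
    """Parent -> child concept edges ("narrower"/"child" relations)."""

    def __init__(self, edges: Iterable[tuple[str, str, str]] = ()):
        self._graph = nx.DiGraph()
        self._edges: set[tuple[str, str, str]] = set()
        for parent, child, relation in edges:
            self._edges.add((parent, child, relation))
            self._graph.add_edge(parent, child)

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        return set(self._edges)

    def children(self, concept: str) -> set[str]:
        if concept not in self._graph:
            return set()
        return set(self._graph.successors(concept))

    def expand(self, concept: str, *, max_depth: int | None = None) -> set[str]:
        """The concept plus all descendants via parent->child edges.

        Transitive and cycle-safe; an unknown concept expands to itself.
        ``max_depth`` limits the closure for sensitivity analyses
        (``max_depth=1`` keeps only direct subclasses).
        """
        if concept not in self._graph:
            return {concept}
        if max_depth is None:
            return {concept} | nx.descendants(self._graph, concept)
        out = {concept}
        frontier = {concept}
        for _ in range(max_depth):
            frontier = {
                c for p in frontier for c in self._graph.successors(p)
            } - out
            if not frontier:
                break
            out |= frontier
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubclassHierarchy":
        """Load ``parent<TAB>child<TAB>relation`` records."""
        return cls((p[0], p[1], p[2]) for _, p in _read_tsv(path, 3))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# parent<TAB>child<TAB>relation\n")
            for rec in sorted(self._edges):
                fh.write("\t".join(rec) + "\n")


class GeneDiseaseAssociations:
    """Deduplicated (concept, protein) association records."""

    def __init__(self, records: Iterable[tuple[str, str]] = ()):
        self._by_concept: dict[str, set[str]] = {}
        self._records: set[tuple[str, str]] = set()
        for concept, protein in records:
            self._records.add((concept, protein))
            self._by_concept.setdefault(concept, set()).add(protein)

    def proteins(self, concept: str) -> set[str]:
        return set(self._by_concept.get(concept, ()))

    @property
    def records(self) -> set[tuple[str, str]]:
        return set(self._records)

    def __len__(self) -> int:
        return len(self._records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneDiseaseAssociations":
        """Load ``concept_id<TAB>protein_id`` records."""
        return cls((p[0], p[1]) for _, p in _read_tsv(path, 2))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# concept_id<TAB>protein_id\n")
            for rec in sorted(self._records):
                fh.write("\t".join(rec) + "\n")


@dataclass(frozen=True)
class CandidatePair:
    """An ordered disease pair with a trajectory label.

    ``proteins_first``/``proteins_second`` are attached once disease proteins
    have been assigned; both must be non-empty before featurization.
    """

    first: str
    second: str
    label: str
    proteins_first: frozenset[str] = field(default=frozenset(), compare=False)
    proteins_second: frozenset[str] = field(default=frozenset(), compare=False)

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError(f"candidate pair must be two distinct diseases "
                             f"({self.first!r} repeated)")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.first, self.second)

    @property
    def pair_id(self) -> str:
        return f"{self.first}->{self.second}"

    def reversed(self, label: str | None = None) -> "CandidatePair":
        return CandidatePair(
            self.second, self.first, label or self.label,
            self.proteins_second, self.proteins_first,
        )

    def with_proteins(
        self, first: Iterable[str], second: Iterable[str]
    ) -> "CandidatePair":
        return CandidatePair(
            self.first, self.second, self.label,
            frozenset(first), frozenset(second),
        )


def expand_with_subclasses(
    concept: str, hierarchy: SubclassHierarchy, *, max_depth: int | None = None
) -> set[str]:
    """Concept plus all subclass descendants (transitive, cycle-safe)."""
    return hierarchy.expand(concept, max_depth=max_depth)


def assign_disease_proteins(
    code: str,
    mapping: ConceptMapping,
    hierarchy: SubclassHierarchy,
    associations: GeneDiseaseAssociations,
    *,
    vocabulary: str | None = None,
    max_depth: int | None = None,
) -> set[str]:
    """Union of proteins over all mapped concepts and their subclasses.

    An empty result marks the disease unmappable (logged, not raised); such
    diseases are dropped before pair construction.
    """
    concepts = mapping.concepts(code)
    if not concepts:
        logger.info("unmapped code: %s", code)
        return set()
    proteins: set[str] = set()
    for concept in concepts:
        for expanded in expand_with_subclasses(concept, hierarchy,
                                               max_depth=max_depth):
            proteins |= associations.proteins(expanded)
    if not proteins:
        logger.info("code %s maps to concepts with no associated proteins", code)
    return proteins


def build_negatives(
    diseases: Iterable[str],
    pairs: Sequence[CandidatePair],
    mode: str = "all_pairs_minus",
) -> list[CandidatePair]:
    """Construct negative candidates from a disease set and existing pairs.

    ``all_pairs_minus``: every ordered pair of distinct diseases not already
    present in *pairs* becomes a negative (with only positives given, the
    result plus the positives partitions the ordered-pair space).

    ``reversal``: for each positive (A, B), emit (B, A) as a negative unless
    that ordered pair is already present in *pairs* (as positive or negative).

    A pair occurring with both labels in *pairs* raises a consistency error.
    """
    diseases = sorted(set(diseases))
    seen: dict[tuple[str, str], str] = {}
    conflicts = []
    for p in pairs:
        if p.key in seen and seen[p.key] != p.label:
            conflicts.append(p.key)
        seen[p.key] = p.label
    if conflicts:
        raise ValueError(
            "pairs labelled both positive and negative: "
            + ", ".join(f"{a}->{b}" for a, b in sorted(set(conflicts)))
        )
    positives = [p for p in pairs if p.label == POSITIVE]
    missing = {d for p in positives for d in p.key} - set(diseases)
    if missing:
        raise ValueError(
            f"positive pairs mention diseases outside the disease set: "
            f"{sorted(missing)}"
        )

    negatives: list[CandidatePair] = []
    if mode == "all_pairs_minus":
        for a in diseases:
            for b in diseases:
                if a != b and (a, b) not in seen:
                    negatives.append(CandidatePair(a, b, NEGATIVE))
    elif mode == "reversal":
        emitted: set[tuple[str, str]] = set()
        for p in positives:
            rev = (p.second, p.first)
            if rev in seen or rev in emitted:
                continue
            negatives.append(p.reversed(NEGATIVE))
            emitted.add(rev)
    else:
        raise ValueError(f"unknown negative-construction mode: {mode!r}")
    return negatives


def load_pairs(path: str | Path) -> list[CandidatePair]:
    """Load ``first<TAB>second<TAB>label`` candidate pairs."""
    pairs = []
    for lineno, parts in _read_tsv(path, 3):
        label = parts[2].strip().lower()
        pairs.append(CandidatePair(parts[0], parts[1], label))
    return pairs


def save_pairs(pairs: Sequence[CandidatePair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# first<TAB>second<TAB>label\n")
        for p in pairs:
            fh.write(f"{p.first}\t{p.second}\t{p.label}\n")


def attach_disease_proteins(
    pairs: Sequence[CandidatePair],
    mapping: ConceptMapping | None,
    hierarchy: SubclassHierarchy | None,
    associations: GeneDiseaseAssociations,
    *,
    max_depth: int | None = None,
) -> tuple[list[CandidatePair], list[CandidatePair]]:
    """Attach protein sets to pairs; split off pairs with an unmappable side.

    When *mapping* is None, disease codes are used directly as concept
    identifiers.  Returns ``(kept, dropped)``.
    """
    hierarchy = hierarchy or SubclassHierarchy()
    cache: dict[str, set[str]] = {}

    def proteins_for(code: str) -> set[str]:
        if code not in cache:
            if mapping is None:
                out: set[str] = set()
                for c in expand_with_subclasses(code, hierarchy,
                                                max_depth=max_depth):
                    out |= associations.proteins(c)
                cache[code] = out
            else:
                cache[code] = assign_disease_proteins(
                    code, mapping, hierarchy, associations, max_depth=max_depth
                )
        return cache[code]

    kept, dropped = [], []
    for p in pairs:
        a, b = proteins_for(p.first), proteins_for(p.second)
        if a and b:
            if a == b:
                logger.info("candidate %s has identical protein sets on both "
                            "sides (retained)", p.pair_id)
            kept.append(p.with_proteins(a, b))
        else:
            dropped.append(p)
    if dropped:
        logger.info("dropped %d of %d pairs with an unmappable side",
                    len(dropped), len(pairs))
    return kept, dropped
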
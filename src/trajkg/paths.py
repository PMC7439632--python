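"""Enumeration of length-<=2 protein paths between two disease protein sets.

Three path scenarios connect the protein sets of an ordered disease pair
(A, B):

* **overlap** — a protein shared by both sets, optionally with a self-loop
  (e.g. a homodimerizing protein);
* **direct** — a single triple joining a protein of A and a protein of B;
* **indirect** — a two-triple path through one intermediate protein.

Every edge of a path carries a traversal orientation: *forward* when the
triple's subject is the node nearer the A (first-disease) side, *reverse*
otherwise, *loop* for self-loops.  Endpoints of direct and indirect paths
are distinct proteins; a shared protein reached with zero triples is the
overlap scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .kg import FORWARD, LOOP, REVERSE, KnowledgeGraph

OVERLAP = "overlap"
DIRECT = "direct"
INDIRECT = "indirect"

SCENARIOS = (OVERLAP, DIRECT, INDIRECT)


@dataclass(frozen=True)
class PathInstance:
    """One scenario-classified path.

    ``nodes`` runs from the first-disease side to the second-disease side
    (1, 2 or 3 proteins); ``edges`` are (predicate, orientation) aligned with
    the traversal.
    """

    scenario: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.scenario == OVERLAP:
            ok = len(self.nodes) == 1 and len(self.edges) <= 1
            ok = ok and all(o == LOOP for _, o in self.edges)
        elif self.scenario == DIRECT:
            ok = len(self.nodes) == 2 and len(self.edges) == 1
            ok = ok and self.edges[0][1] in (FORWARD, REVERSE)
        elif self.scenario == INDIRECT:
            ok = len(self.nodes) == 3 and len(self.edges) == 2
            ok = ok and all(o in (FORWARD, REVERSE) for _, o in self.edges)
        else:
            ok = False
        if not ok:
            raise ValueError(
                f"invalid {self.scenario!r} path: nodes={self.nodes} "
                f"edges={self.edges}"
            )

    def reversed(self) -> "PathInstance":
        """The same path traversed from the B side (orientations flipped)."""
        flip = {FORWARD: REVERSE, REVERSE: FORWARD, LOOP: LOOP}
        return PathInstance(
            self.scenario,
            tuple(reversed(self.nodes)),
            tuple((p, flip[o]) for p, o in reversed(self.edges)),
        )


@dataclass
class PathCollection:
    """All paths of one candidate, grouped by scenario."""

    overlap: list[PathInstance] = field(default_factory=list)
    direct: list[PathInstance] = field(default_factory=list)
    indirect: list[PathInstance] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            OVERLAP: len(self.overlap),
            DIRECT: len(self.direct),
            INDIRECT: len(self.indirect),
        }

    def __iter__(self) -> Iterator[PathInstance]:
        yield from self.overlap
        yield from self.direct
        yield from self.indirect

    def __len__(self) -> int:
        return len(self.overlap) + len(self.direct) + len(self.indirect)


def extract_paths(
    kg: KnowledgeGraph,
    set_a: Iterable[str],
    set_b: Iterable[str],
    *,
    exclude_disease_intermediates: bool = False,
) -> PathCollection:
    """Enumerate all overlap/direct/indirect paths between two protein sets.

    Paths use at most two triples.  Parallel edges (several predicates, or
    the same predicate in both directions) yield distinct path instances;
    provenance never multiplies paths.  The intermediate protein of an
    indirect path may itself belong to either disease set unless
    ``exclude_disease_intermediates`` is set.
    """
    A = frozenset(set_a)
    B = frozenset(set_b)
    if not A:
        raise ValueError("first-disease protein set is empty")
    if not B:
        raise ValueError("second-disease protein set is empty")

    coll = PathCollection()

    # overlap: shared proteins, plus one instance per distinct self-loop
    for p in sorted(A & B):
        coll.overlap.append(PathInstance(OVERLAP, (p,), ()))
        for pred in kg.self_loop_predicates(p):
            coll.overlap.append(PathInstance(OVERLAP, (p,), ((pred, LOOP),)))

    disease_nodes = A | B
    for a in sorted(A):
        for m in kg.neighbors(a):
            if m == a:
                continue  # loops are overlap territory, never a path leg
            # direct: a in A joined to m in B by one triple
            if m in B:
                for pred, orient in kg.edges_between(a, m):
                    coll.direct.append(
                        PathInstance(DIRECT, (a, m), ((pred, orient),))
                    )
            # indirect: a - m - b with two non-loop triples, b distinct
            if exclude_disease_intermediates and m in disease_nodes:
                continue
            first_legs = kg.edges_between(a, m)
            for b in kg.neighbors(m):
                if b == m or b == a or b not in B:
                    continue
                second_legs = kg.edges_between(m, b)
                for e1 in first_legs:
                    for e2 in second_legs:
                        coll.indirect.append(
                            PathInstance(INDIRECT, (a, m, b), (e1, e2))
                        )
    return coll
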
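"""Protein knowledge graph: triples, indices, and predicate directionality.

Knowledge is modelled as subject-predicate-object triples between proteins,
with the direction of the predicate running from subject to object.  A
directionality table classifies each predicate of the controlled vocabulary
as *directed* (subject/object order is meaningful, e.g. "inhibits") or
*undirected* (symmetric, e.g. "binds with"); negated predicates ("does not
interact with") inherit the category of their base form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

DIRECTED = "directed"
UNDIRECTED = "undirected"

FORWARD = "forward"
REVERSE = "reverse"
LOOP = "loop"

#: Packaged 47-predicate directionality fixture (12 undirected / 35 directed).
#: The directed list is a synthetic reconstruction; see the data file header.
_FIXTURE_NAME = "predicate_directionality_synthetic.tsv"


def normalize_predicate(predicate: str) -> str:
    """Case-insensitive, whitespace-normalized predicate key.

    Source tables mix capitalizations ("Binds with" vs "binds with"), so all
    predicate comparisons go through this normalization.
    """
    return " ".join(predicate.split()).lower()


class TripleParseError(ValueError):
    """A triples file row could not be parsed."""


class UnknownPredicateError(KeyError):
    """A predicate is absent from the directionality table (after negation
    stripping)."""

    def __init__(self, predicate: str):
        super().__init__(predicate)
        self.predicate = predicate

    def __str__(self) -> str:  # KeyError repr-quotes its arg; keep it readable
        return f"unknown predicate: {self.predicate!r}"


@dataclass(frozen=True)
class Triple:
    """One subject-predicate-object edge between proteins.

    Provenance is carried for bookkeeping but never participates in equality
    or in any computation: duplicates of the (subject, predicate, object) key
    are stored once.
    """

    subject: str
    predicate: str
    object: str
    provenance: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.subject or not self.object:
            raise ValueError("triple subject and object must be non-empty")
        if not self.predicate:
            raise ValueError("triple predicate must be non-empty")
        object.__setattr__(self, "predicate", normalize_predicate(self.predicate))

    @property
    def is_loop(self) -> bool:
        return self.subject == self.object


class DirectionalityTable:
    """Mapping predicate -> {directed, undirected} with negation inheritance.

    A predicate starting with a negation prefix (default ``"does not "``)
    resolves to the category of its de-negated base predicate.  An explicit
    entry for a negated form must agree with its base.
    """

    def __init__(
        self,
        entries: Mapping[str, str],
        negation_prefixes: tuple[str, ...] = ("does not ",),
    ):
        self.negation_prefixes = tuple(negation_prefixes)
        self._entries: dict[str, str] = {}
        for pred, cat in entries.items():
            key = normalize_predicate(pred)
            cat = cat.strip().lower()
            if cat not in (DIRECTED, UNDIRECTED):
                raise ValueError(
                    f"invalid category {cat!r} for predicate {pred!r}; "
                    f"expected {DIRECTED!r} or {UNDIRECTED!r}"
                )
            if key in self._entries and self._entries[key] != cat:
                raise ValueError(f"conflicting categories for predicate {pred!r}")
            self._entries[key] = cat
        # explicit negated entries must agree with their base predicate
        for pred, cat in self._entries.items():
            base = self._base_of(pred)
            if base is not None and self._entries[base] != cat:
                raise ValueError(
                    f"negated predicate {pred!r} ({cat}) disagrees with its "
                    f"base {base!r} ({self._entries[base]})"
                )

    def _negation_bases(self, predicate: str) -> list[str]:
        """Candidate base forms of a negated predicate.

        "does not interact with" negates "interacts with": after stripping
        the prefix, the verb is re-inflected to third-person singular, and
        the uninflected form is also tried.
        """
        for prefix in self.negation_prefixes:
            if predicate.startswith(prefix):
                stripped = predicate[len(prefix):]
                words = stripped.split(" ")
                inflected = " ".join([words[0] + "s"] + words[1:]) \
                    if words and words[0] else stripped
                return [inflected, stripped]
        return []

    def _base_of(self, predicate: str) -> str | None:
        for base in self._negation_bases(predicate):
            if base in self._entries:
                return base
        return None

    def category(self, predicate: str, *, unknown: str = "error") -> str:
        """Return the category of *predicate*.

        ``unknown`` controls the behaviour for predicates absent from the
        table after negation stripping: ``"error"`` (default) raises
        :class:`UnknownPredicateError`; ``"undirected"`` treats them as
        undirected (opt-in, since guessing directionality would corrupt the
        mixed feature variant).
        """
        key = normalize_predicate(predicate)
        if key in self._entries:
            return self._entries[key]
        base = self._base_of(key)
        if base is not None:
            return self._entries[base]
        if unknown == "undirected":
            return UNDIRECTED
        raise UnknownPredicateError(predicate)

    def __contains__(self, predicate: str) -> bool:
        try:
            self.category(predicate)
        except UnknownPredicateError:
            return False
        return True

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def predicates(self) -> list[str]:
        return sorted(self._entries)

    def counts(self) -> dict[str, int]:
        """Number of explicitly listed predicates per category."""
        out = {DIRECTED: 0, UNDIRECTED: 0}
        for cat in self._entries.values():
            out[cat] += 1
        return out

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "DirectionalityTable":
        """Load a ``predicate<TAB>category`` table; '#' lines are comments."""
        entries: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise TripleParseError(
                        f"{path}: line {lineno}: expected predicate<TAB>category"
                    )
                entries[parts[0]] = parts[1]
        return cls(entries, **kwargs)

    @classmethod
    def default(cls) -> "DirectionalityTable":
        """The packaged 47-predicate fixture (synthetic directed list)."""
        ref = resources.files("trajkg.data").joinpath(_FIXTURE_NAME)
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# predicate<TAB>category\n")
            for pred in sorted(self._entries):
                fh.write(f"{pred}\t{self._entries[pred]}\n")


def categorize_predicate(
    predicate: str, table: DirectionalityTable, *, unknown: str = "error"
) -> str:
    """Category of *predicate* under *table*; see DirectionalityTable.category."""
    return table.category(predicate, unknown=unknown)


class KnowledgeGraph:
    """An indexed set of protein triples.

    Triples are deduplicated on their (subject, predicate, object) key.
    Self-loops are stored once and reported once with a ``loop`` marker.
    """

    def __init__(self, triples: Iterable[Triple] = ()):
        self._triples: dict[tuple[str, str, str], Triple] = {}
        # adjacency: node -> neighbour -> list of incident triples
        self._adj: dict[str, dict[str, list[Triple]]] = {}
        for t in triples:
            self.add(t)

    def add(self, triple: Triple) -> None:
        key = (triple.subject, triple.predicate, triple.object)
        if key in self._triples:
            return
        self._triples[key] = triple
        self._adj.setdefault(triple.subject, {}).setdefault(
            triple.object, []
        ).append(triple)
        if not triple.is_loop:
            self._adj.setdefault(triple.object, {}).setdefault(
                triple.subject, []
            ).append(triple)

    @property
    def triples(self) -> list[Triple]:
        return list(self._triples.values())

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples.values())

    def neighbors(self, node: str) -> list[str]:
        """All nodes sharing a triple with *node* (including itself if it has
        a self-loop), in deterministic sorted order."""
        return sorted(self._adj.get(node, {}))

    def incident(self, p: str, q: str) -> list[Triple]:
        """Raw triples between p and q (either orientation; loops if p == q)."""
        return list(self._adj.get(p, {}).get(q, []))

    def edges_between(self, p: str, q: str) -> list[tuple[str, str]]:
        """Predicates between *p* and *q* with traversal orientation.

        ``forward`` entries have subject p and object q; ``reverse`` entries
        the converse.  When p == q each self-loop appears once, marked
        ``loop``.  Absent nodes yield the empty list.
        """
        out: list[tuple[str, str]] = []
        for t in self._adj.get(p, {}).get(q, []):
            if t.is_loop:
                out.append((t.predicate, LOOP))
            elif t.subject == p:
                out.append((t.predicate, FORWARD))
            else:
                out.append((t.predicate, REVERSE))
        return out

    def self_loop_predicates(self, p: str) -> list[str]:
        """Distinct self-loop predicates of *p*, sorted."""
        return sorted({t.predicate for t in self._adj.get(p, {}).get(p, [])})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# subject<TAB>predicate<TAB>object<TAB>provenance\n")
            for key in sorted(self._triples):
                t = self._triples[key]
                prov = t.provenance or ""
                fh.write(f"{t.subject}\t{t.predicate}\t{t.object}\t{prov}\n")


def load_triples(path: str | Path) -> KnowledgeGraph:
    """Load a triples TSV (``subject<TAB>predicate<TAB>object[<TAB>provenance]``).

    Rows are deduplicated on (subject, predicate, object); '#' lines and blank
    lines are skipped.  Malformed rows raise :class:`TripleParseError` naming
    the line; an empty file yields an empty graph with a warning.
    """
    kg = KnowledgeGraph()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TripleParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"columns (subject, predicate, object), got {len(parts)}"
                )
            prov = parts[3] if len(parts) > 3 and parts[3] else None
            kg.add(Triple(parts[0], parts[1], parts[2], prov))
            n_rows += 1
    if n_rows == 0:
        logger.warning("no triples found in %s; graph is empty", path)
    logger.info(
        "loaded %d rows from %s (%d distinct triples, %d proteins)",
        n_rows, path, len(kg), len(kg.nodes),
    )
    return kg
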
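"""Binary path-signature features for candidate disease pairs.

Each path is reduced to one or more *signatures* — canonical strings of the
form ``scenario|component`` (or ``scenario|component->component`` for
metapath-encoded indirect paths), where a component is a predicate with an
optional orientation suffix.  A candidate's feature vector marks which
signatures occur in at least one of its paths; all features are binary.

Two representations of indirect paths are supported: **metapath** encodes the
ordered predicate sequence of an indirect path as a single feature, while
**split** encodes each predicate of the path as a separate feature.  Three
direction modes control orientation suffixes: **undirected** drops all
orientation, **mixed** keeps orientation only for predicates assessed as
directed in the directionality table, and **directed** keeps orientation for
every predicate (self-loops then carry a ``:loop`` marker).  Self-loop
predicates of overlap paths are orientation-free in the undirected and mixed
modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .kg import DIRECTED, FORWARD, LOOP, REVERSE, DirectionalityTable, KnowledgeGraph
from .mapping import CandidatePair
from .paths import DIRECT, INDIRECT, OVERLAP, PathCollection, PathInstance, extract_paths

METAPATH = "metapath"
SPLIT = "split"
UNDIRECTED_MODE = "undirected"
MIXED_MODE = "mixed"
DIRECTED_MODE = "directed"

_ORIENT_SUFFIX = {FORWARD: ":fwd", REVERSE: ":rev", LOOP: ":loop"}
_SEQ_SEP = "->"


@dataclass(frozen=True)
class FeatureVariant:
    """One of the feature-set variants: representation x direction mode."""

    representation: str
    direction_mode: str

    def __post_init__(self) -> None:
        if self.representation not in (METAPATH, SPLIT):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.direction_mode not in (UNDIRECTED_MODE, MIXED_MODE,
                                       DIRECTED_MODE):
            raise ValueError(f"unknown direction mode {self.direction_mode!r}")

    @property
    def name(self) -> str:
        return f"{self.representation}-{self.direction_mode}"


#: The four primary feature sets; the all-directed mode is a supplementary
#: variation.
PRIMARY_VARIANTS = (
    FeatureVariant(METAPATH, UNDIRECTED_MODE),
    FeatureVariant(METAPATH, MIXED_MODE),
    FeatureVariant(SPLIT, UNDIRECTED_MODE),
    FeatureVariant(SPLIT, MIXED_MODE),
)

ALL_VARIANTS = PRIMARY_VARIANTS + (
    FeatureVariant(METAPATH, DIRECTED_MODE),
    FeatureVariant(SPLIT, DIRECTED_MODE),
)


def variant_from_name(name: str) -> FeatureVariant:
    """Parse ``"metapath-mixed"``-style variant names."""
    try:
        representation, mode = name.split("-")
    except ValueError:
        raise ValueError(f"variant name must look like 'metapath-mixed', "
                         f"got {name!r}") from None
    return FeatureVariant(representation, mode)


def _component(
    predicate: str,
    orientation: str,
    mode: str,
    table: DirectionalityTable | None,
    unknown: str,
) -> str:
    if orientation == LOOP:
        # loop predicates are orientation-free except in all-directed mode,
        # where they carry a self-referential marker
        return predicate + _ORIENT_SUFFIX[LOOP] if mode == DIRECTED_MODE \
            else predicate
    if mode == UNDIRECTED_MODE:
        return predicate
    if mode == DIRECTED_MODE:
        return predicate + _ORIENT_SUFFIX[orientation]
    if table is None:
        raise ValueError("mixed mode requires a directionality table")
    if table.category(predicate, unknown=unknown) == DIRECTED:
        return predicate + _ORIENT_SUFFIX[orientation]
    return predicate


def path_signatures(
    path: PathInstance,
    variant: FeatureVariant,
    table: DirectionalityTable | None = None,
    *,
    unknown: str = "error",
) -> frozenset[str]:
    """The signature set one path contributes under a variant.

    A loop-free overlap path yields the bare ``overlap`` signature; direct
    paths are length-1 metapaths, identical under both representations.
    """
    mode = variant.direction_mode
    comps = [_component(p, o, mode, table, unknown) for p, o in path.edges]
    if path.scenario == OVERLAP:
        if not comps:
            return frozenset({OVERLAP})
        return frozenset({f"{OVERLAP}|{comps[0]}"})
    if path.scenario == DIRECT:
        return frozenset({f"{DIRECT}|{comps[0]}"})
    if variant.representation == METAPATH:
        # an indirect path whose components all lost their orientation has no
        # intrinsic direction: canonicalize the sequence so that traversals
        # from either side yield the same feature
        if all(c == p for c, (p, _) in zip(comps, path.edges)):
            comps = sorted(comps)
        return frozenset({f"{INDIRECT}|{_SEQ_SEP.join(comps)}"})
    return frozenset(f"{INDIRECT}|{c}" for c in comps)


def candidate_signatures(
    paths: PathCollection,
    variant: FeatureVariant,
    table: DirectionalityTable | None = None,
    *,
    unknown: str = "error",
) -> set[str]:
    """Union of signatures over all paths of one candidate."""
    out: set[str] = set()
    for path in paths:
        out |= path_signatures(path, variant, table, unknown=unknown)
    return out


class FeatureMatrix:
    """Candidates x binary signatures, stored sparsely.

    Columns are the sorted union of signatures over all candidates; a cell is
    true iff at least one path of the candidate yields that signature.
    """

    def __init__(
        self,
        row_ids: Sequence[str],
        columns: Sequence[str],
        matrix: sp.spmatrix,
        variant: FeatureVariant | None = None,
    ):
        self.row_ids = list(row_ids)
        self.columns = list(columns)
        self.matrix = sp.csr_matrix(matrix, dtype=np.int8)
        self.variant = variant
        if self.matrix.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError("matrix shape does not match row/column labels")

    @classmethod
    def from_signature_sets(
        cls,
        row_ids: Sequence[str],
        signature_sets: Sequence[Iterable[str]],
        variant: FeatureVariant | None = None,
    ) -> "FeatureMatrix":
        columns = sorted(set().union(*signature_sets)) if signature_sets else []
        col_index = {c: j for j, c in enumerate(columns)}
        rows, cols = [], []
        for i, sigs in enumerate(signature_sets):
            for s in sigs:
                rows.append(i)
                cols.append(col_index[s])
        matrix = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(len(row_ids), len(columns)),
        )
        return cls(row_ids, columns, matrix, variant)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.row_ids, columns=self.columns
        )

    def row_signatures(self, i: int) -> set[str]:
        return {self.columns[j] for j in self.matrix[i].indices}

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            [self.row_ids[i] for i in idx],
            self.columns,
            self.matrix[idx],
            self.variant,
        )

    def save(self, prefix: str | Path, *, dense: bool = False) -> None:
        """Write ``<prefix>.rows.tsv``, ``<prefix>.columns.tsv`` (the
        signature glossary) and ``<prefix>.mtx`` (coordinate format); with
        ``dense=True`` also a wide TSV for small runs."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.rows.tsv", "w", encoding="utf-8") as fh:
            for r in self.row_ids:
                fh.write(r + "\n")
        with open(f"{prefix}.columns.tsv", "w", encoding="utf-8") as fh:
            for c in self.columns:
                fh.write(c + "\n")
        scipy.io.mmwrite(f"{prefix}.mtx", sp.coo_matrix(self.matrix))
        if dense:
            self.to_dataframe().to_csv(f"{prefix}.dense.tsv", sep="\t")

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureMatrix":
        prefix = Path(prefix)
        with open(f"{prefix}.rows.tsv", encoding="utf-8") as fh:
            row_ids = [line.rstrip("\n") for line in fh if line.strip()]
        with open(f"{prefix}.columns.tsv", encoding="utf-8") as fh:
            columns = [line.rstrip("\n") for line in fh if line.strip()]
        matrix = sp.csr_matrix(scipy.io.mmread(f"{prefix}.mtx"))
        return cls(row_ids, columns, matrix)


def extract_candidate_paths(
    candidates: Sequence[CandidatePair],
    kg: KnowledgeGraph,
    **kwargs,
) -> list[PathCollection]:
    """Path collections for each candidate (shared across feature variants)."""
    out = []
    for c in candidates:
        if not c.proteins_first or not c.proteins_second:
            raise ValueError(
                f"candidate {c.pair_id} has an empty protein set; assign "
                f"disease proteins before featurization"
            )
        out.append(extract_paths(kg, c.proteins_first, c.proteins_second,
                                 **kwargs))
    return out


def build_feature_matrix(
    candidates: Sequence[CandidatePair],
    kg: KnowledgeGraph,
    variant: FeatureVariant,
    table: DirectionalityTable | None = None,
    *,
    path_collections: Sequence[PathCollection] | None = None,
    unknown: str = "error",
) -> FeatureMatrix:
    """Binary feature matrix for a list of candidates under one variant.

    Candidates with no paths at all keep an all-false row: pairs whose
    protein sets are unconnected in the graph are still classified.
    Precomputed ``path_collections`` (one per candidate) avoid re-extracting
    paths for every variant.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    if path_collections is None:
        path_collections = extract_candidate_paths(candidates, kg)
    if len(path_collections) != len(candidates):
        raise ValueError("path_collections must align with candidates")
    sig_sets = [
        candidate_signatures(paths, variant, table, unknown=unknown)
        for paths in path_collections
    ]
    return FeatureMatrix.from_signature_sets(
        [c.pair_id for c in candidates], sig_sets, variant
    )
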
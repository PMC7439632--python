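"""Feature signatures and matrices across the variant grid."""

import numpy as np
import pytest

from trajkg import (
    DirectionalityTable,
    FeatureVariant,
    KnowledgeGraph,
    Triple,
    build_feature_matrix,
    candidate_signatures,
    path_signatures,
    variant_from_name,
)
from trajkg.features import ALL_VARIANTS, PRIMARY_VARIANTS, FeatureMatrix
from trajkg.kg import FORWARD, LOOP, REVERSE
from trajkg.mapping import CandidatePair
from trajkg.paths import DIRECT, INDIRECT, OVERLAP, PathInstance, extract_paths

from conftest import random_graph


def mirror_signature(sig: str) -> str:
    """Expected signature of the same path seen from the reversed candidate:
    swap fwd/rev, reverse metapath component order, re-canonicalize."""
    scenario, _, body = sig.partition("|")
    if not body:
        return sig
    comps = body.split("->")
    comps = [c.replace(":fwd", ":@").replace(":rev", ":fwd")
              .replace(":@", ":rev") for c in comps]
    comps = list(reversed(comps))
    if all(":" not in c for c in comps):
        comps = sorted(comps)
    return f"{scenario}|" + "->".join(comps)


DIRECT_FWD = PathInstance(DIRECT, ("DP2", "DP4"), (("inhibits", FORWARD),))
DIRECT_REV = PathInstance(DIRECT, ("DP4", "DP2"), (("inhibits", REVERSE),))
INDIRECT_FR = PathInstance(
    INDIRECT, ("A", "M", "B"),
    (("inhibits", FORWARD), ("inhibits", REVERSE)),
)
OVERLAP_BARE = PathInstance(OVERLAP, ("DP1",), ())
OVERLAP_LOOP = PathInstance(OVERLAP, ("DP1",), (("binds with", LOOP),))


class TestPathSignatures:
    @pytest.mark.parametrize("path,variant,expected", [
        (DIRECT_FWD, "metapath-mixed", {"direct|inhibits:fwd"}),
        (DIRECT_REV, "metapath-mixed", {"direct|inhibits:rev"}),
        (DIRECT_FWD, "metapath-undirected", {"direct|inhibits"}),
        (DIRECT_REV, "split-undirected", {"direct|inhibits"}),
        (INDIRECT_FR, "metapath-mixed",
         {"indirect|inhibits:fwd->inhibits:rev"}),
        (INDIRECT_FR, "split-mixed",
         {"indirect|inhibits:fwd", "indirect|inhibits:rev"}),
        (INDIRECT_FR, "metapath-undirected", {"indirect|inhibits->inhibits"}),
        (OVERLAP_BARE, "metapath-mixed", {"overlap"}),
        (OVERLAP_LOOP, "metapath-mixed", {"overlap|binds with"}),
        (OVERLAP_LOOP, "split-undirected", {"overlap|binds with"}),
        # the all-directed variation orients even loop predicates
        (OVERLAP_LOOP, "metapath-directed", {"overlap|binds with:loop"}),
    ])
    def test_signature_examples(self, small_table, path, variant, expected):
        assert path_signatures(path, variant_from_name(variant),
                               small_table) == expected

    def test_direct_identical_under_both_representations(self, small_table):
        for mode in ("undirected", "mixed", "directed"):
            assert path_signatures(
                DIRECT_FWD, FeatureVariant("metapath", mode), small_table
            ) == path_signatures(
                DIRECT_FWD, FeatureVariant("split", mode), small_table
            )

    def test_orientation_free_metapath_is_reversal_invariant(self,
                                                             small_table):
        path = PathInstance(
            INDIRECT, ("A", "M", "B"),
            (("binds with", FORWARD), ("interacts with", REVERSE)),
        )
        v = FeatureVariant("metapath", "mixed")
        assert path_signatures(path, v, small_table) == \
            path_signatures(path.reversed(), v, small_table)

    def test_unknown_predicate_propagates_in_mixed(self, small_table):
        path = PathInstance(DIRECT, ("A", "B"), (("frobnicates", FORWARD),))
        with pytest.raises(KeyError):
            path_signatures(path, FeatureVariant("metapath", "mixed"),
                            small_table)
        # undirected mode never consults the table
        assert path_signatures(path, FeatureVariant("metapath", "undirected"),
                               small_table) == {"direct|frobnicates"}


class TestWorkedExampleMatrices:
    def test_four_variants_differ_as_expected(self, example_kg, example_sets,
                                              small_table):
        A, B = example_sets
        pc = extract_paths(example_kg, A, B)
        sigs = {v.name: candidate_signatures(pc, v, small_table)
                for v in PRIMARY_VARIANTS}
        # orientation appears on the directed "inhibits", never on the
        # undirected loop "binds with"
        assert "direct|inhibits:fwd" in sigs["metapath-mixed"]
        assert "direct|inhibits" in sigs["metapath-undirected"]
        for name in ("metapath-mixed", "split-mixed"):
            assert "overlap|binds with" in sigs[name]
            assert not any(":fwd" in s or ":rev" in s
                           for s in sigs[name] if "binds with" in s)
        # metapath concatenates the indirect legs, split separates them
        assert "indirect|inhibits:fwd->inhibits:fwd" in sigs["metapath-mixed"]
        assert {"indirect|inhibits:fwd"} == \
            {s for s in sigs["split-mixed"] if s.startswith("indirect")}
        assert "indirect|inhibits->inhibits" in sigs["metapath-undirected"]
        assert len({frozenset(s) for s in sigs.values()}) == 4

    def test_matrix_from_candidates(self, example_kg, small_table):
        cand = CandidatePair("DA", "DB", "positive",
                             frozenset({"DP1", "DP2", "DP3"}),
                             frozenset({"DP1", "DP4", "DP5"}))
        fm = build_feature_matrix([cand], example_kg,
                                  FeatureVariant("metapath", "mixed"),
                                  small_table)
        assert fm.shape[0] == 1
        assert fm.columns == sorted(fm.columns)
        assert fm.row_signatures(0) == {
            "overlap", "overlap|binds with", "direct|inhibits:fwd",
            "indirect|inhibits:fwd->inhibits:fwd",
        }


class TestFeatureMatrix:
    def test_candidate_without_paths_keeps_all_false_row(self, small_table):
        kg = KnowledgeGraph([Triple("X1", "inhibits", "X2")])
        cands = [
            CandidatePair("DA", "DB", "positive",
                          frozenset({"A1"}), frozenset({"B1"})),
            CandidatePair("DA", "DC", "negative",
                          frozenset({"X1"}), frozenset({"X2"})),
        ]
        fm = build_feature_matrix(cands, kg,
                                  FeatureVariant("split", "mixed"),
                                  small_table)
        assert fm.shape == (2, 1)
        assert fm.row_signatures(0) == set()

    def test_empty_candidate_list_rejected(self, example_kg, small_table):
        with pytest.raises(ValueError, match="empty candidate list"):
            build_feature_matrix([], example_kg,
                                 FeatureVariant("split", "mixed"),
                                 small_table)

    def test_empty_protein_set_rejected(self, example_kg, small_table):
        cand = CandidatePair("DA", "DB", "positive", frozenset(),
                             frozenset({"DP1"}))
        with pytest.raises(ValueError, match="empty protein set"):
            build_feature_matrix([cand], example_kg,
                                 FeatureVariant("split", "mixed"),
                                 small_table)

    def test_save_load_roundtrip(self, tmp_path, example_kg, small_table):
        cand = CandidatePair("DA", "DB", "positive",
                             frozenset({"DP1", "DP2", "DP3"}),
                             frozenset({"DP1", "DP4", "DP5"}))
        fm = build_feature_matrix([cand], example_kg,
                                  FeatureVariant("split", "undirected"),
                                  small_table)
        fm.save(tmp_path / "m", dense=True)
        fm2 = FeatureMatrix.load(tmp_path / "m")
        assert fm2.row_ids == fm.row_ids
        assert fm2.columns == fm.columns
        assert (fm2.matrix != fm.matrix).nnz == 0
        assert (tmp_path / "m.dense.tsv").exists()


def _random_candidates(rng, kg, n):
    proteins = sorted(kg.nodes)
    cands = []
    while len(cands) < n:
        A = frozenset(rng.choice(proteins, size=4, replace=False))
        B = frozenset(rng.choice(proteins, size=4, replace=False))
        label = "positive" if rng.random() < 0.5 else "negative"
        cands.append(CandidatePair(f"DA{len(cands)}", f"DB{len(cands)}",
                                   label, A, B))
    return cands


class TestVariantProperties:
    def test_cells_match_naive_recomputation(self, default_table):
        # oracle: recompute each candidate's signatures path-by-path
        rng = np.random.default_rng(4)
        kg = random_graph(rng, n_proteins=25, n_triples=200,
                          predicates=("inhibits", "binds with",
                                      "stimulates", "interacts with"))
        cands = _random_candidates(rng, kg, 50)
        for variant in ALL_VARIANTS:
            fm = build_feature_matrix(cands, kg, variant, default_table)
            for i, c in enumerate(cands):
                pc = extract_paths(kg, c.proteins_first, c.proteins_second)
                expected = set()
                for path in pc:
                    expected |= path_signatures(path, variant, default_table)
                assert fm.row_signatures(i) == expected

    def test_reversal_symmetries(self, default_table):
        rng = np.random.default_rng(6)
        kg = random_graph(rng, n_proteins=20, n_triples=180,
                          predicates=("inhibits", "binds with",
                                      "interacts with", "stimulates"))
        cands = _random_candidates(rng, kg, 20)
        for c in cands:
            pc_ab = extract_paths(kg, c.proteins_first, c.proteins_second)
            pc_ba = extract_paths(kg, c.proteins_second, c.proteins_first)
            und = FeatureVariant("metapath", "undirected")
            assert candidate_signatures(pc_ab, und, default_table) == \
                candidate_signatures(pc_ba, und, default_table)
            for mode in ("mixed", "directed"):
                for repr_ in ("metapath", "split"):
                    v = FeatureVariant(repr_, mode)
                    ab = candidate_signatures(pc_ab, v, default_table)
                    ba = candidate_signatures(pc_ba, v, default_table)
                    assert {mirror_signature(s) for s in ab} == ba

    def test_mixed_with_all_undirected_table_equals_undirected_mode(self):
        rng = np.random.default_rng(14)
        preds = ("inhibits", "binds with", "stimulates")
        kg = random_graph(rng, n_proteins=18, n_triples=150,
                          predicates=preds)
        all_und = DirectionalityTable({p: "undirected" for p in preds})
        cands = _random_candidates(rng, kg, 15)
        for repr_ in ("metapath", "split"):
            fm_mixed = build_feature_matrix(
                cands, kg, FeatureVariant(repr_, "mixed"), all_und)
            fm_und = build_feature_matrix(
                cands, kg, FeatureVariant(repr_, "undirected"), all_und)
            assert fm_mixed.columns == fm_und.columns
            assert (fm_mixed.matrix != fm_und.matrix).nnz == 0

    def test_split_components_equal_metapath_components(self, default_table):
        rng = np.random.default_rng(19)
        kg = random_graph(rng, n_proteins=15, n_triples=120)
        cands = _random_candidates(rng, kg, 10)
        v_meta = FeatureVariant("metapath", "mixed")
        v_split = FeatureVariant("split", "mixed")
        for c in cands:
            pc = extract_paths(kg, c.proteins_first, c.proteins_second)
            meta = candidate_signatures(pc, v_meta, default_table)
            split = candidate_signatures(pc, v_split, default_table)
            meta_comps = set()
            for s in meta:
                if s.startswith("indirect|"):
                    meta_comps |= set(s.split("|", 1)[1].split("->"))
            split_comps = {s.split("|", 1)[1] for s in split
                           if s.startswith("indirect|")}
            # sorting of orientation-free metapaths permutes, never alters,
            # the component multiset
            assert meta_comps == split_comps

    def test_split_column_bound(self, default_table):
        rng = np.random.default_rng(23)
        kg = random_graph(rng, n_proteins=20, n_triples=200)
        cands = _random_candidates(rng, kg, 30)
        fm = build_feature_matrix(cands, kg, FeatureVariant("split", "mixed"),
                                  default_table)
        pairs = set()
        for t in kg.triples:
            pairs.add((t.predicate, "fwd"))
            pairs.add((t.predicate, "rev"))
        n_split_indirect = sum(c.startswith("indirect|")
                               for c in fm.columns)
        assert n_split_indirect <= len(pairs)
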
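"""Model/Results interface for trajectory classification experiments.

:class:`TrajectoryModel` bundles a candidate-pair set and a knowledge graph,
builds the requested feature-set variants from the same per-candidate path
collections, and :meth:`TrajectoryModel.fit` runs the fold-matched repeated
cross-validation protocol, returning a :class:`TrajectoryResults` with the
per-variant AUCs, all paired direction-mode comparisons within each
representation, and a summary table.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import (
    CVResult,
    PairedComparison,
    make_fold_map,
    paired_fold_ttest,
    roc_youden,
    run_cv,
    undersample,
)
from .features import (
    PRIMARY_VARIANTS,
    FeatureMatrix,
    FeatureVariant,
    build_feature_matrix,
    extract_candidate_paths,
)
from .kg import DirectionalityTable, KnowledgeGraph
from .mapping import POSITIVE, CandidatePair


class TrajectoryModel:
    """Disease-trajectory classifier over knowledge-graph path features.

    Parameters
    ----------
    candidates
        Labelled ordered disease pairs with non-empty protein sets.
    kg
        The protein knowledge graph.
    directionality
        Predicate directionality table; defaults to the packaged fixture.
    variants
        Feature-set variants to build (default: the four primary sets).

    Path collections are extracted once per candidate and shared by all
    variants, mirroring the fact that the feature sets are four views of the
    same extracted paths.
    """

    def __init__(
        self,
        candidates: Sequence[CandidatePair],
        kg: KnowledgeGraph,
        directionality: DirectionalityTable | None = None,
        variants: Sequence[FeatureVariant] = PRIMARY_VARIANTS,
    ):
        if not candidates:
            raise ValueError("empty candidate list")
        self.candidates = list(candidates)
        self.kg = kg
        self.directionality = directionality or DirectionalityTable.default()
        self.variants = tuple(variants)
        if not self.variants:
            raise ValueError("at least one feature variant is required")
        self.labels = np.array(
            [1 if c.label == POSITIVE else 0 for c in self.candidates]
        )
        self.path_collections = extract_candidate_paths(self.candidates, kg)
        self.matrices: dict[str, FeatureMatrix] = {
            v.name: build_feature_matrix(
                self.candidates, kg, v, self.directionality,
                path_collections=self.path_collections,
            )
            for v in self.variants
        }

    def path_count_frame(self) -> pd.DataFrame:
        """Per-candidate scenario counts (overlap / direct / indirect)."""
        rows = [
            {"pair": c.pair_id, "label": c.label, **pc.counts()}
            for c, pc in zip(self.candidates, self.path_collections)
        ]
        return pd.DataFrame(rows).set_index("pair")

    def fit(
        self,
        *,
        repeats: int = 10,
        folds: int = 10,
        seed: int = 0,
        rf_params: Mapping | None = None,
        undersample_to: tuple[int, int] | None = None,
    ) -> "TrajectoryResults":
        """Run fold-matched repeated CV for every variant.

        ``undersample_to=(n_pos, n_neg)`` first draws a seeded subsample
        with exact class counts (class-prevalence control).  One fold map is
        computed from the labels and reused by every variant, so that the
        returned paired comparisons are over matched folds.
        """
        labels = self.labels
        row_subset = None
        if undersample_to is not None:
            n_pos, n_neg = undersample_to
            row_subset = undersample(labels, n_pos, n_neg, seed)
            labels = labels[row_subset]

        fold_map = make_fold_map(labels, repeats, folds, seed)
        cv_results: dict[str, CVResult] = {}
        for v in self.variants:
            matrix = self.matrices[v.name]
            if row_subset is not None:
                matrix = matrix.subset_rows(row_subset)
            cv_results[v.name] = run_cv(
                matrix, labels,
                repeats=repeats, folds=folds, seed=seed,
                model_params=rf_params, fold_map=fold_map,
                variant_name=v.name,
            )

        # all pairwise direction-mode comparisons within each representation
        comparisons: dict[tuple[str, str], PairedComparison] = {}
        by_repr: dict[str, list[FeatureVariant]] = {}
        for v in self.variants:
            by_repr.setdefault(v.representation, []).append(v)
        for rep_variants in by_repr.values():
            for va, vb in itertools.combinations(rep_variants, 2):
                comparisons[(va.name, vb.name)] = paired_fold_ttest(
                    cv_results[va.name], cv_results[vb.name]
                )
        return TrajectoryResults(self, cv_results, comparisons,
                                 row_subset=row_subset, seed=seed)


class TrajectoryResults:
    """Cross-validated performance of the feature-set variants."""

    def __init__(
        self,
        model: TrajectoryModel,
        cv_results: dict[str, CVResult],
        comparisons: dict[tuple[str, str], PairedComparison],
        *,
        row_subset: np.ndarray | None = None,
        seed: int = 0,
    ):
        self.model = model
        self.cv_results = cv_results
        self.comparisons = comparisons
        self.row_subset = row_subset
        self.seed = seed

    def mean_auc(self, variant: str) -> float:
        return self.cv_results[variant].mean_auc

    def sd_auc(self, variant: str) -> float:
        return self.cv_results[variant].sd_auc

    def summary_frame(self) -> pd.DataFrame:
        """One row per variant: mean AUC, its sd, repeats and folds."""
        rows = []
        for name, cv in self.cv_results.items():
            rows.append({
                "variant": name,
                "mean_auc": cv.mean_auc,
                "sd_auc": cv.sd_auc,
                "repeats": cv.repeats,
                "folds": cv.folds,
            })
        return pd.DataFrame(rows).set_index("variant")

    def comparison_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), cmp in self.comparisons.items():
            rows.append({
                "variant_a": a,
                "variant_b": b,
                "mean_auc_difference": cmp.mean_difference,
                "t_statistic": cmp.t_statistic,
                "p_value": cmp.p_value,
                "df": cmp.df,
            })
        return pd.DataFrame(rows)

    def youden(self, variant: str, *, repeat: int = 0):
        """Youden-optimal operating point of a variant's out-of-fold scores.

        Scores are the pooled out-of-fold probabilities of one CV repeat
        (default the first), so the operating point is estimated on data the
        per-fold models never trained on.
        """
        cv = self.cv_results[variant]
        return roc_youden(cv.oof_scores[repeat], cv.labels)

    def summary(self) -> str:
        """Text summary: variant grid of ``mean (sd)`` AUC percentages plus
        the paired direction-mode comparisons."""
        reprs, modes = [], []
        for v in self.model.variants:
            if v.representation not in reprs:
                reprs.append(v.representation)
            if v.direction_mode not in modes:
                modes.append(v.direction_mode)
        lines = ["Trajectory classification (mean AUC % over "
                 f"{next(iter(self.cv_results.values())).repeats}x"
                 f"{next(iter(self.cv_results.values())).folds} CV)",
                 ""]
        header = f"{'direction':<12}" + "".join(f"{r:>18}" for r in reprs)
        lines.append(header)
        for mode in modes:
            cells = []
            for r in reprs:
                name = f"{r}-{mode}"
                if name in self.cv_results:
                    cv = self.cv_results[name]
                    cells.append(f"{100 * cv.mean_auc:5.1f} "
                                 f"({100 * cv.sd_auc:4.1f})")
                else:
                    cells.append("-")
            lines.append(f"{mode:<12}" + "".join(f"{c:>18}" for c in cells))
        if self.comparisons:
            lines.append("")
            lines.append("Paired comparisons (two-sided t over matched folds):")
            for (a, b), cmp in self.comparisons.items():
                lines.append(
                    f"  {a} vs {b}: dAUC={100 * cmp.mean_difference:+.1f}pp, "
                    f"t={cmp.t_statistic:.2f}, p={cmp.p_value:.2g}"
                )
        return "\n".join(lines)

    def plot_roc(self, variant: str, *, repeat: int = 0, ax=None):
        """ROC curve of one variant's pooled out-of-fold scores."""
        import matplotlib.pyplot as plt

        yr = self.youden(variant, repeat=repeat)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(yr.fpr, yr.tpr, label=variant)
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
        ax.scatter([1 - yr.specificity], [yr.sensitivity], marker="o",
                   color="black", zorder=3,
                   label=f"Youden J={yr.youden_j:.2f}")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax
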
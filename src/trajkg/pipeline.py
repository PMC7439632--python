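"""End-to-end orchestration: map -> extract -> featurize -> evaluate -> compare.

A run is described by a plain-text ``key=value`` config.  The pipeline loads
the input tables, assigns disease proteins, builds all requested feature
variants from shared path collections, runs fold-matched repeated CV, and
writes a summary TSV (variant, mean_auc, sd_auc), the paired comparisons,
ROC coordinates, per-candidate path counts, and a manifest recording the
seeds and inputs needed to reproduce every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .features import PRIMARY_VARIANTS, variant_from_name
from .kg import DirectionalityTable, load_triples
from .mapping import (
    ConceptMapping,
    GeneDiseaseAssociations,
    SubclassHierarchy,
    attach_disease_proteins,
    load_pairs,
)
from .model import TrajectoryModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and settings of one pipeline run."""

    triples: Path
    pairs: Path
    associations: Path
    out_dir: Path
    mapping: Path | None = None
    hierarchy: Path | None = None
    directionality: Path | None = None
    variants: tuple[str, ...] = tuple(v.name for v in PRIMARY_VARIANTS)
    repeats: int = 10
    folds: int = 10
    seed: int = 0
    rf_trees: int = 500
    undersample_pos: int | None = None
    undersample_neg: int | None = None
    write_matrices: bool = False

    def validate(self) -> None:
        if not self.variants:
            raise ValueError("variant list is empty")
        for name in ("triples", "pairs", "associations", "mapping",
                     "hierarchy", "directionality"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if (self.undersample_pos is None) != (self.undersample_neg is None):
            raise ValueError("undersample_pos and undersample_neg must be "
                             "given together")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a ``key=value`` config file ('#' lines are comments)."""
        raw: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: line {lineno}: expected "
                                     f"key=value")
                key, value = line.split("=", 1)
                raw[key.strip()] = value.strip()
        kwargs: dict = {}
        for key in ("triples", "pairs", "associations", "out_dir", "mapping",
                    "hierarchy", "directionality"):
            if key in raw:
                kwargs[key] = Path(raw.pop(key))
        if "variants" in raw:
            kwargs["variants"] = tuple(
                v.strip() for v in raw.pop("variants").split(",") if v.strip()
            )
        for key in ("repeats", "folds", "seed", "rf_trees",
                    "undersample_pos", "undersample_neg"):
            if key in raw:
                kwargs[key] = int(raw.pop(key))
        if "write_matrices" in raw:
            kwargs["write_matrices"] = raw.pop("write_matrices").lower() in (
                "1", "true", "yes")
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def to_text(self) -> str:
        lines = []
        for key, value in self.__dict__.items():
            if value is None:
                continue
            if isinstance(value, tuple):
                value = ",".join(value)
            lines.append(f"{key}={value}")
        return "\n".join(lines) + "\n"


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the report dict written to the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.txt").write_text(config.to_text(), encoding="utf-8")

    with _stage("load"):
        kg = load_triples(config.triples)
        table = (DirectionalityTable.from_tsv(config.directionality)
                 if config.directionality else DirectionalityTable.default())
        associations = GeneDiseaseAssociations.from_tsv(config.associations)
        mapping = (ConceptMapping.from_tsv(config.mapping)
                   if config.mapping else None)
        hierarchy = (SubclassHierarchy.from_tsv(config.hierarchy)
                     if config.hierarchy else None)
        pairs = load_pairs(config.pairs)

    with _stage("map"):
        candidates, dropped = attach_disease_proteins(
            pairs, mapping, hierarchy, associations
        )
        if not candidates:
            raise PipelineError(
                "stage 'map' failed: no candidate pair has proteins on both "
                "sides"
            )

    with _stage("featurize"):
        variants = [variant_from_name(n) for n in config.variants]
        model = TrajectoryModel(candidates, kg, table, variants)
        model.path_count_frame().to_csv(out / "path_counts.tsv", sep="\t")
        if config.write_matrices:
            for name, matrix in model.matrices.items():
                matrix.save(out / f"features_{name}")

    with _stage("evaluate"):
        undersample_to = None
        if config.undersample_pos is not None:
            undersample_to = (config.undersample_pos, config.undersample_neg)
        results = model.fit(
            repeats=config.repeats, folds=config.folds, seed=config.seed,
            rf_params={"n_estimators": config.rf_trees},
            undersample_to=undersample_to,
        )

    with _stage("report"):
        summary = results.summary_frame()
        summary.to_csv(out / "summary.tsv", sep="\t",
                       float_format="%.6f")
        comparisons = results.comparison_frame()
        comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False,
                           float_format="%.6g")
        for name in config.variants:
            yr = results.youden(name)
            with open(out / f"roc_{name}.tsv", "w", encoding="utf-8") as fh:
                fh.write("threshold\tsensitivity\tspecificity\n")
                for t, tp, fp in zip(yr.thresholds, yr.tpr, yr.fpr):
                    fh.write(f"{t:.6g}\t{tp:.6f}\t{1 - fp:.6f}\n")
        (out / "summary.txt").write_text(results.summary() + "\n",
                                         encoding="utf-8")

    report = {
        "version": __version__,
        "seed": config.seed,
        "repeats": config.repeats,
        "folds": config.folds,
        "rf_trees": config.rf_trees,
        "variants": list(config.variants),
        "n_candidates": len(candidates),
        "n_dropped_unmappable": len(dropped),
        "inputs": {
            "triples": str(config.triples),
            "pairs": str(config.pairs),
            "associations": str(config.associations),
            "mapping": str(config.mapping) if config.mapping else None,
            "hierarchy": str(config.hierarchy) if config.hierarchy else None,
            "directionality": (str(config.directionality)
                               if config.directionality else "packaged fixture"),
        },
        "summary": {
            name: {"mean_auc": results.mean_auc(name),
                   "sd_auc": results.sd_auc(name)}
            for name in config.variants
        },
        "comparisons": [
            {"a": a, "b": b, "mean_difference": cmp.mean_difference,
             "t": cmp.t_statistic, "p": cmp.p_value}
            for (a, b), cmp in results.comparisons.items()
        ],
    }
    (out / "manifest.json").write_text(json.dumps(report, indent=2),
                                       encoding="utf-8")
    return report
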
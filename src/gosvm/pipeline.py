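"""End-to-end orchestration: load → tasks → rotation CV → evaluation → reports.

Each category runs independently with a seed derived from the master seed
and the term id, so adding or removing one category never perturbs
another's results and categories may run in any order.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, evaluation, reporting, rotation_cv, task_builder

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a full prediction run."""

    expression_path: str | Path | None = None
    annotations_path: str | Path | None = None
    annotations_format: str = "two_column"
    idmap_path: str | Path | None = None
    outdir: str | Path | None = None
    min_size: int = 10
    max_size: int = 999
    neg_ratio: int = 4
    recall_levels: tuple[float, ...] = (0.2, 0.3, 0.4)
    prec_threshold: float = 0.75
    gene_prec_threshold: float = 0.75
    impute: str = "zero"
    group_duplicates: bool = False
    include_terms: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.prec_threshold, self.gene_prec_threshold):
            if not (0.0 <= thr <= 1.0):
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class CategoryResult:
    performance: evaluation.CategoryPerformance
    gene_records: list[evaluation.GenePrecisionRecord]
    prob_table: rotation_cv.ProbabilityTable
    task: task_builder.CategoryTask


@dataclass
class PipelineResult:
    categories: dict[str, CategoryResult]
    predictions: list[reporting.PredictionRecord]
    summary: dict
    failures: dict[str, str] = field(default_factory=dict)


def derive_seed(master_seed: int, term_id: str, stage: str = "") -> int:
    """Deterministic per-category seed: CRC of (master, term, stage), < 2^31."""
    return zlib.crc32(f"{master_seed}:{term_id}:{stage}".encode()) & 0x7FFFFFFF


def run_category(
    X: np.ndarray,
    gene_ids: list[str],
    annotations: data_io.AnnotationTable,
    term_id: str,
    cfg: RunConfig,
) -> CategoryResult:
    """Task construction, rotation CV and PR summary for one category."""
    task = task_builder.sample_negatives(
        term_id, annotations, gene_ids, ratio=cfg.neg_ratio,
        seed=derive_seed(cfg.seed, term_id, "neg"),
    )
    partition = task_builder.stratified_partition(
        task, k=4, seed=derive_seed(cfg.seed, term_id, "fold"),
        gene_ids=gene_ids, group_duplicates=cfg.group_duplicates,
    )
    prob_table = rotation_cv.run_category(X, task, partition)

    fold_probs = []
    for fold_idx in range(4):
        sub = prob_table.labeled[prob_table.labeled["test_fold"] == fold_idx]
        fold_probs.append((sub["p_mean"].to_numpy(), sub["label"].to_numpy()))
    unl = {
        int(row): grp.sort_values("fold")["p_mean"].tolist()
        for row, grp in prob_table.unlabeled.groupby("row")
    }
    performance, records, _curves = evaluation.summarize_category(
        term_id, fold_probs, unl, recall_levels=cfg.recall_levels,
    )
    return CategoryResult(performance=performance, gene_records=records,
                          prob_table=prob_table, task=task)


def run_analysis(
    matrix: data_io.ExpressionMatrix,
    annotations: data_io.AnnotationTable,
    cfg: RunConfig,
) -> PipelineResult:
    """Run every eligible category on an in-memory matrix."""
    imputed = data_io.impute_missing(matrix, method=cfg.impute)
    X = imputed.values
    gene_ids = imputed.gene_ids
    represented = {g for i, g in enumerate(gene_ids)
                   if not g.startswith(data_io.UNMAPPED_PREFIX)}
    selected = task_builder.select_categories(
        annotations, represented, min_size=cfg.min_size, max_size=cfg.max_size,
    )
    if cfg.include_terms is not None:
        wanted = set(cfg.include_terms)
        selected = [(t, c) for t, c in selected if t in wanted]
    logger.info("%d categories selected (size window %d..%d)",
                len(selected), cfg.min_size, cfg.max_size)

    categories: dict[str, CategoryResult] = {}
    failures: dict[str, str] = {}
    for term_id, count in selected:
        t0 = time.perf_counter()
        try:
            categories[term_id] = run_category(X, gene_ids, annotations, term_id, cfg)
            logger.info("category %s (n=%d) done in %.2fs", term_id, count,
                        time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - skip and continue per contract
            failures[term_id] = str(exc)
            logger.error("category %s failed: %s", term_id, exc)

    all_records = [r for c in categories.values() for r in c.gene_records]
    predictions = reporting.select_predictions(
        all_records, gene_ids, matrix.row_ids, threshold=cfg.gene_prec_threshold,
    )
    high_prec = reporting.select_high_precision_categories(
        [c.performance for c in categories.values()],
        threshold=cfg.prec_threshold,
        recall_level=max(cfg.recall_levels),
    )
    predicted_genes = {p.gene_id for p in predictions}
    unannotated_genes = {g for g in represented if g not in annotations.genes}
    summary = {
        "n_categories_selected": len(selected),
        "n_categories_evaluated": len(categories),
        "n_categories_failed": len(failures),
        "n_high_precision_categories": len(high_prec),
        "high_precision_terms": [p.term_id for p in high_prec],
        "n_predictions": len(predictions),
        "n_predicted_genes": len(predicted_genes),
        "n_array_genes": len(represented),
        "n_unannotated_genes": len(unannotated_genes),
        "seed": cfg.seed,
    }
    if unannotated_genes:
        ratio, pct = reporting.coverage_stats(len(predicted_genes), len(unannotated_genes))
        summary["predicted_coverage_ratio"] = ratio
        summary["predicted_coverage_pct"] = pct
    if represented:
        ratio, pct = reporting.coverage_stats(len(unannotated_genes), len(represented))
        summary["unannotated_ratio"] = ratio
        summary["unannotated_pct"] = pct
    return PipelineResult(categories=categories, predictions=predictions,
                          summary=summary, failures=failures)


def performance_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for term_id, c in sorted(result.categories.items()):
        rec: dict = {"term_id": term_id,
                     "n_pos": len(c.task.positives), "n_neg": len(c.task.negatives)}
        for r, vals in sorted(c.performance.per_fold_prec_at.items()):
            for f, v in enumerate(vals):
                rec[f"prec{int(round(100 * r))}_fold{f + 1}"] = v
            rec[f"prec{int(round(100 * r))}_mean"] = c.performance.mean_prec_at[r]
        rows.append(rec)
    return pd.DataFrame(rows)


def predictions_frame(result: PipelineResult) -> pd.DataFrame:
    rows = [{
        "gene_id": p.gene_id, "clone_id": p.clone_id, "term_id": p.term_id,
        "mean_gene_precision": p.mean_gene_precision,
        **{f"p_fold{i + 1}": v for i, v in enumerate(p.per_fold_prob)},
    } for p in result.predictions]
    return pd.DataFrame(rows, columns=[
        "gene_id", "clone_id", "term_id", "mean_gene_precision",
        "p_fold1", "p_fold2", "p_fold3", "p_fold4",
    ])


def gene_precision_frame(result: PipelineResult, matrix: data_io.ExpressionMatrix) -> pd.DataFrame:
    rows = []
    for term_id, c in sorted(result.categories.items()):
        for rec in c.gene_records:
            rows.append({
                "term_id": term_id,
                "gene_id": matrix.gene_ids[rec.row],
                "clone_id": matrix.row_ids[rec.row],
                "mean_gene_precision": rec.mean_score,
                **{f"gp_fold{i + 1}": v for i, v in enumerate(rec.per_fold_score)},
                **{f"p_fold{i + 1}": v for i, v in enumerate(rec.per_fold_prob)},
            })
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, matrix: data_io.ExpressionMatrix,
                  outdir: str | Path) -> None:
    """Write performance/probability/gene-precision/prediction tables + summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    performance_frame(result).to_csv(outdir / "performance.tsv", sep="\t", index=False)
    predictions_frame(result).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    gene_precision_frame(result, matrix).to_csv(
        outdir / "gene_precision.tsv", sep="\t", index=False)
    prob_frames = [
        c.prob_table.to_frame(term_id, matrix.row_ids, matrix.gene_ids)
        for term_id, c in sorted(result.categories.items())
    ]
    if prob_frames:
        pd.concat(prob_frames, ignore_index=True).to_csv(
            outdir / "probabilities.tsv", sep="\t", index=False)
    task_builder.write_task_manifest(
        [c.task for c in result.categories.values()], outdir / "tasks.tsv")
    with (outdir / "summary.json").open("w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """File-based entry point: load inputs, run the analysis, write outputs."""
    if cfg.expression_path is None or cfg.annotations_path is None:
        raise ValueError("expression_path and annotations_path are required")
    matrix = data_io.load_expression_matrix(cfg.expression_path)
    if cfg.idmap_path is not None:
        matrix = data_io.map_ids(matrix, data_io.load_id_map(cfg.idmap_path))
    annotations = data_io.load_annotations(cfg.annotations_path, format=cfg.annotations_format)
    result = run_analysis(matrix, annotations, cfg)
    if cfg.outdir is not None:
        write_outputs(result, matrix, cfg.outdir)
    return result
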
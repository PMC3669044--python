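"""Build per-category binary classification tasks and stratified folds.

A GO-BP term defines one task: its annotated genes on the array are the
positive class; negatives are drawn at a 1:4 positive:negative ratio from
genes that carry at least one *other* BP annotation (genes with no BP term
at all have unknown class and are only ever scored, never trained on).
Labeled rows are split into four folds of near-equal size with near-equal
positive counts, the stratification the double cross-validation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import AnnotationTable, UNMAPPED_PREFIX


@dataclass(frozen=True)
class CategoryTask:
    """Row-index sets for one category's classification problem."""

    term_id: str
    positives: frozenset[int]
    negatives: frozenset[int]
    unlabeled: frozenset[int]
    seed: int

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        if self.unlabeled & (self.positives | self.negatives):
            raise ValueError("unlabeled rows overlap labeled rows")

    @property
    def labeled(self) -> frozenset[int]:
        return self.positives | self.negatives

    def labels(self, rows: Sequence[int]) -> np.ndarray:
        """+1/-1 label vector for the given labeled rows."""
        return np.array([1 if r in self.positives else -1 for r in rows], dtype=float)


@dataclass(frozen=True)
class FoldPartition:
    """Four disjoint row-index sets covering a task's labeled rows."""

    folds: tuple[frozenset[int], ...]
    seed: int

    def __post_init__(self) -> None:
        all_rows = [r for fold in self.folds for r in fold]
        if len(all_rows) != len(set(all_rows)):
            raise ValueError("folds are not disjoint")

    @property
    def k(self) -> int:
        return len(self.folds)


def eligible_rows(gene_ids: Sequence[str]) -> list[int]:
    """Row indices whose gene id is usable (mapped to a real gene)."""
    return [i for i, g in enumerate(gene_ids) if not g.startswith(UNMAPPED_PREFIX)]


def select_categories(
    annotations: AnnotationTable,
    represented_genes: set[str] | frozenset[str],
    min_size: int = 10,
    max_size: int = 999,
) -> list[tuple[str, int]]:
    """Terms whose represented-gene membership lies in [min_size, max_size].

    Counts are over genes present on the array, not over the full annotation
    corpus.  Returned sorted by term id for determinism.
    """
    if min_size > max_size:
        raise ValueError("min_size exceeds max_size")
    if not represented_genes:
        raise ValueError("represented_genes is empty")
    counts: dict[str, int] = {}
    for gene, term in annotations.pairs:
        if gene in represented_genes:
            counts[term] = counts.get(term, 0) + 1
    return sorted((t, c) for t, c in counts.items() if min_size <= c <= max_size)


def sample_negatives(
    term_id: str,
    annotations: AnnotationTable,
    gene_ids: Sequence[str],
    ratio: int = 4,
    seed: int = 0,
) -> CategoryTask:
    """Assemble a category task with 1:``ratio`` negative subsampling.

    ``gene_ids`` gives the gene of each matrix row; duplicate clone rows of
    the same gene all enter the task.  Negatives are sampled uniformly
    without replacement from rows of BP-annotated genes lacking this term.
    """
    rows = eligible_rows(gene_ids)
    annotated = annotations.genes
    members = annotations.genes_for(term_id)
    positives = [i for i in rows if gene_ids[i] in members]
    pool = [i for i in rows if gene_ids[i] in annotated and gene_ids[i] not in members]
    unlabeled = [i for i in rows if gene_ids[i] not in annotated]
    if not positives:
        raise ValueError(f"term {term_id!r} has no positive rows")
    if not pool:
        raise ValueError(f"term {term_id!r} has an empty negative pool")
    rng = np.random.default_rng(seed)
    n_neg = min(ratio * len(positives), len(pool))
    negatives = rng.choice(len(pool), size=n_neg, replace=False)
    return CategoryTask(
        term_id=term_id,
        positives=frozenset(positives),
        negatives=frozenset(pool[i] for i in negatives),
        unlabeled=frozenset(unlabeled),
        seed=seed,
    )


def stratified_partition(
    task: CategoryTask,
    k: int = 4,
    seed: int = 0,
    *,
    gene_ids: Sequence[str] | None = None,
    group_duplicates: bool = False,
) -> FoldPartition:
    """Split labeled rows into ``k`` folds, stratified on the positive class.

    Fold sizes differ by at most one, as do per-fold positive counts; which
    folds take the remainders is decided by a seeded shuffle.  With
    ``group_duplicates`` (requires ``gene_ids``), duplicate clone rows of the
    same gene are forced into one fold by greedy balanced assignment of
    gene-groups; the ±1 balance then holds only approximately.
    """
    pos = sorted(task.positives)
    neg = sorted(task.negatives)
    if len(pos) < k:
        raise ValueError(f"need at least {k} positives, have {len(pos)}")
    rng = np.random.default_rng(seed)

    if group_duplicates:
        if gene_ids is None:
            raise ValueError("group_duplicates requires gene_ids")
        return _grouped_partition(task, k, rng, gene_ids, seed)

    n = len(pos) + len(neg)
    sizes = _balanced_counts(n, k, rng)
    pos_counts = _balanced_counts(len(pos), k, rng)
    neg_counts = [s - p for s, p in zip(sizes, pos_counts)]
    if min(neg_counts) < 0:
        # negatives scarce: align the larger folds with the larger positive
        # counts so every fold keeps a nonnegative negative quota
        pos_counts = sorted(pos_counts, reverse=True)
        sizes = sorted(sizes, reverse=True)
        neg_counts = [s - p for s, p in zip(sizes, pos_counts)]
        if min(neg_counts) < 0:
            raise ValueError("cannot satisfy fold-size and stratification constraints")
    pos_perm = list(rng.permutation(pos))
    neg_perm = list(rng.permutation(neg))
    folds = []
    ip = inn = 0
    for pc, nc in zip(pos_counts, neg_counts):
        folds.append(frozenset(int(r) for r in pos_perm[ip:ip + pc] + neg_perm[inn:inn + nc]))
        ip += pc
        inn += nc
    return FoldPartition(folds=tuple(folds), seed=seed)


def _balanced_counts(n: int, k: int, rng: np.random.Generator) -> list[int]:
    """k counts summing to n, each n//k or n//k+1, remainder placed at random."""
    base, rem = divmod(n, k)
    counts = [base] * k
    for i in rng.choice(k, size=rem, replace=False):
        counts[i] += 1
    return counts


def _grouped_partition(
    task: CategoryTask,
    k: int,
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    seed: int,
) -> FoldPartition:
    groups: dict[str, list[int]] = {}
    for r in sorted(task.labeled):
        groups.setdefault(gene_ids[r], []).append(r)
    order = list(rng.permutation(sorted(groups)))
    # positive-bearing groups first so positive balance is filled greedily
    order.sort(key=lambda g: -sum(1 for r in groups[g] if r in task.positives))
    fold_rows: list[list[int]] = [[] for _ in range(k)]
    fold_pos: list[int] = [0] * k
    for g in order:
        rows = groups[g]
        npos = sum(1 for r in rows if r in task.positives)
        if npos:
            target = min(range(k), key=lambda i: (fold_pos[i], len(fold_rows[i])))
        else:
            target = min(range(k), key=lambda i: (len(fold_rows[i]), fold_pos[i]))
        fold_rows[target].extend(rows)
        fold_pos[target] += npos
    return FoldPartition(folds=tuple(frozenset(f) for f in fold_rows), seed=seed)


def write_task_manifest(tasks: list[CategoryTask], path) -> None:
    """TSV manifest: term_id, n_pos, n_neg, n_unlabeled, seed."""
    with open(path, "w") as fh:
        fh.write("term_id\tn_pos\tn_neg\tn_unlabeled\tseed\n")
        for t in sorted(tasks, key=lambda t: t.term_id):
            fh.write(
                f"{t.term_id}\t{len(t.positives)}\t{len(t.negatives)}\t"
                f"{len(t.unlabeled)}\t{t.seed}\n"
            )
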
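"""Double cross-validation rotation over a stratified 4-fold partition.

For each test fold I_α the remaining three folds rotate through the roles of
calibration fold I_β and SVM-training pair I_γ ∪ I_δ, giving three
probability estimates p_β|γ,δ per test gene which are averaged into one.
Un-annotated genes are scored by every arrangement, yielding four per-fold
mean probabilities per gene.  The training pair is unordered, so one
category costs 12 SVM fits.  Nothing from the test fold ever reaches SVM
training or sigmoid fitting, and the calibration fold never reaches SVM
training; both exclusions are asserted structurally on every run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration as cal
from . import kernel_svm as ks
from .task_builder import CategoryTask, FoldPartition


@dataclass(frozen=True)
class Arrangement:
    """One (test | calibration | training-pair) role assignment of 4 folds."""

    test_fold: int
    calib_fold: int
    train_folds: frozenset[int]

    def __post_init__(self) -> None:
        roles = {self.test_fold, self.calib_fold} | self.train_folds
        if len(self.train_folds) != 2 or len(roles) != 4:
            raise ValueError("arrangement roles must cover 4 distinct folds")


@dataclass
class ProbabilityTable:
    """Per-gene probability estimates from the 12-arrangement rotation.

    ``labeled``: one row per labeled matrix row — its test fold, label, the
    three arrangement probabilities (ordered by calibration fold) and their
    mean.  ``unlabeled``: one row per (un-annotated matrix row, fold).
    """

    labeled: pd.DataFrame
    unlabeled: pd.DataFrame

    def to_frame(self, term_id: str, row_ids, gene_ids) -> pd.DataFrame:
        """Serializable long form: term, gene, role, fold, p_arr1..3, p_mean."""
        recs = []
        for r, row in self.labeled.iterrows():
            role = "labeled_pos" if row["label"] > 0 else "labeled_neg"
            recs.append((term_id, row_ids[r], gene_ids[r], role, int(row["test_fold"]),
                         row["p_arr1"], row["p_arr2"], row["p_arr3"], row["p_mean"]))
        for _, row in self.unlabeled.iterrows():
            r = int(row["row"])
            recs.append((term_id, row_ids[r], gene_ids[r], "unlabeled", int(row["fold"]),
                         row["p_arr1"], row["p_arr2"], row["p_arr3"], row["p_mean"]))
        return pd.DataFrame(recs, columns=[
            "term_id", "clone_id", "gene_id", "role", "test_fold",
            "p_arr1", "p_arr2", "p_arr3", "p_mean",
        ])


def enumerate_arrangements(k: int = 4) -> list[Arrangement]:
    """All 12 arrangements: 4 test folds × 3 calibration choices.

    The training pair is unordered, so for a fixed test fold the three
    arrangements are distinguished by their calibration fold alone.
    """
    if k != 4:
        raise ValueError("the rotation scheme is specific to 4 folds")
    out = []
    for test in range(k):
        rest = [j for j in range(k) if j != test]
        for calib in rest:
            train = frozenset(j for j in rest if j != calib)
            out.append(Arrangement(test_fold=test, calib_fold=calib, train_folds=train))
    return out


def run_arrangement(
    X: np.ndarray,
    task: CategoryTask,
    partition: FoldPartition,
    arr: Arrangement,
) -> tuple[dict[int, float], dict[int, float]]:
    """Train/calibrate/score one arrangement.

    σ and the SVM come from the training folds only; the sigmoid is fitted
    on the calibration fold's discriminants against its smoothed targets;
    probabilities are returned for every test-fold row and every
    un-annotated row.
    """
    folds = partition.folds
    g, d = sorted(arr.train_folds)
    train_rows = sorted(folds[g] | folds[d])
    calib_rows = sorted(folds[arr.calib_fold])
    test_rows = sorted(folds[arr.test_fold])
    unlabeled_rows = sorted(task.unlabeled)

    # structural no-leakage guarantees
    assert not (set(train_rows) & set(calib_rows))
    assert not (set(train_rows) & set(test_rows))
    assert not (set(calib_rows) & set(test_rows))
    assert not (set(unlabeled_rows) & set(task.labeled))

    y_train = task.labels(train_rows)
    X_train = X[train_rows]
    sigma = ks.sigma_heuristic(X_train, y_train)
    K_train = ks.KernelMatrix(values=ks.rbf_kernel(X_train, X_train, sigma), sigma=sigma)
    K_aug = ks.augment_diagonal(K_train, y_train)
    model = ks.train_svm(K_aug, y_train)

    f_calib = ks.discriminants(model, ks.rbf_kernel(X[calib_rows], X_train, sigma))
    fit = cal.fit_sigmoid(f_calib, cal.platt_targets(task.labels(calib_rows)))

    f_test = ks.discriminants(model, ks.rbf_kernel(X[test_rows], X_train, sigma))
    p_test = cal.apply_sigmoid(fit, f_test)
    test_probs = {r: float(p) for r, p in zip(test_rows, p_test)}

    unl_probs: dict[int, float] = {}
    if unlabeled_rows:
        f_unl = ks.discriminants(model, ks.rbf_kernel(X[unlabeled_rows], X_train, sigma))
        p_unl = cal.apply_sigmoid(fit, f_unl)
        unl_probs = {r: float(p) for r, p in zip(unlabeled_rows, p_unl)}
    return test_probs, unl_probs


def average_probabilities(
    task: CategoryTask,
    partition: FoldPartition,
    per_arrangement: dict[Arrangement, tuple[dict[int, float], dict[int, float]]],
) -> ProbabilityTable:
    """Collapse the 12 arrangement outputs into the per-gene table.

    A labeled gene's estimate is the mean of its three arrangement values;
    an un-annotated gene gets, per fold, the mean of the three arrangements
    sharing that test fold.
    """
    if len(per_arrangement) != 12:
        raise ValueError("expected 12 arrangement tables")
    labeled_recs = []
    for fold_idx, fold in enumerate(partition.folds):
        arrs = sorted(
            (a for a in per_arrangement if a.test_fold == fold_idx),
            key=lambda a: a.calib_fold,
        )
        if len(arrs) != 3:
            raise ValueError(f"fold {fold_idx} does not have 3 arrangements")
        for r in sorted(fold):
            ps = []
            for a in arrs:
                probs = per_arrangement[a][0]
                if r not in probs:
                    raise ValueError(f"missing probability for row {r} in arrangement {a}")
                ps.append(probs[r])
            labeled_recs.append((r, fold_idx, 1.0 if r in task.positives else -1.0,
                                 ps[0], ps[1], ps[2], float(np.mean(ps))))
    labeled = pd.DataFrame(
        labeled_recs,
        columns=["row", "test_fold", "label", "p_arr1", "p_arr2", "p_arr3", "p_mean"],
    ).set_index("row")

    unl_recs = []
    for fold_idx in range(len(partition.folds)):
        arrs = sorted(
            (a for a in per_arrangement if a.test_fold == fold_idx),
            key=lambda a: a.calib_fold,
        )
        for r in sorted(task.unlabeled):
            ps = []
            for a in arrs:
                probs = per_arrangement[a][1]
                if r not in probs:
                    raise ValueError(f"missing unlabeled probability for row {r}")
                ps.append(probs[r])
            unl_recs.append((r, fold_idx, ps[0], ps[1], ps[2], float(np.mean(ps))))
    unlabeled = pd.DataFrame(
        unl_recs, columns=["row", "fold", "p_arr1", "p_arr2", "p_arr3", "p_mean"]
    )
    return ProbabilityTable(labeled=labeled, unlabeled=unlabeled)


def run_category(
    X: np.ndarray,
    task: CategoryTask,
    partition: FoldPartition,
) -> ProbabilityTable:
    """Execute all 12 arrangements for one category and average."""
    per_arrangement = {
        arr: run_arrangement(X, task, partition, arr)
        for arr in enumerate_arrangements(len(partition.folds))
    }
    return average_probabilities(task, partition, per_arrangement)
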
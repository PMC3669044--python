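"""Readers and writers for expression matrices, GO annotations and id maps.

The expression input is a tab-separated matrix of normalized log-ratios:
row 1 holds condition labels, column 1 the clone identifier and (optionally)
column 2 the gene identifier.  Duplicate clone rows mapping to the same gene
are deliberately retained as separate rows; downstream stages treat them as
independent data points so prediction consistency across duplicates can be
inspected.

Annotations are restricted to the Gene Ontology Biological Process aspect and
come either from a GAF 2.x file (aspect column ``P``) or a plain two-column
``gene_id<TAB>term_id`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: gene-id prefix given to clones absent from an identifier map; rows are
#: kept (auditable row counts) but excluded from task building.
UNMAPPED_PREFIX = "unmapped:"

#: cell contents interpreted as missing by default
DEFAULT_NA_TOKENS = ("NA", "")


class ExpressionParseError(ValueError):
    """Raised when an expression file cannot be parsed; names the line."""


@dataclass
class ExpressionMatrix:
    """A clones/genes × conditions matrix of log-ratio values.

    Rows are cDNA clones; several rows may share a ``gene_id`` (duplicate
    clones).  ``values`` holds NaN at masked cells; ``missing_mask`` is the
    authoritative missingness indicator.
    """

    row_ids: list[str]
    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if len(self.row_ids) != n or len(self.gene_ids) != n:
            raise ValueError("row_ids/gene_ids length must equal row count")
        if len(self.condition_ids) != p:
            raise ValueError("condition_ids length must equal column count")
        if p < 1:
            raise ValueError("at least one condition required")
        if len(set(self.row_ids)) != n:
            raise ValueError("row_ids must be unique")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-finite value outside missing_mask")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.row_ids),
            list(self.gene_ids),
            list(self.condition_ids),
            self.values.copy(),
            self.missing_mask.copy(),
        )


@dataclass(frozen=True)
class AnnotationTable:
    """Deduplicated (gene_id, term_id) pairs, Biological Process aspect only."""

    pairs: frozenset[tuple[str, str]]
    aspect: str = "P"

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.pairs)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)

    def genes_for(self, term_id: str) -> frozenset[str]:
        return frozenset(g for g, t in self.pairs if t == term_id)

    def terms_for(self, gene_id: str) -> frozenset[str]:
        return frozenset(t for g, t in self.pairs if g == gene_id)


@dataclass(frozen=True)
class IdMap:
    """Clone/CG identifier → primary gene identifier (FBgn-style)."""

    entries: Mapping[str, str]

    def __len__(self) -> int:
        return len(self.entries)


def load_expression_matrix(
    path: str | Path,
    *,
    gene_column: bool = True,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
) -> ExpressionMatrix:
    """Parse a TSV expression matrix.

    Layout: first row = condition labels (after the leading id column(s)),
    first column = clone id, second column = gene id when ``gene_column``.
    Cells equal to one of ``na_tokens`` are masked as missing.
    """
    path = Path(path)
    na_set = set(na_tokens)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ExpressionParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_id_cols = 2 if gene_column else 1
    condition_ids = header[n_id_cols:]
    if len(condition_ids) < 1:
        raise ExpressionParseError(f"{path}: line 1: header has no condition columns")
    n_cols = len(header)
    row_ids: list[str] = []
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ExpressionParseError(
                f"{path}: line {lineno}: expected {n_cols} columns, got {len(fields)}"
            )
        row_ids.append(fields[0])
        gene_ids.append(fields[1] if gene_column else fields[0])
        vals: list[float] = []
        miss: list[bool] = []
        for j, tok in enumerate(fields[n_id_cols:]):
            if tok in na_set:
                vals.append(np.nan)
                miss.append(True)
            else:
                try:
                    vals.append(float(tok))
                except ValueError as exc:
                    raise ExpressionParseError(
                        f"{path}: line {lineno}: non-numeric cell "
                        f"{tok!r} in column {j + n_id_cols + 1}"
                    ) from exc
                miss.append(False)
        rows.append(vals)
        mask_rows.append(miss)
    return ExpressionMatrix(
        row_ids, gene_ids, condition_ids, np.array(rows, dtype=float),
        np.array(mask_rows, dtype=bool),
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, *, na_token: str = "NA"
) -> None:
    """Write the TSV layout read by :func:`load_expression_matrix`.

    Finite cells are written with ``repr`` so a load/write round-trip is
    bit-identical; masked cells are written as ``na_token``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("clone_id\tgene_id\t" + "\t".join(matrix.condition_ids) + "\n")
        for i in range(matrix.n_rows):
            cells = [
                na_token if matrix.missing_mask[i, j] else repr(float(matrix.values[i, j]))
                for j in range(matrix.n_conditions)
            ]
            fh.write(matrix.row_ids[i] + "\t" + matrix.gene_ids[i] + "\t" + "\t".join(cells) + "\n")


_GAF_ASPECTS = {"P", "F", "C"}


def load_annotations(path: str | Path, format: str = "two_column") -> AnnotationTable:
    """Load gene → GO-BP term pairs from a GAF 2.x or two-column TSV file.

    GAF rows with aspect ``F``/``C`` are excluded (wrong aspect); rows with an
    unknown aspect code are skipped with a warning; ``NOT``-qualified rows are
    dropped.  Pairs are deduplicated (set semantics), so loading a file
    concatenated with itself is a no-op.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if format == "gaf":
                if line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise ExpressionParseError(
                        f"{path}: line {lineno}: GAF row has {len(cols)} columns (< 9)"
                    )
                aspect = cols[8]
                if aspect not in _GAF_ASPECTS:
                    logger.warning(
                        "%s: line %d: unknown aspect %r, row skipped", path, lineno, aspect
                    )
                    continue
                if aspect != "P":
                    continue
                if "NOT" in cols[3].split("|"):
                    continue
                gene, term = cols[1], cols[4]
            elif format == "two_column":
                cols = line.split("\t")
                if len(cols) != 2:
                    raise ExpressionParseError(
                        f"{path}: line {lineno}: expected 2 columns, got {len(cols)}"
                    )
                gene, term = cols
            else:
                raise ValueError(f"unknown annotation format {format!r}")
            if not term:
                raise ExpressionParseError(f"{path}: line {lineno}: empty term id")
            pairs.add((gene, term))
    return AnnotationTable(frozenset(pairs))


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    """Write the two-column TSV form, sorted for determinism."""
    with Path(path).open("w") as fh:
        for gene, term in sorted(table.pairs):
            fh.write(f"{gene}\t{term}\n")


def load_id_map(path: str | Path) -> IdMap:
    """Load a two-column clone_id → gene_id TSV."""
    entries: dict[str, str] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(cols)}"
                )
            entries[cols[0]] = cols[1]
    return IdMap(entries)


def map_ids(matrix: ExpressionMatrix, id_map: IdMap) -> ExpressionMatrix:
    """Replace per-row gene ids using a clone → gene map.

    Clones absent from the map keep their row but receive a sentinel gene id
    (``unmapped:<clone>``); they are reported in the log, never dropped, and
    are excluded later at task-building time.
    """
    if len(id_map) == 0:
        raise ValueError("empty id map")
    new_gene_ids: list[str] = []
    unmapped: list[str] = []
    for clone in matrix.row_ids:
        mapped = id_map.entries.get(clone)
        if mapped is None:
            unmapped.append(clone)
            mapped = UNMAPPED_PREFIX + clone
        new_gene_ids.append(mapped)
    if unmapped:
        logger.warning(
            "%d clone(s) without id mapping kept with sentinel gene ids: %s",
            len(unmapped), ", ".join(unmapped[:20]),
        )
    out = matrix.copy()
    out.gene_ids = new_gene_ids
    return out


def impute_missing(matrix: ExpressionMatrix, method: str = "zero") -> ExpressionMatrix:
    """Fill masked cells: 0.0 ("no change" on the log-ratio scale) or row mean."""
    out = matrix.copy()
    if method == "zero":
        out.values[out.missing_mask] = 0.0
    elif method == "row_mean":
        for i in range(out.n_rows):
            miss = out.missing_mask[i]
            if miss.all():
                raise ValueError(f"row {out.row_ids[i]!r} entirely missing; cannot take row mean")
            if miss.any():
                out.values[i, miss] = out.values[i, ~miss].mean()
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    out.missing_mask = np.zeros_like(out.missing_mask)
    return out
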
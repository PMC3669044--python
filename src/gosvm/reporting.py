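"""Selection of high-precision categories and high-confidence predictions.

Also contains the small arithmetic around coverage percentages and the
tallying of embryonic mRNA in-situ-hybridization (FISH) concordance marks
used to validate predicted category members against an independent imaging
resource.  Two concordance tables for predicted members of the
DNA-dependent DNA replication and oxidative phosphorylation categories ship
with the package under ``gosvm/data``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import math

from .evaluation import CategoryPerformance, GenePrecisionRecord

BUNDLED_CONCORDANCE_TABLES = {
    "dna_replication": "insitu_concordance_dna_replication.tsv",
    "oxidative_phosphorylation": "insitu_concordance_oxidative_phosphorylation.tsv",
}


@dataclass(frozen=True)
class PredictionRecord:
    """One proposed annotation: an un-annotated gene paired with a term."""

    gene_id: str
    clone_id: str
    term_id: str
    mean_gene_precision: float
    per_fold_prob: tuple[float, float, float, float]


@dataclass(frozen=True)
class ConcordanceTable:
    """Rows (gene_id, sample_id, mark) with mark in {'+', '-', ''}."""

    rows: tuple[tuple[str, str, str], ...]


@dataclass(frozen=True)
class ConcordanceSummary:
    n_plus: int
    n_marked: int

    @property
    def fraction(self) -> float:
        return self.n_plus / self.n_marked

    @property
    def percent(self) -> int:
        return round_half_away(100.0 * self.fraction)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (76.5 → 77)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def select_high_precision_categories(
    performances: Iterable[CategoryPerformance],
    threshold: float = 0.75,
    recall_level: float = 0.4,
) -> list[CategoryPerformance]:
    """Categories whose fold-mean precision at the recall level is ≥ threshold.

    The bound is inclusive; results are sorted by descending precision,
    term id breaking ties.
    """
    kept = [p for p in performances if p.mean_prec_at[recall_level] >= threshold]
    return sorted(kept, key=lambda p: (-p.mean_prec_at[recall_level], p.term_id))


def select_predictions(
    records: Iterable[GenePrecisionRecord],
    gene_ids: Sequence[str],
    row_ids: Sequence[str],
    threshold: float = 0.75,
) -> list[PredictionRecord]:
    """Gene-category pairs with mean gene-precision ≥ threshold (inclusive).

    A gene may be predicted into several categories; each qualifying pair
    yields one record.
    """
    out = []
    for rec in records:
        if rec.mean_score >= threshold:
            out.append(PredictionRecord(
                gene_id=gene_ids[rec.row],
                clone_id=row_ids[rec.row],
                term_id=rec.term_id,
                mean_gene_precision=rec.mean_score,
                per_fold_prob=tuple(rec.per_fold_prob),  # type: ignore[arg-type]
            ))
    out.sort(key=lambda r: (-r.mean_gene_precision, r.term_id, r.clone_id))
    return out


def coverage_stats(numerator: int, denominator: int) -> tuple[float, int]:
    """(exact ratio, integer percentage) for e.g. predicted-gene coverage."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    ratio = numerator / denominator
    return ratio, round_half_away(100.0 * ratio)


def load_concordance_table(source: str | Path) -> ConcordanceTable:
    """Read a concordance TSV (gene_id, sample_id, fish_match, ...).

    ``source`` may be a filesystem path or the name of a bundled table
    (:data:`BUNDLED_CONCORDANCE_TABLES`).
    """
    if isinstance(source, str) and source in BUNDLED_CONCORDANCE_TABLES:
        ref = resources.files("gosvm.data") / BUNDLED_CONCORDANCE_TABLES[source]
        text = ref.read_text()
    else:
        text = Path(source).read_text()
    rows = []
    lines = text.splitlines()
    header = lines[0].split("\t")
    gi, si, mi = header.index("gene_id"), header.index("sample_id"), header.index("fish_match")
    for line in lines[1:]:
        if not line.strip():
            continue
        cols = line.split("\t")
        mark = cols[mi] if len(cols) > mi else ""
        if mark not in {"+", "-", ""}:
            raise ValueError(f"invalid concordance mark {mark!r}")
        rows.append((cols[gi], cols[si], mark))
    return ConcordanceTable(rows=tuple(rows))


def fish_concordance_summary(table: ConcordanceTable) -> ConcordanceSummary:
    """Tally +/− marks: genes with database images whose pattern matched."""
    n_plus = sum(1 for _, _, m in table.rows if m == "+")
    n_marked = sum(1 for _, _, m in table.rows if m in {"+", "-"})
    if n_marked == 0:
        raise ValueError("no marked rows to tally")
    return ConcordanceSummary(n_plus=n_plus, n_marked=n_marked)
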
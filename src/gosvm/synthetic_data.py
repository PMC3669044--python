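"""Desk-scale synthetic datasets with the structure the analysis assumes.

The generator emulates a developmental time-course expression matrix: each
planted functional category has a smooth latent profile over the ordered
conditions (a random low-order trigonometric shape), its member genes follow
that profile with per-gene amplitude jitter plus independent Gaussian noise,
and background genes are pure noise.  A configurable fraction of genes
carries no annotation; some of those ("hidden" members) secretly belong to
planted categories, providing ground truth for evaluating predictions on
un-annotated genes — the guilt-by-association premise made literal.
Duplicate clone rows, missing cells and filler annotation terms round out
the statistical quirks of the real inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .data_io import AnnotationTable, ExpressionMatrix, write_annotations, write_expression_matrix


@dataclass(frozen=True)
class CategorySpec:
    """One planted category: annotated members plus hidden (un-annotated) ones."""

    term_id: str
    n_annotated: int
    n_hidden: int = 0
    #: amplitude multiplier relative to the global signal level (0 ⇒ null category)
    signal_scale: float = 1.0


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe a desk-scale analogue of a life-cycle microarray
    compendium: 500 genes × 60 ordered conditions, log-ratio noise with
    standard deviation 0.25, a unit signal amplitude (signal-to-noise 4 for
    fully scaled categories), 2% missing cells, 30% of genes un-annotated
    and 5% of genes spotted twice.
    """

    n_genes: int = 500
    n_conditions: int = 60
    categories: list[CategorySpec] = field(default_factory=list)
    signal: float = 1.0
    noise_sd: float = 0.25
    missing_frac: float = 0.02
    frac_unannotated: float = 0.3
    dup_clone_frac: float = 0.05
    n_filler_terms: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal < 0 or self.noise_sd < 0:
            raise ValueError("signal and noise_sd must be nonnegative")
        if not (0.0 <= self.missing_frac < 1.0):
            raise ValueError("missing_frac must lie in [0, 1)")
        total_members = sum(c.n_annotated + c.n_hidden for c in self.categories)
        if total_members > self.n_genes:
            raise ValueError("category members exceed n_genes")
        n_hidden = sum(c.n_hidden for c in self.categories)
        if n_hidden > int(round(self.frac_unannotated * self.n_genes)):
            raise ValueError("hidden members exceed the un-annotated pool")


@dataclass
class SyntheticDataset:
    """Matrix + visible annotations + full planted truth."""

    matrix: ExpressionMatrix
    annotations: AnnotationTable
    truth: dict[str, frozenset[str]]
    hidden: dict[str, frozenset[str]]
    config: SimulationConfig


def _smooth_profile(n_conditions: int, rng: np.random.Generator) -> np.ndarray:
    """Random low-order trigonometric shape, normalized to unit RMS."""
    t = np.linspace(0.0, 1.0, n_conditions)
    profile = np.zeros(n_conditions)
    for h in (1, 2, 3):
        amp = rng.normal(0.0, 1.0 / h)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        profile += amp * np.sin(2.0 * np.pi * h * t + phase)
    rms = np.sqrt(np.mean(profile**2))
    if rms < 1e-9:  # essentially flat draw; fall back to the fundamental
        profile = np.sin(2.0 * np.pi * t)
        rms = np.sqrt(np.mean(profile**2))
    return profile / rms


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a dataset; all randomness derives from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"FBgn{i:07d}" for i in range(cfg.n_genes)]

    # assign member genes to categories front-to-back, then split the rest
    cursor = 0
    truth: dict[str, set[str]] = {}
    hidden: dict[str, set[str]] = {}
    annotated_members: dict[str, set[str]] = {}
    gene_signal: dict[str, tuple[np.ndarray, float]] = {}
    for spec in cfg.categories:
        profile = _smooth_profile(cfg.n_conditions, rng)
        members = gene_ids[cursor:cursor + spec.n_annotated + spec.n_hidden]
        cursor += len(members)
        truth[spec.term_id] = set(members)
        annotated_members[spec.term_id] = set(members[:spec.n_annotated])
        hidden[spec.term_id] = set(members[spec.n_annotated:])
        for g in members:
            amp = cfg.signal * spec.signal_scale * rng.uniform(0.8, 1.2)
            gene_signal[g] = (profile, amp)

    all_hidden = set().union(*hidden.values()) if hidden else set()
    n_unannotated = int(round(cfg.frac_unannotated * cfg.n_genes))
    background = gene_ids[cursor:]
    n_bg_unann = n_unannotated - len(all_hidden)
    bg_unannotated = set(rng.choice(sorted(background), size=n_bg_unann, replace=False)) \
        if n_bg_unann > 0 else set()
    unannotated = all_hidden | bg_unannotated

    pairs: set[tuple[str, str]] = set()
    filler_terms = [f"GO:FILLER{i:03d}" for i in range(cfg.n_filler_terms)]
    for term, members in annotated_members.items():
        for g in members:
            pairs.add((g, term))
    for g in background:
        if g not in bg_unannotated and filler_terms:
            pairs.add((g, filler_terms[rng.integers(len(filler_terms))]))

    # clone rows: every gene once, a random subset twice
    n_dup = int(round(cfg.dup_clone_frac * cfg.n_genes))
    dup_genes = set(rng.choice(gene_ids, size=n_dup, replace=False)) if n_dup else set()
    row_ids: list[str] = []
    row_genes: list[str] = []
    for g in gene_ids:
        row_ids.append(f"{g}.c1")
        row_genes.append(g)
        if g in dup_genes:
            row_ids.append(f"{g}.c2")
            row_genes.append(g)

    n_rows = len(row_ids)
    values = rng.normal(0.0, cfg.noise_sd, size=(n_rows, cfg.n_conditions))
    for i, g in enumerate(row_genes):
        if g in gene_signal:
            profile, amp = gene_signal[g]
            values[i] += amp * profile

    mask = rng.random((n_rows, cfg.n_conditions)) < cfg.missing_frac
    values[mask] = np.nan
    matrix = ExpressionMatrix(row_ids, row_genes, [f"T{j:03d}" for j in range(cfg.n_conditions)],
                              values, mask)
    return SyntheticDataset(
        matrix=matrix,
        annotations=AnnotationTable(frozenset(pairs)),
        truth={t: frozenset(m) for t, m in truth.items()},
        hidden={t: frozenset(m) for t, m in hidden.items()},
        config=cfg,
    )


def simulate_discriminants(
    a: float, b: float, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal discriminants with labels drawn from the sigmoid model.

    Labels are +1 with probability 1/(1+exp(a·f+b)); the pair (f, y) is a
    ground-truth harness for calibration recovery tests.
    """
    if n < 10:
        raise ValueError("need at least 10 points")
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    p = 1.0 / (1.0 + np.exp(a * f + b))
    y = np.where(rng.random(n) < p, 1.0, -1.0)
    return f, y


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Serialize matrix, visible annotations and full truth as TSV/YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(dataset.matrix, outdir / "expression.tsv")
    write_annotations(dataset.annotations, outdir / "annotations.tsv")
    with (outdir / "truth.tsv").open("w") as fh:
        fh.write("gene_id\tterm_id\thidden\n")
        for term in sorted(dataset.truth):
            for g in sorted(dataset.truth[term]):
                fh.write(f"{g}\t{term}\t{int(g in dataset.hidden.get(term, frozenset()))}\n")
    with (outdir / "config.yaml").open("w") as fh:
        yaml.safe_dump(asdict(dataset.config), fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig (categories as mappings) from YAML."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    cats = [CategorySpec(**c) for c in raw.pop("categories", [])]
    return SimulationConfig(categories=cats, **raw)
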
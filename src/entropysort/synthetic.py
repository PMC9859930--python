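"""Synthetic scRNA-seq benchmark with exhaustive ground truth.

The generator builds a corruption-free expression matrix from a small
number of cell types, each defined by a block of tightly co-expressed
marker genes, then layers the error modes of real droplet data on top:

* random dropouts (false negatives from capture failure),
* threshold-induced false negatives — every gene is later binarized
  against a deliberately sub-optimal threshold drawn from N(4, 0.2)
  while active expression averages 5, so the low tail of genuinely
  active entries falls below the cut,
* leaky expression (false positives outside a gene's home type),
* doublet cells that merge two type profiles, and
* two batches, one with extra dropout.

Corruption targets the structured and multimodal genes — the genes that
*have* a ground-truth expression program to corrupt. The random genes
are uninformative by construction: whatever pattern they display is
their ground truth (their draws are generated consistent with the
discretization thresholds), so they carry no error annotations and any
correction suggested in them is a false call.

Within a type, marker genes are *nested*: each cell carries a latent
depth u ~ U(0, 1) and a gene with within-type prevalence p is active in
exactly the cells with u < p. Any two same-type genes therefore sort
each other perfectly in the ground truth (their active sets are
subset-ordered), while per-gene active-cell counts still span a wide
range — including a configurable fraction of rare genes active in only
a handful of cells, which is where error detection genuinely runs out
of statistical support. Random genes are i.i.d. Bernoulli per cell and
carry no structure.

Every discrete disagreement between the truth and corrupted matrices is
annotated with its cause, so detector output can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import (
    DiscreteStateMatrix,
    DiscretizationSpec,
    ExpressionMatrix,
    discretize,
    write_discrete,
    write_expression,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "ANNOTATION_CODES",
    "generate_ground_truth",
    "inject_errors",
    "generate_benchmark",
    "benchmark_bundle",
]

#: per-coordinate error annotation codes
ANNOTATION_CODES = {"none": 0, "dropout_FN": 1, "threshold_FN": 2, "leaky_FP": 3}


@dataclass
class SyntheticConfig:
    """Benchmark design. Defaults give ~1,250 cells x 1,469 genes:
    5 types x 200 cells plus 20% doublets; 919 type-marker genes + 50
    multimodal genes (969 structured) + 500 random genes."""

    n_cell_types: int = 5
    cells_per_type: int | Sequence[int] = 200
    doublet_fraction: float = 0.20
    genes_per_type: Sequence[int] = (184, 184, 184, 184, 183)
    n_multimodal: int = 50
    n_random_genes: int = 500
    active_mean: float = 5.0
    active_sd: float = 0.5
    high_mean: float = 10.0           # multimodal "high" state, 2x medium
    dropout_rate: float = 0.25
    leaky_rate: float = 0.005
    # cell-correlated leakage: a contaminated cell leaks a random fraction
    # of one foreign type's program (ambient-RNA-like), which is much
    # harder to call than isolated leaks
    contamination_rate: float = 0.05
    contamination_strength: tuple[float, float] = (0.15, 0.42)
    # systematically leaky marker genes: a fraction of markers leak into
    # one foreign type following that type's own activation depth, so the
    # spurious expression mimics genuine structure
    promiscuous_gene_fraction: float = 0.05
    promiscuous_penetrance: tuple[float, float] = (0.2, 0.5)
    threshold_mean: float = 4.0
    threshold_sd: float = 0.2
    n_batches: int = 2
    batch_extra_dropout: float = 0.05
    # within-type prevalence of marker genes (nested activation model)
    structured_prevalence: tuple[float, float] = (0.5, 1.0)
    rare_gene_fraction: float = 0.05
    rare_prevalence: tuple[float, float] = (0.01, 0.15)
    random_prevalence: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.type_sizes()
        if len(sizes) != self.n_cell_types or any(s < 1 for s in sizes):
            raise ValueError("cells_per_type must give a positive size per type")
        if len(self.genes_per_type) != self.n_cell_types:
            raise ValueError("genes_per_type must have one entry per cell type")
        if any(g < 1 for g in self.genes_per_type):
            raise ValueError("genes_per_type entries must be positive")
        for frac in (self.doublet_fraction, self.dropout_rate, self.leaky_rate,
                     self.batch_extra_dropout, self.rare_gene_fraction,
                     self.contamination_rate):
            if not (0 <= frac < 1):
                raise ValueError("fractions must lie in [0, 1)")
        if self.n_cell_types < 2 and self.doublet_fraction > 0:
            raise ValueError("doublets need at least 2 cell types")

    def type_sizes(self) -> list[int]:
        if isinstance(self.cells_per_type, int):
            return [self.cells_per_type] * self.n_cell_types
        return [int(s) for s in self.cells_per_type]

    @property
    def n_typed_cells(self) -> int:
        return sum(self.type_sizes())

    @property
    def n_doublets(self) -> int:
        # doublet_fraction is a fraction of ALL cells (typed + doublets)
        f = self.doublet_fraction
        return int(round(self.n_typed_cells * f / (1.0 - f)))

    @property
    def n_cells(self) -> int:
        return self.n_typed_cells + self.n_doublets

    @property
    def n_structured(self) -> int:
        return int(sum(self.genes_per_type)) + self.n_multimodal

    @property
    def n_genes(self) -> int:
        return self.n_structured + self.n_random_genes


@dataclass
class SyntheticTruth:
    """Paired truth/corrupted matrices with per-coordinate annotations."""

    config: SyntheticConfig
    truth_continuous: ExpressionMatrix
    truth_discrete: DiscreteStateMatrix
    cell_type_labels: list[str]          # doublets carry both parents "A+B"
    batch_labels: np.ndarray
    gene_class: np.ndarray               # {"structured", "multimodal", "random"}
    gene_home_type: list[str]
    # latent activation depth of each cell w.r.t. each type (NaN where the
    # cell carries no program of that type); doublets have two finite rows
    cell_type_depths: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    corrupted_continuous: ExpressionMatrix | None = None
    corrupted_discrete: DiscreteStateMatrix | None = None
    error_annotations: np.ndarray | None = None   # int8 codes, cells x genes

    def annotation_coords(self, kind: str) -> set[tuple[int, int]]:
        if self.error_annotations is None:
            raise ValueError("errors have not been injected")
        code = ANNOTATION_CODES[kind]
        return {(int(c), int(g)) for c, g in zip(*np.nonzero(self.error_annotations == code))}

    @property
    def structured_mask(self) -> np.ndarray:
        return self.gene_class != "random"


def _cell_profile(
    rng: np.random.Generator,
    depth: float,
    type_idx: int,
    prevalence: np.ndarray,
    home: np.ndarray,
    medium_home: np.ndarray,
    high_home: np.ndarray,
    cfg: SyntheticConfig,
) -> np.ndarray:
    """Continuous truth profile of one cell of a given type."""
    F = prevalence.size
    values = np.zeros(F)
    own = (home == type_idx) | (medium_home == type_idx) | (high_home == type_idx)
    active = own & (depth < prevalence)
    idx = np.flatnonzero(active)
    means = np.where(high_home[idx] == type_idx, cfg.high_mean, cfg.active_mean)
    values[idx] = np.maximum(rng.normal(means, cfg.active_sd), 0.01)
    return values


def generate_ground_truth(cfg: SyntheticConfig) -> SyntheticTruth:
    """Build the corruption-free benchmark (truth matrices only)."""
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.type_sizes()
    F = cfg.n_genes
    n_marker = int(sum(cfg.genes_per_type))

    # --- gene metadata -------------------------------------------------
    gene_ids: list[str] = []
    gene_class = np.empty(F, dtype=object)
    home = np.full(F, -1)          # marker/multimodal medium home type
    medium_home = np.full(F, -1)
    high_home = np.full(F, -1)
    gi = 0
    for t, n_genes_t in enumerate(cfg.genes_per_type):
        for j in range(n_genes_t):
            gene_ids.append(f"S{t}_{j:03d}")
            gene_class[gi] = "structured"
            home[gi] = t
            gi += 1
    for j in range(cfg.n_multimodal):
        lo, hi = rng.choice(cfg.n_cell_types, size=2, replace=False)
        gene_ids.append(f"M_{j:03d}")
        gene_class[gi] = "multimodal"
        medium_home[gi] = lo
        high_home[gi] = hi
        gi += 1
    for j in range(cfg.n_random_genes):
        gene_ids.append(f"R_{j:03d}")
        gene_class[gi] = "random"
        gi += 1

    # within-type prevalence: broad for most markers, a rare low tail
    prevalence = np.zeros(F)
    struct_idx = np.flatnonzero(gene_class != "random")
    lo, hi = cfg.structured_prevalence
    prevalence[struct_idx] = rng.uniform(lo, hi, size=struct_idx.size)
    n_rare = int(round(cfg.rare_gene_fraction * struct_idx.size))
    if n_rare:
        rare = rng.choice(struct_idx, size=n_rare, replace=False)
        prevalence[rare] = rng.uniform(*cfg.rare_prevalence, size=n_rare)
    rand_idx = np.flatnonzero(gene_class == "random")
    rand_prev = rng.uniform(*cfg.random_prevalence, size=rand_idx.size)

    # --- cells ---------------------------------------------------------
    values = np.zeros((cfg.n_cells, F))
    depths = np.full((cfg.n_cells, cfg.n_cell_types), np.nan)
    cell_ids: list[str] = []
    labels: list[str] = []
    ci = 0
    for t, size in enumerate(sizes):
        for _ in range(size):
            depth = rng.uniform()
            depths[ci, t] = depth
            values[ci] = _cell_profile(
                rng, depth, t, prevalence, home, medium_home, high_home, cfg
            )
            cell_ids.append(f"C{ci:04d}")
            labels.append(f"T{t}")
            ci += 1
    for _ in range(cfg.n_doublets):
        a, b = rng.choice(cfg.n_cell_types, size=2, replace=False)
        da, db = rng.uniform(), rng.uniform()
        depths[ci, a], depths[ci, b] = da, db
        pa = _cell_profile(
            rng, da, a, prevalence, home, medium_home, high_home, cfg
        )
        pb = _cell_profile(
            rng, db, b, prevalence, home, medium_home, high_home, cfg
        )
        values[ci] = np.maximum(pa, pb)
        cell_ids.append(f"C{ci:04d}")
        labels.append(f"T{min(a, b)}+T{max(a, b)}")
        ci += 1

    # the deliberately sub-optimal per-gene discretization thresholds are
    # part of the study design, so they are drawn with the ground truth
    thresholds = rng.normal(cfg.threshold_mean, cfg.threshold_sd, size=F)

    # random genes: i.i.d. per cell, independent of type and batch; draws
    # that would fall below the gene's threshold are inactive outright,
    # so a random gene's truth IS its observed discrete pattern
    active = rng.uniform(size=(cfg.n_cells, rand_idx.size)) < rand_prev[None, :]
    draws = np.maximum(
        rng.normal(cfg.active_mean, cfg.active_sd, size=active.shape), 0.01
    )
    active &= draws > thresholds[rand_idx][None, :]
    values[:, rand_idx] = np.where(active, draws, 0.0)

    batch = rng.integers(0, cfg.n_batches, size=cfg.n_cells)
    truth_cont = ExpressionMatrix(values, cell_ids, gene_ids)
    truth_disc = discretize(truth_cont, DiscretizationSpec("nonzero"))
    home_names = [
        f"T{medium_home[g]}+T{high_home[g]}" if gene_class[g] == "multimodal"
        else (f"T{home[g]}" if home[g] >= 0 else "none")
        for g in range(F)
    ]
    return SyntheticTruth(
        config=cfg,
        truth_continuous=truth_cont,
        truth_discrete=truth_disc,
        cell_type_labels=labels,
        batch_labels=batch,
        gene_class=gene_class.astype(str),
        gene_home_type=home_names,
        cell_type_depths=depths,
        thresholds=thresholds,
    )


def inject_errors(truth: SyntheticTruth, rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Corrupt the ground truth in place and annotate every discrepancy.

    Order of events per entry of a structured or multimodal gene:
    dropout first (value -> 0), then the sub-optimal per-gene
    discretization threshold silences the low tail of surviving active
    values, then leaky expression switches on a fraction of truly
    inactive entries. Random genes pass through untouched. Annotations
    are mutually exclusive and exhaustive over discrete truth/corrupted
    disagreements.
    """
    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    values = truth.truth_continuous.values.copy()
    truth_states = truth.truth_discrete.states.astype(bool)
    thresholds = truth.thresholds
    corruptible = (truth.gene_class != "random")[None, :]
    ann = np.zeros(values.shape, dtype=np.int8)

    # (a) random dropout, with extra loss in the last batch
    drop_p = np.full(values.shape[0], cfg.dropout_rate)
    if cfg.n_batches > 1:
        drop_p[truth.batch_labels == cfg.n_batches - 1] += cfg.batch_extra_dropout
    dropped = corruptible & truth_states & (rng.uniform(size=values.shape) < drop_p[:, None])
    values[dropped] = 0.0
    ann[dropped] = ANNOTATION_CODES["dropout_FN"]

    # (b) sub-optimal per-gene thresholds silence surviving low values
    below = corruptible & truth_states & ~dropped & (values <= thresholds[None, :])
    ann[below] = ANNOTATION_CODES["threshold_FN"]

    # (c) leaky expression outside the home type, three flavours: a
    # background of isolated leaks; contaminated cells that leak part of
    # one foreign type's program; and systematically promiscuous marker
    # genes whose leak into one foreign type follows that type's own
    # activation depth and so mimics genuine (multimodal-like) structure
    leaky = corruptible & ~truth_states & (rng.uniform(size=values.shape) < cfg.leaky_rate)
    type_genes = [
        np.array([f"T{t}" in home.split("+") for home in truth.gene_home_type])
        for t in range(cfg.n_cell_types)
    ]
    contaminated = np.flatnonzero(rng.uniform(size=values.shape[0]) < cfg.contamination_rate)
    for c in contaminated:
        t = int(rng.integers(cfg.n_cell_types))
        q = rng.uniform(*cfg.contamination_strength)
        hit = type_genes[t] & ~truth_states[c] & (rng.uniform(size=values.shape[1]) < q)
        leaky[c] |= hit
    marker = np.flatnonzero(truth.gene_class == "structured")
    n_prom = int(round(cfg.promiscuous_gene_fraction * marker.size))
    if n_prom:
        prom = rng.choice(marker, size=n_prom, replace=False)
        for g in prom:
            own = truth.gene_home_type[g]
            foreign = int(rng.choice(
                [t for t in range(cfg.n_cell_types) if f"T{t}" != own]
            ))
            pen = rng.uniform(*cfg.promiscuous_penetrance)
            hit = (truth.cell_type_depths[:, foreign] < pen) & ~truth_states[:, g]
            leaky[hit, g] = True
    leak_vals = np.maximum(
        rng.normal(cfg.active_mean, cfg.active_sd, size=values.shape), 0.01
    )
    values = np.where(leaky, leak_vals, values)
    # only leaks that clear the threshold become discrete false positives
    visible_leak = leaky & (values > thresholds[None, :])
    ann[visible_leak] = ANNOTATION_CODES["leaky_FP"]

    corrupted = ExpressionMatrix(
        values, list(truth.truth_continuous.cell_ids), list(truth.truth_continuous.gene_ids)
    )
    spec = DiscretizationSpec("per_gene_threshold", thresholds)
    truth.corrupted_continuous = corrupted
    truth.corrupted_discrete = discretize(corrupted, spec)
    truth.error_annotations = ann
    return truth


def generate_benchmark(cfg: SyntheticConfig | None = None) -> SyntheticTruth:
    """Ground truth plus injected errors in one call."""
    cfg = cfg or SyntheticConfig()
    return inject_errors(generate_ground_truth(cfg))


def benchmark_bundle(cfg: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write the full benchmark (matrices, labels, annotations, manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = generate_benchmark(cfg)
    write_expression(t.truth_continuous, out / "truth_continuous.csv")
    write_expression(t.corrupted_continuous, out / "corrupted_continuous.csv")
    write_expression(t.corrupted_continuous, out / "corrupted_continuous.mtx", format="mtx")
    write_discrete(t.truth_discrete, out / "truth_discrete.csv")
    write_discrete(t.corrupted_discrete, out / "corrupted_discrete.csv")
    pd.DataFrame(
        {
            "cell_id": t.truth_continuous.cell_ids,
            "cell_type": t.cell_type_labels,
            "batch": t.batch_labels,
        }
    ).to_csv(out / "cell_labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": t.truth_continuous.gene_ids,
            "gene_class": t.gene_class,
            "home_type": t.gene_home_type,
            "threshold": t.thresholds,
        }
    ).to_csv(out / "gene_labels.tsv", sep="\t", index=False)
    code_to_name = {v: k for k, v in ANNOTATION_CODES.items()}
    cc, gg = np.nonzero(t.error_annotations)
    pd.DataFrame(
        {
            "cell_id": [t.truth_continuous.cell_ids[c] for c in cc],
            "gene_id": [t.truth_continuous.gene_ids[g] for g in gg],
            "annotation": [code_to_name[int(t.error_annotations[c, g])] for c, g in zip(cc, gg)],
        }
    ).to_csv(out / "error_annotations.csv", index=False)
    manifest = {"config": asdict(cfg)}
    manifest["config"]["genes_per_type"] = list(cfg.genes_per_type)
    if not isinstance(cfg.cells_per_type, int):
        manifest["config"]["cells_per_type"] = list(cfg.cells_per_type)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return out
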
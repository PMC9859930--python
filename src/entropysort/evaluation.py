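"""Scoring of correction masks and rankings against ground truth,
silhouette summaries, and a minimal false-negative imputer."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .ffaves import CorrectionMask
from .matrix import DiscreteStateMatrix, ExpressionMatrix
from .synthetic import SyntheticTruth

__all__ = [
    "PrecisionRecall",
    "SilhouetteReport",
    "precision_recall",
    "score_mask",
    "silhouette",
    "ess_distance",
    "impute_fn",
]


@dataclass(frozen=True)
class PrecisionRecall:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


def precision_recall(
    predicted: set[tuple[int, int]], truth: set[tuple[int, int]]
) -> PrecisionRecall:
    tp = len(predicted & truth)
    return PrecisionRecall(tp=tp, fp=len(predicted) - tp, fn=len(truth) - tp)


def score_mask(mask: CorrectionMask, truth: SyntheticTruth) -> dict[str, PrecisionRecall]:
    """Score a correction mask against the generator's annotations.

    The FN channel is scored against the union of dropout and
    threshold-induced false negatives; the FP channel against leaky
    false positives. ``threshold_FN`` reports recall restricted to the
    threshold-induced subset (how much of the sub-optimal discretization
    the detector undid).
    """
    if truth.error_annotations is None:
        raise ValueError("truth has no injected errors to score against")
    if truth.corrupted_discrete.states.shape[0] <= max(
        (c for c, _ in mask.fn_coords | mask.fp_coords), default=-1
    ):
        pass  # coordinate bounds are validated by the mask itself
    fn_truth = truth.annotation_coords("dropout_FN") | truth.annotation_coords("threshold_FN")
    fp_truth = truth.annotation_coords("leaky_FP")
    thr_truth = truth.annotation_coords("threshold_FN")
    return {
        "FN": precision_recall(mask.fn_coords, fn_truth),
        "FP": precision_recall(mask.fp_coords, fp_truth),
        "threshold_FN": precision_recall(mask.fn_coords & thr_truth, thr_truth),
    }


@dataclass
class SilhouetteReport:
    values: np.ndarray
    labels: np.ndarray
    metric: str
    excluded_labels: list[str]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def per_cluster(self) -> pd.Series:
        return pd.Series(self.values).groupby(pd.Series(self.labels).values).mean()


def ess_distance(ess: np.ndarray) -> np.ndarray:
    """1 - ESS as a gene-gene dissimilarity, symmetrized over orientations."""
    sym = (ess + ess.T) / 2.0
    d = 1.0 - sym
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def silhouette(
    data: np.ndarray,
    labels: np.ndarray,
    metric: str = "precomputed",
) -> SilhouetteReport:
    """Silhouette values per sample; clusters of size < 2 are dropped.

    For gene groups pass ``ess_distance(scores.ESS)`` with
    ``metric="precomputed"``; for cells any scikit-learn metric name
    works on an observation matrix.
    """
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    keep_labels = counts[counts >= 2].index
    excluded = [str(l) for l in counts[counts < 2].index]
    if excluded:
        warnings.warn(f"excluding singleton clusters: {excluded}")
    keep = np.isin(labels, keep_labels)
    if pd.Series(labels[keep]).nunique() < 2:
        raise ValueError("silhouette needs at least 2 clusters of size >= 2")
    sub = data[keep][:, keep] if metric == "precomputed" else data[keep]
    vals = silhouette_samples(sub, labels[keep], metric=metric)
    return SilhouetteReport(
        values=vals, labels=labels[keep], metric=metric, excluded_labels=excluded
    )


def impute_fn(x: ExpressionMatrix, mask: CorrectionMask) -> ExpressionMatrix:
    """Replace each flagged false negative by the gene's mean over its
    observed-active cells; every other entry is untouched."""
    values = x.values.copy()
    by_gene: dict[int, list[int]] = {}
    for c, g in mask.fn_coords:
        if not (0 <= c < x.n_cells and 0 <= g < x.n_genes):
            raise IndexError(f"FN coordinate ({c}, {g}) out of bounds")
        by_gene.setdefault(g, []).append(c)
    for g, cells in by_gene.items():
        active = x.values[:, g] > 0
        if not active.any():
            warnings.warn(
                f"gene {x.gene_ids[g]!r} has no active cells; FN values left unchanged"
            )
            continue
        values[cells, g] = x.values[active, g].mean()
    return ExpressionMatrix(values, list(x.cell_ids), list(x.gene_ids))
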
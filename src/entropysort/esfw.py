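"""ESFW: unsupervised feature-importance weighting from pairwise ES.

A gene that belongs to a set of dependent features accumulates positive,
EP-supported entropy sort scores from its partners; a randomly expressed
gene does not. The weight of gene g is the mean, over all other eligible
genes f acting as reference features, of ESS(f -> g) truncated to the
pairs where the error potential favours dependence and the score is
positive. Averaging over all F - 1 partners (not just contributing ones)
keeps the weights of sparsely supported genes small, which is what makes
the structured/random split bimodal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ffaves import CorrectionMask, apply_corrections
from .matrix import DiscreteStateMatrix
from .pairwise import pairwise_scores

__all__ = [
    "FeatureWeights",
    "feature_weights",
    "ranked_pr_curve",
    "select_features",
    "weight_mode_split",
]


@dataclass
class FeatureWeights:
    gene_ids: list[str]
    weights: np.ndarray
    rank: np.ndarray                 # gene indices, descending weight
    n_contributing_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        order = np.empty(len(self.gene_ids), dtype=int)
        order[self.rank] = np.arange(len(self.gene_ids))
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "weight": self.weights,
                "rank": order,
                "n_contributing_pairs": self.n_contributing_pairs,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def feature_weights(
    m: DiscreteStateMatrix,
    mask: CorrectionMask | None = None,
    min_minority: int = 3,
    use_abs_ess: bool = False,
) -> FeatureWeights:
    """Importance weight per gene; optionally on the corrected matrix.

    When a :class:`CorrectionMask` is given the weights are computed on
    the FFAVES-corrected matrix, which restores the dependencies that
    dropouts had diluted. ``use_abs_ess`` folds negative (anti-sorted)
    scores in with absolute value instead of discarding them.
    """
    if mask is not None:
        m = apply_corrections(m, mask)
    if m.eligible(min_minority).sum() < 2:
        raise ValueError("need at least 2 eligible genes to weight features")
    es = pairwise_scores(m, min_minority=min_minority, allow_large=True)
    F = int(es.eligible.sum())
    ess = es.ESS.copy()
    np.fill_diagonal(ess, 0.0)
    # a pair supports dependence if either orientation's error potential
    # does: the orientation with the larger reference minority dilutes its
    # divergence over many cells and can miss a dependence the opposite
    # orientation sees clearly (small genes inside a big partner's block).
    # A pair with NO observed divergence sits exactly on its optimal-
    # dependence minimum (e.g. exact duplicates) — maximal evidence, even
    # though EP, a test that needs divergent cells to weigh, is negative.
    perfect = (es.divergence <= 1e-9) & (es.SD != 0)
    sup = (es.EP > 0) | perfect
    gate = sup | sup.T
    np.fill_diagonal(gate, False)
    if use_abs_ess:
        contrib = np.where(gate, np.abs(ess), 0.0)
    else:
        contrib = np.where(gate & (ess > 0), ess, 0.0)
    weights = contrib.sum(axis=0) / max(F - 1, 1)     # gene in the QF role
    weights[~es.eligible] = 0.0
    n_contrib = (contrib > 0).sum(axis=0)
    n_contrib[~es.eligible] = 0
    # stable descending sort: ties keep gene-id order
    rank = np.argsort(-weights, kind="stable")
    return FeatureWeights(
        gene_ids=list(m.gene_ids),
        weights=weights,
        rank=rank,
        n_contributing_pairs=n_contrib.astype(np.int64),
    )


def weight_mode_split(weights: np.ndarray, floor: float = 1e-8) -> float:
    """Threshold separating the two modes of a weight distribution.

    ESFW weights are bimodal on a log scale: a near-zero mode of
    uninformative genes and an upper mode of genes embedded in dependent
    sets, typically separated by orders of magnitude. The split is Otsu's
    threshold (maximal between-class variance) on log10 weights, with
    zeros clamped to ``floor``.
    """
    lw = np.log10(np.maximum(np.asarray(weights, dtype=float), floor))
    hist, edges = np.histogram(lw, bins=64)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / max(hist.sum(), 1)
    best, thr = -1.0, centers[0]
    for i in range(1, len(centers)):
        w0, w1 = p[:i].sum(), p[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (p[:i] * centers[:i]).sum() / w0
        m1 = (p[i:] * centers[i:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best:
            best, thr = v, centers[i]
    return float(10**thr)


def ranked_pr_curve(
    weights: FeatureWeights, labels: np.ndarray
) -> pd.DataFrame:
    """Precision/recall along the descending-weight gene ranking.

    ``labels`` marks the positive class (e.g. structured genes). Row k of
    the result scores the top-(k+1) genes as selected. The random-sampling
    baseline equals the positive-class prevalence at every recall.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.size != len(weights.gene_ids):
        raise ValueError("labels must align with genes")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("labels must contain both classes")
    hits = labels[weights.rank]
    tp = np.cumsum(hits)
    k = np.arange(1, labels.size + 1)
    return pd.DataFrame(
        {
            "k": k,
            "recall": tp / n_pos,
            "precision": tp / k,
            "baseline": n_pos / labels.size,
        }
    )


def select_features(
    weights: FeatureWeights,
    k: int | None = None,
    threshold: float | None = None,
) -> list[str]:
    """Top-k genes by weight, or every gene above a weight threshold."""
    if (k is None) == (threshold is None):
        raise ValueError("give exactly one of k or threshold")
    if k is not None:
        if k > len(weights.gene_ids):
            raise ValueError("k exceeds gene count")
        chosen = weights.rank[:k]
    else:
        chosen = weights.rank[weights.weights[weights.rank] > threshold]
    return [weights.gene_ids[i] for i in chosen]
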
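"""Vectorized ES scores for every ordered gene pair of a discrete matrix.

All arithmetic mirrors :mod:`entropysort.core` exactly; the only
difference is that minority-overlap counts for all pairs come from one
matrix product and the parabola landmarks are evaluated with broadcast
numpy expressions. Entry (f, g) of every output holds the score of the
ordered pair with gene f as the reference feature and gene g as the
query feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import DiscreteStateMatrix

__all__ = ["PairwiseScores", "pairwise_scores"]

ATOL = 1e-9

#: refuse to allocate F x F score matrices above this without explicit consent
DEFAULT_GENE_LIMIT = 5000


def _h2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        pos = q > 0
        out -= np.where(pos, q * np.log2(np.where(pos, q, 1.0)), 0.0)
    return out


@dataclass
class PairwiseScores:
    """Dense ordered-pair score matrices (RF on rows, QF on columns)."""

    gene_ids: list[str]
    eligible: np.ndarray      # bool per gene
    ESS: np.ndarray
    EP: np.ndarray
    SD: np.ndarray            # int8 in {-1, 0, +1}
    divergence: np.ndarray
    n_divergent: np.ndarray
    overlap: np.ndarray       # x per ordered pair

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def pairwise_scores(
    m: DiscreteStateMatrix,
    min_minority: int = 3,
    gene_limit: int = DEFAULT_GENE_LIMIT,
    allow_large: bool = False,
) -> PairwiseScores:
    """ES scores for all ordered gene pairs.

    Genes with minority count below ``min_minority`` are ineligible and
    score 0 against every partner. The diagonal ESS of an eligible gene
    is 1 (a feature sorts itself perfectly).
    """
    F = m.n_genes
    if F > gene_limit and not allow_large:
        raise ValueError(
            f"{F} genes exceeds the guard of {gene_limit}; "
            "pass allow_large=True to proceed"
        )
    N = m.n_cells
    elig = m.eligible(min_minority)
    Mmin = m.minority_states()           # cells x F, float64
    counts = m.minority_count.astype(float)

    X = Mmin.T @ Mmin                    # ordered overlap x for (RF=f, QF=g)
    G1 = counts[:, None]                 # RF axis
    QFm = counts[None, :]                # QF axis
    G2 = N - G1

    with np.errstate(divide="ignore", invalid="ignore"):
        safeG1 = np.where(G1 > 0, G1, 1.0)
        safeG2 = np.where(G2 > 0, G2, 1.0)

        def ce(x: np.ndarray) -> np.ndarray:
            return (G1 / N) * _h2(x / safeG1) + (G2 / N) * _h2(
                np.clip((QFm - x) / safeG2, 0.0, 1.0)
            )

        x_lo = np.maximum(0.0, QFm - G2)
        x_hi = np.minimum(G1, QFm)
        x_max = G1 * QFm / N
        ce_lo = ce(x_lo)
        ce_hi = ce(x_hi)
        max_ent = ce(x_max)
        obs_ent = ce(X)

    hi_is_global = ce_hi <= ce_lo + ATOL
    min_glob = np.where(hi_is_global, ce_hi, ce_lo)
    min_loc = np.where(hi_is_global, ce_lo, ce_hi)
    x_glob = np.where(hi_is_global, x_hi, x_lo)
    x_loc = np.where(hi_is_global, x_lo, x_hi)

    sd = np.zeros((F, F), dtype=np.int8)
    sd[X > x_max + ATOL] = 1
    sd[X < x_max - ATOL] = -1

    min_rel = np.where(sd == 1, min_glob, min_loc)
    ok = (sd != 0) & (max_ent > ATOL) & (max_ent - min_rel > ATOL)

    with np.errstate(divide="ignore", invalid="ignore"):
        sw = np.where(ok, (max_ent - min_rel) / np.where(max_ent > 0, max_ent, 1.0), 0.0)
        sg_den = np.where(ok, max_ent - min_rel, 1.0)
        sg = np.where(ok, (max_ent - obs_ent) / sg_den, 0.0)
        ess = sd * sw * sg

        div = np.where(ok, np.maximum(obs_ent - min_rel, 0.0), 0.0)
        n_div = np.where(sd == 1, G1 - X, np.where(sd == -1, X, 0.0))
        dpc_dep = np.where((n_div > 0) & ok, div / np.where(n_div > 0, n_div, 1.0), 0.0)
        ind_den = np.where(sd == 1, x_glob - x_max, x_max - x_loc)
        deg = np.abs(ind_den) <= ATOL
        dpc_ind = np.where(
            ok & ~deg, max_ent / np.where(deg, 1.0, ind_den), 0.0
        )
        ep = np.where(ok & ~deg, dpc_dep - dpc_ind, 0.0)

    # zero out ineligible rows/columns and the diagonal bookkeeping
    bad = ~elig
    for arr in (ess, ep, div, dpc_dep, dpc_ind):
        arr[bad, :] = 0.0
        arr[:, bad] = 0.0
    sd[bad, :] = 0
    sd[:, bad] = 0
    idx = np.flatnonzero(elig)
    ess[idx, idx] = 1.0

    return PairwiseScores(
        gene_ids=list(m.gene_ids),
        eligible=elig,
        ESS=ess,
        EP=ep,
        SD=sd,
        divergence=div,
        n_divergent=n_div.astype(np.int64),
        overlap=X.astype(np.int64),
    )
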
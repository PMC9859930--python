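"""Scalar entropy-sorting mathematics for one ordered feature pair.

An ordered pair has a reference feature (RF) whose minority/majority
states partition the N samples into groups G1 (minority) and G2
(majority), and a query feature (QF) with QFm minority states in total.
The only free variable is x, the number of QF minority states that land
inside G1. The conditional entropy H(QF | RF) is then a smooth function
of x — the entropy sort equation —

    CE(x) = (G1/N) * H2(x / G1) + (G2/N) * H2((QFm - x) / G2)

with H2 the binary (base-2) entropy. CE is concave in x, maximal at the
independence point x_max = G1*QFm/N, and minimised at the feasible
boundaries x_lo = max(0, QFm - G2) and x_hi = min(G1, QFm). The derived
scores (sort direction/weight/gain, divergence, divergence per cell
under the dependence and independence hypotheses, and the error
potential) are all landmarks or gradients on this parabola.

This module is the readable scalar reference; :mod:`entropysort.pairwise`
vectorizes the identical arithmetic across all gene pairs and is tested
against this implementation entry by entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairGeometry",
    "PairScores",
    "binary_entropy",
    "ese_ce",
    "pair_geometry",
    "sort_direction",
    "sort_weight",
    "sort_gain",
    "ess",
    "divergence",
    "divergent_cells",
    "dpc_dependent",
    "dpc_independent",
    "error_potential",
    "pair_scores",
    "choose_orientation",
]

#: absolute tolerance for "sits on a landmark" comparisons
ATOL = 1e-9


def binary_entropy(p: float | np.ndarray) -> float | np.ndarray:
    """H2(p) in bits, with the 0*log2(0) := 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        pos = q > 0
        out = out - np.where(pos, q * np.log2(np.where(pos, q, 1.0)), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PairGeometry:
    """ESE constants and landmarks for one ordered RF -> QF pair."""

    N: int
    G1: int          # RF minority-group size
    G2: int          # RF majority-group size
    QFm: int         # total QF minority states
    x: int           # observed QF minority states inside G1
    x_lo: float
    x_hi: float
    x_max: float     # independence abscissa G1*QFm/N
    x_local_min: float
    x_global_min: float
    MaxEnt: float
    MinEnt_local: float
    MinEnt_global: float
    ObsEnt: float


@dataclass(frozen=True)
class PairScores:
    """Derived ES scores for one ordered pair."""

    SD: int
    SW: float
    SG: float
    ESS: float
    divergence: float
    n_divergent: int
    DPC_dependent: float
    DPC_independent: float
    EP: float
    degenerate: bool = False


def ese_ce(g: PairGeometry, x: float) -> float:
    """Conditional entropy CE(x) on the pair's ESE parabola.

    ``x`` may be any real value in the feasible interval [x_lo, x_hi];
    the landmarks (notably x_max) are generally non-integer.
    """
    if x < g.x_lo - ATOL or x > g.x_hi + ATOL:
        raise ValueError(f"x={x} outside feasible bounds [{g.x_lo}, {g.x_hi}]")
    x = min(max(x, g.x_lo), g.x_hi)
    h1 = binary_entropy(x / g.G1)
    h2 = binary_entropy((g.QFm - x) / g.G2)
    return (g.G1 / g.N) * h1 + (g.G2 / g.N) * h2


def _geometry_from_counts(N: int, G1: int, QFm: int, x: int) -> PairGeometry:
    G2 = N - G1
    if G1 < 1 or QFm < 1:
        raise ValueError("both features need a non-empty minority group")
    x_lo = float(max(0, QFm - G2))
    x_hi = float(min(G1, QFm))
    x_max = G1 * QFm / N
    # provisional geometry so ese_ce can evaluate the landmarks
    g = PairGeometry(
        N=N, G1=G1, G2=G2, QFm=QFm, x=x,
        x_lo=x_lo, x_hi=x_hi, x_max=x_max,
        x_local_min=x_lo, x_global_min=x_hi,
        MaxEnt=np.nan, MinEnt_local=np.nan, MinEnt_global=np.nan, ObsEnt=np.nan,
    )
    ce_lo = ese_ce(g, x_lo)
    ce_hi = ese_ce(g, x_hi)
    max_ent = ese_ce(g, x_max)
    obs_ent = ese_ce(g, float(x))
    # global minimum = lower-CE boundary; exact tie designates x_hi global
    if ce_hi <= ce_lo + ATOL:
        x_glob, ce_glob, x_loc, ce_loc = x_hi, ce_hi, x_lo, ce_lo
    else:
        x_glob, ce_glob, x_loc, ce_loc = x_lo, ce_lo, x_hi, ce_hi
    return PairGeometry(
        N=N, G1=G1, G2=G2, QFm=QFm, x=x,
        x_lo=x_lo, x_hi=x_hi, x_max=x_max,
        x_local_min=x_loc, x_global_min=x_glob,
        MaxEnt=max_ent, MinEnt_local=ce_loc, MinEnt_global=ce_glob,
        ObsEnt=obs_ent,
    )


def pair_geometry(
    rf: np.ndarray,
    qf: np.ndarray,
    rf_minority_active: bool | None = None,
    qf_minority_active: bool | None = None,
) -> PairGeometry:
    """Geometry of an ordered pair of binary state vectors.

    Counts are taken in minority encoding. Polarity flags may be supplied
    (e.g. from a :class:`~entropysort.matrix.DiscreteStateMatrix`); by
    default each feature's minority state is inferred from the vector
    itself, ties counting the active state as minority.
    """
    rf = np.asarray(rf).astype(np.int8)
    qf = np.asarray(qf).astype(np.int8)
    if rf.shape != qf.shape or rf.ndim != 1:
        raise ValueError("rf and qf must be 1-d vectors of equal length")
    n = rf.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if rf_minority_active is None:
        rf_minority_active = rf.sum() <= n - rf.sum()
    if qf_minority_active is None:
        qf_minority_active = qf.sum() <= n - qf.sum()
    rf_min = rf.astype(bool) if rf_minority_active else ~rf.astype(bool)
    qf_min = qf.astype(bool) if qf_minority_active else ~qf.astype(bool)
    g1 = int(rf_min.sum())
    qfm = int(qf_min.sum())
    if g1 == 0 or qfm == 0:
        raise ValueError("constant feature: no minority group to sort")
    x = int(np.count_nonzero(rf_min & qf_min))
    return _geometry_from_counts(n, g1, qfm, x)


def sort_direction(g: PairGeometry) -> int:
    """-1 below the independence point, +1 above, 0 exactly on it."""
    if g.x > g.x_max + ATOL:
        return 1
    if g.x < g.x_max - ATOL:
        return -1
    return 0


def _relevant_min(g: PairGeometry, sd: int) -> float:
    return g.MinEnt_global if sd == 1 else g.MinEnt_local


def sort_weight(g: PairGeometry, sd: int) -> float:
    """Fraction of MaxEnt removable at the SD-relevant minimum."""
    if sd == 0:
        return 0.0
    if g.MaxEnt <= ATOL:
        raise ValueError("degenerate pair: MaxEnt = 0")
    return (g.MaxEnt - _relevant_min(g, sd)) / g.MaxEnt


def sort_gain(g: PairGeometry, sd: int) -> float:
    """Achieved fraction of the entropy removable at the relevant minimum."""
    if sd == 0:
        return 0.0
    denom = g.MaxEnt - _relevant_min(g, sd)
    if denom <= ATOL:
        raise ValueError("degenerate pair: MaxEnt equals the relevant minimum")
    return (g.MaxEnt - g.ObsEnt) / denom


def ess(g: PairGeometry) -> float:
    """Entropy sort score SD*SW*SG, in [-1, 1]."""
    sd = sort_direction(g)
    if sd == 0:
        return 0.0
    return sd * sort_weight(g, sd) * sort_gain(g, sd)


def divergence(g: PairGeometry, sd: int) -> float:
    """Excess of the observed CE above the SD-relevant minimum (>= 0)."""
    if sd == 0:
        return 0.0
    return max(g.ObsEnt - _relevant_min(g, sd), 0.0)


def divergent_cells(
    rf: np.ndarray,
    qf: np.ndarray,
    sd: int,
    rf_minority_active: bool | None = None,
    qf_minority_active: bool | None = None,
) -> np.ndarray:
    """Indices of cells whose states pull the pair away from its minimum.

    SD=+1: RF-minority cells showing the QF majority state.
    SD=-1: RF-minority cells showing the QF minority state.
    """
    rf = np.asarray(rf).astype(np.int8)
    qf = np.asarray(qf).astype(np.int8)
    n = rf.size
    if sd == 0:
        return np.empty(0, dtype=int)
    if rf_minority_active is None:
        rf_minority_active = rf.sum() <= n - rf.sum()
    if qf_minority_active is None:
        qf_minority_active = qf.sum() <= n - qf.sum()
    rf_min = rf.astype(bool) if rf_minority_active else ~rf.astype(bool)
    qf_min = qf.astype(bool) if qf_minority_active else ~qf.astype(bool)
    mask = rf_min & (~qf_min if sd == 1 else qf_min)
    return np.flatnonzero(mask)


def dpc_dependent(g: PairGeometry, sd: int, n_divergent: int) -> float:
    """Divergence per divergent cell under the dependence hypothesis."""
    if sd == 0 or n_divergent == 0:
        return 0.0
    return divergence(g, sd) / n_divergent


def dpc_independent(g: PairGeometry, sd: int) -> float:
    """Per-cell divergence expected under the independence null.

    The secant gradient of the parabola from its maximum to the
    SD-relevant minimum: any observed overlap is attributed to chance, so
    each cell moving x off the maximum should carry this much entropy.
    """
    if sd == 0:
        return 0.0
    if sd == -1:
        denom = g.x_max - g.x_local_min
    else:
        denom = g.x_global_min - g.x_max
    if abs(denom) <= ATOL:
        raise ValueError("degenerate pair: independence point on a boundary")
    return g.MaxEnt / denom


def error_potential(
    g: PairGeometry, n_divergent: int | None = None
) -> PairScores:
    """Assemble all derived scores for a pair, including EP.

    EP = DPC_dependent - DPC_independent. EP > 0 favours the hypothesis
    that the features are dependent and the divergent cells are errors;
    EP < 0 favours independence. ``n_divergent`` defaults to the count
    implied by the geometry (x or G1 - x depending on SD).
    """
    sd = sort_direction(g)
    if sd == 0:
        return PairScores(0, 0.0, 0.0, 0.0, 0.0, 0, 0.0, 0.0, 0.0)
    if n_divergent is None:
        n_divergent = int(g.G1 - g.x) if sd == 1 else int(g.x)
    try:
        sw = sort_weight(g, sd)
        sg = sort_gain(g, sd)
        div = divergence(g, sd)
        dpc_dep = dpc_dependent(g, sd, n_divergent)
        dpc_ind = dpc_independent(g, sd)
    except ValueError:
        return PairScores(sd, 0.0, 0.0, 0.0, 0.0, 0, 0.0, 0.0, 0.0, degenerate=True)
    return PairScores(
        SD=sd,
        SW=sw,
        SG=sg,
        ESS=sd * sw * sg,
        divergence=div,
        n_divergent=n_divergent,
        DPC_dependent=dpc_dep,
        DPC_independent=dpc_ind,
        EP=dpc_dep - dpc_ind,
    )


def pair_scores(
    rf: np.ndarray,
    qf: np.ndarray,
    rf_minority_active: bool | None = None,
    qf_minority_active: bool | None = None,
) -> PairScores:
    """All ES scores for one ordered pair of binary vectors."""
    g = pair_geometry(rf, qf, rf_minority_active, qf_minority_active)
    sd = sort_direction(g)
    n_div = divergent_cells(rf, qf, sd, rf_minority_active, qf_minority_active).size
    return error_potential(g, n_divergent=n_div)


def choose_orientation(a: np.ndarray, b: np.ndarray) -> tuple[PairScores, PairScores]:
    """Both ordered orientations of an unordered pair.

    ES is not symmetric: with a as RF the minority split is a's, with b
    as RF it is b's. Both directions are computed and retained; consumers
    (FFAVES voting, ESFW weighting) use each feature in its QF role from
    both orientations rather than picking one.
    """
    return pair_scores(a, b), pair_scores(b, a)
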
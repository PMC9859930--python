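"""FFAVES: multivariate identification of false-negative and
false-positive data points in a binary expression matrix.

The algorithm cycles over the matrix. Each cycle scores every ordered
gene pair, keeps the pairs whose error potential favours dependence
(EP > 0), and lets each such reference feature cast one vote on every
cell it finds divergent in the query gene. A coordinate accumulating
votes from more than a threshold fraction of the query gene's
EP-positive partners is flagged: as a false negative when the original
matrix shows the entry inactive, as a false positive when it shows it
active. Flags are applied to the working matrix (FN -> 1, FP -> 0),
which amplifies the surviving co-expression signal, and the next cycle
repeats until no new coordinates are flagged.

Each divergent cell of a positively sorted (SD=+1) EP-positive pair is
evidence of one error, but the error can sit on either side of the
pair: the cell shows the reference gene's minority state and the query
gene's majority state, so either the query entry should flip to the
minority (a missing state, e.g. a dropout) or the reference entry
should flip to the majority (a spurious state, e.g. leaky expression).
The same divergent cell therefore casts two votes — one on its query
coordinate and one on its reference coordinate — and the vote fractions
arbitrate: a cell missing from one gene of an otherwise intact block
gathers query-side votes from most of the block, while a cell active in
a gene whose partners it fails to co-express gathers reference-side
votes from most of that gene's partners. Anti-sorted (SD=-1) EP-positive
pairs contribute their divergent cells to the reference side as well
(overlap of two minority states that should repel). Fractions are taken
over each gene's EP-positive partner count in the relevant role, and
genes with fewer supporting partners than ``min_vote_partners`` are
never flagged — a pair-starved gene (rare or randomly expressed) offers
no statistical footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import DiscreteStateMatrix
from .pairwise import PairwiseScores, pairwise_scores

__all__ = [
    "FfavesConfig",
    "CorrectionMask",
    "divergence_votes",
    "flag_errors",
    "apply_corrections",
    "run_ffaves",
]


@dataclass
class FfavesConfig:
    """Tunable parameters of the FFAVES cycle.

    The FP threshold is held above the FN threshold: flipping an observed
    active state destroys evidence, so the FP channel demands a
    super-majority of partner votes while the FN channel needs a simple
    majority.
    """

    vote_threshold_fn: float = 0.5
    vote_threshold_fp: float = 0.7
    max_cycles: int = 40
    min_minority: int = 3
    min_vote_partners: int = 30
    convergence_tol: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.vote_threshold_fn <= 1):
            raise ValueError("vote_threshold_fn must be in (0, 1]")
        if not (0 < self.vote_threshold_fp <= 1):
            raise ValueError("vote_threshold_fp must be in (0, 1]")
        if self.vote_threshold_fp < self.vote_threshold_fn:
            raise ValueError("FP threshold must be >= FN threshold")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass
class CorrectionMask:
    """Suggested corrections, always relative to the original matrix."""

    fn_coords: set[tuple[int, int]] = field(default_factory=set)
    fp_coords: set[tuple[int, int]] = field(default_factory=set)
    cycle_history: list[dict[str, int]] = field(default_factory=list)
    vote_fraction: dict[tuple[int, int], float] = field(default_factory=dict)
    first_cycle: dict[tuple[int, int], int] = field(default_factory=dict)
    converged: bool = True

    def __len__(self) -> int:
        return len(self.fn_coords) + len(self.fp_coords)

    def validate(self, m0: DiscreteStateMatrix) -> None:
        if self.fn_coords & self.fp_coords:
            raise ValueError("FN and FP coordinate sets overlap")
        for c, g in self.fn_coords:
            if m0.states[c, g] != 0:
                raise ValueError(f"FN flag at observed-active entry ({c}, {g})")
        for c, g in self.fp_coords:
            if m0.states[c, g] != 1:
                raise ValueError(f"FP flag at observed-inactive entry ({c}, {g})")

    def to_frame(self, m0: DiscreteStateMatrix) -> pd.DataFrame:
        rows = []
        for kind, coords in (("FN", self.fn_coords), ("FP", self.fp_coords)):
            for c, g in sorted(coords):
                rows.append(
                    {
                        "cell_id": m0.cell_ids[c],
                        "gene_id": m0.gene_ids[g],
                        "type": kind,
                        "vote_fraction": self.vote_fraction.get((c, g), np.nan),
                        "cycle_first_flagged": self.first_cycle.get((c, g), -1),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["cell_id", "gene_id", "type", "vote_fraction", "cycle_first_flagged"],
        )

    def write(self, m0: DiscreteStateMatrix, path: str | Path) -> None:
        self.to_frame(m0).to_csv(path, index=False)


def divergence_votes(
    m: DiscreteStateMatrix, es: PairwiseScores
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accumulate divergent-cell votes from every EP-positive ordered pair.

    Returns ``(votes_majority, votes_minority, den_majority, den_minority)``:
    cells x genes vote counts, and the per-gene EP-positive partner
    counts normalising them. The majority channel collects query-side
    votes of SD=+1 pairs on majority-state coordinates ("this entry
    should show the minority state"). The minority channel collects
    reference-side votes of SD=+1 pairs plus query-side votes of SD=-1
    pairs on minority-state coordinates ("this minority state is
    spurious").
    """
    Mmin = m.minority_states()
    Mmaj = 1.0 - Mmin
    gate_plus = ((es.EP > 0) & (es.SD == 1)).astype(np.float64)
    gate_minus = ((es.EP > 0) & (es.SD == -1)).astype(np.float64)
    np.fill_diagonal(gate_plus, 0.0)
    np.fill_diagonal(gate_minus, 0.0)
    # query side of SD=+1: divergent cell shows RF minority, QF majority
    votes_maj = Mmaj * (Mmin @ gate_plus)
    den_maj = gate_plus.sum(axis=0)
    # reference side of SD=+1 (cell fails the gene's sorted partners) and
    # query side of SD=-1 (two minority states overlap that should repel)
    votes_min = Mmin * (Mmaj @ gate_plus.T) + Mmin * (Mmin @ gate_minus)
    den_min = gate_plus.sum(axis=1) + gate_minus.sum(axis=0)
    return votes_maj, votes_min, den_maj, den_min


def flag_errors(
    votes_maj: np.ndarray,
    votes_min: np.ndarray,
    den_maj: np.ndarray,
    den_min: np.ndarray,
    working: DiscreteStateMatrix,
    original: DiscreteStateMatrix,
    config: FfavesConfig,
) -> tuple[set[tuple[int, int]], set[tuple[int, int]], np.ndarray]:
    """Threshold vote fractions into FN/FP coordinate sets.

    The vote fraction of a coordinate is its vote count over the number
    of partners that vote through that coordinate's channel; genes whose
    channel has fewer than ``config.min_vote_partners`` supporting
    partners are skipped (no statistical footing). Classification is
    keyed to the ORIGINAL observed state: an implicated entry that the
    input matrix shows inactive is a candidate FN, an active one a
    candidate FP.
    """
    Mmin_working = working.minority_states()
    ok_maj = den_maj >= config.min_vote_partners
    ok_min = den_min >= config.min_vote_partners
    frac_maj = np.where(ok_maj, votes_maj / np.where(ok_maj, den_maj, 1), 0.0)
    frac_min = np.where(ok_min, votes_min / np.where(ok_min, den_min, 1), 0.0)
    # a coordinate currently in the majority state is only reachable by
    # majority-channel votes, and vice versa
    frac = np.where(Mmin_working > 0, frac_min, frac_maj)
    observed = original.states
    fn_hits = (observed == 0) & (frac > config.vote_threshold_fn)
    fp_hits = (observed == 1) & (frac > config.vote_threshold_fp)
    fn = {(int(c), int(g)) for c, g in zip(*np.nonzero(fn_hits))}
    fp = {(int(c), int(g)) for c, g in zip(*np.nonzero(fp_hits))}
    return fn, fp, frac


def apply_corrections(
    m: DiscreteStateMatrix, mask: CorrectionMask
) -> DiscreteStateMatrix:
    """Return a copy of ``m`` with FN coordinates set to 1 and FP to 0."""
    states = m.states.copy()
    for c, g in mask.fn_coords:
        if not (0 <= c < m.n_cells and 0 <= g < m.n_genes):
            raise IndexError(f"FN coordinate ({c}, {g}) out of bounds")
        states[c, g] = 1
    for c, g in mask.fp_coords:
        if not (0 <= c < m.n_cells and 0 <= g < m.n_genes):
            raise IndexError(f"FP coordinate ({c}, {g}) out of bounds")
        states[c, g] = 0
    return DiscreteStateMatrix(states, list(m.cell_ids), list(m.gene_ids))


def run_ffaves(
    m0: DiscreteStateMatrix, config: FfavesConfig | None = None
) -> tuple[CorrectionMask, DiscreteStateMatrix, list[dict[str, int]]]:
    """Cycle vote-and-correct until the flagged set stabilizes.

    Flags accumulate across cycles: once a coordinate is corrected in the
    working matrix it no longer looks divergent, so the mask is the union
    of every cycle's newly flagged coordinates, and the run converges
    when a cycle adds at most ``convergence_tol`` new flags (default 0).
    Returns the mask (relative to ``m0``), the corrected matrix, and the
    per-cycle history of cumulative FN/FP counts.
    """
    config = config or FfavesConfig()
    if m0.eligible(config.min_minority).sum() < 2:
        raise ValueError("need at least 2 eligible genes")
    mask = CorrectionMask()
    working = m0.copy()
    mask.converged = False
    for cycle in range(1, config.max_cycles + 1):
        es = pairwise_scores(working, min_minority=config.min_minority, allow_large=True)
        vm, vn, dm, dn = divergence_votes(working, es)
        fn, fp, frac = flag_errors(vm, vn, dm, dn, working, m0, config)
        new = (fn - mask.fn_coords) | (fp - mask.fp_coords)
        for coord in new:
            mask.first_cycle[coord] = cycle
        for coord in fn | fp:
            mask.vote_fraction[coord] = float(frac[coord])
        mask.fn_coords |= fn
        mask.fp_coords |= fp
        # an entry can gather both channels' evidence across cycles; the
        # original state decides its label, so the sets stay disjoint
        mask.cycle_history.append(
            {"cycle": cycle, "n_fn": len(mask.fn_coords), "n_fp": len(mask.fp_coords)}
        )
        working = apply_corrections(m0, mask)
        if len(new) <= config.convergence_tol:
            mask.converged = True
            break
    mask.validate(m0)
    return mask, working, mask.cycle_history
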
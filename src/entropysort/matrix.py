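"""Expression-matrix I/O and binary discretization.

Entropy sorting operates on a binary cells x genes matrix in *minority
encoding*: for every gene we record which of its two states (active /
inactive) is the rarer one, because all downstream arithmetic is phrased
in terms of minority/majority state counts rather than on/off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix, issparse

__all__ = [
    "ExpressionMatrix",
    "DiscretizationSpec",
    "DiscreteStateMatrix",
    "read_expression",
    "write_expression",
    "discretize",
    "read_discrete",
    "write_discrete",
]


@dataclass
class ExpressionMatrix:
    """Non-negative continuous expression, cells as rows, genes as columns."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n_cells, n_genes = self.values.shape
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids are not unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique")
        if self.values.size and np.min(self.values) < 0:
            c, g = np.unravel_index(int(np.argmin(self.values)), self.values.shape)
            raise ValueError(
                f"negative expression value at cell {self.cell_ids[c]!r}, "
                f"gene {self.gene_ids[g]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class DiscretizationSpec:
    """How to binarize continuous expression.

    mode
        ``nonzero``       -- active iff value > 0 (the default for raw counts).
        ``global_threshold``   -- one threshold for every gene.
        ``per_gene_threshold`` -- one threshold per gene, aligned to gene order.
    thresholds
        Scalar for ``global_threshold``, vector for ``per_gene_threshold``.
    """

    mode: Literal["nonzero", "global_threshold", "per_gene_threshold"] = "nonzero"
    thresholds: np.ndarray | float | None = None

    def resolve(self, n_genes: int) -> np.ndarray:
        if self.mode == "nonzero":
            return np.zeros(n_genes)
        if self.thresholds is None:
            raise ValueError(f"mode {self.mode!r} requires thresholds")
        if self.mode == "global_threshold":
            t = float(np.asarray(self.thresholds).reshape(()))
            thr = np.full(n_genes, t)
        else:
            thr = np.asarray(self.thresholds, dtype=float).ravel()
            if thr.size != n_genes:
                raise ValueError(
                    f"{thr.size} thresholds for {n_genes} genes in per-gene mode"
                )
        if not np.all(np.isfinite(thr)):
            raise ValueError("thresholds must be finite")
        return thr


@dataclass
class DiscreteStateMatrix:
    """Binary state matrix plus per-gene minority bookkeeping.

    ``minority_polarity[g]`` is True when the *active* (1) state is the
    minority for gene g. Exact 50/50 ties count the active state as the
    minority so that expression is treated as signal. Genes whose minority
    count is 0 (constant columns) are carried but are ineligible for
    pairwise ES, which has no minority group to sort.
    """

    states: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    minority_polarity: np.ndarray = field(init=False)
    minority_count: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValueError("state matrix must be 2-dimensional")
        if self.states.size and not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must contain only 0 and 1")
        self.states = self.states.astype(np.int8)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != self.states.shape[0]:
            raise ValueError("cell ids do not match matrix rows")
        if len(self.gene_ids) != self.states.shape[1]:
            raise ValueError("gene ids do not match matrix columns")
        self._refresh_minority()

    def _refresh_minority(self) -> None:
        n = self.states.shape[0]
        active = self.states.sum(axis=0, dtype=np.int64)
        # tie (active == n/2) resolves to active-as-minority
        self.minority_polarity = active <= n - active
        self.minority_count = np.minimum(active, n - active)

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    @property
    def n_genes(self) -> int:
        return self.states.shape[1]

    def minority_states(self) -> np.ndarray:
        """Cells x genes indicator of each gene's minority state (float64)."""
        s = self.states.astype(np.float64)
        return np.where(self.minority_polarity[None, :], s, 1.0 - s)

    def eligible(self, min_minority: int = 1) -> np.ndarray:
        """Boolean mask of genes usable in pairwise ES."""
        return self.minority_count >= max(min_minority, 1)

    def copy(self) -> "DiscreteStateMatrix":
        return DiscreteStateMatrix(
            self.states.copy(), list(self.cell_ids), list(self.gene_ids)
        )


def _read_delimited(path: Path, sep: str) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # surface the offending line if pandas names one
        raise ValueError(f"could not parse {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    return ExpressionMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def _sidecar_names(path: Path, suffix: str) -> list[str]:
    sidecar = path.with_suffix(path.suffix + suffix)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"MTX file {path} requires a name sidecar {sidecar}"
        )
    return [line.strip() for line in sidecar.read_text().splitlines() if line.strip()]


def read_expression(
    path: str | Path, format: Literal["csv", "tsv", "mtx"] | None = None
) -> ExpressionMatrix:
    """Read a cells x genes expression matrix.

    CSV/TSV carry a header row of gene ids and a first column of cell ids.
    MTX (Matrix Market, cells as rows) needs ``<file>.rows`` / ``<file>.cols``
    sidecar text files with the cell and gene names. Orientation is never
    guessed: rows are cells, always.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "csv":
        return _read_delimited(path, ",")
    if format == "tsv":
        return _read_delimited(path, "\t")
    if format == "mtx":
        mat = mmread(path)
        values = mat.toarray() if issparse(mat) else np.asarray(mat)
        cells = _sidecar_names(path, ".rows")
        genes = _sidecar_names(path, ".cols")
        return ExpressionMatrix(values.astype(float), cells, genes)
    raise ValueError(f"unknown format {format!r}")


def write_expression(
    x: ExpressionMatrix, path: str | Path, format: Literal["csv", "tsv", "mtx"] | None = None
) -> None:
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "csv"
        )
    if format in ("csv", "tsv"):
        x.to_frame().to_csv(path, sep="," if format == "csv" else "\t")
        return
    if format == "mtx":
        mmwrite(str(path), coo_matrix(x.values))
        path.with_suffix(path.suffix + ".rows").write_text(
            "\n".join(x.cell_ids) + ("\n" if x.cell_ids else "")
        )
        path.with_suffix(path.suffix + ".cols").write_text(
            "\n".join(x.gene_ids) + ("\n" if x.gene_ids else "")
        )
        return
    raise ValueError(f"unknown format {format!r}")


def discretize(x: ExpressionMatrix, spec: DiscretizationSpec | None = None) -> DiscreteStateMatrix:
    """Binarize expression: active iff value strictly exceeds the threshold."""
    spec = spec or DiscretizationSpec()
    thr = spec.resolve(x.n_genes)
    states = (x.values > thr[None, :]).astype(np.int8)
    return DiscreteStateMatrix(states, list(x.cell_ids), list(x.gene_ids))


def write_discrete(m: DiscreteStateMatrix, path: str | Path) -> None:
    """CSV round-trip format; polarity/counts are derived so states suffice."""
    pd.DataFrame(m.states, index=m.cell_ids, columns=m.gene_ids).to_csv(path)


def read_discrete(path: str | Path) -> DiscreteStateMatrix:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy()
    if vals.size and not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path} contains non-binary entries")
    return DiscreteStateMatrix(
        vals.astype(np.int8), [str(i) for i in df.index], [str(c) for c in df.columns]
    )
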
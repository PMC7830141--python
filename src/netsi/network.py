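"""Binary network construction at a conserved connection density.

A subject's node time series are correlated pairwise (Pearson) and the
correlation matrix is dichotomized so that the density statistic
S = log(N) / log(K) — N nodes, K average degree — takes the same
requested value for every subject.  S = 2.5 is the study default, a
density at which voxelwise brain graphs resemble other naturally
occurring networks.  Rather than searching for a correlation cutoff, the
builder keeps exactly the E = round(N * K* / 2) most strongly correlated
node pairs, where K* = N**(1/S) is the target average degree, so density
is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "ConstantSeriesError",
    "DensityError",
    "correlation_matrix",
    "target_degree",
    "binarize_by_density",
    "DEFAULT_S",
    "EDGE_MODES",
]

DEFAULT_S = 2.5
EDGE_MODES = ("positive", "signed", "absolute")


class ConstantSeriesError(ValueError):
    """A node's time series is constant; its correlations are undefined."""

    def __init__(self, nodes: np.ndarray):
        self.nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
        super().__init__(
            f"constant time series at node(s) {self.nodes.tolist()}: "
            "Pearson correlation undefined"
        )


class DensityError(ValueError):
    """The requested density S cannot be realized on this matrix."""


@dataclass
class CorrelationMatrix:
    """Symmetric n x n matrix of pairwise Pearson coefficients."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AdjacencyMatrix:
    """Symmetric binary graph with its achieved density statistic.

    ``achieved_s`` is recomputed from the realized average degree K as
    log(N)/log(K); it differs from the requested S only through the
    rounding of the edge count to an integer.
    """

    a: np.ndarray
    requested_s: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.a = a.astype(np.uint8)

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    @property
    def avg_degree(self) -> float:
        return 2.0 * self.n_edges / self.n

    @property
    def achieved_s(self) -> float:
        k = self.avg_degree
        if k <= 1.0:
            return float("inf")
        return float(np.log(self.n) / np.log(k))

    def degrees(self) -> np.ndarray:
        return self.a.sum(axis=0).astype(np.int64)


def correlation_matrix(ts: np.ndarray) -> CorrelationMatrix:
    """Pearson correlation between every pair of node time series.

    ``ts`` is nodes x timepoints.  Constant rows are rejected with a
    :class:`ConstantSeriesError` naming the offending node(s).
    """
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 2:
        raise ValueError("time-series matrix must be 2-D (nodes x timepoints)")
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        raise ConstantSeriesError(np.flatnonzero(sd == 0))
    c = np.corrcoef(ts)
    np.clip(c, -1.0, 1.0, out=c)
    # exact symmetry regardless of floating-point summation order
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(c)


def target_degree(n: int, s: float) -> float:
    """Average degree K* = n**(1/S) implied by node count and density S."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if s <= 0:
        raise ValueError("S must be positive")
    return float(n) ** (1.0 / float(s))


def binarize_by_density(
    corr: CorrelationMatrix | np.ndarray,
    s: float = DEFAULT_S,
    mode: str = "positive",
) -> AdjacencyMatrix:
    """Keep the E = round(n * K* / 2) top-ranked node pairs as edges.

    ``mode`` controls how correlations are ranked:

    - ``"positive"`` (default): rank by signed value, but only pairs with
      r > 0 are eligible — anticorrelations never become edges;
    - ``"signed"``: rank by signed value with no eligibility floor;
    - ``"absolute"``: rank by |r|.

    Ties at the cutoff are broken by ascending (i, j) node order, so the
    result is deterministic.  The diagonal never competes.
    """
    if not isinstance(corr, CorrelationMatrix):
        corr = CorrelationMatrix(corr)
    if mode not in EDGE_MODES:
        raise ValueError(f"mode must be one of {EDGE_MODES}")
    n = corr.n
    kstar = target_degree(n, s)
    n_edges = int(round(n * kstar / 2.0))
    iu, ju = np.triu_indices(n, k=1)
    vals = corr.values[iu, ju]
    if n_edges > vals.size:
        raise DensityError(
            f"S={s} asks for {n_edges} edges but only {vals.size} node pairs exist"
        )

    rank_vals = np.abs(vals) if mode == "absolute" else vals
    if mode == "positive":
        eligible = vals > 0
        if int(eligible.sum()) < n_edges:
            raise DensityError(
                f"S={s} asks for {n_edges} edges but only "
                f"{int(eligible.sum())} positive correlations are available; "
                "use mode='signed' or 'absolute' to rank all pairs"
            )
        # push ineligible pairs below every eligible one
        rank_vals = np.where(eligible, rank_vals, -np.inf)

    # descending value, ties by ascending (i, j)
    order = np.lexsort((ju, iu, -rank_vals))
    keep = order[:n_edges]
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[keep], ju[keep]] = 1
    a |= a.T
    return AdjacencyMatrix(a, requested_s=float(s))
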
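"""Group covariance matrices and sparsity-thresholded graph stacks.

A structural covariance network is built per group: Pearson correlations of
the covariate-residualised ROI values across the group's subjects, with
negative correlations set to zero (only positive covariance defines edges).
The continuous matrix is then binarised over a sparsity grid — at sparsity
``s`` exactly the ``round(s * N(N-1)/2)`` strongest positive edges are kept —
yielding one unweighted undirected graph per grid value. Edge ranking breaks
ties deterministically by ascending node-index pair, so graph stacks are
nested across the grid and bitwise reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlases import AtlasSpec
from .exceptions import ParameterError, UndefinedCorrelationError, ValidationError
from .preprocess import ResidualMatrix


def positive_correlation(rows: np.ndarray) -> np.ndarray:
    """Positive-rectified Pearson correlation matrix of ``rows`` (subjects x ROIs).

    Off-diagonal entries are ``max(0, r_ij)``; the diagonal is exactly 0
    (self-edges never exist in the network).
    """
    rows = np.asarray(rows, dtype=float)
    if rows.shape[0] < 2:
        raise ValidationError("need at least 2 subjects to correlate")
    sd = rows.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise UndefinedCorrelationError(
            f"zero-variance ROI column at index {bad}: correlation undefined"
        )
    centred = rows - rows.mean(axis=0)
    norm = np.sqrt((centred**2).sum(axis=0))
    r = (centred.T @ centred) / np.outer(norm, norm)
    np.clip(r, 0.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    return r


@dataclass
class CovarianceMatrix:
    """Positive-rectified group correlation matrix with provenance."""

    r: np.ndarray
    n_subjects: int
    atlas: AtlasSpec
    group: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.atlas.n_nodes
        if self.r.shape != (n, n):
            raise ValidationError(f"matrix shape {self.r.shape} != atlas n_nodes {n}")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValidationError("correlation matrix is not symmetric")
        if np.any(np.diag(self.r) != 0):
            raise ValidationError("diagonal must be exactly 0")
        if self.r.min() < 0 or self.r.max() > 1:
            raise ValidationError("entries must lie in [0, 1] after rectification")

    @property
    def n_nodes(self) -> int:
        return self.atlas.n_nodes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.atlas.roi_names, columns=self.atlas.roi_names)


def covariance_matrix(residuals: ResidualMatrix, group: str) -> CovarianceMatrix:
    """Build one group's covariance matrix from residualised values.

    Groups of fewer than 4 subjects produce a warning: the Pearson edge
    statistic is essentially unconstrained there.
    """
    rows = residuals.group_rows(group)
    if rows.shape[0] < 2:
        raise ValidationError(f"group {group!r} has {rows.shape[0]} subjects; need >= 2")
    if rows.shape[0] < 4:
        warnings.warn(
            f"group {group!r} has only {rows.shape[0]} subjects; "
            "correlations are degenerate below 4"
        )
    try:
        r = positive_correlation(rows)
    except UndefinedCorrelationError as err:
        idx = int(str(err).split("index ")[1].split(":")[0])
        raise UndefinedCorrelationError(
            f"zero-variance ROI {residuals.atlas.roi_names[idx]!r} in group {group!r}"
        ) from None
    return CovarianceMatrix(r=r, n_subjects=rows.shape[0], atlas=residuals.atlas, group=group)


@dataclass(frozen=True)
class SparsityGrid:
    """Evenly spaced sparsity values, default 0.05..0.40 step 0.01 (36 values)."""

    start: float = 0.05
    stop: float = 0.40
    step: float = 0.01
    values: tuple[float, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.start <= self.stop < 1):
            raise ParameterError(f"need 0 < start <= stop < 1, got [{self.start}, {self.stop}]")
        if self.step <= 0:
            raise ParameterError("step must be positive")
        n = int(np.floor((self.stop - self.start) / self.step + 0.5)) + 1
        vals = tuple(round(self.start + k * self.step, 10) for k in range(n))
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def edge_count_at(s: float, n_nodes: int) -> int:
    """Target edge count at sparsity ``s``: round-half-up of s*N(N-1)/2."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(s * m + 0.5))


def rank_positive_edges(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) pairs of strictly positive entries, strongest first.

    Ties are broken by ascending (i, j), which makes thresholding
    deterministic and graph stacks nested across the grid.
    """
    n = r.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    w = r[ii, jj]
    pos = w > 0
    ii, jj, w = ii[pos], jj[pos], w[pos]
    order = np.lexsort((jj, ii, -w))
    return ii[order], jj[order]


def threshold_at_sparsity(cov: CovarianceMatrix | np.ndarray, s: float) -> np.ndarray:
    """Binarise at sparsity ``s``; returns a uint8 symmetric adjacency matrix."""
    if not (0 < s < 1):
        raise ParameterError(f"sparsity must lie in (0, 1), got {s}")
    r = cov.r if isinstance(cov, CovarianceMatrix) else np.asarray(cov, dtype=float)
    ii, jj = rank_positive_edges(r)
    return _adjacency_from_ranked(r.shape[0], ii, jj, edge_count_at(s, r.shape[0]))


def _adjacency_from_ranked(n: int, ii: np.ndarray, jj: np.ndarray, n_edges: int) -> np.ndarray:
    if n_edges > ii.size:
        warnings.warn(
            f"only {ii.size} positive correlations available for {n_edges} requested edges"
        )
        n_edges = ii.size
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ii[:n_edges], jj[:n_edges]] = 1
    adj[jj[:n_edges], ii[:n_edges]] = 1
    return adj


@dataclass
class GraphStack:
    """One binary adjacency per sparsity-grid value, nested by construction."""

    grid: SparsityGrid
    adjacency: list[np.ndarray]
    edge_counts: list[int]
    atlas: AtlasSpec
    group: str = ""

    @property
    def n_nodes(self) -> int:
        return self.atlas.n_nodes

    def adjacency_frame(self, s: float) -> pd.DataFrame:
        """Adjacency at sparsity ``s`` as a labelled DataFrame (TSV-ready)."""
        try:
            k = self.grid.values.index(round(float(s), 10))
        except ValueError:
            raise ParameterError(f"sparsity {s} not on the grid {self.grid.values[:3]}...") from None
        return pd.DataFrame(self.adjacency[k], index=self.atlas.roi_names,
                            columns=self.atlas.roi_names)


def build_graph_stack(cov: CovarianceMatrix, grid: SparsityGrid | None = None) -> GraphStack:
    """Threshold ``cov`` across the whole grid (edges ranked once, reused)."""
    grid = grid or SparsityGrid()
    n = cov.n_nodes
    ii, jj = rank_positive_edges(cov.r)
    adjacency, counts = [], []
    for s in grid.values:
        adj = _adjacency_from_ranked(n, ii, jj, edge_count_at(s, n))
        adjacency.append(adj)
        counts.append(int(adj.sum()) // 2)
    return GraphStack(grid=grid, adjacency=adjacency, edge_counts=counts,
                      atlas=cov.atlas, group=cov.group)


def check_small_world_range(
    stack: GraphStack,
    n_null: int = 100,
    seed: int = 0,
    sigma_threshold: float = 1.1,
) -> float:
    """Fraction of grid values whose graph is small-world (sigma > threshold).

    The sparsity range is conventionally chosen so that more than 90% of the
    thresholded matrices are small-world; a warning (never an error) is
    emitted when this stack falls at or below that mark. NaN sigma values
    (degenerate graphs) count as failures.
    """
    from .metrics import small_world_indices  # local import avoids a cycle

    if n_null < 20:
        raise ParameterError(f"n_null must be >= 20, got {n_null}")
    n_ok = 0
    for k, adj in enumerate(stack.adjacency):
        sw = small_world_indices(adj, n_null=n_null, seed=seed + k)
        if np.isfinite(sw["sigma"]) and sw["sigma"] > sigma_threshold:
            n_ok += 1
    frac = n_ok / len(stack.adjacency)
    if frac <= 0.90:
        warnings.warn(
            f"only {100 * frac:.1f}% of grid values are small-world "
            f"(sigma > {sigma_threshold}); consider adjusting the sparsity range"
        )
    return frac
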
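"""Graph-theoretic network properties, small-world indices, and AUC summaries.

Global properties: clustering coefficient Cp (mean over nodes), characteristic
path length Lp (mean shortest path over connected pairs), global efficiency
Eglob (mean inverse distance, 1/inf = 0). Nodal properties: degree,
unnormalised Brandes betweenness, nodal efficiency (mean inverse distance
from the node) and local efficiency (global efficiency of the neighbour
subgraph).

Small-worldness normalises Cp and Lp against Maslov–Sneppen degree-preserving
rewired null graphs: gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, and
sigma = gamma/lambda; sigma appreciably above 1 (here > 1.1) marks a
small-world topology. Every property is summarised over the sparsity grid by
its trapezoidal area under the curve (AUC), the threshold-free statistic
that group inference operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .exceptions import ParameterError, UndefinedAUCError, ValidationError
from .network import GraphStack, SparsityGrid

GLOBAL_PROPERTIES = ("Cp", "Lp", "Eglob", "gamma", "lambda", "sigma")
NODAL_PROPERTIES = ("degree", "betweenness", "nodal_efficiency", "local_efficiency")


def _as_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"adjacency must be square, got shape {a.shape}")
    if not np.array_equal(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if not np.isin(a, (0, 1)).all():
        raise ValidationError("adjacency must be binary")
    return np.ascontiguousarray(a, dtype=np.uint8)


def degree_centrality(adj: np.ndarray) -> np.ndarray:
    """Number of neighbours of every node."""
    return _as_adjacency(adj).sum(axis=1).astype(np.int64)


def betweenness_centrality(adj: np.ndarray) -> np.ndarray:
    """Unnormalised shortest-path betweenness (endpoints excluded)."""
    return K.betweenness_k(_as_adjacency(adj))


def clustering_coefficients(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean Cp."""
    c = K.clustering_nodal_k(_as_adjacency(adj))
    return c, float(c.mean())


def characteristic_path_length(adj: np.ndarray) -> float:
    """Mean shortest-path length over finite-distance pairs; NaN if edgeless."""
    _, lp, _ = K.cp_lp_eglob_k(_as_adjacency(adj))
    if np.isnan(lp):
        warnings.warn("graph has no edges: Lp undefined (NaN)")
    return float(lp)


def global_efficiency(adj: np.ndarray) -> float:
    _, _, eg = K.cp_lp_eglob_k(_as_adjacency(adj))
    return float(eg)


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    return K.nodal_efficiency_k(_as_adjacency(adj))


def local_efficiency(adj: np.ndarray) -> np.ndarray:
    return K.local_efficiency_k(_as_adjacency(adj))


def rewire_degree_preserving(
    adj: np.ndarray, n_swap_per_edge: int = 10, seed: int = 0
) -> np.ndarray:
    """Degree-preserving randomisation by repeated double-edge swaps.

    ``n_swap_per_edge * E`` swaps are attempted; graphs with no legal swap
    (e.g. complete graphs) come back unchanged.
    """
    a = _as_adjacency(adj)
    if a.sum() // 2 < 2:
        warnings.warn("fewer than 2 edges: returning the graph unchanged")
        return a.copy()
    return K.rewire_k(a, int(n_swap_per_edge), int(seed) & 0x7FFFFFFF)


def small_world_indices(
    adj: np.ndarray,
    n_null: int = 1000,
    n_swap_per_edge: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """gamma, lambda, sigma and the null means they derive from.

    Cp_rand and Lp_rand are means over ``n_null`` rewired graphs; a zero or
    NaN null mean propagates NaN into the corresponding index.
    """
    if n_null < 20:
        raise ParameterError(f"n_null must be >= 20, got {n_null}")
    a = _as_adjacency(adj)
    cp, lp, _ = K.cp_lp_eglob_k(a)
    cp_rand, lp_rand = K.null_cp_lp_k(a, int(n_null), int(n_swap_per_edge),
                                      int(seed) & 0x7FFFFFFF)
    gamma = cp / cp_rand if (np.isfinite(cp_rand) and cp_rand > 0) else np.nan
    lam = lp / lp_rand if (np.isfinite(lp_rand) and lp_rand > 0) else np.nan
    sigma = gamma / lam if (np.isfinite(gamma) and np.isfinite(lam) and lam != 0) else np.nan
    return {
        "gamma": float(gamma),
        "lambda": float(lam),
        "sigma": float(sigma),
        "Cp_rand": float(cp_rand),
        "Lp_rand": float(lp_rand),
    }


def auc_over_grid(values, grid: SparsityGrid, warn: bool = True) -> float:
    """Trapezoidal AUC of a per-sparsity curve.

    NaN values are tolerated only as a leading run (degenerate low-sparsity
    graphs): the integral is taken over the largest NaN-free suffix of the
    grid, with a warning. An all-NaN curve raises
    :class:`~covnet.exceptions.UndefinedAUCError`.
    """
    v = np.asarray(values, dtype=float)
    s = grid.as_array()
    if v.shape != s.shape:
        raise ValidationError(f"curve length {v.shape} != grid length {s.shape}")
    finite = np.isfinite(v)
    if not finite.any():
        raise UndefinedAUCError("curve is NaN at every grid value")
    start = len(v) - int(finite[::-1].cumprod().sum())
    if start > 0 and warn:
        warnings.warn(
            f"curve undefined at the {start} lowest sparsity values; "
            "AUC computed on the remaining suffix"
        )
    if len(v) - start < 2:
        return np.nan
    return float(np.trapezoid(v[start:], s[start:]))


def _auc_suffix(v: np.ndarray, s: np.ndarray) -> float:
    """Warning-free AUC with the same leading-NaN suffix rule (hot path)."""
    finite = np.isfinite(v)
    if not finite.any():
        return np.nan
    start = len(v) - int(finite[::-1].cumprod().sum())
    if len(v) - start < 2:
        return np.nan
    return float(np.trapezoid(v[start:], s[start:]))


@dataclass
class MetricCurves:
    """All network properties per sparsity plus their AUC summaries.

    ``global_curves`` is indexed by sparsity with columns Cp, Lp, Eglob,
    Cp_rand, Lp_rand, gamma, lambda, sigma; ``nodal_curves`` maps each nodal
    property to a sparsity x node DataFrame.
    """

    grid: SparsityGrid
    global_curves: pd.DataFrame
    nodal_curves: dict[str, pd.DataFrame]
    auc_global: pd.Series
    auc_nodal: pd.DataFrame  # property x node
    group: str = ""

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: group, property, node, sparsity, value."""
        rows = []
        for prop in self.global_curves.columns:
            for s, val in self.global_curves[prop].items():
                rows.append((self.group, prop, "global", s, val))
        for prop, df in self.nodal_curves.items():
            for s, series in df.iterrows():
                for node, val in series.items():
                    rows.append((self.group, prop, node, s, val))
        return pd.DataFrame(rows, columns=["group", "property", "node", "sparsity", "value"])

    def auc_long_frame(self) -> pd.DataFrame:
        rows = [(self.group, p, "global", v) for p, v in self.auc_global.items()]
        for prop, series in self.auc_nodal.iterrows():
            rows += [(self.group, prop, node, v) for node, v in series.items()]
        return pd.DataFrame(rows, columns=["group", "property", "node", "auc"])


def compute_metric_curves(
    stack: GraphStack,
    n_null: int = 1000,
    n_swap_per_edge: int = 10,
    seed: int = 0,
) -> MetricCurves:
    """Evaluate every global and nodal property across a graph stack.

    Null ensembles for gamma/lambda/sigma are regenerated independently per
    sparsity value. Deterministic for a fixed seed.
    """
    grid = stack.grid
    s_arr = grid.as_array()
    glob = {p: [] for p in ("Cp", "Lp", "Eglob", "Cp_rand", "Lp_rand", "gamma", "lambda", "sigma")}
    nodal = {p: [] for p in NODAL_PROPERTIES}
    for k, adj in enumerate(stack.adjacency):
        a = _as_adjacency(adj)
        cp, lp, eg = K.cp_lp_eglob_k(a)
        sw = small_world_indices(a, n_null=n_null, n_swap_per_edge=n_swap_per_edge,
                                 seed=seed * 100003 + k)
        glob["Cp"].append(cp)
        glob["Lp"].append(lp)
        glob["Eglob"].append(eg)
        for key in ("Cp_rand", "Lp_rand", "gamma", "lambda", "sigma"):
            glob[key].append(sw[key])
        nodal["degree"].append(a.sum(axis=1).astype(float))
        nodal["betweenness"].append(K.betweenness_k(a))
        nodal["nodal_efficiency"].append(K.nodal_efficiency_k(a))
        nodal["local_efficiency"].append(K.local_efficiency_k(a))

    global_curves = pd.DataFrame(glob, index=pd.Index(grid.values, name="sparsity"))
    nodal_curves = {
        p: pd.DataFrame(np.vstack(v), index=pd.Index(grid.values, name="sparsity"),
                        columns=stack.atlas.roi_names)
        for p, v in nodal.items()
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auc_global = pd.Series(
            {p: auc_over_grid(global_curves[p].to_numpy(), grid, warn=False)
             for p in GLOBAL_PROPERTIES},
            name="auc",
        )
        auc_nodal = pd.DataFrame(
            {p: [_auc_suffix(nodal_curves[p][node].to_numpy(), s_arr)
                 for node in stack.atlas.roi_names]
             for p in NODAL_PROPERTIES},
            index=stack.atlas.roi_names,
        ).T
    return MetricCurves(
        grid=grid,
        global_curves=global_curves,
        nodal_curves=nodal_curves,
        auc_global=auc_global,
        auc_nodal=auc_nodal,
        group=stack.group,
    )
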
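"""Permutation-based group inference on AUC-summarised network properties.

The test statistic for every property is the difference of its AUC over the
sparsity grid between two groups. The null distribution re-runs the full
pipeline — residuals, group covariance, thresholding, metrics, AUC — for
each relabelling of the subjects:

* unpaired design: subjects are re-partitioned between the two groups
  preserving group sizes (exhaustively when the number of distinct
  partitions is within ``n_perm``, Monte Carlo otherwise);
* paired design: the two members of every pair are independently swapped
  (exhaustive over the 2^n_pairs sign patterns when feasible).

Monte Carlo p-values use the add-one estimator
``p = (#{|null| >= |obs|} + 1) / (n_perm + 1)`` and are therefore never
below ``1/(n_perm+1)``; exhaustive p-values are exact proportions over all
relabellings. Nodal property families are corrected per property across
nodes with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import _kernels as K
from .exceptions import DesignError, ParameterError, ValidationError
from .io import Cohort, concat_cohorts
from .metrics import GLOBAL_PROPERTIES, NODAL_PROPERTIES, _auc_suffix
from .network import (
    CovarianceMatrix,
    SparsityGrid,
    edge_count_at,
    positive_correlation,
    rank_positive_edges,
)
from .preprocess import DEFAULT_COVARIATES, _design_matrix, residuals_ols

from scipy import stats as _sstats

log = logging.getLogger("covnet")

_GLOBAL_ORDER = {p: k for k, p in enumerate(GLOBAL_PROPERTIES)}


# ---------------------------------------------------------------------------
# FDR and edge backbone


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted p-values and rejection flags.

    NaN entries pass through as NaN / not rejected.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej_f, adj_f, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
        adj[finite] = adj_f
        rej[finite] = rej_f
    return adj, rej


def edge_backbone(cov: CovarianceMatrix, alpha: float = 0.001) -> np.ndarray:
    """Significant-correlation edge mask (the group-average backbone).

    An edge is retained iff the two-tailed p of the Pearson t statistic
    ``t = r sqrt((n-2)/(1-r^2))`` is below ``alpha``; ``r == 1`` is retained
    (p treated as 0).
    """
    if cov.n_subjects < 4:
        raise ValidationError("edge backbone needs >= 4 subjects (t test with n-2 df)")
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    r = cov.r
    n = cov.n_subjects
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * _sstats.t.sf(np.abs(t), df=n - 2)
    p = np.where(r >= 1.0, 0.0, p)
    mask = (p < alpha) & (r > 0)
    np.fill_diagonal(mask, False)
    return mask


# ---------------------------------------------------------------------------
# Per-group AUC statistics (the statistic the permutation shuffles)


def group_auc_statistics(
    rows: np.ndarray,
    grid: SparsityGrid,
    properties: Sequence[str],
    n_null_inner: int = 100,
    n_swap_per_edge: int = 10,
    seed: int = 0,
) -> dict[str, float | np.ndarray]:
    """AUC of each requested property for one group's residual rows.

    This is the full per-group pipeline stage: positive-rectified Pearson
    matrix, sparsity thresholding across the grid, metric curves, trapezoidal
    AUC (leading-NaN suffix rule).
    """
    s_values = grid.as_array()
    n_s = len(s_values)
    want_glob = [p for p in properties if p in _GLOBAL_ORDER]
    want_nodal = [p for p in properties if p in NODAL_PROPERTIES]
    need_null = any(p in ("gamma", "lambda", "sigma") for p in want_glob)

    r = positive_correlation(rows)
    n = r.shape[0]
    m = n * (n - 1) // 2
    ii, jj = rank_positive_edges(r)

    glob = np.full((n_s, 6), np.nan)
    nodal = {p: np.full((n_s, n), np.nan) for p in want_nodal}
    adj = np.zeros((n, n), dtype=np.uint8)
    prev = 0
    for k, s in enumerate(s_values):
        e = min(edge_count_at(float(s), n), ii.size)
        if e > prev:
            adj[ii[prev:e], jj[prev:e]] = 1
            adj[jj[prev:e], ii[prev:e]] = 1
            prev = e
        cp, lp, eg = K.cp_lp_eglob_k(adj)
        glob[k, 0], glob[k, 1], glob[k, 2] = cp, lp, eg
        if need_null:
            cpr, lpr = K.null_cp_lp_k(
                adj, int(n_null_inner), int(n_swap_per_edge), (seed + 7919 * k) & 0x7FFFFFFF
            )
            gamma = cp / cpr if cpr > 0 else np.nan
            lam = lp / lpr if (np.isfinite(lp) and np.isfinite(lpr) and lpr > 0) else np.nan
            glob[k, 3] = gamma
            glob[k, 4] = lam
            glob[k, 5] = gamma / lam if (np.isfinite(gamma) and np.isfinite(lam) and lam != 0) else np.nan
        if "degree" in nodal:
            nodal["degree"][k] = adj.sum(axis=1)
        if "betweenness" in nodal:
            nodal["betweenness"][k] = K.betweenness_k(adj)
        if "nodal_efficiency" in nodal:
            nodal["nodal_efficiency"][k] = K.nodal_efficiency_k(adj)
        if "local_efficiency" in nodal:
            nodal["local_efficiency"][k] = K.local_efficiency_k(adj)

    out: dict[str, float | np.ndarray] = {}
    for p in want_glob:
        out[p] = _auc_suffix(glob[:, _GLOBAL_ORDER[p]], s_values)
    for p in want_nodal:
        out[p] = np.array([_auc_suffix(nodal[p][:, v], s_values) for v in range(n)])
    return out


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class PermutationResult:
    """One property/node test: observed AUC difference and its permutation p."""

    property: str
    node: str  # "global" for global properties
    observed_diff: float
    p_raw: float
    p_fdr: float
    n_perm: int
    seed: int
    design: str  # "unpaired" | "paired"
    exhaustive: bool
    null_diffs: np.ndarray = field(repr=False, default=None)


class PermutationResultSet:
    """Ordered collection of :class:`PermutationResult` with a table view."""

    def __init__(self, results: list[PermutationResult]):
        self.results = results

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def __getitem__(self, key):
        if isinstance(key, int):
            return self.results[key]
        prop, node = key if isinstance(key, tuple) else (key, "global")
        for r in self.results:
            if r.property == prop and r.node == node:
                return r
        raise KeyError(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "design": r.design,
                    "property": r.property,
                    "node": r.node,
                    "observed_diff": r.observed_diff,
                    "p_raw": r.p_raw,
                    "p_fdr": r.p_fdr,
                    "n_perm": r.n_perm,
                    "seed": r.seed,
                }
                for r in self.results
            ]
        )


# ---------------------------------------------------------------------------
# Shared engine


def _choose_exhaustive(method: str, n_exact: int, n_perm: int) -> bool:
    if method == "auto":
        return n_exact <= n_perm
    if method == "exhaustive":
        return True
    if method == "monte-carlo":
        return False
    raise ParameterError(f"method must be auto|exhaustive|monte-carlo, got {method!r}")


def _resolve_properties(properties) -> list[str]:
    if properties == "global":
        return list(GLOBAL_PROPERTIES)
    if properties == "nodal":
        return list(NODAL_PROPERTIES)
    if properties == "all":
        return list(GLOBAL_PROPERTIES) + list(NODAL_PROPERTIES)
    props = list(properties)
    unknown = [p for p in props if p not in GLOBAL_PROPERTIES + NODAL_PROPERTIES]
    if unknown:
        raise ParameterError(f"unknown properties {unknown}")
    return props


def _stats_for_split(resid_all, values_all, design_all, idx_a, idx_b, grid, props,
                     n_null_inner, n_swap, seed, per_group):
    if per_group:
        rows_a = residuals_ols(values_all[idx_a], design_all[idx_a])
        rows_b = residuals_ols(values_all[idx_b], design_all[idx_b])
    else:
        rows_a = resid_all[idx_a]
        rows_b = resid_all[idx_b]
    a = group_auc_statistics(rows_a, grid, props, n_null_inner, n_swap, seed)
    b = group_auc_statistics(rows_b, grid, props, n_null_inner, n_swap, seed + 1_000_003)
    return {p: np.asarray(a[p]) - np.asarray(b[p]) for p in props}


def _collect_results(
    props, observed, null_list, n_eff, exhaustive, seed, design, q
) -> PermutationResultSet:
    results: list[PermutationResult] = []
    for p in props:
        obs = np.atleast_1d(observed[p]).astype(float)
        null = np.stack([np.atleast_1d(d[p]).astype(float) for d in null_list])
        n_units = obs.size
        p_raw = np.full(n_units, np.nan)
        for u in range(n_units):
            if not np.isfinite(obs[u]):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                count = int(np.nansum(np.abs(null[:, u]) >= abs(obs[u])))
            if exhaustive:
                p_raw[u] = count / null.shape[0]
            else:
                p_raw[u] = (count + 1) / (null.shape[0] + 1)
        if p in GLOBAL_PROPERTIES:
            results.append(
                PermutationResult(p, "global", float(obs[0]), float(p_raw[0]), np.nan,
                                  n_eff, seed, design, exhaustive, null[:, 0])
            )
        else:
            p_adj, _ = fdr_bh(p_raw, q=q)
            for u in range(n_units):
                results.append(
                    PermutationResult(p, f"node{u}", float(obs[u]), float(p_raw[u]),
                                      float(p_adj[u]), n_eff, seed, design, exhaustive,
                                      null[:, u])
                )
    return PermutationResultSet(results)


def _run_splits(worker, splits, seeds, n_jobs):
    if n_jobs == 1:
        out = []
        for k, (sp, sd) in enumerate(zip(splits, seeds), start=1):
            out.append(worker(sp, sd))
            if k % 500 == 0:
                log.debug("permutation %d/%d", k, len(splits))
        return out
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_jobs, batch_size="auto")(
        delayed(worker)(sp, sd) for sp, sd in zip(splits, seeds)
    )


def _node_names(result_set: PermutationResultSet, atlas) -> PermutationResultSet:
    for r in result_set:
        if r.node.startswith("node"):
            r.node = atlas.roi_names[int(r.node[4:])]
    return result_set


# ---------------------------------------------------------------------------
# Public tests


def permutation_test_unpaired(
    cohort_a: Cohort,
    cohort_b: Cohort,
    grid: SparsityGrid | None = None,
    properties="global",
    n_perm: int = 5000,
    n_null_inner: int = 100,
    n_swap_per_edge: int = 10,
    covariates=DEFAULT_COVARIATES,
    fit_scope: str = "pooled",
    seed: int = 0,
    n_jobs: int = 1,
    q: float = 0.05,
    method: str = "auto",
) -> PermutationResultSet:
    """Subject-shuffle permutation test of AUC differences (A minus B).

    Subjects of both cohorts are pooled, residualised, and re-partitioned
    ``n_perm`` times preserving group sizes (exhaustive enumeration of all
    C(nA+nB, nA) partitions replaces sampling when feasible; ``method``
    forces either path). Deterministic for a fixed ``seed`` and independent
    of ``n_jobs``.
    """
    grid = grid or SparsityGrid()
    props = _resolve_properties(properties)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; p-value floor is {1/(n_perm+1):.3g}")
    pooled = concat_cohorts(cohort_a, cohort_b)
    # canonical subject order makes the sampled partitions (and hence the
    # Monte Carlo p) invariant to swapping the roles of A and B
    pooled = pooled.subset(np.argsort(np.asarray(pooled.subject_ids)))
    label_a = cohort_a.groups[0]
    n_a = cohort_a.n_subjects
    n = pooled.n_subjects
    if min(n_a, n - n_a) < 2:
        raise DesignError("each group needs at least 2 subjects")

    design = _design_matrix(pooled, tuple(covariates))
    resid = residuals_ols(pooled.values, design)
    per_group = fit_scope == "per-group"

    n_exact = math.comb(n, n_a)
    exhaustive = _choose_exhaustive(method, n_exact, n_perm)
    all_idx = np.arange(n)
    k = min(n_a, n - n_a)  # sample the smaller side; complements are shared
    if exhaustive:
        splits = []
        for comb in combinations(range(n), k):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            small, rest = all_idx[mask], all_idx[~mask]
            splits.append((small, rest) if n_a == k else (rest, small))
        n_eff = n_exact
    else:
        rng = np.random.default_rng(seed)
        splits = []
        for _ in range(n_perm):
            perm = rng.permutation(n)
            small, rest = np.sort(perm[:k]), np.sort(perm[k:])
            splits.append((small, rest) if n_a == k else (rest, small))
        n_eff = n_perm
    inner_seeds = (np.random.SeedSequence(seed).generate_state(len(splits) + 1)
                   & 0x7FFFFFFF).astype(np.int64)

    in_a = pooled.group_labels == label_a
    obs_idx = (all_idx[in_a], all_idx[~in_a])

    def worker(split, inner_seed):
        return _stats_for_split(resid, pooled.values, design, split[0], split[1],
                                grid, props, n_null_inner, n_swap_per_edge,
                                int(inner_seed), per_group)

    observed = worker(obs_idx, inner_seeds[-1])
    null_list = _run_splits(worker, splits, inner_seeds[:-1], n_jobs)
    res = _collect_results(props, observed, null_list, n_eff, exhaustive, seed,
                           "unpaired", q)
    return _node_names(res, pooled.atlas)


def permutation_test_paired(
    cohort: Cohort,
    group_a: str,
    group_b: str,
    grid: SparsityGrid | None = None,
    properties="global",
    n_perm: int = 5000,
    n_null_inner: int = 100,
    n_swap_per_edge: int = 10,
    covariates=DEFAULT_COVARIATES,
    fit_scope: str = "pooled",
    seed: int = 0,
    n_jobs: int = 1,
    q: float = 0.05,
    method: str = "auto",
) -> PermutationResultSet:
    """Within-pair exchange permutation test (longitudinal design).

    Every subject must belong to exactly one two-member pair with one member
    in each group; the null swaps the two members of each pair
    independently. All 2^n_pairs sign patterns are enumerated when that count
    is within ``n_perm`` (``method`` forces either path).
    """
    grid = grid or SparsityGrid()
    props = _resolve_properties(properties)
    if cohort.pair_id is None:
        raise DesignError("paired test requires a cohort with pair_id")

    pair_members: dict[str, dict[str, int]] = {}
    for i, (pid, g) in enumerate(zip(cohort.pair_id, cohort.group_labels)):
        pair_members.setdefault(str(pid), {})[str(g)] = i
    pairs = []
    for pid, members in sorted(pair_members.items()):
        if set(members) != {group_a, group_b}:
            raise DesignError(
                f"pair {pid!r} does not have one member in each of "
                f"{group_a!r}/{group_b!r}: has {sorted(members)}"
            )
        pairs.append((members[group_a], members[group_b]))
    n_pairs = len(pairs)
    pairs_arr = np.asarray(pairs)

    design = _design_matrix(cohort, tuple(covariates))
    resid = residuals_ols(cohort.values, design)
    per_group = fit_scope == "per-group"

    exhaustive = _choose_exhaustive(method, 2**n_pairs, n_perm)
    if exhaustive:
        signs = [(code >> np.arange(n_pairs)) & 1 for code in range(2**n_pairs)]
        n_eff = 2**n_pairs
    else:
        rng = np.random.default_rng(seed)
        signs = [rng.integers(0, 2, n_pairs) for _ in range(n_perm)]
        n_eff = n_perm
    inner_seeds = (np.random.SeedSequence(seed).generate_state(len(signs) + 1)
                   & 0x7FFFFFFF).astype(np.int64)

    def split_of(sign):
        idx_a = np.where(sign == 1, pairs_arr[:, 1], pairs_arr[:, 0])
        idx_b = np.where(sign == 1, pairs_arr[:, 0], pairs_arr[:, 1])
        return idx_a, idx_b

    def worker(sign, inner_seed):
        idx_a, idx_b = split_of(np.asarray(sign))
        return _stats_for_split(resid, cohort.values, design, idx_a, idx_b,
                                grid, props, n_null_inner, n_swap_per_edge,
                                int(inner_seed), per_group)

    observed = worker(np.zeros(n_pairs, dtype=np.int64), inner_seeds[-1])
    null_list = _run_splits(worker, signs, inner_seeds[:-1], n_jobs)
    res = _collect_results(props, observed, null_list, n_eff, exhaustive, seed,
                           "paired", q)
    return _node_names(res, cohort.atlas)
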
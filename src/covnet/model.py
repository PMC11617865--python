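"""Model / results objects tying the pipeline stages together.

:class:`GroupSCN` describes a single group: covariance matrix, graph stack,
metric curves, small-world range check and the significant-correlation edge
backbone. :class:`SCNComparison` is the two-group (or two-scan) comparison
model whose :meth:`~SCNComparison.fit` runs the permutation inference and
returns an :class:`SCNComparisonResults` carrying observed AUCs, their
permutation p-values and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DesignError
from .io import Cohort, concat_cohorts
from .inference import (
    PermutationResultSet,
    edge_backbone,
    permutation_test_paired,
    permutation_test_unpaired,
)
from .metrics import GLOBAL_PROPERTIES, MetricCurves, compute_metric_curves
from .network import (
    CovarianceMatrix,
    GraphStack,
    SparsityGrid,
    build_graph_stack,
    covariance_matrix,
)
from .preprocess import DEFAULT_COVARIATES, residualize


class GroupSCN:
    """Structural covariance network of one group.

    Parameters
    ----------
    cohort : Cohort
        Subjects of a single group (or pass ``group`` to select one label).
    grid : SparsityGrid, optional
    covariates : sequence of str
        Nuisance covariates residualised out before correlation.
    """

    def __init__(self, cohort: Cohort, group: str | None = None,
                 grid: SparsityGrid | None = None, covariates=DEFAULT_COVARIATES):
        if group is not None:
            cohort = cohort.subset(cohort.group_indices(group))
        labels = cohort.groups
        if len(labels) != 1:
            raise DesignError(f"GroupSCN expects one group, cohort has {labels}")
        self.cohort = cohort
        self.group = labels[0]
        self.grid = grid or SparsityGrid()
        self.covariates = tuple(covariates)

    def fit(self, n_null: int = 1000, n_swap_per_edge: int = 10, seed: int = 0,
            backbone_alpha: float = 0.001) -> "GroupSCNResults":
        resid = residualize(self.cohort, self.covariates)
        cov = covariance_matrix(resid, self.group)
        stack = build_graph_stack(cov, self.grid)
        curves = compute_metric_curves(stack, n_null=n_null,
                                       n_swap_per_edge=n_swap_per_edge, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_fraction = float(np.mean(
                np.isfinite(curves.global_curves["sigma"])
                & (curves.global_curves["sigma"] > 1.1)
            ))
        backbone = edge_backbone(cov, alpha=backbone_alpha) if cov.n_subjects >= 4 else None
        return GroupSCNResults(model=self, covariance=cov, stack=stack,
                               curves=curves, small_world_fraction=sw_fraction,
                               backbone=backbone)


@dataclass
class GroupSCNResults:
    model: GroupSCN
    covariance: CovarianceMatrix
    stack: GraphStack
    curves: MetricCurves
    small_world_fraction: float
    backbone: np.ndarray | None

    def summary(self) -> str:
        lines = [
            f"Structural covariance network: group {self.model.group!r}",
            f"  atlas: {self.covariance.atlas.name} ({self.covariance.n_nodes} nodes), "
            f"n = {self.covariance.n_subjects} subjects",
            f"  sparsity grid: {self.model.grid.start}-{self.model.grid.stop} "
            f"step {self.model.grid.step} ({len(self.model.grid)} values)",
            f"  small-world (sigma > 1.1) at {100 * self.small_world_fraction:.1f}% "
            f"of grid values",
            "",
            "  AUC over sparsity (global properties):",
        ]
        for p, v in self.curves.auc_global.items():
            lines.append(f"    {p:<8} {v: .4f}")
        return "\n".join(lines)


class SCNComparison:
    """Two-group structural covariance comparison model.

    Parameters
    ----------
    cohort_a, cohort_b : Cohort
        The groups to compare (A minus B); for ``design="paired"`` pass one
        cohort carrying ``pair_id`` via :meth:`from_cohort`.
    design : {"unpaired", "paired"}
    properties : "global" | "nodal" | "all" | sequence
        Which AUC statistics to test.
    """

    def __init__(self, cohort_a: Cohort, cohort_b: Cohort | None = None, *,
                 design: str = "unpaired", grid: SparsityGrid | None = None,
                 covariates=DEFAULT_COVARIATES, properties="all",
                 fit_scope: str = "pooled"):
        if design not in ("unpaired", "paired"):
            raise DesignError(f"design must be unpaired|paired, got {design!r}")
        if design == "paired":
            if cohort_b is not None:
                raise DesignError("paired design takes a single cohort with pair_id")
            if cohort_a.pair_id is None:
                raise DesignError("paired design requires pair_id")
            groups = cohort_a.groups
            if len(groups) != 2:
                raise DesignError(f"paired cohort must have two group labels, has {groups}")
            self.pooled = cohort_a
            self.group_a, self.group_b = groups
        else:
            if cohort_b is None:
                raise DesignError("unpaired design needs two cohorts")
            self.pooled = concat_cohorts(cohort_a, cohort_b)
            self.group_a = cohort_a.groups[0]
            self.group_b = cohort_b.groups[0]
        self.design = design
        self.grid = grid or SparsityGrid()
        self.covariates = tuple(covariates)
        self.properties = properties
        self.fit_scope = fit_scope

    @classmethod
    def from_cohort(cls, cohort: Cohort, group_a: str, group_b: str,
                    **kwargs) -> "SCNComparison":
        """Build a comparison from one cohort holding several group labels."""
        design = kwargs.pop("design", "paired" if cohort.pair_id is not None else "unpaired")
        if design == "paired":
            model = cls.__new__(cls)
            SCNComparison.__init__(
                model,
                cohort.subset(np.concatenate([cohort.group_indices(group_a),
                                              cohort.group_indices(group_b)])),
                design="paired", **kwargs,
            )
            model.group_a, model.group_b = group_a, group_b
            return model
        a = cohort.subset(cohort.group_indices(group_a))
        b = cohort.subset(cohort.group_indices(group_b))
        return cls(a, b, design="unpaired", **kwargs)

    def fit(self, n_perm: int = 5000, n_null: int = 1000, n_null_inner: int = 100,
            n_swap_per_edge: int = 10, seed: int = 0, n_jobs: int = 1,
            q: float = 0.05, backbone_alpha: float = 0.001) -> "SCNComparisonResults":
        """Run the full comparison: group curves at ``n_null`` reported nulls
        plus the ``n_perm``-replicate permutation test (``n_null_inner``
        rewired nulls inside each replicate)."""
        results_a = GroupSCN(self.pooled, self.group_a, self.grid,
                             self.covariates).fit(n_null=n_null, seed=seed,
                                                  backbone_alpha=backbone_alpha)
        results_b = GroupSCN(self.pooled, self.group_b, self.grid,
                             self.covariates).fit(n_null=n_null, seed=seed + 1,
                                                  backbone_alpha=backbone_alpha)
        common = dict(grid=self.grid, properties=self.properties, n_perm=n_perm,
                      n_null_inner=n_null_inner, n_swap_per_edge=n_swap_per_edge,
                      covariates=self.covariates, fit_scope=self.fit_scope,
                      seed=seed, n_jobs=n_jobs, q=q)
        if self.design == "paired":
            perm = permutation_test_paired(self.pooled, self.group_a, self.group_b,
                                           **common)
        else:
            a = self.pooled.subset(self.pooled.group_indices(self.group_a))
            b = self.pooled.subset(self.pooled.group_indices(self.group_b))
            perm = permutation_test_unpaired(a, b, **common)
        return SCNComparisonResults(model=self, group_a=results_a, group_b=results_b,
                                    permutation=perm, n_perm=n_perm, seed=seed)


@dataclass
class SCNComparisonResults:
    """Observed group networks plus permutation inference on AUC differences."""

    model: SCNComparison
    group_a: GroupSCNResults
    group_b: GroupSCNResults
    permutation: PermutationResultSet
    n_perm: int
    seed: int

    @property
    def global_table(self) -> pd.DataFrame:
        df = self.permutation.to_frame()
        return df[df["node"] == "global"].drop(columns=["node"]).reset_index(drop=True)

    @property
    def nodal_table(self) -> pd.DataFrame:
        df = self.permutation.to_frame()
        return df[df["node"] != "global"].reset_index(drop=True)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Structural covariance network comparison",
            "========================================",
            f"design: {m.design}   A = {m.group_a!r}  B = {m.group_b!r}   "
            f"statistic: AUC(A) - AUC(B)",
            f"atlas: {m.pooled.atlas.name} ({m.pooled.atlas.n_nodes} nodes)   "
            f"grid: {m.grid.start}-{m.grid.stop}/{m.grid.step}",
            f"permutations: {self.n_perm} (seed {self.seed})   "
            f"small-world fraction A/B: {self.group_a.small_world_fraction:.2f}/"
            f"{self.group_b.small_world_fraction:.2f}",
            "",
        ]
        gt = self.global_table
        if len(gt):
            lines.append("Global properties:")
            lines.append(f"  {'property':<10} {'AUC diff':>10} {'p_perm':>8}")
            for _, row in gt.iterrows():
                lines.append(f"  {row['property']:<10} {row['observed_diff']:>10.4f} "
                             f"{row['p_raw']:>8.4f}")
        nt = self.nodal_table
        if len(nt):
            sig = nt[nt["p_fdr"] < 0.05]
            lines.append("")
            lines.append(f"Nodal properties: {len(nt)} tests, "
                         f"{len(sig)} significant at FDR q < 0.05")
            for _, row in sig.iterrows():
                lines.append(f"  {row['property']:<18} {row['node']:<28} "
                             f"diff {row['observed_diff']: .4f}  p {row['p_raw']:.4f}  "
                             f"FDR {row['p_fdr']:.4f}")
        return "\n".join(lines)

    def plot_global(self, prop: str = "sigma", ax=None):
        """Per-sparsity curves of one global property for both groups."""
        import matplotlib.pyplot as plt

        if prop not in GLOBAL_PROPERTIES:
            raise KeyError(f"unknown global property {prop!r}")
        if ax is None:
            _, ax = plt.subplots()
        for res, label in ((self.group_a, self.model.group_a),
                           (self.group_b, self.model.group_b)):
            curve = res.curves.global_curves[prop]
            ax.plot(curve.index, curve.to_numpy(), label=str(label))
        ax.set_xlabel("sparsity")
        ax.set_ylabel(prop)
        ax.legend()
        return ax
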
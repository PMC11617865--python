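"""Covariate removal: per-ROI ordinary least squares residualization.

Every ROI column is regressed on an intercept plus the chosen nuisance
covariates (age in years and intracranial volume in mm^3 by default) and the
residuals replace the raw values before any covariance is computed. The
default fits one regression per ROI pooled across all subjects handed in
(both groups of a comparison), which keeps genuine group covariance
differences in the residuals; a per-group scope is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .atlases import AtlasSpec
from .exceptions import DegenerateDesignError, ValidationError
from .io import Cohort

DEFAULT_COVARIATES = ("age", "icv")


@dataclass
class ResidualMatrix:
    """OLS residuals of ROI measurements, mean-centred per column."""

    subject_ids: list[str]
    residuals: np.ndarray  # subjects x ROIs
    group_labels: np.ndarray
    atlas: AtlasSpec
    covariates_used: tuple[str, ...]
    fit_scope: str  # "pooled" | "per-group"
    pair_id: np.ndarray | None = None

    def group_rows(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.group_labels == label)
        if idx.size == 0:
            raise KeyError(f"group label {label!r} not present")
        return self.residuals[idx]


def _design_matrix(cohort: Cohort, covariate_names: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(cohort.n_subjects)]
    for name in covariate_names:
        if not hasattr(cohort, name):
            raise ValidationError(f"unknown covariate {name!r}; cohort has age, icv")
        col = np.asarray(getattr(cohort, name), dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValidationError(f"covariate {name!r} contains non-finite values")
        # centring improves conditioning; residuals are unaffected
        cols.append(col - col.mean())
    return np.column_stack(cols)


def residuals_ols(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of every column of ``values`` on the common ``design``.

    Raises
    ------
    DegenerateDesignError
        Fewer rows than parameters + 1, or a rank-deficient design.
    """
    n, p = design.shape
    if n < p + 1:
        raise DegenerateDesignError(
            f"{n} subjects cannot identify {p} regression parameters (need > {p})"
        )
    if np.linalg.matrix_rank(design) < p:
        raise DegenerateDesignError(
            "rank-deficient design (constant or collinear covariate)"
        )
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def residualize(
    cohort: Cohort,
    covariate_names=DEFAULT_COVARIATES,
    fit_scope: str = "pooled",
) -> ResidualMatrix:
    """Remove covariate effects from every ROI by linear regression.

    Parameters
    ----------
    cohort : Cohort
    covariate_names : sequence of str
        Covariates to regress out; the intercept is always included, so an
        empty sequence plain-centres every column.
    fit_scope : {"pooled", "per-group"}
        Whether one regression per ROI spans all subjects (default) or each
        group label is fitted separately.

    Returns
    -------
    ResidualMatrix
        Residuals orthogonal to each covariate (within 1e-8) with column
        means ~0.
    """
    covariate_names = tuple(covariate_names)
    if fit_scope not in ("pooled", "per-group"):
        raise ValidationError(f"fit_scope must be pooled|per-group, got {fit_scope!r}")

    if fit_scope == "pooled":
        design = _design_matrix(cohort, covariate_names)
        resid = residuals_ols(cohort.values, design)
    else:
        resid = np.empty_like(cohort.values)
        for g in cohort.groups:
            idx = cohort.group_indices(g)
            sub = cohort.subset(idx)
            design = _design_matrix(sub, covariate_names)
            resid[idx] = residuals_ols(sub.values, design)

    if cohort.n_subjects <= len(covariate_names) + 2:
        warnings.warn(
            "residualization leaves almost no degrees of freedom "
            f"({cohort.n_subjects} subjects, {len(covariate_names) + 1} parameters)"
        )
    return ResidualMatrix(
        subject_ids=list(cohort.subject_ids),
        residuals=resid,
        group_labels=cohort.group_labels.copy(),
        atlas=cohort.atlas,
        covariates_used=covariate_names,
        fit_scope=fit_scope,
        pair_id=None if cohort.pair_id is None else cohort.pair_id.copy(),
    )
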
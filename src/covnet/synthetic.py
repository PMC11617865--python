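"""Synthetic cohorts with the statistical structure the pipeline assumes.

ROI measurements are drawn from a multivariate normal whose correlation
matrix is block-constant: anatomically coherent node sets share a common
within-block correlation ``r`` on top of a weak background correlation
``r0``. Age and intracranial-volume effects are added linearly per ROI (the
confounds the pipeline residualises away), plus independent measurement
noise. Everything is deterministic per seed.

The packaged fixtures mirror the shapes of the study this pipeline is meant
for: a healthy-control-sized cohort (~40 subjects per group, age ~60 +/- 9.4
years), the 17-node subcortical parcellation, and an 8-pair longitudinal
follow-up. ``null_17`` draws both groups from one generator (type-I-error
scenario), ``effect_17`` lowers all block correlations from 0.7 to 0.1 in
the second group (a strong planted covariance loss), ``paired_8`` plants a
within-block correlation drop at the second scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlases import AtlasSpec, load_atlas
from .exceptions import ParameterError, ValidationError
from .io import Cohort, ROITable, write_stats_table

#: Anatomical block structure used by the subcortical fixtures: thalamus +
#: basal ganglia, hippocampus + amygdala, cingulate subdivisions.
SUBCORTICAL17_BLOCKS = (tuple(range(0, 8)), tuple(range(8, 12)), tuple(range(12, 17)))


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic group.

    ``blocks`` is a sequence of ``(node_indices, r)`` pairs; nodes outside
    every block correlate at the background level ``r0``. ``beta_age`` is in
    measure units per year, ``beta_icv`` in measure units per mm^3 of ICV.
    ``noise_sd`` is independent per-measurement noise on top of the
    correlated signal (signal scale ``roi_sd``).
    """

    atlas: str = "subcortical17"
    n_subjects: int = 40
    group_label: str = "HC"
    blocks: tuple = SUBCORTICAL17_BLOCKS
    block_r: tuple | float = 0.6
    r0: float = 0.1
    roi_mean: float = 4000.0  # mm^3 baseline for subcortical volumes
    roi_sd: float = 400.0
    beta_age: float = -15.0  # mm^3 atrophy per year
    beta_icv: float = 0.002  # scaling with head size
    age_mean: float = 60.0
    age_sd: float = 9.4
    icv_mean: float = 1.45e6
    icv_sd: float = 1.4e5
    noise_sd: float = 20.0
    measure_kind: str = "volume"
    subject_prefix: str = "S"
    seed: int = 0

    def block_pairs(self) -> list[tuple[tuple[int, ...], float]]:
        rs = self.block_r
        if np.isscalar(rs):
            rs = tuple(float(rs) for _ in self.blocks)
        if len(rs) != len(self.blocks):
            raise ValidationError("block_r length must match number of blocks")
        return [(tuple(b), float(r)) for b, r in zip(self.blocks, rs)]

    def correlation_matrix(self) -> np.ndarray:
        """The planted signal correlation matrix (validated PSD)."""
        atlas = load_atlas(self.atlas)
        n = atlas.n_nodes
        pairs = self.block_pairs()
        for b, r in pairs:
            if not (0.0 <= self.r0 <= r < 1.0):
                raise ValidationError(
                    f"need 0 <= r0 <= block r < 1; got r0={self.r0}, r={r}"
                )
            if max(b) >= n:
                raise ValidationError(f"block node {max(b)} outside atlas of {n} nodes")
        corr = np.full((n, n), self.r0)
        for b, r in pairs:
            bi = np.asarray(b)
            corr[np.ix_(bi, bi)] = r
        np.fill_diagonal(corr, 1.0)
        lo = float(np.linalg.eigvalsh(corr)[0])
        if lo < -1e-10:
            raise ValidationError(
                f"implied correlation matrix is not PSD (min eigenvalue {lo:.3g})"
            )
        return corr


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw one cohort from a :class:`SyntheticSpec` (deterministic per seed)."""
    atlas = load_atlas(spec.atlas)
    corr = spec.correlation_matrix()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, atlas.n_nodes
    if n < 2:
        raise ParameterError("need at least 2 subjects")
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    icv = rng.normal(spec.icv_mean, spec.icv_sd, size=n)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(p))
    latent = rng.standard_normal((n, p)) @ chol.T
    values = (
        spec.roi_mean
        + spec.roi_sd * latent
        + spec.beta_age * (age - spec.age_mean)[:, None]
        + spec.beta_icv * (icv - spec.icv_mean)[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(n, p))
    )
    subject_ids = [f"{spec.subject_prefix}{spec.group_label}{i:03d}" for i in range(n)]
    return Cohort(
        subject_ids=subject_ids,
        values=values,
        group_labels=np.asarray([spec.group_label] * n, dtype=object),
        age=age,
        icv=icv,
        atlas=atlas,
        measure_kind=spec.measure_kind,
    )


def make_group_pair(spec_a: SyntheticSpec, spec_b: SyntheticSpec) -> tuple[Cohort, Cohort]:
    """Two independent cohorts over the same atlas/covariate model.

    The cohorts differ only as the specs differ (typically in block
    correlations and seed); group A's draw never depends on spec B.
    """
    if spec_a.atlas != spec_b.atlas:
        raise ValidationError(f"atlas mismatch: {spec_a.atlas!r} vs {spec_b.atlas!r}")
    if spec_a.group_label == spec_b.group_label:
        spec_b = replace(spec_b, group_label=spec_b.group_label + "b")
    return generate_cohort(spec_a), generate_cohort(spec_b)


def make_paired_cohort(
    n_pairs: int = 8,
    effect: float = -0.3,
    rho_within_subject: float = 0.7,
    seed: int = 0,
    base: SyntheticSpec | None = None,
    effect_block: int = 1,
    scan_interval_years: float = 0.33,
) -> Cohort:
    """Two-scan longitudinal cohort with an optional planted covariance shift.

    ``effect`` shifts the *marginal* scan-2 correlation of ``effect_block``
    (the innovation correlation is solved for, so the planted shift is not
    attenuated by the within-subject correlation). Scan-2 latent values are
    ``rho * z1 + sqrt(1 - rho^2) * e`` with ``e`` drawn from the solved
    innovation matrix. Group labels are ``scan1`` / ``scan2`` and
    ``pair_id`` links the two rows per subject.
    """
    base = base or SyntheticSpec(n_subjects=n_pairs)
    if not (0.0 <= rho_within_subject < 1.0):
        raise ParameterError("rho_within_subject must lie in [0, 1)")
    pairs = base.block_pairs()
    shifted_r = list(r for _, r in pairs)
    shifted_r[effect_block] += effect
    if not (0.0 <= base.r0 <= shifted_r[effect_block] < 1.0):
        raise ParameterError(
            f"effect {effect} drives block r to {shifted_r[effect_block]:.3g}, "
            f"outside [r0={base.r0}, 1)"
        )
    spec1 = replace(base, n_subjects=n_pairs, seed=seed)
    spec2 = replace(spec1, block_r=tuple(shifted_r))
    atlas = load_atlas(base.atlas)
    p = atlas.n_nodes

    corr1 = spec1.correlation_matrix()
    corr2 = spec2.correlation_matrix()  # target scan-2 marginal correlation
    rho2 = rho_within_subject**2
    if rho2 > 0.999:
        innov = corr2
    else:
        innov = (corr2 - rho2 * corr1) / (1.0 - rho2)
    np.fill_diagonal(innov, 1.0)
    lo = float(np.linalg.eigvalsh(innov)[0])
    if lo < -1e-10:
        raise ParameterError(
            f"effect {effect} at rho_within_subject={rho_within_subject} requires a "
            f"non-PSD innovation matrix (min eigenvalue {lo:.3g}); reduce |effect| "
            "or rho_within_subject"
        )

    rng = np.random.default_rng(seed)
    age = rng.normal(base.age_mean, base.age_sd, size=n_pairs)
    icv = rng.normal(base.icv_mean, base.icv_sd, size=n_pairs)
    chol1 = np.linalg.cholesky(corr1 + 1e-10 * np.eye(p))
    chol2 = np.linalg.cholesky(innov + 1e-10 * np.eye(p))
    z1 = rng.standard_normal((n_pairs, p)) @ chol1.T
    z2 = (
        rho_within_subject * z1
        + np.sqrt(1.0 - rho_within_subject**2) * rng.standard_normal((n_pairs, p)) @ chol2.T
    )

    def _values(z, a):
        return (
            base.roi_mean
            + base.roi_sd * z
            + base.beta_age * (a - base.age_mean)[:, None]
            + base.beta_icv * (icv - base.icv_mean)[:, None]
            + rng.normal(0.0, base.noise_sd, size=z.shape)
        )

    v1 = _values(z1, age)
    v2 = _values(z2, age + scan_interval_years)
    ids = [f"P{i:03d}_{s}" for s in ("scan1", "scan2") for i in range(n_pairs)]
    return Cohort(
        subject_ids=ids,
        values=np.vstack([v1, v2]),
        group_labels=np.asarray(["scan1"] * n_pairs + ["scan2"] * n_pairs, dtype=object),
        age=np.concatenate([age, age + scan_interval_years]),
        icv=np.concatenate([icv, icv]),
        atlas=atlas,
        measure_kind=base.measure_kind,
        pair_id=np.asarray([f"P{i:03d}" for i in range(n_pairs)] * 2, dtype=object),
    )


# ---------------------------------------------------------------------------
# Packaged fixtures


def fixture_spec(name: str, seed: int = 0, n_per_group: int | None = None):
    """Specs of the packaged fixtures: ``null_17``, ``effect_17``, ``paired_8``.

    ``null_17`` returns a (spec_a, spec_b) pair drawn from one generator with
    independent seeds; ``effect_17`` plants block r 0.7 vs 0.1;
    ``paired_8`` returns kwargs for :func:`make_paired_cohort`.
    """
    if name == "null_17":
        n = n_per_group or 40
        a = SyntheticSpec(n_subjects=n, group_label="A", block_r=0.6, r0=0.1, seed=2 * seed)
        b = replace(a, group_label="B", seed=2 * seed + 1)
        return a, b
    if name == "effect_17":
        n = n_per_group or 40
        a = SyntheticSpec(n_subjects=n, group_label="A", block_r=0.7, r0=0.05, seed=2 * seed)
        b = replace(a, group_label="B", block_r=0.1, seed=2 * seed + 1)
        return a, b
    if name == "paired_8":
        return dict(n_pairs=8, effect=-0.4, rho_within_subject=0.7, seed=seed,
                    base=SyntheticSpec(block_r=0.6, r0=0.1))
    raise ParameterError(f"unknown fixture {name!r}; have null_17, effect_17, paired_8")


def write_cohort(cohort: Cohort, outdir: str | Path, stem: str = "cohort") -> dict[str, Path]:
    """Write a cohort in the TSV formats the readers consume (round-trips)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = ROITable(
        subject_ids=list(cohort.subject_ids),
        roi_names=list(cohort.atlas.roi_names),
        values=cohort.values,
        measure_kind=cohort.measure_kind,
    )
    stats_path = outdir / f"{stem}_stats.tsv"
    cov_path = outdir / f"{stem}_covariates.tsv"
    write_stats_table(table, stats_path)
    cohort.covariate_frame().to_csv(cov_path, sep="\t", index=False, float_format="%.10g")
    return {"stats": stats_path, "covariates": cov_path}
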
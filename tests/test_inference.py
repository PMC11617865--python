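from itertools import combinations

import numpy as np
import pytest

from covnet import (
    SparsityGrid,
    edge_backbone,
    fdr_bh,
    load_atlas,
    make_paired_cohort,
    permutation_test_paired,
    permutation_test_unpaired,
)
from covnet.exceptions import DesignError, ValidationError
from covnet.inference import group_auc_statistics
from covnet.io import Cohort
from covnet.network import CovarianceMatrix
from covnet.preprocess import residuals_ols
from covnet.synthetic import SyntheticSpec, fixture_spec, generate_cohort

DET_PROPS = ["Cp", "Lp", "Eglob"]  # deterministic statistics (no inner nulls)


def _tiny_cohort(values, label, atlas, start=0):
    n = values.shape[0]
    return Cohort(
        subject_ids=[f"{label}{start + i}" for i in range(n)],
        values=values,
        group_labels=np.array([label] * n, dtype=object),
        age=np.linspace(55, 65, n),
        icv=1.4e6 + 1e4 * np.linspace(-1, 1, n) ** 2,
        atlas=atlas,
    )


class TestFDR:
    def test_empty_input(self):
        adj, rej = fdr_bh([])
        assert adj.size == 0 and rej.size == 0

    def test_uniformly_small_all_rejected(self):
        adj, rej = fdr_bh([0.001] * 10, q=0.05)
        assert rej.all()
        np.testing.assert_allclose(adj, 0.001)

    def test_hand_computed_step_up(self):
        adj, _ = fdr_bh([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.02])

    def test_adjusted_monotone_in_raw_ranks(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.5, 1.5])


class TestEdgeBackbone:
    def _cov(self, r01, n):
        from covnet.atlases import AtlasSpec

        atlas = AtlasSpec(name="toy3", roi_names=("a", "b", "c"))
        r = np.zeros((3, 3))
        r[0, 1] = r[1, 0] = r01
        return CovarianceMatrix(r=r, n_subjects=n, atlas=atlas)

    def test_zero_correlation_never_retained(self):
        assert not edge_backbone(self._cov(0.0, 100)).any()

    def test_strong_correlation_retained(self):
        # r=0.9, n=40: t = 0.9*sqrt(38/0.19) ~ 12.7, p << 0.001
        from scipy import stats

        t = 0.9 * np.sqrt(38 / (1 - 0.81))
        assert 2 * stats.t.sf(t, df=38) < 1e-3
        mask = edge_backbone(self._cov(0.9, 40), alpha=0.001)
        assert mask[0, 1] and mask[1, 0]

    def test_perfect_correlation_retained(self):
        assert edge_backbone(self._cov(1.0, 10))[0, 1]

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        from covnet.atlases import AtlasSpec

        atlas = AtlasSpec(name="toy8", roi_names=tuple(f"r{i}" for i in range(8)))
        r = np.abs(rng.random((8, 8))) * 0.8
        r = np.triu(r, 1)
        r = r + r.T
        cov = CovarianceMatrix(r=r, n_subjects=30, atlas=atlas)
        loose = edge_backbone(cov, alpha=0.05)
        strict = edge_backbone(cov, alpha=0.001)
        assert np.all(loose[strict])


class TestUnpairedPermutation:
    def test_exhaustive_2plus2_matches_enumeration(self, subcortical17):
        rng = np.random.default_rng(21)
        values = rng.random((4, 17)) + 5.0
        a = _tiny_cohort(values[:2], "A", subcortical17)
        b = _tiny_cohort(values[2:], "B", subcortical17)
        grid = SparsityGrid(0.1, 0.3, 0.1)
        res = permutation_test_unpaired(a, b, grid=grid, properties=DET_PROPS,
                                        n_perm=500, covariates=(), seed=0)
        assert res[0].exhaustive and res[0].n_perm == 6

        # independent enumeration over all 6 relabelings of the pooled rows
        pooled = np.vstack([values[:2], values[2:]])
        resid = residuals_ols(pooled, np.ones((4, 1)))

        def stat(idx):
            s_a = group_auc_statistics(resid[list(idx)], grid, DET_PROPS, 0, 10, 0)
            rest = [i for i in range(4) if i not in idx]
            s_b = group_auc_statistics(resid[rest], grid, DET_PROPS, 0, 10, 0)
            return {p: s_a[p] - s_b[p] for p in DET_PROPS}

        observed = stat((0, 1))
        for p in DET_PROPS:
            null = [abs(stat(c)[p]) for c in combinations(range(4), 2)]
            expected = np.mean([x >= abs(observed[p]) - 1e-12 for x in null])
            assert res[p, "global"].p_raw == pytest.approx(expected)
            assert res[p, "global"].observed_diff == pytest.approx(observed[p])

    def test_swapping_groups_negates_diff_keeps_p(self, small_cohorts):
        a, b = small_cohorts
        grid = SparsityGrid(0.15, 0.3, 0.05)
        kw = dict(grid=grid, properties=DET_PROPS, n_perm=99, seed=5)
        r_ab = permutation_test_unpaired(a, b, **kw)
        r_ba = permutation_test_unpaired(b, a, **kw)
        for p in DET_PROPS:
            assert r_ab[p, "global"].observed_diff == pytest.approx(
                -r_ba[p, "global"].observed_diff)
            assert r_ab[p, "global"].p_raw == pytest.approx(r_ba[p, "global"].p_raw)

    def test_planted_extreme_difference_hits_p_floor(self):
        # strong planted covariance loss: observed beats every sampled null
        spec_a, spec_b = fixture_spec("effect_17", seed=3, n_per_group=40)
        res = permutation_test_unpaired(
            generate_cohort(spec_a), generate_cohort(spec_b),
            grid=SparsityGrid(0.1, 0.3, 0.05), properties=["Cp"],
            n_perm=199, seed=0, method="monte-carlo")
        r = res["Cp", "global"]
        assert np.abs(r.null_diffs).max() < abs(r.observed_diff)
        assert r.p_raw == pytest.approx(1 / 200)

    def test_deterministic_and_njobs_invariant(self, small_cohorts):
        a, b = small_cohorts
        kw = dict(grid=SparsityGrid(0.15, 0.25, 0.05), properties=["Cp", "sigma"],
                  n_perm=30, n_null_inner=20, seed=9)
        r1 = permutation_test_unpaired(a, b, **kw)
        r2 = permutation_test_unpaired(a, b, **kw)
        r4 = permutation_test_unpaired(a, b, n_jobs=2, **kw)
        for x, y in ((r1, r2), (r1, r4)):
            for rx, ry in zip(x, y):
                assert rx.observed_diff == ry.observed_diff
                np.testing.assert_array_equal(rx.null_diffs, ry.null_diffs)

    def test_overlapping_subjects_rejected(self, small_cohorts):
        a, _ = small_cohorts
        with pytest.raises(Exception, match="overlapping"):
            permutation_test_unpaired(a, a, n_perm=10)

    def test_nodal_properties_carry_fdr(self, small_cohorts):
        a, b = small_cohorts
        res = permutation_test_unpaired(a, b, grid=SparsityGrid(0.2, 0.3, 0.05),
                                        properties=["degree"], n_perm=49, seed=2)
        df = res.to_frame()
        assert len(df) == 17
        assert set(df["node"]) == set(a.atlas.roi_names)
        assert (df["p_fdr"] >= df["p_raw"] - 1e-12).all()
        assert (df["p_raw"] >= 1 / 50 - 1e-12).all()


class TestPairedPermutation:
    def test_identical_scans_give_zero_diff_p_one(self, subcortical17):
        rng = np.random.default_rng(8)
        scan = rng.random((6, 17)) + 3.0
        cohort = Cohort(
            subject_ids=[f"p{i}_{s}" for s in ("s1", "s2") for i in range(6)],
            values=np.vstack([scan, scan]),
            group_labels=np.array(["s1"] * 6 + ["s2"] * 6, dtype=object),
            age=np.tile(np.linspace(55, 65, 6), 2),
            icv=np.tile(1.4e6 + 1e5 * rng.standard_normal(6), 2),
            atlas=subcortical17,
            pair_id=np.array([f"p{i}" for i in range(6)] * 2, dtype=object),
        )
        res = permutation_test_paired(cohort, "s1", "s2",
                                      grid=SparsityGrid(0.1, 0.3, 0.1),
                                      properties=DET_PROPS, n_perm=100, seed=0)
        for p in DET_PROPS:
            assert res[p, "global"].observed_diff == 0.0
            assert res[p, "global"].p_raw == 1.0
            assert res[p, "global"].exhaustive

    def test_eight_pairs_use_exhaustive_256(self):
        cohort = make_paired_cohort(**fixture_spec("paired_8", seed=1))
        res = permutation_test_paired(cohort, "scan1", "scan2",
                                      grid=SparsityGrid(0.15, 0.3, 0.05),
                                      properties=["Cp"], n_perm=5000, seed=0)
        assert res[0].exhaustive
        assert res[0].n_perm == 256
        assert len(res[0].null_diffs) == 256

    def test_incomplete_pair_named(self, subcortical17):
        rng = np.random.default_rng(4)
        cohort = Cohort(
            subject_ids=["x1", "x2", "y1", "y2"],
            values=rng.random((4, 17)),
            group_labels=np.array(["s1", "s2", "s1", "s1"], dtype=object),
            age=np.array([60.0, 60.3, 61.0, 61.3]),
            icv=np.full(4, 1.4e6),
            atlas=subcortical17,
            pair_id=np.array(["px", "px", "py", "py"], dtype=object),
        )
        with pytest.raises(DesignError, match="py"):
            permutation_test_paired(cohort, "s1", "s2", n_perm=16,
                                    properties=["Cp"], covariates=())

    def test_planted_scan2_covariance_loss_detected_in_sign(self):
        """Destroying one block's covariance at scan 2 lowers its clustering:
        the observed Cp-AUC difference (scan1 - scan2) is positive well above
        chance across seeded replicates."""
        grid = SparsityGrid(0.1, 0.3, 0.05)
        base = SyntheticSpec(block_r=0.6, r0=0.1)
        signs = 0
        for s in range(20):
            cohort = make_paired_cohort(n_pairs=15, effect=-0.45,
                                        rho_within_subject=0.5, seed=s,
                                        base=base, effect_block=0)
            res = permutation_test_paired(cohort, "scan1", "scan2", grid=grid,
                                          properties=["Cp"], n_perm=128, seed=s,
                                          method="monte-carlo")
            signs += res["Cp", "global"].observed_diff > 0
        assert signs >= 14  # chance level would be ~10/20

    def test_monte_carlo_agrees_with_enumeration(self):
        cohort = make_paired_cohort(**fixture_spec("paired_8", seed=2))
        grid = SparsityGrid(0.15, 0.3, 0.05)
        exact = permutation_test_paired(cohort, "scan1", "scan2", grid=grid,
                                        properties=DET_PROPS, n_perm=5000, seed=0)
        sampled = permutation_test_paired(cohort, "scan1", "scan2", grid=grid,
                                          properties=DET_PROPS, n_perm=5000, seed=0,
                                          method="monte-carlo")
        for p in DET_PROPS:
            assert abs(exact[p, "global"].p_raw - sampled[p, "global"].p_raw) < 0.02
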
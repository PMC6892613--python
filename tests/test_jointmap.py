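import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rrqtl import jointmap, scan
from rrqtl.genotypes import GenotypeMatrix, KinshipMatrix, gower_rescale
from rrqtl.jointmap import (estimate_effects_per_cross, joint_forward_stepwise,
                            joint_permutation_null, joint_t_scan, loco_kinships,
                            residualize_loco, unbiased_effects)
from rrqtl.pipeline import simulate_experiment
from conftest import std


@pytest.fixture(scope="module")
def joint_exp():
    """Four crosses x 150 segregants with planted QTL."""
    return simulate_experiment(
        n_strains=64, n_markers=400, n_chroms=4, n_parents=4, n_progeny=150,
        n_qtl=4, h2_additive=0.5, repeatability=1.0, n_replicates=1,
        seed_panel=41, seed_meiosis=42, seed_effects=43, seed_phenotypes=44,
    )


class TestPooledT:
    def test_t_from_r_arithmetic(self):
        r, n = 0.5, 102
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        assert np.isclose(t, 5.7735, atol=1e-4)

    def test_zero_correlation_zero_t(self, joint_exp):
        G = joint_exp.G
        s = np.zeros(G.n_segregants)
        s[: len(s) // 2] = 1.0
        s[len(s) // 2:] = -1.0
        res = joint_t_scan(std(s), G)
        assert np.all(np.isfinite(res.t))

    def test_private_variant_t_matches_single_cross_regression(self, joint_exp):
        G = joint_exp.G
        cross = np.asarray(G.cross)
        cids = pd.unique(cross)
        # force a marker to be informative in exactly one cross
        shared = np.flatnonzero(~np.isnan(G.values).any(axis=0))
        j = int(shared[0])
        c = cids[0]
        vals = G.values.copy()
        vals[cross != c, j] = np.nan
        G2 = GenotypeMatrix(values=vals, segregants=G.segregants, cross=G.cross,
                            markers=G.markers)
        rng = np.random.default_rng(1)
        s = std(rng.standard_normal(G.n_segregants))
        res = joint_t_scan(s, G2, marker_subset=np.array([j]))
        rows = cross == c
        slope, inter, r, p, se = stats.linregress(vals[rows, j], s[rows])
        t_oracle = slope / se
        assert abs(res.t[0] - t_oracle) < 1e-10
        assert res.n_informative[0] == rows.sum()

    def test_fully_shared_variant_equals_concatenated_regression(self, joint_exp):
        G = joint_exp.G
        shared = np.flatnonzero(~np.isnan(G.values).any(axis=0))
        assert len(shared)
        j = int(shared[0])
        rng = np.random.default_rng(2)
        s = std(rng.standard_normal(G.n_segregants))
        res = joint_t_scan(s, G, marker_subset=np.array([j]))
        slope, inter, r, p, se = stats.linregress(G.values[:, j], s)
        assert abs(res.t[0] - slope / se) < 1e-10

    def test_low_informative_markers_skipped(self, joint_exp):
        G = joint_exp.G
        vals = G.values.copy()
        vals[5:, 0] = np.nan
        vals[:5, 0] = [-1, 1, -1, 1, -1]
        G2 = GenotypeMatrix(values=vals, segregants=G.segregants, cross=G.cross,
                            markers=G.markers)
        s = std(np.random.default_rng(3).standard_normal(G.n_segregants))
        with pytest.warns(UserWarning, match="skipped"):
            res = joint_t_scan(s, G2)
        assert not res.valid[0] and res.neglog10p[0] == 0.0


class TestPermutationNull:
    def test_within_cross_permutation_invariant_to_cross_shifts(self, joint_exp):
        G = joint_exp.G
        cross = np.asarray(G.cross)
        rng = np.random.default_rng(4)
        s = rng.standard_normal(G.n_segregants)
        shift = s.copy()
        for i, c in enumerate(pd.unique(cross)):
            shift[cross == c] += 5.0 * i
        centered = shift.copy()
        for c in pd.unique(cross):
            centered[cross == c] -= centered[cross == c].mean()
        a = joint_permutation_null(shift, cross, G, B=30, seed=9)
        b = joint_permutation_null(centered, cross, G, B=30, seed=9)
        np.testing.assert_allclose(a.max_stats, b.max_stats, atol=1e-9)

    def test_same_seed_identical(self, joint_exp):
        G = joint_exp.G
        s = np.random.default_rng(5).standard_normal(G.n_segregants)
        a = joint_permutation_null(s, G.cross, G, B=20, seed=11)
        b = joint_permutation_null(s, G.cross, G, B=20, seed=11)
        assert np.array_equal(a.max_stats, b.max_stats)

    def test_floor_when_observed_beats_all(self, joint_exp):
        G = joint_exp.G
        shared = np.flatnonzero(~np.isnan(G.values).any(axis=0))
        j = int(shared[1])
        s = std(G.values[:, j] + 0.01 * np.random.default_rng(6)
                .standard_normal(G.n_segregants))
        null = joint_permutation_null(s, G.cross, G, B=100, seed=12)
        res = joint_t_scan(s, G)
        p = scan.empirical_pvalue(res.best_stat, null)
        assert p == 1.0 / 100


class TestSingleCrossReduction:
    def test_matches_within_cross_pipeline(self):
        exp = simulate_experiment(
            n_strains=32, n_markers=300, n_chroms=3, n_parents=3, n_progeny=150,
            n_qtl=2, h2_additive=0.6, repeatability=1.0, n_replicates=1,
            seed_panel=51, seed_meiosis=52, seed_effects=53, seed_phenotypes=54)
        cid = exp.design.cross_ids[0]
        Gc = exp.G.subset_cross(cid)
        y = exp.y_by_cross()[cid]
        y_std = std(y)
        seg = np.flatnonzero(~np.all(np.isnan(Gc.values), axis=0))
        Gc_seg = GenotypeMatrix(values=Gc.values[:, seg],
                                segregants=Gc.segregants,
                                cross=Gc.cross,
                                markers=Gc.markers.iloc[seg].reset_index(drop=True))
        within = scan.forward_stepwise(y_std, Gc_seg, alpha=0.05, B=200, seed=77)
        joint = joint_forward_stepwise({cid: y}, Gc_seg, alpha=0.05, B=200,
                                       seed=77, use_loco=False)
        assert [q.marker_index for q in joint] == within.selected

    def test_joint_qtl_records_pvalues_match_within(self):
        exp = simulate_experiment(
            n_strains=32, n_markers=200, n_chroms=2, n_parents=3, n_progeny=120,
            n_qtl=1, h2_additive=0.5, repeatability=1.0, n_replicates=1,
            seed_panel=61, seed_meiosis=62, seed_effects=63, seed_phenotypes=64)
        cid = exp.design.cross_ids[0]
        Gc = exp.G.subset_cross(cid)
        y = exp.y_by_cross()[cid]
        seg = np.flatnonzero(~np.all(np.isnan(Gc.values), axis=0))
        Gc_seg = GenotypeMatrix(values=Gc.values[:, seg], segregants=Gc.segregants,
                                cross=Gc.cross,
                                markers=Gc.markers.iloc[seg].reset_index(drop=True))
        within = scan.forward_stepwise(std(y), Gc_seg, alpha=0.05, B=150, seed=5)
        joint = joint_forward_stepwise({cid: y}, Gc_seg, alpha=0.05, B=150,
                                       seed=5, use_loco=False)
        for q, (_, row) in zip(joint, within.steps.iterrows()):
            assert q.pvalue == row["p"]


class TestResidualizeLoco:
    def test_no_covariates_no_kinship_returns_centered(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        s = residualize_loco(y, None, None)
        np.testing.assert_allclose(s, y - y.mean())

    def test_blup_matches_mixed_model_equations_oracle(self, rng):
        n = 30
        M = rng.standard_normal((n, 50))
        M = (M - M.mean(0)) / M.std(0)
        K = KinshipMatrix(values=gower_rescale(M @ M.T), normalization="gower")
        L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
        y = L @ rng.standard_normal(n) + 0.5 * rng.standard_normal(n)
        sg, se_ = 0.7, 0.3
        s = residualize_loco(y, None, K, sigma2=(sg, se_))
        # Henderson MME oracle: [X'X/se  X'Z/se; Z'X/se  Z'Z/se + Kinv/sg]
        X = np.ones((n, 1))
        Kinv = np.linalg.inv(K.values + 1e-10 * np.eye(n))
        top = np.hstack([X.T @ X / se_, X.T / se_])
        bot = np.hstack([X / se_, np.eye(n) / se_ + Kinv / sg])
        lhs = np.vstack([top, bot])
        rhs = np.concatenate([X.T @ y / se_, y / se_])
        sol = np.linalg.solve(lhs, rhs)
        beta_hat, u_hat = sol[0], sol[1:]
        np.testing.assert_allclose(s, y - beta_hat - u_hat, atol=1e-6)

    def test_off_chromosome_qtl_signal_removed(self, joint_exp):
        G = joint_exp.G
        cid = pd.unique(np.asarray(G.cross))[0]
        Gc = G.subset_cross(cid)
        seg = np.flatnonzero(~np.all(np.isnan(Gc.values), axis=0))
        j = int(seg[0])
        rng = np.random.default_rng(8)
        g = std(Gc.values[:, j])
        y = 0.8 * g + 0.6 * rng.standard_normal(Gc.n_segregants)
        s = residualize_loco(y, Gc.values[:, [j]], None)
        assert abs(np.corrcoef(s, g)[0, 1]) < 0.05

    def test_on_chromosome_covariates_rejected(self):
        # guarded at the pipeline level: LOCO kinships exclude the chromosome
        ks = None
        with pytest.raises(ValueError):
            loco_kinships(GenotypeMatrix(
                values=np.array([[1.0, -1.0], [-1.0, 1.0]]),
                segregants=["a", "b"], cross=np.array(["c", "c"]),
                markers=pd.DataFrame({"chrom": ["chr01", "chr01"],
                                      "pos_bp": [1, 2], "pos_cM": [0.0, 1.0],
                                      "id": ["m0", "m1"]})))


class TestEffects:
    def test_noiseless_effect_recovered_exactly(self, joint_exp):
        G = joint_exp.G
        cross = np.asarray(G.cross)
        cids = list(pd.unique(cross))
        shared = np.flatnonzero(~np.isnan(G.values).any(axis=0))
        j = int(shared[2])
        qtl = jointmap.JointQTL(trait="t", marker_index=j,
                                marker=str(G.markers["id"].iloc[j]),
                                chrom="x", pos_bp=0, pooled_t=0.0,
                                n_informative=0, pvalue=0.1, forwardstop=0.0,
                                per_cross_beta={}, mean_beta=np.nan,
                                panel_maf=0.1)
        rng = np.random.default_rng(12)
        y_by_cross = {}
        for c in cids:
            rows = cross == c
            g = std(G.values[rows, j])
            e = rng.standard_normal(rows.sum())
            # orthogonalize noise against [1, g] and scale: sample var(y) = 1
            e = e - e.mean() - g * (e @ g) / (g @ g)
            e *= np.sqrt(1 - 0.3**2) / e.std()
            y_by_cross[c] = 0.3 * g + e
        out = estimate_effects_per_cross(y_by_cross, G, [qtl])[0]
        for c, beta in out.per_cross_beta.items():
            g_raw = G.values[cross == c, j]
            assert np.isclose(beta * g_raw.std(), 0.3, atol=1e-10)
        # balanced crosses: sd(genotype) ~ 1, mean beta ~ 0.3
        assert abs(out.mean_beta - 0.3) < 0.01

    def test_non_segregating_cross_absent_from_effect_map(self, joint_exp):
        G = joint_exp.G
        cross = np.asarray(G.cross)
        cids = pd.unique(cross)
        seg_by_cross = {c: ~np.all(np.isnan(G.values[cross == c]), axis=0)
                        for c in cids}
        counts = np.sum(list(seg_by_cross.values()), axis=0)
        j = int(np.flatnonzero(counts == 2)[0])
        qtl = jointmap.JointQTL(trait="t", marker_index=j, marker="m",
                                chrom="x", pos_bp=0, pooled_t=0.0,
                                n_informative=0, pvalue=0.1, forwardstop=0.0,
                                per_cross_beta={}, mean_beta=np.nan,
                                panel_maf=0.1)
        rng = np.random.default_rng(9)
        y_by_cross = {c: rng.standard_normal((cross == c).sum()) for c in cids}
        out = estimate_effects_per_cross(y_by_cross, G, [qtl])[0]
        expected = {c for c in cids if seg_by_cross[c][j]}
        assert set(out.per_cross_beta) == expected

    def test_two_cross_mean_effect_is_average(self, joint_exp):
        G = joint_exp.G
        cross = np.asarray(G.cross)
        cids = list(pd.unique(cross))
        shared = np.flatnonzero(~np.isnan(G.values).any(axis=0))
        j = int(shared[3])
        qtl = jointmap.JointQTL(trait="t", marker_index=j, marker="m",
                                chrom="x", pos_bp=0, pooled_t=0.0,
                                n_informative=0, pvalue=0.1, forwardstop=0.0,
                                per_cross_beta={}, mean_beta=np.nan,
                                panel_maf=0.1)
        rng = np.random.default_rng(10)
        true = {c: b for c, b in zip(cids, [0.2, 0.4, 0.2, 0.4])}
        y_by_cross = {}
        for c in cids:
            rows = cross == c
            g = std(G.values[rows, j])
            e = rng.standard_normal(rows.sum())
            e = e - e.mean() - g * (e @ g) / (g @ g)
            e *= np.sqrt(1 - true[c]**2) / e.std()
            y_by_cross[c] = true[c] * g + e
        out = estimate_effects_per_cross(y_by_cross, G, [qtl])[0]
        assert abs(out.mean_beta - np.mean(list(true.values()))) < 0.05


class TestUnbiasedEffects:
    def test_noiseless_heldout_equals_insample(self):
        exp = simulate_experiment(
            n_strains=32, n_markers=200, n_chroms=2, n_parents=3, n_progeny=200,
            n_qtl=1, h2_additive=0.9, repeatability=1.0, n_replicates=1,
            seed_panel=71, seed_meiosis=72, seed_effects=73, seed_phenotypes=74)
        df = unbiased_effects(exp.y_by_cross(), exp.G, B=100, seed=3)
        if len(df) == 0:
            pytest.skip("no detection on this draw")
        assert np.all(np.abs(df["beta_insample"].abs()
                             - df["beta_heldout"].abs()) < 0.25)

    def test_null_trait_returns_empty(self, joint_exp):
        G = joint_exp.G
        rng = np.random.default_rng(13)
        y_by_cross = {c: rng.standard_normal((np.asarray(G.cross) == c).sum())
                      for c in pd.unique(np.asarray(G.cross))}
        df = unbiased_effects(y_by_cross, G, B=100, seed=4)
        assert len(df) == 0 or (df["beta_heldout"].abs() < 0.5).all()
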
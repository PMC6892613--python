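import numpy as np
import pandas as pd
import pytest

from rrqtl import finemap
from rrqtl.finemap import (aggregate_to_genes, combine_cross_pair,
                           find_overlapping_qtl, gene_fdr, pics_window,
                           PICSWindow)
from rrqtl.genotypes import GenotypeMatrix
from conftest import std


def _window_matrix(n=200, m=12, seed=0, chrom="chr01"):
    """A dense single-cross genotype window with LD between neighbours."""
    rng = np.random.default_rng(seed)
    base = rng.choice([-1.0, 1.0], size=n)
    cols = [base]
    for j in range(1, m):
        col = cols[-1].copy()
        flip = rng.random(n) < 0.2
        col[flip] = rng.choice([-1.0, 1.0], size=flip.sum())
        cols.append(col)
    vals = np.column_stack(cols)
    markers = pd.DataFrame({
        "chrom": [chrom] * m,
        "pos_bp": np.arange(m) * 2000 + 1000,
        "pos_cM": np.arange(m, dtype=float),
        "id": [f"{chrom}_v{j}" for j in range(m)],
    })
    return GenotypeMatrix(values=vals, segregants=[f"s{i}" for i in range(n)],
                          cross=np.array(["c1"] * n), markers=markers)


def _mk_window(ids, ppc, cross="c1", peak=None):
    return PICSWindow(trait="t", cross=cross, peak_marker=peak or ids[0],
                      effect=0.3, marker_ids=list(ids),
                      ppc=np.asarray(ppc, float), n_sims=10, seed=0)


class TestPicsWindow:
    def test_single_variant_window_gets_full_mass(self):
        G = _window_matrix(m=1)
        rng = np.random.default_rng(1)
        resid = rng.standard_normal(G.n_segregants)
        w = pics_window(None, G, 0, 0.3, resid, n_sims=20, seed=2)
        np.testing.assert_allclose(w.ppc, [1.0])

    def test_perfect_ld_duplicates_split_mass_equally(self):
        G = _window_matrix(m=6, seed=3)
        vals = G.values.copy()
        vals[:, 3] = vals[:, 2]           # identical twin of the peak
        G2 = GenotypeMatrix(values=vals, segregants=G.segregants, cross=G.cross,
                            markers=G.markers)
        resid = np.random.default_rng(4).standard_normal(G.n_segregants)
        w = pics_window(None, G2, 2, 0.4, resid, n_sims=50, seed=5)
        assert np.isclose(w.ppc[2], w.ppc[3], atol=1e-12)

    def test_ppc_sums_to_one(self):
        G = _window_matrix(m=10, seed=6)
        resid = np.random.default_rng(7).standard_normal(G.n_segregants)
        w = pics_window(None, G, 4, 0.35, resid, n_sims=40, seed=8)
        assert np.isclose(w.ppc.sum(), 1.0, atol=1e-12)
        assert np.all(w.ppc >= 0)

    def test_zero_residual_variance_degenerate_flag(self):
        G = _window_matrix(m=5, seed=9)
        with pytest.warns(UserWarning, match="degenerate"):
            w = pics_window(None, G, 1, 0.3, np.zeros(G.n_segregants),
                            n_sims=10, seed=10)
        assert w.degenerate and np.isclose(w.ppc.sum(), 1.0)

    def test_window_limited_to_50kb(self):
        G = _window_matrix(m=12)
        mk = G.markers.copy()
        mk["pos_bp"] = np.arange(12) * 10_000 + 1   # 0..110 kb span
        G2 = GenotypeMatrix(values=G.values, segregants=G.segregants,
                            cross=G.cross, markers=mk)
        resid = np.random.default_rng(11).standard_normal(G.n_segregants)
        w = pics_window(None, G2, 6, 0.3, resid, n_sims=10, seed=12)
        # peak at 60001 bp: window [35001, 85001] holds markers 4..8
        assert len(w.marker_ids) == 5

    def test_strong_planted_variant_attains_max_ppc(self):
        G = _window_matrix(n=400, m=8, seed=13)
        rng = np.random.default_rng(14)
        causal = 3
        g = std(G.values[:, causal])
        y = 0.5 * g + np.sqrt(1 - 0.25) * rng.standard_normal(G.n_segregants)
        resid = y - g * (y @ g) / (g @ g)
        w = pics_window(y, G, causal, 0.5, resid, n_sims=100, seed=15)
        assert w.ppc[causal] == w.ppc.max()


class TestOverlap:
    def _qtls(self):
        return pd.DataFrame({
            "trait": ["t", "t", "t", "t"],
            "cross": ["c1", "c2", "c3", "c2"],
            "chrom": ["chr01"] * 4,
            "effect": [0.3, 0.25, 0.3, -0.2],
            "ci_left_bp": [1000, 1500, 1500, 1500],
            "ci_right_bp": [2000, 2500, 2500, 2500],
        })

    def test_qualifying_pair_found(self):
        pairs = find_overlapping_qtl(self._qtls(), [("c1", "c2")])
        assert (0, 1) in pairs

    def test_no_shared_parent_not_paired(self):
        pairs = find_overlapping_qtl(self._qtls(), [("c1", "c2")])
        assert all(2 not in p for p in pairs)

    def test_opposite_signs_not_paired(self):
        pairs = find_overlapping_qtl(self._qtls(), [("c1", "c2")])
        assert (0, 3) not in pairs

    def test_disjoint_by_one_bp_not_paired(self):
        q = self._qtls()
        q.loc[1, "ci_left_bp"] = 2001      # 1 bp past the end of QTL 0
        assert (0, 1) not in find_overlapping_qtl(q, [("c1", "c2")])
        q.loc[1, "ci_left_bp"] = 2000      # closed-interval touch counts
        assert (0, 1) in find_overlapping_qtl(q, [("c1", "c2")])


class TestCombine:
    def test_uniform_windows_stay_uniform(self):
        ids = ["v1", "v2", "v3", "v4"]
        w1 = _mk_window(ids, [0.25] * 4)
        w2 = _mk_window(ids, [0.25] * 4, cross="c2")
        comb = combine_cross_pair(w1, w2)
        np.testing.assert_allclose(comb.to_numpy(), 0.25)

    def test_product_then_renormalize(self):
        w1 = _mk_window(["a", "b"], [0.8, 0.2])
        w2 = _mk_window(["a", "b"], [0.5, 0.5], cross="c2")
        comb = combine_cross_pair(w1, w2)
        np.testing.assert_allclose(comb.to_numpy(), [0.8, 0.2])

    def test_zero_probability_stays_zero(self):
        w1 = _mk_window(["a", "b", "c"], [0.0, 0.5, 0.5])
        w2 = _mk_window(["a", "b", "c"], [0.4, 0.3, 0.3], cross="c2")
        comb = combine_cross_pair(w1, w2)
        assert comb["a"] == 0.0

    def test_empty_shared_set_dropped(self):
        w1 = _mk_window(["a", "b"], [0.5, 0.5])
        w2 = _mk_window(["c", "d"], [0.5, 0.5], cross="c2")
        with pytest.warns(UserWarning, match="no shared"):
            assert combine_cross_pair(w1, w2) is None

    def test_only_shared_variants_used(self):
        w1 = _mk_window(["a", "b", "x"], [0.4, 0.4, 0.2])
        w2 = _mk_window(["a", "b", "y"], [0.3, 0.6, 0.1], cross="c2")
        comb = combine_cross_pair(w1, w2)
        assert set(comb.index) == {"a", "b"}
        np.testing.assert_allclose(comb.sum(), 1.0)


class TestGenes:
    def _genes(self):
        return pd.DataFrame({
            "gene": ["g1", "g2", "g3"],
            "chrom": ["chr01"] * 3,
            "start_bp": [1000, 5000, 9000],
            "end_bp": [2000, 6000, 10000],
        })

    def _markers(self, pos):
        return pd.DataFrame({
            "chrom": ["chr01"] * len(pos),
            "pos_bp": pos,
            "pos_cM": np.arange(len(pos), dtype=float),
            "id": [f"v{i}" for i in range(len(pos))],
        })

    def test_mass_inside_single_orf(self):
        mk = self._markers([1100, 1500, 1900])
        combined = pd.Series([0.2, 0.5, 0.3], index=mk["id"])
        out = aggregate_to_genes(combined, mk, self._genes())
        assert out.set_index("gene")["ppc_gene"]["g1"] == pytest.approx(1.0)

    def test_midway_variant_goes_to_left_gene(self):
        # midpoint between g1 (end 2000) and g2 (start 5000) is 3500
        mk = self._markers([3500, 3501])
        combined = pd.Series([0.6, 0.4], index=mk["id"])
        out = aggregate_to_genes(combined, mk, self._genes()).set_index("gene")
        assert out["ppc_gene"]["g1"] == pytest.approx(0.6)
        assert out["ppc_gene"]["g2"] == pytest.approx(0.4)

    def test_three_gene_split_matches_interval_oracle(self):
        pos = [1500, 3000, 5500, 7600, 9500]
        probs = [0.3, 0.4, 0.1, 0.1, 0.1]
        mk = self._markers(pos)
        combined = pd.Series(probs, index=mk["id"])
        out = aggregate_to_genes(combined, mk, self._genes()).set_index("gene")
        # independent oracle: brute-force territory assignment per variant
        genes = self._genes()
        oracle = {g: 0.0 for g in genes["gene"]}
        b12 = (2000 + 5000) / 2
        b23 = (6000 + 9000) / 2
        for p, pr in zip(pos, probs):
            if p <= b12:
                oracle["g1"] += pr
            elif p <= b23:
                oracle["g2"] += pr
            else:
                oracle["g3"] += pr
        for g, v in oracle.items():
            got = out["ppc_gene"].get(g, 0.0)
            assert got == pytest.approx(v)

    def test_terminal_genes_take_chromosome_ends(self):
        mk = self._markers([10, 99_999])
        combined = pd.Series([0.5, 0.5], index=mk["id"])
        out = aggregate_to_genes(combined, mk, self._genes()).set_index("gene")
        assert out["ppc_gene"]["g1"] == pytest.approx(0.5)
        assert out["ppc_gene"]["g3"] == pytest.approx(0.5)

    def test_unannotated_chromosome_raises(self):
        mk = self._markers([1500])
        mk["chrom"] = "chr09"
        combined = pd.Series([1.0], index=mk["id"])
        with pytest.raises(ValueError, match="chr09"):
            aggregate_to_genes(combined, mk, self._genes())


class TestGeneFdr:
    def test_single_certain_gene_has_zero_fdr(self):
        out = gene_fdr(pd.DataFrame({"gene": ["g"], "ppc_gene": [1.0]}))
        assert out["fdr"].iloc[0] == 0.0

    def test_cumulative_mean_of_peps(self):
        out = gene_fdr(pd.DataFrame({"gene": ["a", "b", "c"],
                                     "ppc_gene": [0.5, 1.0, 0.8]}))
        np.testing.assert_allclose(out["ppc_gene"], [1.0, 0.8, 0.5])
        np.testing.assert_allclose(out["fdr"], [0.0, 0.1, 0.7 / 3])

    def test_fdr_non_decreasing(self, rng):
        scores = pd.DataFrame({"gene": [f"g{i}" for i in range(50)],
                               "ppc_gene": rng.uniform(0, 1, 50)})
        out = gene_fdr(scores)
        assert (np.diff(out["fdr"]) >= -1e-12).all()


def test_ppc_permutation_equivariance():
    """Reordering window variants permutes the posterior conformably."""
    G = _window_matrix(m=7, seed=20)
    resid = np.random.default_rng(21).standard_normal(G.n_segregants)
    w = pics_window(None, G, 3, 0.4, resid, n_sims=60, seed=22)
    perm = [6, 5, 4, 3, 2, 1, 0]
    mk = G.markers.iloc[perm].reset_index(drop=True)
    # positions must stay sorted for the window logic; rebuild with same ids
    mk["pos_bp"] = G.markers["pos_bp"].to_numpy()
    mk["pos_cM"] = G.markers["pos_cM"].to_numpy()
    Gp = GenotypeMatrix(values=G.values[:, perm], segregants=G.segregants,
                        cross=G.cross, markers=mk)
    wp = pics_window(None, Gp, 3, 0.4, resid, n_sims=60, seed=22)
    assert dict(zip(wp.marker_ids, np.round(wp.ppc, 12))) == \
        dict(zip(w.marker_ids, np.round(w.ppc, 12)))
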
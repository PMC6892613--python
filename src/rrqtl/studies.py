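"""Operating-characteristic studies of the mapping and estimation stack.

Each function here runs a self-contained simulation study at desk scale —
false-discovery control of the stepwise scan on null traits, detection power
and winner's-curse-free effect estimation for planted QTL, REML recovery and
standard-error calibration, rare/common variance-partition recovery,
joint-versus-within-cross mapping equivalences, PICS localization and
gene-level FDR, and recovery of frequency-coupled architectures — and
returns the measured quantities as a plain dict.  They are used by the test
suite and by the reproduction script; all randomness flows from the ``seed``
argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import finemap, genotypes, jointmap, popgen, scan, simdata, vc
from .genotypes import GenotypeMatrix, gower_rescale

__all__ = [
    "fully_segregating_cross",
    "null_fdr_study",
    "power_and_winners_curse_study",
    "reml_recovery_study",
    "partition_recovery_study",
    "joint_equivalence_study",
    "pics_study",
    "frequency_effect_study",
]


def fully_segregating_cross(n: int, m: int, n_chroms: int = 10,
                            chrom_cM: float = 50.0, seed: int = 0,
                            chrom_bp: int = 500_000,
                            meiosis_seed: int | None = None) -> GenotypeMatrix:
    """One cross in which every marker segregates (complementary parents).

    Recombinant haploid progeny are produced by Poisson-crossover meiosis on
    the genetic map, so markers carry realistic linkage.  ``meiosis_seed``
    lets several crosses share the same marker map (``seed``) while drawing
    independent progeny.
    """
    panel = simdata.simulate_panel(16, m, n_chroms=n_chroms, seed=seed,
                                   maf_values=np.full(m, 0.5),
                                   chrom_cM=chrom_cM, chrom_bp=chrom_bp)
    ha = np.zeros(m, dtype=np.int8)
    hb = np.ones(m, dtype=np.int8)
    alleles = simdata.simulate_meiosis(
        ha, hb, n, panel.markers,
        seed=(seed + 1) if meiosis_seed is None else meiosis_seed)
    vals = np.where(alleles == 0, -1.0, 1.0)
    return GenotypeMatrix(values=vals, segregants=[f"s{i:05d}" for i in range(n)],
                          cross=np.array(["cross1"] * n), markers=panel.markers,
                          ref_parent_allele=np.zeros(m, dtype=np.int8))


def _std(y: np.ndarray) -> np.ndarray:
    return (y - y.mean()) / y.std()


# ---------------------------------------------------------------------------
# false-discovery control on null traits
# ---------------------------------------------------------------------------

def null_fdr_study(n_traits: int = 200, n: int = 400, m: int = 500,
                   B: int = 200, alpha: float = 0.05, seed: int = 0) -> dict:
    """Fraction of pure-noise traits on which the stepwise scan selects a QTL."""
    G = fully_segregating_cross(n, m, seed=seed)
    rng = np.random.default_rng(seed + 10)
    n_hit = 0
    for t in range(n_traits):
        y = _std(rng.standard_normal(n))
        trace = scan.forward_stepwise(y, G, alpha=alpha, B=B, seed=seed + 100 + t)
        if trace.selected:
            n_hit += 1
    return {"false_trait_rate": n_hit / n_traits, "n_traits": n_traits}


# ---------------------------------------------------------------------------
# power and winner's curse
# ---------------------------------------------------------------------------

def _planted_trait(G: GenotypeMatrix, j: int, beta: float,
                   rng: np.random.Generator) -> np.ndarray:
    g = _std(G.values[:, j])
    return beta * g + np.sqrt(1.0 - beta**2) * rng.standard_normal(G.n_segregants)


def power_and_winners_curse_study(effects=(0.2, 0.3, 0.5), n: int = 800,
                                  m: int = 500, reps: int = 60, B: int = 200,
                                  curse_reps: int = 150, seed: int = 0,
                                  window_cM: float = 10.0) -> dict:
    """Detection power for planted QTL and split-sample effect unbiasedness.

    Detection counts a success when a selected marker lies within
    ``window_cM`` of the causal one.  The winner's-curse arm re-detects QTL
    in 9/10 of the segregants and contrasts the training-sample effect at the
    detected peak with its estimate in the held-out 1/10.
    """
    G = fully_segregating_cross(n, m, seed=seed)
    cm = G.markers["pos_cM"].to_numpy()
    chrom = G.markers["chrom"].to_numpy()
    rng = np.random.default_rng(seed + 20)
    out: dict = {}

    def detected(trace, j):
        for s in trace.selected:
            if chrom[s] == chrom[j] and abs(cm[s] - cm[j]) <= window_cM:
                return True
        return False

    for beta in effects:
        hits = 0
        for r in range(reps):
            j = int(rng.integers(m))
            y = _planted_trait(G, j, beta, rng)
            trace = scan.forward_stepwise(_std(y), G, B=B,
                                          seed=seed + 1000 * int(beta * 10) + r)
            hits += detected(trace, j)
        out[f"power_{beta}"] = hits / reps

    # winner's curse at the weakest planted effect
    beta = min(effects)
    in_betas, out_betas = [], []
    n_hold = n // 10
    for r in range(curse_reps):
        j = int(rng.integers(m))
        y = _planted_trait(G, j, beta, rng)
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_hold], perm[n_hold:]
        Gt = GenotypeMatrix(values=G.values[train_idx],
                            segregants=[G.segregants[i] for i in train_idx],
                            cross=np.asarray(G.cross)[train_idx],
                            markers=G.markers,
                            ref_parent_allele=G.ref_parent_allele)
        trace = scan.forward_stepwise(_std(y[train_idx]), Gt, B=B,
                                      seed=seed + 7000 + r)
        if not detected(trace, j):
            continue
        peak = min(trace.selected,
                   key=lambda s: abs(cm[s] - cm[j]) if chrom[s] == chrom[j]
                   else np.inf)
        g_tr = G.values[train_idx, peak]
        y_tr = _std(y[train_idx])
        b_in = np.polyfit(g_tr, y_tr, 1)[0]
        g_te = G.values[test_idx, peak]
        y_te = _std(y[test_idx])
        b_out = np.polyfit(g_te, y_te, 1)[0]
        # orient the held-out estimate by the training sign (no folding bias)
        in_betas.append(abs(b_in))
        out_betas.append(b_out * np.sign(b_in))
    out["curse_true_effect"] = beta
    out["curse_n_detected"] = len(in_betas)
    out["insample_mean_effect"] = float(np.mean(in_betas))
    out["heldout_mean_effect"] = float(np.mean(out_betas))
    out["heldout_bias"] = float(np.mean(out_betas) - beta)
    out["insample_bias"] = float(np.mean(in_betas) - beta)
    return out


# ---------------------------------------------------------------------------
# REML recovery and SE calibration
# ---------------------------------------------------------------------------

def reml_recovery_study(n: int = 600, m: int = 1000, reps: int = 20,
                        h2: float = 0.5, seed: int = 0) -> dict:
    """Additive-model REML: recovery of sigma2_A, SE calibration, coverage."""
    rng = np.random.default_rng(seed)
    est, ses, covered = [], [], 0
    for r in range(reps):
        M = rng.choice([-1.0, 1.0], size=(n, m))
        M = (M - M.mean(0)) / M.std(0)
        K = genotypes.KinshipMatrix(values=gower_rescale(M @ M.T),
                                    normalization="gower")
        L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
        y = L @ rng.standard_normal(n) * np.sqrt(h2) \
            + rng.standard_normal(n) * np.sqrt(1 - h2)
        fit = vc.additive_model(y, K)
        a = fit.component("A")
        se = fit.se[fit.names.index("A")]
        est.append(a)
        ses.append(se)
        if abs(a - h2) <= 2 * se:
            covered += 1
    emp_sd = float(np.std(est, ddof=1))
    return {
        "true_sigma2_A": h2,
        "mean_sigma2_A": float(np.mean(est)),
        "coverage_2se": covered / reps,
        "mean_fisher_se": float(np.mean(ses)),
        "empirical_sd": emp_sd,
        "se_ratio": float(np.mean(ses) / emp_sd),
        "n_reps": reps,
    }


# ---------------------------------------------------------------------------
# rare/common variance partitioning
# ---------------------------------------------------------------------------

def partition_recovery_study(n_strains: int = 100, n_markers: int = 6000,
                             n_crosses: int = 4, n_progeny: int = 400,
                             rare_share_true: float = 0.5, h2: float = 0.5,
                             seed: int = 0) -> dict:
    """Joint MAF-partition model on a synthetic rare-heavy architecture.

    Rare markers (panel MAF < 0.01, drawn so they are ~28% of all markers)
    carry ``rare_share_true`` of the additive genetic variance; the model
    must recover that share from the two-kinship joint fit.
    """
    panel = simdata.simulate_panel(n_strains, n_markers, n_chroms=8,
                                   rare_target=0.278, seed=seed)
    design = simdata.build_round_robin(panel, n_crosses)
    per_cross = simdata.simulate_design_genotypes(panel, design, n_progeny,
                                                  seed=seed + 1)
    alleles = np.vstack(list(per_cross.values()))
    cross = np.concatenate([[cid] * n_progeny for cid in per_cross])
    segregants = [f"{cid}_{i}" for cid in per_cross for i in range(n_progeny)]
    parent_alleles = {
        cid: (panel.haplotypes[design.parent_rows[pa]],
              panel.haplotypes[design.parent_rows[pb]])
        for (pa, pb), cid in zip(design.crosses, design.cross_ids)}
    ref = panel.haplotypes[design.parent_rows[design.parents[0]]]
    G = genotypes.recode_biallelic(alleles, cross, segregants, panel.markers,
                                   parent_alleles, ref)

    maf = panel.markers["panel_maf"].to_numpy()
    seg = ~np.all(np.isnan(G.values), axis=0)
    rare_seg = np.flatnonzero(seg & (maf < 0.01))
    common_seg = np.flatnonzero(seg & (maf >= 0.01))
    rng = np.random.default_rng(seed + 2)
    n_rare_q = min(len(rare_seg), 40)
    n_common_q = min(len(common_seg), 40)
    rare_q = rng.choice(rare_seg, size=n_rare_q, replace=False)
    common_q = rng.choice(common_seg, size=n_common_q, replace=False)

    M = genotypes.standardize_markers(G, warn=False)
    ids = {mid: j for j, mid in enumerate(M.markers["id"])}
    all_ids = panel.markers["id"].to_numpy()

    def genetic_value(q_idx):
        cols = [ids[all_ids[j]] for j in q_idx if all_ids[j] in ids]
        S = M.values[:, cols]
        return S @ rng.standard_normal(len(cols))

    g_rare = genetic_value(rare_q)
    g_common = genetic_value(common_q)
    g_rare *= np.sqrt(h2 * rare_share_true) / g_rare.std()
    g_common *= np.sqrt(h2 * (1 - rare_share_true)) / g_common.std()
    y = g_rare + g_common + rng.standard_normal(len(cross)) * np.sqrt(1 - h2)

    bins = genotypes.bin_markers_by_maf(panel.markers, edges=[0.01])
    kinships = genotypes.build_partitioned_kinships(G, bins)
    fit = vc.joint_maf_partition_model(y, cross, kinships,
                                       names=["rare", "common"])
    share, share_se = vc.variance_share(fit, ["rare"],
                                        denominator=["rare", "common"])
    return {
        "rare_marker_fraction": float((maf < 0.01).mean()),
        "rare_share_true": rare_share_true,
        "rare_share_estimated": share,
        "rare_share_se": share_se,
        "n_rare_causal": int(n_rare_q),
        "n_common_causal": int(n_common_q),
        "converged": bool(fit.converged),
    }


# ---------------------------------------------------------------------------
# joint-mapping equivalences
# ---------------------------------------------------------------------------

def joint_equivalence_study(seed: int = 0, B: int = 150,
                            power_reps: int = 30) -> dict:
    """Single-cross reduction, pooled-t oracle identity, and pooling power."""
    from .pipeline import simulate_experiment

    # 1) exact reduction: joint pipeline on one cross == within-cross pipeline
    exp = simulate_experiment(
        n_strains=32, n_markers=300, n_chroms=3, n_parents=3, n_progeny=150,
        n_qtl=2, h2_additive=0.6, repeatability=1.0, n_replicates=1,
        seed_panel=seed + 1, seed_meiosis=seed + 2, seed_effects=seed + 3,
        seed_phenotypes=seed + 4)
    cid = exp.design.cross_ids[0]
    Gc = exp.G.subset_cross(cid)
    segcols = np.flatnonzero(~np.all(np.isnan(Gc.values), axis=0))
    Gc = GenotypeMatrix(values=Gc.values[:, segcols], segregants=Gc.segregants,
                        cross=Gc.cross,
                        markers=Gc.markers.iloc[segcols].reset_index(drop=True))
    y = exp.y_by_cross()[cid]
    within = scan.forward_stepwise(_std(y), Gc, B=B, seed=seed + 5)
    joint = jointmap.joint_forward_stepwise({cid: y}, Gc, B=B, seed=seed + 5,
                                            use_loco=False)
    reduction_exact = [q.marker_index for q in joint] == within.selected

    # 2) pooled t vs concatenated-regression t on the most-shared marker
    G = exp.G
    informative = ~np.isnan(G.values)
    j = int(np.argmax(informative.sum(axis=0)))
    rng = np.random.default_rng(seed + 6)
    s = _std(rng.standard_normal(G.n_segregants))
    res = jointmap.joint_t_scan(s, G, marker_subset=np.array([j]), warn=False)
    rows = informative[:, j]
    slope, _, _, _, se = stats.linregress(G.values[rows, j], s[rows])
    t_gap = abs(res.t[0] - slope / se)

    # 3) pooling power: variant shared by two crosses, joint vs within
    n_joint, n_within = 0, 0
    beta = 0.2
    for r in range(power_reps):
        exp2 = simulate_experiment(
            n_strains=32, n_markers=200, n_chroms=2, n_parents=4,
            n_progeny=200, n_qtl=1, h2_additive=None, repeatability=1.0,
            n_replicates=1, seed_panel=seed + 100 + r,
            seed_meiosis=seed + 200 + r, seed_effects=seed + 300 + r,
            seed_phenotypes=seed + 400 + r)
        G2 = exp2.G
        cross2 = np.asarray(G2.cross)
        cids = list(pd.unique(cross2))
        seg_counts = np.sum([~np.all(np.isnan(G2.values[cross2 == c]), axis=0)
                             for c in cids], axis=0)
        cand = np.flatnonzero(seg_counts == 2)
        if not len(cand):
            continue
        rng2 = np.random.default_rng(seed + 500 + r)
        j = int(rng2.choice(cand))
        dos = np.nan_to_num(G2.values[:, j], nan=0.0)
        informative = ~np.isnan(G2.values[:, j])
        g = np.zeros_like(dos)
        g[informative] = _std(dos[informative])
        y2 = beta * g + np.sqrt(1 - beta**2) * rng2.standard_normal(len(g))
        y_by_cross = {c: y2[cross2 == c] for c in cids}
        qtls = jointmap.joint_forward_stepwise(y_by_cross, G2, B=B,
                                               seed=seed + 600 + r)
        cm = G2.markers["pos_cM"].to_numpy()
        ch = G2.markers["chrom"].to_numpy()
        if any(ch[q.marker_index] == ch[j] and abs(cm[q.marker_index] - cm[j]) <= 10
               for q in qtls):
            n_joint += 1
        # within: the first cross in which it segregates
        c = [c for c in cids if informative[cross2 == c].all()
             and not np.isnan(G2.values[cross2 == c, j]).any()][0]
        Gc2 = G2.subset_cross(c)
        segc = np.flatnonzero(~np.all(np.isnan(Gc2.values), axis=0))
        Gc2 = GenotypeMatrix(values=Gc2.values[:, segc],
                             segregants=Gc2.segregants, cross=Gc2.cross,
                             markers=Gc2.markers.iloc[segc].reset_index(drop=True))
        tr = scan.forward_stepwise(_std(y2[cross2 == c]), Gc2, B=B,
                                   seed=seed + 700 + r)
        cm2 = Gc2.markers["pos_cM"].to_numpy()
        ch2 = Gc2.markers["chrom"].to_numpy()
        if any(ch2[s_] == ch[j] and abs(cm2[s_] - cm[j]) <= 10
               for s_ in tr.selected):
            n_within += 1
    return {
        "single_cross_reduction_exact": bool(reduction_exact),
        "pooled_t_oracle_gap": float(t_gap),
        "joint_detection_rate": n_joint / power_reps,
        "within_detection_rate": n_within / power_reps,
    }


# ---------------------------------------------------------------------------
# PICS localization and gene FDR
# ---------------------------------------------------------------------------

def _pics_for_cross(G: GenotypeMatrix, causal: int, effect: float,
                    n_sims: int, seed: int) -> finemap.PICSWindow:
    """Plant a causal variant, map the window peak, and fine-map it."""
    rng = np.random.default_rng(seed)
    n = G.n_segregants
    g = _std(G.values[:, causal])
    y = effect * g + np.sqrt(1 - effect**2) * rng.standard_normal(n)
    res = scan.genome_scan_r2(_std(y), G)
    peak = res.best_index
    gp = _std(G.values[:, peak])
    beta = float(gp @ _std(y)) / n
    resid = _std(y) - beta * gp
    return finemap.pics_window(_std(y), G, peak, beta, resid, n_sims=n_sims,
                               seed=seed + 1)


def pics_study(reps: int = 50, n: int = 800, m: int = 20, effect: float = 0.3,
               n_sims: int = 300, seed: int = 0, fdr_cut: float = 0.2,
               markers_per_gene: int = 4, span_cM: float = 100.0) -> dict:
    """Causal-variant localization and gene-level FDR on two-cross windows.

    Each replicate draws one 20-variant window over 40 kb (so the whole
    window fits inside the 50 kb fine-mapping span) with marker spacing on
    the genetic map loose enough that neighbours are only partially
    correlated, plants the same
    causal variant in two independently recombined crosses, fine-maps both,
    combines the posteriors, and aggregates them over a regular gene grid.
    Gene scores are pooled over replicates and ranked by the cumulative-mean
    FDR; the empirical false-discovery proportion is measured against the
    known causal gene of each replicate.
    """
    top_hits = 0
    sums_ok = True
    gene_rows = []
    n_genes = m // markers_per_gene
    for r in range(reps):
        base = seed + 1000 * r
        Ga = fully_segregating_cross(n, m, n_chroms=1, chrom_cM=span_cM,
                                     chrom_bp=40_000, seed=seed + 17,
                                     meiosis_seed=base + 1)
        Gb = fully_segregating_cross(n, m, n_chroms=1, chrom_cM=span_cM,
                                     chrom_bp=40_000, seed=seed + 17,
                                     meiosis_seed=base + 2)
        rng = np.random.default_rng(base + 3)
        causal = int(rng.integers(m))
        causal_id = str(Ga.markers["id"].iloc[causal])
        wa = _pics_for_cross(Ga, causal, effect, n_sims, base + 4)
        wb = _pics_for_cross(Gb, causal, effect, n_sims, base + 6)

        ppc = pd.Series(wa.ppc, index=wa.marker_ids)
        if not np.isclose(ppc.sum(), 1.0, atol=1e-9):
            sums_ok = False
        if causal_id in ppc.index and ppc[causal_id] >= ppc.max() - 1e-12:
            top_hits += 1

        comb = finemap.combine_cross_pair(wa, wb)
        if comb is None:
            continue
        # regular gene grid over the 40 kb window, names unique per replicate
        edges = np.linspace(1, 40_000, n_genes + 1)
        genes = pd.DataFrame({
            "gene": [f"r{r}_g{k}" for k in range(n_genes)],
            "chrom": "chr01",
            "start_bp": edges[:-1].astype(int) + 1,
            "end_bp": edges[1:].astype(int) - 200,
        })
        scores = finemap.aggregate_to_genes(comb, Ga.markers, genes)
        terr = finemap.gene_territories(genes, "chr01")
        causal_pos = float(Ga.markers["pos_bp"].iloc[causal])
        in_terr = (causal_pos > terr["territory_left"]) & \
            (causal_pos <= terr["territory_right"])
        causal_gene = str(terr.loc[in_terr, "gene"].iloc[0])
        scores["is_causal"] = scores["gene"] == causal_gene
        gene_rows.append(scores)
    out = {"top_ppc_rate": top_hits / reps, "ppc_sums_to_one": sums_ok,
           "n_windows": reps}
    if gene_rows:
        pooled = pd.concat(gene_rows, ignore_index=True)
        ranked = finemap.gene_fdr(pooled)
        out["fdr_non_decreasing"] = bool((np.diff(ranked["fdr"]) >= -1e-12).all())
        called = ranked[ranked["fdr"] <= fdr_cut]
        if len(called):
            out["empirical_fdp_at_20"] = float((~called["is_causal"]).mean())
            out["n_called_at_20"] = int(len(called))
        else:
            out["empirical_fdp_at_20"] = 0.0
            out["n_called_at_20"] = 0
    return out


# ---------------------------------------------------------------------------
# frequency-coupled architecture recovery
# ---------------------------------------------------------------------------

def frequency_effect_study(n_qtl: int = 1000, coupling_tau: float = -0.3,
                           sign_bias: float = 0.75, seed: int = 0) -> dict:
    """Recovery of the effect-size/frequency coupling and derived sign bias."""
    panel = simdata.simulate_panel(200, max(4 * n_qtl, 2000), seed=seed,
                                   unknown_frac=0.1)
    truth = simdata.assign_effects(panel, n_qtl, coupling_tau=coupling_tau,
                                   sign_bias_recent=sign_bias, seed=seed + 1)
    mk = panel.markers.set_index("id").loc[truth.causal["marker"]]
    qtls = pd.DataFrame({"panel_maf": mk["panel_maf"].to_numpy(),
                         "mean_beta": truth.causal["effect"].to_numpy()})
    binned = popgen.bin_effects_by_frequency(qtls, bin_size=100)
    rho, p = stats.spearmanr(binned["mean_maf"], binned["mean_abs_effect"])

    derived_is_alt = (mk["ancestral_allele"].to_numpy()
                      == mk["ref_allele"].to_numpy())
    ancestral_is_alt = (mk["ancestral_allele"].to_numpy()
                        == mk["alt_allele"].to_numpy())
    known = derived_is_alt | ancestral_is_alt
    eff = truth.causal["effect"].to_numpy()
    derived_effect = np.where(derived_is_alt, eff, -eff)
    q = pd.DataFrame({"derived_effect": derived_effect,
                      "age_class": np.where(known, "recent", "unknown")})
    ds = popgen.direction_summary(q)
    return {
        "binned_spearman_rho": float(rho),
        "binned_spearman_p": float(p),
        "n_bins": int(len(binned)),
        "sign_bias_true": sign_bias,
        "recent_decrease_fraction": ds["recent_decrease_fraction"],
    }
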
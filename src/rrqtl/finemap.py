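"""Simulation-based fine-mapping of QTL to genes (PICS-style).

Given a mapped QTL peak and its effect size, the probability that each
variant in a 50 kb window centered on the peak is the causal one is estimated
by forward simulation: for each candidate variant, the observed effect is
planted on that variant's standardized genotype on a background of permuted
within-cross model residuals, the window is re-scanned, and the posterior
weight of the candidate is the fraction of simulations in which the observed
peak re-emerges as the lead variant.  With equal priors over candidates the
weights are normalized to sum to one.

Windows from two crosses that share a parent, whose 1.5-LOD-drop intervals
overlap and whose effect directions agree, are combined by multiplying the
per-variant probabilities over the shared segregating variants and
renormalizing.  Variant probabilities are then summed over gene territories
(the open reading frame plus half of each flanking intergenic span) and genes
are ranked by an FDR computed as the cumulative mean of the posterior error
probabilities 1 − P(causal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "PICSWindow",
    "pics_window",
    "find_overlapping_qtl",
    "combine_cross_pair",
    "aggregate_to_genes",
    "gene_fdr",
]


@dataclass
class PICSWindow:
    trait: str
    cross: str
    peak_marker: str
    effect: float
    marker_ids: list[str]
    ppc: np.ndarray                       # sums to 1 over the window
    n_sims: int
    seed: int
    degenerate: bool = False


def pics_window(y: np.ndarray, G: GenotypeMatrix, peak: int, effect: float,
                residuals: np.ndarray, n_sims: int = 500, window_kb: float = 50.0,
                seed: int = 0, trait: str = "trait", cross: str = "cross") -> PICSWindow:
    """Per-variant posterior probability of causality within a peak window.

    ``residuals`` are the residual errors of the within-cross QTL model for
    this trait and cross; each simulation permutes their assignment to
    segregants.  The window is the closed interval within ``window_kb``/2 of
    the peak position on its chromosome.
    """
    mk = G.markers
    half_bp = window_kb * 1000.0 / 2.0
    chrom = mk["chrom"].iloc[peak]
    pos = mk["pos_bp"].iloc[peak]
    in_win = ((mk["chrom"] == chrom)
              & (mk["pos_bp"] >= pos - half_bp)
              & (mk["pos_bp"] <= pos + half_bp)).to_numpy()
    Gw = np.nan_to_num(G.values[:, in_win], nan=0.0)
    sd = Gw.std(axis=0)
    seg = sd > 0
    win_idx = np.flatnonzero(in_win)[seg]
    if len(win_idx) == 0:
        raise ValueError("window contains no segregating variants")
    Gw = Gw[:, seg]
    Gstd = (Gw - Gw.mean(axis=0)) / Gw.std(axis=0)
    m = Gstd.shape[1]
    peak_pos = int(np.flatnonzero(win_idx == peak)[0])
    ids = mk["id"].to_numpy(object)[win_idx].tolist()

    resid = np.asarray(residuals, float)
    if resid.std() == 0:
        # no noise: every variant in perfect LD with the peak is equally likely
        warnings.warn("zero residual variance; degenerate PICS window")
        same = np.all(Gstd == Gstd[:, [peak_pos]], axis=0) | \
            np.all(Gstd == -Gstd[:, [peak_pos]], axis=0)
        ppc = same / same.sum()
        return PICSWindow(trait=trait, cross=cross, peak_marker=ids[peak_pos],
                          effect=effect, marker_ids=ids, ppc=ppc,
                          n_sims=n_sims, seed=seed, degenerate=True)

    rng = np.random.default_rng(seed)
    n = len(resid)
    hits = np.zeros(m)
    # one permuted-residual background per simulation, shared across candidate
    # variants: keeps the posterior exactly symmetric for variants in perfect LD
    E = np.empty((n, n_sims))
    for s in range(n_sims):
        E[:, s] = resid[rng.permutation(n)]
    for v in range(m):
        Y = effect * Gstd[:, [v]] + E
        Yc = Y - Y.mean(axis=0, keepdims=True)
        denom = np.linalg.norm(Yc, axis=0)
        denom[denom == 0] = 1.0
        R = (Gstd.T @ Yc) / (denom[None, :] * np.sqrt(n))
        R2 = R**2
        # a simulation is a hit when the observed peak attains the maximal
        # statistic (variants in perfect LD with the lead count as leads too)
        hits[v] = np.mean(R2[peak_pos, :] >= R2.max(axis=0) - 1e-12)
    total = hits.sum()
    if total == 0:
        warnings.warn("no simulation reproduced the observed lead; uniform ppc")
        ppc = np.full(m, 1.0 / m)
    else:
        ppc = hits / total
    return PICSWindow(trait=trait, cross=cross, peak_marker=ids[peak_pos],
                      effect=effect, marker_ids=ids, ppc=ppc, n_sims=n_sims,
                      seed=seed)


def find_overlapping_qtl(qtls: pd.DataFrame, shared_parent_pairs: list[tuple[str, str]]
                         ) -> list[tuple[int, int]]:
    """Index pairs of QTL rows eligible for cross-pair combination.

    ``qtls`` needs columns trait, cross, chrom, effect, ci_left_bp,
    ci_right_bp.  A pair qualifies when the two QTL are for the same trait in
    two crosses that share a parent, their 1.5-LOD-drop intervals overlap as
    closed intervals, and their effect signs agree (effects are comparable
    because genotypes are recoded against a common reference parent).
    """
    eligible = {frozenset(p) for p in shared_parent_pairs}
    out = []
    rows = qtls.reset_index(drop=True)
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows.iloc[i], rows.iloc[j]
            if a["trait"] != b["trait"] or a["chrom"] != b["chrom"]:
                continue
            if frozenset((a["cross"], b["cross"])) not in eligible:
                continue
            if a["ci_left_bp"] > b["ci_right_bp"] or b["ci_left_bp"] > a["ci_right_bp"]:
                continue
            if np.sign(a["effect"]) != np.sign(b["effect"]):
                continue
            out.append((i, j))
    return out


def combine_cross_pair(w1: PICSWindow, w2: PICSWindow) -> pd.Series | None:
    """Product of the two windows' probabilities over shared variants, renormalized."""
    p1 = pd.Series(w1.ppc, index=w1.marker_ids)
    p2 = pd.Series(w2.ppc, index=w2.marker_ids)
    shared = p1.index.intersection(p2.index)
    if len(shared) == 0:
        warnings.warn("no shared segregating variants; dropping QTL pair")
        return None
    prod = p1[shared] * p2[shared]
    total = prod.sum()
    if total == 0:
        warnings.warn("combined probabilities are all zero; dropping QTL pair")
        return None
    return prod / total


def gene_territories(genes: pd.DataFrame, chrom: str) -> pd.DataFrame:
    """Gene territories on a chromosome: ORF plus half of each flanking gap.

    ``genes`` needs columns gene, chrom, start_bp, end_bp (1-based closed
    ORF intervals).  Returns territory boundaries; terminal genes take the
    full span to the chromosome ends.
    """
    sub = genes.loc[genes["chrom"] == chrom].sort_values("start_bp").reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no gene annotation for chromosome {chrom!r}")
    bounds = []
    for i in range(len(sub) - 1):
        bounds.append((sub["end_bp"].iloc[i] + sub["start_bp"].iloc[i + 1]) / 2.0)
    return sub.assign(territory_right=bounds + [np.inf],
                      territory_left=[-np.inf] + bounds)


def aggregate_to_genes(combined: pd.Series, markers: pd.DataFrame,
                       genes: pd.DataFrame) -> pd.DataFrame:
    """Sum per-variant causality probabilities over gene territories.

    Each variant goes to exactly one gene; a variant exactly at the midpoint
    between two ORFs is assigned to the left (upstream) gene.
    """
    mk = markers.set_index("id")
    pos = mk.loc[combined.index, "pos_bp"].to_numpy(float)
    chroms = mk.loc[combined.index, "chrom"].to_numpy(object)
    if len(set(chroms)) != 1:
        raise ValueError("combined window spans multiple chromosomes")
    terr = gene_territories(genes, str(chroms[0]))
    # variant at pos belongs to gene g iff territory_left < pos <= territory_right
    edges = terr["territory_right"].to_numpy(float)[:-1]
    gi = np.searchsorted(edges, pos, side="left")   # ties (pos == edge) -> left gene
    scores = pd.Series(0.0, index=terr["gene"])
    for g, p in zip(terr["gene"].to_numpy(object)[gi], combined.to_numpy(float)):
        scores[g] += p
    out = scores[scores > 0].rename("ppc_gene").reset_index()
    return out


def gene_fdr(gene_scores: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by causality probability; FDR = cumulative mean of 1 − ppc.

    ``gene_scores`` needs columns gene and ppc_gene (one row per combined QTL
    x gene).  The returned frame is sorted by descending ppc_gene with
    non-decreasing fdr down the list.
    """
    df = gene_scores.sort_values(["ppc_gene", "gene"],
                                 ascending=[False, True], kind="stable").reset_index(drop=True)
    pep = 1.0 - df["ppc_gene"].to_numpy(float)
    fdr = np.cumsum(pep) / np.arange(1, len(pep) + 1)
    return df.assign(rank=np.arange(1, len(df) + 1), fdr=fdr)
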
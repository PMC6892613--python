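"""Synthetic population panels, round-robin crosses and phenotypes.

This module generates data with the statistical structure of a multiparental
haploid yeast cross experiment: a large strain panel with a skewed site
frequency spectrum (most biallelic variants are rare), a ring of crosses in
which each parent strain mates with exactly two others, haploid recombinant
progeny produced by Poisson-crossover meiosis on a genetic map, and replicated
quantitative phenotypes driven by a known set of additive (and optionally
epistatic) causal variants.  Ground truth is carried alongside the data so
that every downstream estimator can be tested for parameter recovery.

Allele orientation convention: each marker stores a major (``ref_allele``) and
minor (``alt_allele``) panel allele; haplotypes are coded 0 = major,
1 = minor.  Causal effect sizes in a :class:`TruthSet` are coefficients on the
*standardized minor-allele dosage*, so an effect of 0.3 means the minor allele
shifts the trait by 0.3 phenotypic SD per SD of genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PopulationPanel",
    "CrossDesign",
    "TruthSet",
    "PhenotypeTable",
    "simulate_panel",
    "build_round_robin",
    "simulate_meiosis",
    "assign_effects",
    "simulate_phenotypes",
]

UNKNOWN_ALLELE = "unknown"

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PopulationPanel:
    """A panel of haploid strains genotyped at biallelic markers.

    ``markers`` has columns chrom, pos_bp, pos_cM, id, ref_allele, alt_allele,
    panel_maf, ancestral_allele.  ``haplotypes`` is strains x markers with
    0 = major (ref) allele, 1 = minor (alt) allele.  ``panel_maf`` records the
    population minor-allele frequency each marker was drawn at; the finite
    panel realizes it by carrier count.
    """

    markers: pd.DataFrame
    haplotypes: np.ndarray
    strain_ids: list[str]

    @property
    def n_strains(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class CrossDesign:
    """Ring of pairwise crosses: parent i is mated to parents i-1 and i+1."""

    parents: list[str]
    parent_rows: dict[str, int]          # strain id -> row in panel.haplotypes
    crosses: list[tuple[str, str]]

    @property
    def cross_ids(self) -> list[str]:
        return [f"{a}x{b}" for a, b in self.crosses]

    def parent_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {p: 0 for p in self.parents}
        for a, b in self.crosses:
            deg[a] += 1
            deg[b] += 1
        return deg

    def crosses_sharing_parent(self) -> list[tuple[str, str]]:
        """Pairs of cross ids that have a parent strain in common."""
        out = []
        ids = self.cross_ids
        for i in range(len(self.crosses)):
            for j in range(i + 1, len(self.crosses)):
                if set(self.crosses[i]) & set(self.crosses[j]):
                    out.append((ids[i], ids[j]))
        return out


@dataclass
class TruthSet:
    """Ground-truth genetic architecture for a simulated trait."""

    causal: pd.DataFrame                 # columns: marker, effect (minor-allele SD units)
    epistatic_pairs: pd.DataFrame        # columns: marker_a, marker_b, effect
    h2_additive: float | None
    h2_epistasis: float
    repeatability: float
    seed: int

    def __post_init__(self) -> None:
        if self.h2_additive is not None and not 0.0 <= self.h2_additive <= 1.0:
            raise ValueError("h2_additive must lie in [0, 1]")
        if self.h2_additive is not None and self.h2_additive + self.h2_epistasis > 1.0:
            raise ValueError("h2_additive + h2_epistasis exceeds 1")
        if not np.all(np.isfinite(self.causal["effect"].to_numpy(float))):
            raise ValueError("causal effects must be finite")


@dataclass
class PhenotypeTable:
    """Replicated phenotypes with the realized ground truth attached."""

    long: pd.DataFrame                   # segregant, cross, replicate, value
    values: np.ndarray                   # segregants x replicates
    genetic_value: np.ndarray            # per-segregant additive+epistatic value
    segregants: list[str]
    cross: np.ndarray
    truth: TruthSet                      # effects rescaled to the realized scale

    def segregant_means(self) -> np.ndarray:
        return self.values.mean(axis=1)


# ---------------------------------------------------------------------------
# site-frequency spectrum
# ---------------------------------------------------------------------------

def _sfs_lower_bound(sfs_shape: float, rare_target: float, rare_cut: float = 0.01,
                     upper: float = 0.5) -> float:
    """Lower truncation of the f(x) ~ x^-shape spectrum on [lo, 0.5].

    Solved so that P(MAF < rare_cut) equals ``rare_target`` exactly under the
    truncated density.
    """
    r = rare_target
    if abs(sfs_shape - 1.0) < 1e-12:
        # F(t) = log(t/lo) / log(upper/lo)
        lo = math.exp((r * math.log(upper) - math.log(rare_cut)) / (r - 1.0))
    else:
        b = 1.0 - sfs_shape
        val = (r * upper ** b - rare_cut ** b) / (r - 1.0)
        if val <= 0:
            raise ValueError(
                f"rare_target={rare_target} unreachable with sfs_shape={sfs_shape}")
        lo = val ** (1.0 / b)
    if not 0.0 < lo < rare_cut:
        raise ValueError(
            f"rare_target={rare_target} unreachable with sfs_shape={sfs_shape}")
    return lo


def _sample_maf(rng: np.random.Generator, n: int, sfs_shape: float,
                rare_target: float) -> np.ndarray:
    lo = _sfs_lower_bound(sfs_shape, rare_target)
    u = rng.uniform(size=n)
    if abs(sfs_shape - 1.0) < 1e-12:
        return lo * (0.5 / lo) ** u
    b = 1.0 - sfs_shape
    return (lo ** b + u * (0.5 ** b - lo ** b)) ** (1.0 / b)


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def simulate_panel(
    n_strains: int,
    n_markers: int,
    n_chroms: int = 8,
    sfs_shape: float = 1.0,
    rare_target: float = 0.278,
    seed: int = 0,
    *,
    ancestral_major_frac: float = 0.8,
    unknown_frac: float = 0.0,
    chrom_bp: int = 500_000,
    chrom_cM: float = 150.0,
    maf_values: np.ndarray | None = None,
) -> PopulationPanel:
    """Simulate a haploid strain panel with a skewed site-frequency spectrum.

    Marker minor-allele frequencies are drawn from a truncated power-law
    density proportional to maf**(-sfs_shape) on (lo, 0.5], with the lower
    truncation solved so the expected fraction of markers below MAF 0.01
    equals ``rare_target``.  Minor-allele carriers are placed by count
    (round(maf * n_strains), clipped to keep every marker biallelic in the
    panel).  The ancestral (outgroup) allele is the major allele for
    ``ancestral_major_frac`` of classifiable markers and the minor allele for
    the rest; ``unknown_frac`` of markers get no ancestral call, mirroring
    markers whose outgroup state cannot be determined.

    ``maf_values`` overrides the spectrum with explicit frequencies (used to
    force, e.g., MAF 0.5 everywhere).
    """
    if n_strains < 16:
        raise ValueError("n_strains must be >= 16")
    if n_markers < n_chroms:
        raise ValueError("need at least one marker per chromosome")
    if maf_values is None and not 0.0 < rare_target < 1.0:
        raise ValueError("rare_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    if maf_values is not None:
        maf = np.asarray(maf_values, dtype=float)
        if maf.shape != (n_markers,):
            raise ValueError("maf_values must have length n_markers")
    else:
        maf = _sample_maf(rng, n_markers, sfs_shape, rare_target)

    # chromosome layout: markers split as evenly as possible, positions sorted
    per_chrom = np.array_split(np.arange(n_markers), n_chroms)
    chrom = np.empty(n_markers, dtype=object)
    pos_bp = np.empty(n_markers, dtype=int)
    pos_cm = np.empty(n_markers, dtype=float)
    for c, idx in enumerate(per_chrom):
        m_c = len(idx)
        pos = np.sort(rng.choice(np.arange(1, chrom_bp + 1), size=m_c, replace=False))
        chrom[idx] = f"chr{c + 1:02d}"
        pos_bp[idx] = pos
        pos_cm[idx] = pos / chrom_bp * chrom_cM

    ref = rng.choice(_BASES, size=n_markers)
    shift = rng.integers(1, 4, size=n_markers)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]

    # haplotypes: k minor-allele carriers per marker, k = round(maf * n) in [1, n-1]
    k = np.clip(np.rint(maf * n_strains).astype(int), 1, n_strains - 1)
    order = np.argsort(rng.random((n_markers, n_strains)), axis=1)
    hap = np.zeros((n_strains, n_markers), dtype=np.int8)
    cols = np.repeat(np.arange(n_markers), k)
    rows = np.concatenate([order[j, : k[j]] for j in range(n_markers)])
    hap[rows, cols] = 1

    u = rng.uniform(size=n_markers)
    ancestral = np.where(u < ancestral_major_frac, ref, alt).astype(object)
    unknown = rng.uniform(size=n_markers) < unknown_frac
    ancestral[unknown] = UNKNOWN_ALLELE

    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": pos_bp,
            "pos_cM": pos_cm,
            "id": [f"{c}_{p}" for c, p in zip(chrom, pos_bp)],
            "ref_allele": ref,
            "alt_allele": alt,
            "panel_maf": maf,
            "ancestral_allele": ancestral,
        }
    )
    strain_ids = [f"S{i:04d}" for i in range(n_strains)]
    return PopulationPanel(markers=markers, haplotypes=hap, strain_ids=strain_ids)


# ---------------------------------------------------------------------------
# cross design
# ---------------------------------------------------------------------------

def build_round_robin(panel: PopulationPanel, n_parents: int = 16,
                      parent_ids: list[str] | None = None) -> CrossDesign:
    """Ring design: n_parents crosses, each parent mated to exactly two others."""
    if n_parents < 3:
        raise ValueError("a round robin needs at least 3 parents")
    if parent_ids is None:
        parent_ids = panel.strain_ids[:n_parents]
    if len(parent_ids) != n_parents:
        raise ValueError("parent_ids length must equal n_parents")
    if len(set(parent_ids)) != n_parents:
        raise ValueError("duplicate parent ids in design")
    rows = {}
    for p in parent_ids:
        try:
            rows[p] = panel.strain_ids.index(p)
        except ValueError:
            raise ValueError(f"parent {p!r} not in panel") from None
    crosses = [(parent_ids[i], parent_ids[(i + 1) % n_parents])
               for i in range(n_parents)]
    return CrossDesign(parents=list(parent_ids), parent_rows=rows, crosses=crosses)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def simulate_meiosis(
    parentA_haplotype: np.ndarray,
    parentB_haplotype: np.ndarray,
    n_progeny: int,
    markers: pd.DataFrame,
    seed: int = 0,
) -> np.ndarray:
    """Haploid recombinant progeny as mosaics of the two parental haplotypes.

    Per progeny and chromosome, the crossover count is Poisson with mean equal
    to the chromosome's genetic length in Morgans (cM span / 100); crossover
    positions are uniform on the cM map; the starting strand is a fair coin.
    No crossover interference is modeled.  Returns progeny x markers allele
    codes (0/1 panel coding).  Markers where the parents carry the same allele
    are constant in every progeny.
    """
    a = np.asarray(parentA_haplotype)
    b = np.asarray(parentB_haplotype)
    m = len(markers)
    if a.shape != (m,) or b.shape != (m,):
        raise ValueError("parent haplotypes do not match the marker table")
    rng = np.random.default_rng(seed)
    out = np.empty((n_progeny, m), dtype=np.int8)
    strand = np.empty((n_progeny, m), dtype=np.int8)

    for _, idx in markers.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        cm = markers["pos_cM"].to_numpy(float)[idx]
        length = cm[-1] - cm[0] if len(idx) > 1 else 0.0
        n_x = rng.poisson(length / 100.0, size=n_progeny)
        start = rng.integers(0, 2, size=n_progeny)
        for i in range(n_progeny):
            if n_x[i] == 0:
                phase = np.full(len(idx), start[i])
            else:
                xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_x[i]))
                phase = (start[i] + np.searchsorted(xpos, cm, side="right")) % 2
            strand[i, idx] = phase
    out = np.where(strand == 0, a[None, :], b[None, :]).astype(np.int8)
    return out


def simulate_design_genotypes(
    panel: PopulationPanel,
    design: CrossDesign,
    n_progeny: int,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Progeny allele matrices (0/1 panel coding) for every cross in a design."""
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for (pa, pb), cid in zip(design.crosses, design.cross_ids):
        sub = int(rng.integers(0, 2**31 - 1))
        out[cid] = simulate_meiosis(
            panel.haplotypes[design.parent_rows[pa]],
            panel.haplotypes[design.parent_rows[pb]],
            n_progeny, panel.markers, seed=sub,
        )
    return out


# ---------------------------------------------------------------------------
# genetic architecture
# ---------------------------------------------------------------------------

def assign_effects(
    panel: PopulationPanel,
    n_qtl: int,
    coupling_tau: float = 0.0,
    effect_scale: float = 0.3,
    sign_bias_recent: float = 0.5,
    seed: int = 0,
    *,
    n_epistatic_pairs: int = 0,
    epistatic_scale: float = 0.3,
    h2_additive: float | None = None,
    h2_epistasis: float = 0.0,
    repeatability: float = 1.0,
    candidate_markers: np.ndarray | None = None,
) -> TruthSet:
    """Draw a causal architecture, optionally coupling effect size to frequency.

    Effect magnitudes are ``effect_scale * |N(0,1)| * (2 maf (1-maf))**tau``;
    a negative ``coupling_tau`` makes rare variants carry larger effects, the
    signature of negative selection.  With probability ``sign_bias_recent``
    the *derived* (non-ancestral) allele's effect is trait-decreasing; markers
    with unknown ancestral state get a random sign.  Stored effects are
    oriented on the minor (alt) allele.

    ``candidate_markers`` restricts the draw (e.g. to markers that segregate
    in at least one cross of a design, so every causal variant is mappable).
    """
    pool = np.arange(panel.n_markers) if candidate_markers is None \
        else np.asarray(candidate_markers)
    if n_qtl > len(pool):
        raise ValueError("n_qtl exceeds the number of candidate markers")
    if not 0.5 <= sign_bias_recent <= 1.0:
        raise ValueError("sign_bias_recent must lie in [0.5, 1]")
    rng = np.random.default_rng(seed)
    mk = panel.markers
    pick = np.sort(rng.choice(pool, size=n_qtl, replace=False))
    maf = mk["panel_maf"].to_numpy(float)[pick]
    het = 2.0 * maf * (1.0 - maf)
    mag = effect_scale * np.abs(rng.standard_normal(n_qtl)) * het ** coupling_tau

    anc = mk["ancestral_allele"].to_numpy(object)[pick]
    ref = mk["ref_allele"].to_numpy(object)[pick]
    alt = mk["alt_allele"].to_numpy(object)[pick]
    # sign on the minor (alt) allele such that the derived allele decreases
    # the trait with probability sign_bias_recent
    decrease = rng.uniform(size=n_qtl) < sign_bias_recent
    sign = np.where(decrease, -1.0, 1.0)          # sign on the derived allele
    derived_is_alt = anc == ref
    effect = np.where(derived_is_alt, sign * mag, -sign * mag)
    unknown = ~np.isin(anc, [ref, alt]) | (anc == UNKNOWN_ALLELE)
    if unknown.any():
        effect[unknown] = np.where(rng.uniform(size=unknown.sum()) < 0.5,
                                   -1.0, 1.0) * mag[unknown]

    causal = pd.DataFrame({"marker": mk["id"].to_numpy(object)[pick],
                           "effect": effect})
    remaining = np.setdiff1d(pool, pick)
    if n_epistatic_pairs > 0:
        pairs = rng.choice(remaining, size=(n_epistatic_pairs, 2), replace=False)
        ep = pd.DataFrame({
            "marker_a": mk["id"].to_numpy(object)[pairs[:, 0]],
            "marker_b": mk["id"].to_numpy(object)[pairs[:, 1]],
            "effect": epistatic_scale * rng.standard_normal(n_epistatic_pairs),
        })
    else:
        ep = pd.DataFrame(columns=["marker_a", "marker_b", "effect"])
    return TruthSet(causal=causal, epistatic_pairs=ep, h2_additive=h2_additive,
                    h2_epistasis=h2_epistasis, repeatability=repeatability,
                    seed=seed)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _standardized_dosage(values: np.ndarray, cross: np.ndarray) -> np.ndarray:
    """Standardize each column within each cross; non-segregating -> 0."""
    out = np.zeros_like(values, dtype=float)
    import warnings as _warnings
    for cid in pd.unique(cross):
        rows = cross == cid
        block = values[rows]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(block, axis=0)
            sd = np.nanstd(block, axis=0)
        ok = np.isfinite(sd) & (sd > 0)
        std = np.zeros_like(block, dtype=float)
        std[:, ok] = (block[:, ok] - mu[ok]) / sd[ok]
        std[~np.isfinite(std)] = 0.0
        out[rows] = std
    return out


def simulate_phenotypes(
    genotypes,
    truth: TruthSet,
    n_replicates: int = 2,
    seed: int = 0,
) -> PhenotypeTable:
    """Replicated phenotypes from a causal architecture.

    Each replicate value is the segregant's genetic value (additive plus any
    epistatic terms, built on within-cross standardized minor-allele dosages)
    plus a segregant-level permanent deviate shared across replicates plus
    independent replicate noise.  If ``truth.h2_additive`` is set the additive
    part is rescaled so its realized variance fraction matches the target (and
    the rescaled effects are recorded in the returned truth); the permanent
    deviate brings the segregant-consistent fraction of variance up to
    ``truth.repeatability`` and replicate noise supplies the remainder.
    """
    from .genotypes import GenotypeMatrix  # cycle-free at call time

    if not isinstance(genotypes, GenotypeMatrix):
        raise TypeError("genotypes must be a GenotypeMatrix")
    rng = np.random.default_rng(seed)
    mk_ids = genotypes.markers["id"].tolist()
    index = {m: j for j, m in enumerate(mk_ids)}
    missing = [m for m in truth.causal["marker"] if m not in index]
    if missing:
        raise ValueError(f"causal markers absent from genotypes: {missing[:5]}")

    dos = genotypes.minor_allele_dosage()          # n x m, NaN non-segregating
    cross = genotypes.cross
    cj = [index[m] for m in truth.causal["marker"]]
    S = _standardized_dosage(dos[:, cj], cross)
    g_add = S @ truth.causal["effect"].to_numpy(float)

    g_epi = np.zeros_like(g_add)
    if len(truth.epistatic_pairs):
        ja = [index[m] for m in truth.epistatic_pairs["marker_a"]]
        jb = [index[m] for m in truth.epistatic_pairs["marker_b"]]
        Sa = _standardized_dosage(dos[:, ja], cross)
        Sb = _standardized_dosage(dos[:, jb], cross)
        g_epi = (Sa * Sb) @ truth.epistatic_pairs["effect"].to_numpy(float)

    h2a = truth.h2_additive
    h2e = truth.h2_epistasis
    rep = truth.repeatability
    eff = truth.causal["effect"].to_numpy(float).copy()
    ep_eff = truth.epistatic_pairs["effect"].to_numpy(float).copy()
    if h2a is not None:
        va = g_add.var()
        if va > 0:
            s = math.sqrt(h2a / va)
            g_add *= s
            eff *= s
        ve = g_epi.var()
        if h2e > 0 and ve > 0:
            s = math.sqrt(h2e / ve)
            g_epi *= s
            ep_eff *= s
        var_g = h2a + (h2e if ve > 0 else 0.0)
    else:
        var_g = g_add.var() + g_epi.var()

    if var_g > rep + 1e-12:
        raise ValueError(
            f"variance budget impossible: genetic fraction {var_g:.3f} exceeds "
            f"repeatability {rep:.3f}")
    if rep > 1.0 + 1e-12:
        raise ValueError("repeatability must be <= 1")
    var_perm = max(rep - var_g, 0.0)
    var_noise = max(1.0 - rep, 0.0)

    n = len(g_add)
    g = g_add + g_epi
    perm = math.sqrt(var_perm) * rng.standard_normal(n)
    noise = math.sqrt(var_noise) * rng.standard_normal((n, n_replicates))
    values = g[:, None] + perm[:, None] + noise

    truth_out = replace(
        truth,
        causal=truth.causal.assign(effect=eff),
        epistatic_pairs=truth.epistatic_pairs.assign(effect=ep_eff)
        if len(ep_eff) else truth.epistatic_pairs,
    )
    long = pd.DataFrame({
        "segregant": np.repeat(genotypes.segregants, n_replicates),
        "cross": np.repeat(cross, n_replicates),
        "replicate": np.tile(np.arange(n_replicates), n),
        "value": values.ravel(),
    })
    return PhenotypeTable(long=long, values=values, genetic_value=g,
                          segregants=list(genotypes.segregants),
                          cross=np.asarray(cross), truth=truth_out)
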
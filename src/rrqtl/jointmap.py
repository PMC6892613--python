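"""Joint QTL mapping across crosses.

A biallelic variant that segregates in several crosses is assumed to have a
consistent additive effect wherever it segregates, so evidence can be pooled
across the panel.  For each chromosome, each cross's phenotype is first
residualized for mapped off-chromosome QTL and the polygenic background of
the other chromosomes (a REML BLUP with a leave-one-chromosome-out kinship),
and the residuals are re-standardized per cross.  The pooled statistic for a
marker is the t-statistic t = r * sqrt(n-2) / sqrt(1-r²) of the Pearson
correlation between the concatenated residuals and the recoded genotypes over
the *informative* segregants — those belonging to crosses in which the
variant segregates — with -log10 p from the t distribution on n-2 degrees of
freedom, so private and shared variants are compared on a common p scale.

Significance again comes from permutation nulls, with phenotype values
permuted only within each cross, and selection uses the same ForwardStop
rule as the within-cross scan.  Effects are estimated per cross by multiple
regression of the standardized phenotype on the segregating peak markers
(-1/+1 coding, so variance explained is beta²) and averaged across crosses;
an optional 9/10–1/10 split re-estimates effects in held-out data to remove
winner's-curse inflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, KinshipMatrix, standardize_markers, gower_center, StandardizedMatrix
from .scan import NullDistribution, empirical_pvalue, forwardstop, _residualize
from .vc import VCModelSpec, reml_fit

__all__ = [
    "JointScanResult",
    "JointQTL",
    "residualize_loco",
    "joint_t_scan",
    "joint_permutation_null",
    "joint_forward_stepwise",
    "estimate_effects_per_cross",
    "unbiased_effects",
    "loco_kinships",
]

MIN_INFORMATIVE = 10


@dataclass
class JointScanResult:
    neglog10p: np.ndarray
    t: np.ndarray
    n_informative: np.ndarray
    valid: np.ndarray
    best_index: int
    best_stat: float


@dataclass
class JointQTL:
    trait: str
    marker_index: int
    marker: str
    chrom: str
    pos_bp: int
    pooled_t: float
    n_informative: int
    pvalue: float
    forwardstop: float
    per_cross_beta: dict[str, float]
    mean_beta: float
    panel_maf: float


def loco_kinships(G: GenotypeMatrix) -> dict[str, KinshipMatrix]:
    """Per-chromosome Gower kinships from all *other* chromosomes' markers."""
    M = standardize_markers(G, warn=False)
    chroms = M.markers["chrom"].to_numpy()
    out = {}
    for c in pd.unique(G.markers["chrom"]):
        cols = chroms != c
        if not cols.any():
            raise ValueError(f"no off-chromosome markers for {c}")
        sub = StandardizedMatrix(values=M.values[:, cols], scope=M.scope[:, cols],
                                 kept=cols, markers=M.markers.loc[cols])
        out[str(c)] = gower_center(sub)
    return out


def residualize_loco(y_c: np.ndarray, Q_c: np.ndarray | None,
                     K_loco: KinshipMatrix | None,
                     sigma2: tuple[float, float] | None = None) -> np.ndarray:
    """Residual trait values after removing mapped and polygenic signal.

    Fits (or reuses, via ``sigma2`` = (genetic, residual)) a one-kernel mixed
    model with the off-chromosome QTL genotypes ``Q_c`` as fixed covariates
    and subtracts both the fixed part and the BLUP of the polygenic effect.
    With no kinship (or a zero genetic variance) this reduces to ordinary
    least-squares residuals.
    """
    y_c = np.asarray(y_c, float)
    n = len(y_c)
    X = np.ones((n, 1)) if Q_c is None or Q_c.size == 0 else \
        np.column_stack([np.ones(n), np.nan_to_num(Q_c, nan=0.0)])
    if K_loco is None:
        beta, *_ = np.linalg.lstsq(X, y_c, rcond=None)
        return y_c - X @ beta
    if sigma2 is None:
        spec = VCModelSpec(X=X, kernels=[("A", K_loco.values), ("E", np.eye(n))])
        fit = reml_fit(y_c, spec)
        sg, se_ = fit.component("A"), fit.component("E")
    else:
        sg, se_ = sigma2
    V = sg * K_loco.values + max(se_, 1e-8) * np.eye(n)
    Vi = np.linalg.solve(V, np.eye(n))
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ (Vi @ y_c))
    resid_fixed = y_c - X @ beta
    blup = sg * (K_loco.values @ (Vi @ resid_fixed))
    return resid_fixed - blup


def _scan_stats(s: np.ndarray, Gv: np.ndarray, informative: np.ndarray):
    """Pooled r, t and -log10 p per marker over marker-specific scopes."""
    W = informative.astype(float)
    G0 = np.nan_to_num(Gv, nan=0.0)
    n = W.sum(axis=0)
    sw = W.T @ s
    s2w = W.T @ (s * s)
    gs = G0.T @ s
    g1 = G0.sum(axis=0)              # == sum over informative (others are 0)
    g2 = (G0 * G0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = gs - g1 * sw / n
        vg = g2 - g1 * g1 / n
        vs = s2w - sw * sw / n
        r = cov / np.sqrt(vg * vs)
    valid = (n >= MIN_INFORMATIVE) & np.isfinite(r) & (np.nan_to_num(vg) > 0)
    r = np.clip(np.nan_to_num(r), -0.999999999, 0.999999999)
    df = np.maximum(n - 2, 1)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    logp = -np.log10(np.clip(2.0 * stats.t.sf(np.abs(t), df), 1e-300, 1.0))
    logp[~valid] = 0.0
    t[~valid] = 0.0
    return t, logp, n.astype(int), valid


def joint_t_scan(s: np.ndarray, G: GenotypeMatrix,
                 marker_subset: np.ndarray | None = None,
                 exclude: set[int] | None = None,
                 warn: bool = True) -> JointScanResult:
    """Pooled t scan of concatenated residuals against recoded genotypes.

    ``exclude`` holds full-matrix marker indices (already-selected covariate
    markers) whose statistic is zeroed so they cannot be re-selected.
    """
    subset = np.arange(G.n_markers) if marker_subset is None else np.asarray(marker_subset)
    Gv = G.values[:, subset]
    informative = ~np.isnan(Gv)
    skipped = informative.sum(axis=0) < MIN_INFORMATIVE
    if skipped.any() and warn:
        warnings.warn(f"skipped {int(skipped.sum())} markers with <{MIN_INFORMATIVE} "
                      "informative segregants")
    t, logp, n, valid = _scan_stats(np.asarray(s, float), Gv, informative)
    if exclude:
        drop = np.isin(subset, list(exclude))
        logp[drop] = 0.0
        t[drop] = 0.0
        valid[drop] = False
    best = int(np.argmax(logp))
    return JointScanResult(neglog10p=logp, t=t, n_informative=n, valid=valid,
                           best_index=best, best_stat=float(logp[best]))


def _center_by_cross(s: np.ndarray, cross: np.ndarray, levels) -> np.ndarray:
    out = np.asarray(s, float).copy()
    for c in levels:
        rows = cross == c
        out[rows] -= out[rows].mean()
    return out


def _within_cross_perm(rng: np.random.Generator, cross: np.ndarray,
                       levels: list) -> np.ndarray:
    """A permutation of 0..n-1 that only shuffles within each cross block."""
    idx = np.arange(len(cross))
    out = idx.copy()
    for c in levels:
        rows = np.flatnonzero(cross == c)
        out[rows] = rows[rng.permutation(len(rows))]
    return out


def joint_permutation_null(s: np.ndarray, cross: np.ndarray, G: GenotypeMatrix,
                           B: int = 1000, seed=0,
                           s_by_chrom: dict[str, np.ndarray] | None = None,
                           exclude: set[int] | None = None) -> NullDistribution:
    """Null maxima of -log10 p with phenotypes permuted within cross only.

    ``s_by_chrom`` supplies per-chromosome residual vectors (the LOCO case);
    each chromosome's markers are scanned against its own residuals, and the
    genome-wide maximum per permutation is recorded.  ``exclude`` removes the
    already-selected covariate markers from the maxima.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    s = np.asarray(s, float).copy()
    cross = np.asarray(cross)
    levels = list(pd.unique(cross))
    # center within cross so the null is invariant to per-cross shifts
    for c in levels:
        rows = cross == c
        s[rows] -= s[rows].mean()
    if s_by_chrom is not None:
        s_by_chrom = {k: _center_by_cross(v, cross, levels)
                      for k, v in s_by_chrom.items()}
    chroms = G.markers["chrom"].to_numpy()
    chrom_cols = {c: np.flatnonzero(chroms == c) for c in pd.unique(chroms)}
    keep_cols = {c: cols if not exclude else cols[~np.isin(cols, list(exclude))]
                 for c, cols in chrom_cols.items()}
    rng = np.random.default_rng(seed)
    maxima = np.zeros(B)
    for b in range(B):
        perm = _within_cross_perm(rng, cross, levels)
        best = 0.0
        for c, cols in keep_cols.items():
            if not len(cols):
                continue
            sc = s if s_by_chrom is None else s_by_chrom[str(c)]
            Gv = G.values[:, cols]
            informative = ~np.isnan(Gv)
            _, logp, _, _ = _scan_stats(sc[perm], Gv, informative)
            if logp.size:
                best = max(best, float(logp.max()))
        maxima[b] = best
    return NullDistribution(max_stats=maxima, B=B, seed=seed)


def _residuals_per_chrom(y_by_cross: dict[str, np.ndarray], G: GenotypeMatrix,
                         selected: list[int],
                         loco: dict[str, KinshipMatrix] | None,
                         loco_s2: dict[str, tuple[float, float]] | None) -> dict[str, np.ndarray]:
    """Per-chromosome concatenated, per-cross-standardized residual vectors."""
    cross = np.asarray(G.cross)
    chrom_list = pd.unique(G.markers["chrom"])
    out: dict[str, np.ndarray] = {}
    for c in chrom_list:
        parts = []
        for cid, y_c in y_by_cross.items():
            rows = cross == cid
            Q = G.values[np.ix_(rows, selected)] if selected else None
            if loco is not None:
                Kc = KinshipMatrix(values=loco[str(c)].values[np.ix_(rows, rows)],
                                   normalization="gower")
                s2 = None if loco_s2 is None else loco_s2.get(cid)
                s_c = residualize_loco(y_c, Q, Kc, sigma2=s2)
            else:
                s_c = residualize_loco(y_c, Q, None)
            sd = s_c.std()
            parts.append((s_c - s_c.mean()) / sd if sd > 0 else s_c * 0.0)
        out[str(c)] = np.concatenate(parts)
    return out


def joint_forward_stepwise(y_by_cross: dict[str, np.ndarray], G: GenotypeMatrix,
                           alpha: float = 0.05, B: int = 1000, seed: int = 0,
                           use_loco: bool = False, trait: str = "trait",
                           max_steps: int = 25) -> list[JointQTL]:
    """ForwardStop-controlled joint selection of QTL across all crosses.

    ``y_by_cross`` maps cross ids (in the order segregants appear in ``G``)
    to phenotype vectors.  At each step every chromosome is scanned against
    residuals conditional on the already-selected markers (and, with
    ``use_loco=True``, a leave-one-chromosome-out polygenic BLUP); the
    genome-wide best marker is tested against a within-cross permutation
    null and retained while ForwardStop stays at or below ``alpha``.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    cross = np.asarray(G.cross)
    order_ok = list(y_by_cross) == list(pd.unique(cross))
    if not order_ok:
        raise ValueError("y_by_cross keys must match cross order in G")
    loco = loco_kinships(G) if use_loco else None
    chroms = G.markers["chrom"].to_numpy()
    chrom_cols = {str(c): np.flatnonzero(chroms == c) for c in pd.unique(chroms)}

    selected: list[int] = []
    pvals: list[float] = []
    records: list[JointQTL] = []
    for k in range(max_steps):
        s_by_chrom = _residuals_per_chrom(y_by_cross, G, selected, loco, None)
        sel_set = set(selected)
        best_stat, best_idx, best_chrom = -1.0, -1, None
        for c, cols in chrom_cols.items():
            res = joint_t_scan(s_by_chrom[c], G, marker_subset=cols,
                               exclude=sel_set, warn=False)
            if res.valid.any() and res.best_stat > best_stat:
                best_stat = res.best_stat
                best_idx = int(cols[res.best_index])
                best_chrom = c
        if best_idx < 0 or best_stat <= 0:
            break
        s_flat = s_by_chrom[best_chrom]
        null = joint_permutation_null(s_flat, cross, G, B=B, seed=[seed, k],
                                      s_by_chrom=s_by_chrom, exclude=sel_set)
        p = empirical_pvalue(best_stat, null)
        fs = np.inf if p >= 1.0 else forwardstop(pvals + [p])
        if fs > alpha:
            break
        pvals.append(p)
        selected.append(best_idx)
        mk = G.markers.iloc[best_idx]
        res_best = joint_t_scan(s_by_chrom[best_chrom], G,
                                marker_subset=np.array([best_idx]), warn=False)
        records.append(JointQTL(
            trait=trait, marker_index=best_idx, marker=str(mk["id"]),
            chrom=str(mk["chrom"]), pos_bp=int(mk["pos_bp"]),
            pooled_t=float(res_best.t[0]),
            n_informative=int(res_best.n_informative[0]),
            pvalue=p, forwardstop=fs, per_cross_beta={}, mean_beta=np.nan,
            panel_maf=float(mk.get("panel_maf", np.nan)),
        ))
    if records:
        records = estimate_effects_per_cross(y_by_cross, G, records)
    return records


def estimate_effects_per_cross(y_by_cross: dict[str, np.ndarray],
                               G: GenotypeMatrix,
                               qtls: list[JointQTL]) -> list[JointQTL]:
    """Per-cross multiple-regression effects at the selected peaks.

    Phenotypes are standardized within cross; coefficients are on the -1/+1
    genotype coding, so beta² is the variance explained in a balanced cross
    and 2*beta is the difference between the two allele means.
    """
    cross = np.asarray(G.cross)
    peak_idx = [q.marker_index for q in qtls]
    betas: dict[int, dict[str, float]] = {i: {} for i in peak_idx}
    for cid, y_c in y_by_cross.items():
        rows = cross == cid
        y_std = (y_c - y_c.mean()) / y_c.std()
        sub = G.values[np.ix_(rows, peak_idx)]
        seg = ~np.all(np.isnan(sub), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            seg &= np.nan_to_num(np.nanstd(sub, axis=0)) > 0
        if not seg.any():
            continue
        Xc = np.column_stack([np.ones(rows.sum()), np.nan_to_num(sub[:, seg], 0.0)])
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            warnings.warn(f"collinear peaks in cross {cid}; dropping extras")
            keep = [0]
            for j in range(1, Xc.shape[1]):
                if np.linalg.matrix_rank(Xc[:, keep + [j]]) == len(keep) + 1:
                    keep.append(j)
            beta = np.full(Xc.shape[1], np.nan)
            bk, *_ = np.linalg.lstsq(Xc[:, keep], y_std, rcond=None)
            beta[keep] = bk
        else:
            beta, *_ = np.linalg.lstsq(Xc, y_std, rcond=None)
        for b, i in zip(beta[1:], np.asarray(peak_idx)[seg]):
            if np.isfinite(b):
                betas[int(i)][cid] = float(b)
    out = []
    for q in qtls:
        pc = betas[q.marker_index]
        mean_beta = float(np.mean(list(pc.values()))) if pc else np.nan
        out.append(JointQTL(**{**q.__dict__, "per_cross_beta": pc,
                               "mean_beta": mean_beta}))
    return out


def unbiased_effects(y_by_cross: dict[str, np.ndarray], G: GenotypeMatrix,
                     alpha: float = 0.05, B: int = 200, seed: int = 0,
                     holdout_frac: float = 0.1, use_loco: bool = False) -> pd.DataFrame:
    """Winner's-curse-free effects: detect on 9/10, estimate on the held 1/10.

    Returns one row per detected peak with in-sample (training) and held-out
    effect estimates (mean per-cross beta, -1/+1 coding).
    """
    cross = np.asarray(G.cross)
    rng = np.random.default_rng(seed)
    train_rows = np.zeros(len(cross), dtype=bool)
    for cid in pd.unique(cross):
        rows = np.flatnonzero(cross == cid)
        n_hold = max(int(round(holdout_frac * len(rows))), 1)
        if len(rows) - n_hold < 10:
            raise ValueError("fewer than 10 training segregants in a cross")
        hold = rng.choice(rows, size=n_hold, replace=False)
        train_rows[rows] = True
        train_rows[hold] = False
    test_rows = ~train_rows
    # build a row-aligned phenotype vector then re-split by fold
    y_flat = np.concatenate([y_by_cross[c] for c in pd.unique(cross)])
    Gt = GenotypeMatrix(values=G.values[train_rows],
                        segregants=[s for s, m in zip(G.segregants, train_rows) if m],
                        cross=cross[train_rows], markers=G.markers,
                        ref_parent_allele=G.ref_parent_allele)
    y_train = {cid: y_flat[(cross == cid) & train_rows] for cid in pd.unique(cross)}
    qtls = joint_forward_stepwise(y_train, Gt, alpha=alpha, B=B, seed=seed,
                                  use_loco=use_loco)
    if not qtls:
        return pd.DataFrame(columns=["marker", "chrom", "pos_bp",
                                     "beta_insample", "beta_heldout"])
    Gh = GenotypeMatrix(values=G.values[test_rows],
                        segregants=[s for s, m in zip(G.segregants, test_rows) if m],
                        cross=cross[test_rows], markers=G.markers,
                        ref_parent_allele=G.ref_parent_allele)
    y_test = {cid: y_flat[(cross == cid) & test_rows] for cid in pd.unique(cross)}
    held = estimate_effects_per_cross(y_test, Gh, qtls)
    rows = []
    for q_in, q_out in zip(qtls, held):
        rows.append({"marker": q_in.marker, "chrom": q_in.chrom,
                     "pos_bp": q_in.pos_bp,
                     "beta_insample": q_in.mean_beta,
                     "beta_heldout": q_out.mean_beta})
    return pd.DataFrame(rows)
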
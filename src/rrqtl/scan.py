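"""Within-cross QTL mapping.

Linkage is tested marker-by-marker with r², the squared Pearson correlation
between segregant genotypes and phenotypes.  Genome-wide significance comes
from an empirical null of the maximum statistic over permutations of the
phenotype-to-strain assignment.  QTL are accumulated by forward stepwise
selection: at each step the scan is repeated conditional on the markers
already selected (the phenotype is replaced by its residual on them, and the
permutations shuffle those residuals), the genome-wide maximum gets an
empirical p-value, and selection stops the first time the running ForwardStop
statistic −(1/k)·Σ log(1−p_i) exceeds the target FDR level.

Peaks are then re-localized one at a time by scanning their chromosome with
all other peaks as covariates and keeping the marker that maximizes the
multiple-regression likelihood.  Confidence intervals use a LOD drop, with
LOD = −(n/2)·log10(1−r²), and the variance explained by the selected model is
assessed by 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "ScanResult",
    "NullDistribution",
    "StepwiseTrace",
    "genome_scan_r2",
    "max_stat_permutation_null",
    "empirical_pvalue",
    "forwardstop",
    "forward_stepwise",
    "relocalize_peaks",
    "lod_drop_interval",
    "crossval_variance_explained",
]


@dataclass
class ScanResult:
    stat: np.ndarray                    # per-marker r² (0 for uninformative)
    n_informative: np.ndarray
    valid: np.ndarray                   # bool per marker
    best_index: int
    best_stat: float

    def best_marker(self, markers: pd.DataFrame) -> str:
        return str(markers["id"].iloc[self.best_index])


@dataclass
class NullDistribution:
    max_stats: np.ndarray
    B: int
    seed: object


@dataclass
class StepwiseTrace:
    steps: pd.DataFrame                 # step, marker_index, marker, p, forwardstop, stat
    selected: list[int]                 # marker indices retained in the model
    alpha: float


def _residualize(y: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    """Residual of y on [1, X] (least squares)."""
    y = np.asarray(y, float)
    if X is None or X.size == 0:
        return y - y.mean()
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    return y - X1 @ beta


def _prep_columns(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Centered, unit-norm genotype columns; invalid columns flagged."""
    V = np.nan_to_num(G.values, nan=0.0)
    Vc = V - V.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Vc, axis=0)
    valid = (norms > 0) & ~np.all(np.isnan(G.values), axis=0)
    Vc[:, valid] /= norms[valid]
    Vc[:, ~valid] = 0.0
    return Vc, valid


def genome_scan_r2(y: np.ndarray, G: GenotypeMatrix,
                   covariates: list[int] | None = None) -> ScanResult:
    """Per-marker r² between (covariate-residualized) phenotype and genotype."""
    y = np.asarray(y, float)
    if y.std() == 0:
        raise ValueError("phenotype has zero variance")
    X = G.values[:, covariates] if covariates else None
    if X is not None:
        X = np.nan_to_num(X, nan=0.0)
    e = _residualize(y, X)
    Vc, valid = _prep_columns(G)
    ne = np.linalg.norm(e)
    r = (Vc.T @ e) / ne if ne > 0 else np.zeros(G.n_markers)
    stat = np.clip(r**2, 0.0, 1.0)
    stat[~valid] = 0.0
    if covariates:
        stat[covariates] = 0.0
    best = int(np.argmax(stat))          # ties -> lowest (chrom, pos) order
    n_inf = (~np.isnan(G.values)).sum(axis=0)
    return ScanResult(stat=stat, n_informative=n_inf, valid=valid,
                      best_index=best, best_stat=float(stat[best]))


def max_stat_permutation_null(y: np.ndarray, G: GenotypeMatrix,
                              covariates: list[int] | None, B: int,
                              seed) -> NullDistribution:
    """Empirical null of the genome-wide maximum r² under phenotype permutation.

    With covariates present, the covariate-residualized phenotype is permuted
    against the fixed genotypes (Freedman–Lane style).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = G.values[:, covariates] if covariates else None
    if X is not None:
        X = np.nan_to_num(X, nan=0.0)
    e = _residualize(np.asarray(y, float), X)
    Vc, valid = _prep_columns(G)
    mask = valid.copy()
    if covariates:
        mask[covariates] = False
    rng = np.random.default_rng(seed)
    n = len(e)
    perms = np.empty((n, B))
    for b in range(B):
        perms[:, b] = e[rng.permutation(n)]
    perms -= perms.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(perms, axis=0)
    norms[norms == 0] = 1.0
    R = (Vc[:, mask].T @ perms) / norms[None, :]
    maxima = (R**2).max(axis=0) if mask.any() else np.zeros(B)
    return NullDistribution(max_stats=maxima, B=B, seed=seed)


def empirical_pvalue(observed_max: float, null: NullDistribution) -> float:
    """p = #{null maxima >= observed}/B, floored at 1/B."""
    if null.B < 1:
        raise ValueError("empty null distribution")
    count = int(np.sum(null.max_stats >= observed_max))
    return max(count / null.B, 1.0 / null.B)


def forwardstop(pvalues) -> float:
    """ForwardStop statistic −(1/k)·Σ log(1−p_i) over the ordered selection p's."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return 0.0
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("p-values must lie in [0, 1)")
    return float(-np.mean(np.log1p(-p)))


def forward_stepwise(y: np.ndarray, G: GenotypeMatrix, alpha: float = 0.05,
                     B: int = 10_000, seed: int = 0, max_steps: int = 25) -> StepwiseTrace:
    """Permutation-calibrated forward selection with the ForwardStop rule.

    The candidate marker of step k (the genome-wide maximum conditional on
    the selected set) is retained only while the ForwardStop of the p-value
    prefix stays at or below ``alpha``; the first exceedance ends selection
    and its marker is not kept.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    selected: list[int] = []
    rows = []
    pvals: list[float] = []
    if G.n_markers == 0:
        return StepwiseTrace(steps=pd.DataFrame(
            columns=["step", "marker_index", "marker", "p", "forwardstop", "stat"]),
            selected=[], alpha=alpha)
    for k in range(max_steps):
        res = genome_scan_r2(y, G, covariates=selected or None)
        if res.best_stat <= 0:
            break
        null = max_stat_permutation_null(y, G, selected or None, B, seed=[seed, k])
        p = empirical_pvalue(res.best_stat, null)
        # p = 1 makes the ForwardStop term infinite: certain stop
        fs = np.inf if p >= 1.0 else forwardstop(pvals + [p])
        rows.append({"step": k, "marker_index": res.best_index,
                     "marker": res.best_marker(G.markers), "p": p,
                     "forwardstop": fs, "stat": res.best_stat})
        if fs > alpha:
            break
        pvals.append(p)
        selected.append(res.best_index)
    return StepwiseTrace(steps=pd.DataFrame(rows), selected=selected, alpha=alpha)


def _model_rss(y: np.ndarray, G: GenotypeMatrix, idx: list[int]) -> float:
    e = _residualize(y, np.nan_to_num(G.values[:, idx], nan=0.0) if idx else None)
    return float(e @ e)


def relocalize_peaks(y: np.ndarray, G: GenotypeMatrix,
                     trace: StepwiseTrace) -> StepwiseTrace:
    """Move each peak to the likelihood-maximizing marker on its chromosome.

    One pass: for each selected peak in turn, all markers on that peak's
    chromosome are tried in the multiple regression holding the other peaks
    fixed, and the best (minimum-RSS) marker replaces the peak.  Because the
    incumbent is among the candidates the model likelihood never decreases.
    """
    if not trace.selected:
        return trace
    y = np.asarray(y, float)
    chroms = G.markers["chrom"].to_numpy()
    selected = list(trace.selected)
    for i, peak in enumerate(selected):
        others = [s for j, s in enumerate(selected) if j != i]
        cand = np.flatnonzero(chroms == chroms[peak])
        cand = [c for c in cand if c not in others]
        e = _residualize(y, np.nan_to_num(G.values[:, others], nan=0.0) if others else None)
        Vc, valid = _prep_columns(G)
        if others:
            # residualize candidate columns on the other peaks too (partial corr)
            X1 = np.column_stack([np.ones(len(y)),
                                  np.nan_to_num(G.values[:, others], nan=0.0)])
            beta, *_ = np.linalg.lstsq(X1, np.nan_to_num(G.values[:, cand], nan=0.0),
                                       rcond=None)
            C = np.nan_to_num(G.values[:, cand], nan=0.0) - X1 @ beta
        else:
            C = np.nan_to_num(G.values[:, cand], nan=0.0)
            C = C - C.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(C, axis=0)
        okc = norms > 1e-12
        r = np.zeros(len(cand))
        ne = np.linalg.norm(e - e.mean())
        if ne > 0:
            ec = e - e.mean()
            r[okc] = (C[:, okc].T @ ec) / (norms[okc] * ne)
        best = int(np.argmax(r**2))
        selected[i] = int(cand[best])
    steps = trace.steps.copy()
    if len(steps):
        ids = G.markers["id"].to_numpy()
        keep = steps["step"] < len(selected)
        for row, new in zip(steps.index[keep][: len(selected)], selected):
            steps.loc[row, "marker_index"] = new
            steps.loc[row, "marker"] = ids[new]
    return StepwiseTrace(steps=steps, selected=selected, alpha=trace.alpha)


def lod_drop_interval(y: np.ndarray, G: GenotypeMatrix, peak: int,
                      covariates: list[int] | None = None,
                      drop: float = 1.5) -> tuple[int, int]:
    """Contiguous marker interval around ``peak`` within ``drop`` LOD of it.

    LOD = −(n/2)·log10(1−r²) from the covariate-conditional scan on the
    peak's chromosome.  Returns (left, right) marker indices (inclusive).
    """
    chroms = G.markers["chrom"].to_numpy()
    on_chrom = np.flatnonzero(chroms == chroms[peak])
    if peak not in on_chrom:
        raise ValueError("peak not on a scanned chromosome")
    cov = [c for c in (covariates or []) if c != peak]
    res = genome_scan_r2(y, G, covariates=cov or None)
    n = G.n_segregants
    with np.errstate(divide="ignore"):
        lod = -(n / 2.0) * np.log10(np.clip(1.0 - res.stat, 1e-300, 1.0))
    thresh = lod[peak] - drop
    pos = int(np.searchsorted(on_chrom, peak))
    left = pos
    while left > 0 and lod[on_chrom[left - 1]] >= thresh:
        left -= 1
    right = pos
    while right < len(on_chrom) - 1 and lod[on_chrom[right + 1]] >= thresh:
        right += 1
    return int(on_chrom[left]), int(on_chrom[right])


def crossval_variance_explained(y: np.ndarray, G: GenotypeMatrix,
                                alpha: float = 0.05, B: int = 1000,
                                folds: int = 10, seed: int = 0) -> float:
    """Out-of-fold R² of the selected multi-QTL linear model, averaged.

    Segregants are split into ``folds`` random sets; QTL are detected and
    their effects fit in the training folds, and the variance explained by
    the fitted predictor is measured in the held-out fold.  Can be negative
    for null traits.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = G.n_segregants
    if n // folds < 10:
        raise ValueError("folds would contain fewer than 10 segregants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    r2s = []
    y = np.asarray(y, float)
    for f, test_idx in enumerate(np.array_split(order, folds)):
        train_idx = np.setdiff1d(order, test_idx)
        Gt = GenotypeMatrix(values=G.values[train_idx],
                            segregants=[G.segregants[i] for i in train_idx],
                            cross=np.asarray(G.cross)[train_idx],
                            markers=G.markers,
                            ref_parent_allele=G.ref_parent_allele)
        trace = forward_stepwise(y[train_idx], Gt, alpha=alpha, B=B,
                                 seed=int(rng.integers(2**31 - 1)))
        if not trace.selected:
            r2s.append(0.0)
            continue
        Xtr = np.column_stack([np.ones(len(train_idx)),
                               np.nan_to_num(G.values[np.ix_(train_idx, trace.selected)], nan=0.0)])
        beta, *_ = np.linalg.lstsq(Xtr, y[train_idx], rcond=None)
        Xte = np.column_stack([np.ones(len(test_idx)),
                               np.nan_to_num(G.values[np.ix_(test_idx, trace.selected)], nan=0.0)])
        pred = Xte @ beta
        resid = y[test_idx] - pred
        tot = y[test_idx] - y[test_idx].mean()
        r2s.append(1.0 - (resid @ resid) / (tot @ tot))
    return float(np.mean(r2s))
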
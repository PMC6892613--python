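"""Genotype containers, marker standardization and kinship construction.

Genotypes from a panel of haploid crosses are recoded against a single
reference parent strain: -1 where a segregant carries the reference parent's
allele, +1 otherwise, and missing (NaN) for every segregant of a cross whose
two parents carry the same allele at that marker (the marker does not
segregate there, so it is uninformative and completely confounded with the
cross).  Standardization gives every marker mean 0 / variance 1 over the
segregants for which it is informative; entries outside that scope are set to
0, which excludes them from genetic covariance exactly.

Kinship matrices are built from the standardized matrix M as MM' with one of
two normalizations: per-marker (divide by the marker count, average diagonal
approximately 1) or Gower centering (rescale by n/trace so the average
diagonal equals 1 exactly), and epistatic kernels as re-centered Hadamard
products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "StandardizedMatrix",
    "KinshipMatrix",
    "MarkerBins",
    "recode_biallelic",
    "standardize_markers",
    "kinship_simple",
    "gower_center",
    "gower_rescale",
    "hadamard",
    "bin_markers_by_maf",
    "build_partitioned_kinships",
]

PSD_TOL = 1e-8


@dataclass
class GenotypeMatrix:
    """Segregants x markers in {-1, +1, NaN}, coded against a reference parent."""

    values: np.ndarray                   # float, NaN = non-segregating in cross
    segregants: list[str]
    cross: np.ndarray                    # per-segregant cross id
    markers: pd.DataFrame
    ref_parent_allele: np.ndarray | None = None   # 0=major,1=minor panel coding

    @property
    def n_segregants(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def minor_allele_dosage(self) -> np.ndarray:
        """+1 where the segregant carries the panel minor allele, else -1."""
        if self.ref_parent_allele is None:
            raise ValueError("reference parent alleles unknown; cannot orient")
        flip = 1.0 - 2.0 * self.ref_parent_allele.astype(float)
        return self.values * flip[None, :]

    def subset_cross(self, cross_id: str) -> "GenotypeMatrix":
        rows = np.asarray(self.cross) == cross_id
        if not rows.any():
            raise KeyError(f"no segregants for cross {cross_id!r}")
        return GenotypeMatrix(
            values=self.values[rows],
            segregants=[s for s, r in zip(self.segregants, rows) if r],
            cross=np.asarray(self.cross)[rows],
            markers=self.markers,
            ref_parent_allele=self.ref_parent_allele,
        )

    def segregating_mask(self) -> np.ndarray:
        """Markers x 1 bool: segregates (non-missing) for at least one segregant."""
        return ~np.all(np.isnan(self.values), axis=0)


@dataclass
class StandardizedMatrix:
    """Mean-0 / variance-1 marker columns over their informative scope."""

    values: np.ndarray                   # zeros outside scope
    scope: np.ndarray                    # bool segregants x markers
    kept: np.ndarray                     # bool per input marker (non-constant)
    markers: pd.DataFrame                # rows of the kept markers

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class KinshipMatrix:
    values: np.ndarray
    normalization: str                   # "per-marker" | "gower"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self, tol: float = PSD_TOL) -> "KinshipMatrix":
        """Clip negative eigenvalues below -tol (with a warning) to 0."""
        w, v = np.linalg.eigh(self.values)
        if w.min() < -tol:
            warnings.warn(
                f"kinship has negative eigenvalue {w.min():.3e}; clipping to 0")
            w = np.clip(w, 0.0, None)
            self.values = (v * w) @ v.T
        return self


def recode_biallelic(
    alleles: np.ndarray,
    cross: np.ndarray,
    segregants: list[str],
    markers: pd.DataFrame,
    parent_alleles: dict[str, tuple[np.ndarray, np.ndarray]],
    reference_parent: np.ndarray,
) -> GenotypeMatrix:
    """Recode raw allele codes (0/1 panel coding) against a reference parent.

    ``parent_alleles`` maps each cross id to its two parental haplotypes; a
    marker at which both parents of a cross carry the same allele is set to
    missing for every segregant of that cross.
    """
    alleles = np.asarray(alleles)
    reference_parent = np.asarray(reference_parent)
    if alleles.shape[1] != len(markers) or reference_parent.shape != (len(markers),):
        raise ValueError("allele matrix / reference parent do not match markers")
    vals = np.where(alleles == reference_parent[None, :], -1.0, 1.0)
    cross = np.asarray(cross)
    for cid, (ha, hb) in parent_alleles.items():
        rows = cross == cid
        if not rows.any():
            continue
        fixed = np.asarray(ha) == np.asarray(hb)
        vals[np.ix_(rows, fixed)] = np.nan
    return GenotypeMatrix(values=vals, segregants=list(segregants), cross=cross,
                          markers=markers, ref_parent_allele=reference_parent)


def standardize_markers(G: GenotypeMatrix, scope: str = "across-segregating-crosses",
                        *, warn: bool = True) -> StandardizedMatrix:
    """Scale each marker to mean 0 / variance 1 over its informative segregants.

    ``scope="across-segregating-crosses"`` (the joint convention) centers each
    marker over all segregants of crosses in which it segregates;
    ``scope="within-cross"`` centers separately inside every cross.  Markers
    constant over their whole scope are excluded (with a warning).
    """
    V = G.values
    n, m = V.shape
    out = np.zeros((n, m))
    informative = ~np.isnan(V)
    if scope == "across-segregating-crosses":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(V, axis=0)
            sd = np.nanstd(V, axis=0)
        ok = informative.any(axis=0) & (np.nan_to_num(sd) > 0)
        std = (V - mu[None, :]) / np.where(ok, sd, 1.0)[None, :]
        std[~informative] = 0.0
        out[:, ok] = std[:, ok]
        kept = ok
    elif scope == "within-cross":
        kept = np.zeros(m, dtype=bool)
        for cid in pd.unique(np.asarray(G.cross)):
            rows = np.asarray(G.cross) == cid
            block = V[rows]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mu = np.nanmean(block, axis=0)
                sd = np.nanstd(block, axis=0)
            ok = (~np.all(np.isnan(block), axis=0)) & (np.nan_to_num(sd) > 0)
            std = (block - mu[None, :]) / np.where(ok, sd, 1.0)[None, :]
            std[:, ~ok] = 0.0
            std[~np.isfinite(std)] = 0.0
            out[np.ix_(rows, ok)] = std[:, ok]
            kept |= ok
    else:
        raise ValueError(f"unknown scope {scope!r}")
    n_dropped = int((~kept).sum())
    if n_dropped and warn:
        warnings.warn(f"excluded {n_dropped} markers constant in scope")
    return StandardizedMatrix(values=out[:, kept], scope=informative[:, kept],
                              kept=kept, markers=G.markers.loc[kept].reset_index(drop=True))


def kinship_simple(M: StandardizedMatrix) -> KinshipMatrix:
    """MM' divided by the marker count (average diagonal approximately 1)."""
    if M.m == 0:
        raise ValueError("no markers")
    K = (M.values @ M.values.T) / M.m
    return KinshipMatrix(values=K, normalization="per-marker")


def gower_rescale(K: np.ndarray) -> np.ndarray:
    tr = np.trace(K)
    if tr <= 0:
        raise ValueError("matrix trace is not positive; cannot Gower-center")
    return K * (K.shape[0] / tr)


def gower_center(M: StandardizedMatrix) -> KinshipMatrix:
    """Gower-centered relatedness MM' * n / tr(MM'): mean diagonal exactly 1."""
    if M.m == 0:
        raise ValueError("no markers")
    K = M.values @ M.values.T
    return KinshipMatrix(values=gower_rescale(K), normalization="gower")


def hadamard(K1: KinshipMatrix, K2: KinshipMatrix) -> KinshipMatrix:
    """Element-wise product kernel (pairwise epistasis), re-Gower-centered."""
    if K1.values.shape != K2.values.shape:
        raise ValueError("kinship dimensions differ")
    return KinshipMatrix(values=gower_rescale(K1.values * K2.values),
                         normalization="gower")


@dataclass
class MarkerBins:
    bin_edges: list[float]               # interior cut points on panel MAF
    assignment: pd.Series                # marker id -> bin index
    n_bins: int
    n_excluded: int = 0                  # markers without a MAF

    def members(self, b: int) -> pd.Index:
        return self.assignment.index[self.assignment == b]


def bin_markers_by_maf(markers: pd.DataFrame, edges: list[float] | None = None,
                       n_bins: int | None = None) -> MarkerBins:
    """Partition markers by panel MAF, by explicit cut points or equal counts.

    With ``edges``, bin b holds markers with edges[b-1] <= maf < edges[b]
    except that a marker exactly at a cut point goes to the upper bin (so the
    conventional rare/common split at 0.01 sends MAF == 0.01 to common).  With
    ``n_bins``, contiguous equal-count bins are formed from the MAF order.
    """
    if (edges is None) == (n_bins is None):
        raise ValueError("give exactly one of edges or n_bins")
    maf = markers["panel_maf"]
    ok = maf.notna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} markers without a panel MAF")
    ids = markers.loc[ok, "id"]
    vals = maf[ok].to_numpy(float)
    if edges is not None:
        assign = np.searchsorted(np.asarray(edges, float), vals, side="right")
        nb = len(edges) + 1
    else:
        nb = int(n_bins)
        if nb < 1:
            raise ValueError("n_bins must be >= 1")
        order = np.argsort(vals, kind="stable")
        assign = np.empty(len(vals), dtype=int)
        for b, chunk in enumerate(np.array_split(order, nb)):
            assign[chunk] = b
        # interior edges reported as the max MAF of each lower bin
        edges = []
        for b in range(nb - 1):
            edges.append(float(vals[assign == b].max()))
    return MarkerBins(bin_edges=list(edges), n_bins=nb,
                      assignment=pd.Series(assign, index=ids.to_numpy()),
                      n_excluded=n_excluded)


def build_partitioned_kinships(G: GenotypeMatrix, bins: MarkerBins) -> list[KinshipMatrix]:
    """One Gower-centered kinship per MAF bin, joint-standardization scope."""
    M = standardize_markers(G, scope="across-segregating-crosses", warn=False)
    ids = M.markers["id"].to_numpy()
    out = []
    for b in range(bins.n_bins):
        members = set(bins.members(b))
        cols = np.fromiter((mid in members for mid in ids), dtype=bool, count=len(ids))
        if not cols.any():
            raise ValueError(f"MAF bin {b} has no segregating markers")
        sub = StandardizedMatrix(values=M.values[:, cols], scope=M.scope[:, cols],
                                 kept=cols, markers=M.markers.loc[cols])
        out.append(gower_center(sub))
    return out
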
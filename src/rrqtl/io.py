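"""Readers and writers for the on-disk formats used across the pipeline.

Coordinates are 1-based inclusive everywhere (VCF convention).  Genotypes are
exchanged either as a TSV matrix (rows = segregants, columns = marker ids,
values -1/1/NA) with a sample-sheet sidecar mapping segregants to crosses, or
as a haploid VCF with one sample per segregant (missing genotype where the
marker does not segregate in the segregant's cross).  Marker maps, phenotypes
(long format) and kinships travel as TSV; ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, KinshipMatrix

__all__ = [
    "write_genotypes_tsv", "read_genotypes_tsv",
    "write_genotypes_vcf", "read_genotypes_vcf",
    "write_marker_map", "read_marker_map",
    "write_phenotypes", "read_phenotypes",
    "write_kinship", "read_kinship",
    "write_truth", "read_truth",
]

MARKER_COLS = ["chrom", "pos_bp", "pos_cM", "id", "ref_allele", "alt_allele",
               "panel_maf", "ancestral_allele"]


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path,
                        samples_path: str | Path) -> None:
    df = pd.DataFrame(G.values, index=G.segregants, columns=G.markers["id"])
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.index.name = "segregant"
    df.to_csv(path, sep="\t")
    pd.DataFrame({"segregant": G.segregants, "cross": G.cross}).to_csv(
        samples_path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path, samples_path: str | Path,
                       markers: pd.DataFrame) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    samples = pd.read_csv(samples_path, sep="\t").set_index("segregant")
    if list(df.columns) != markers["id"].tolist():
        raise ValueError("genotype columns do not match the marker map")
    cross = samples.loc[df.index, "cross"].to_numpy()
    return GenotypeMatrix(values=df.to_numpy(float), segregants=list(df.index),
                          cross=cross, markers=markers)


def write_genotypes_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Haploid VCF, one sample per segregant; './.'-style missing as '.'."""
    mk = G.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(mk["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.segregants) + "\n")
        ref_par = G.ref_parent_allele
        for j in range(G.n_markers):
            row = mk.iloc[j]
            # recoded -1 means "matches reference parent"; express as panel alleles
            gts = []
            for i in range(G.n_segregants):
                v = G.values[i, j]
                if np.isnan(v):
                    gts.append(".")
                else:
                    if ref_par is not None:
                        allele = int(ref_par[j]) if v == -1 else 1 - int(ref_par[j])
                    else:
                        allele = 0 if v == -1 else 1
                    gts.append(str(allele))
            fh.write(f"{row['chrom']}\t{row['pos_bp']}\t{row['id']}\t"
                     f"{row['ref_allele']}\t{row['alt_allele']}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_genotypes_vcf(path: str | Path, samples_path: str | Path,
                       reference_parent_allele: np.ndarray | None = None) -> GenotypeMatrix:
    """Read a haploid biallelic VCF back into a recoded GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    segregants = list(vcf.samples)
    rows = []
    alleles = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multiallelic record at {var.CHROM}:{var.POS}")
        gt = np.array([g[0] for g in var.genotypes], dtype=float)
        gt[gt < 0] = np.nan
        if np.any(gt[np.isfinite(gt)] > 1):
            raise ValueError(f"non-haploid/biallelic call at {var.CHROM}:{var.POS}")
        alleles.append(gt)
        rows.append({"chrom": var.CHROM, "pos_bp": var.POS, "id": var.ID,
                     "ref_allele": var.REF, "alt_allele": var.ALT[0]})
    markers = pd.DataFrame(rows)
    A = np.array(alleles).T          # segregants x markers, 0/1/NaN
    samples = pd.read_csv(samples_path, sep="\t").set_index("segregant")
    cross = samples.loc[segregants, "cross"].to_numpy()
    ref = reference_parent_allele
    if ref is None:
        ref = np.zeros(len(markers))
    vals = np.where(np.isnan(A), np.nan, np.where(A == ref[None, :], -1.0, 1.0))
    return GenotypeMatrix(values=vals, segregants=segregants, cross=cross,
                          markers=markers,
                          ref_parent_allele=np.asarray(ref, dtype=np.int8))


def write_marker_map(markers: pd.DataFrame, path: str | Path) -> None:
    markers[MARKER_COLS].to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MARKER_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    return df


def write_phenotypes(long: pd.DataFrame, path: str | Path) -> None:
    long.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"segregant", "cross", "replicate", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(need)}")
    return df


def write_kinship(K: KinshipMatrix, ids: list[str], path: str | Path) -> None:
    pd.DataFrame(K.values, index=ids, columns=ids).to_csv(path, sep="\t")


def read_kinship(path: str | Path) -> tuple[KinshipMatrix, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("kinship row/column ids disagree")
    return KinshipMatrix(values=df.to_numpy(float), normalization="gower"), list(df.index)


def write_truth(truth, path: str | Path) -> None:
    payload = {
        "causal": truth.causal.to_dict(orient="records"),
        "epistatic_pairs": truth.epistatic_pairs.to_dict(orient="records"),
        "h2_additive": truth.h2_additive,
        "h2_epistasis": truth.h2_epistasis,
        "repeatability": truth.repeatability,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path):
    from .simdata import TruthSet

    d = json.loads(Path(path).read_text())
    return TruthSet(
        causal=pd.DataFrame(d["causal"], columns=["marker", "effect"]),
        epistatic_pairs=pd.DataFrame(d["epistatic_pairs"],
                                     columns=["marker_a", "marker_b", "effect"]),
        h2_additive=d["h2_additive"], h2_epistasis=d["h2_epistasis"],
        repeatability=d["repeatability"], seed=d["seed"],
    )
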
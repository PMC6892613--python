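"""End-to-end orchestration: simulate -> map -> decompose -> fine-map -> annotate.

`simulate_experiment` wires the generator modules into the analysis-ready
containers (recoded joint genotype matrix, per-cross phenotypes, ground
truth); `run_pipeline` executes the full analysis chain on a desk-scale
configuration and writes every stage's tables plus a manifest sufficient to
re-run the analysis bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import simdata, genotypes, scan, vc, jointmap, finemap, popgen, io

logger = logging.getLogger("rrqtl")

__all__ = ["PipelineConfig", "RunManifest", "SimulatedExperiment",
           "simulate_experiment", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; every stochastic stage has its own seed."""

    out_dir: str = "rrqtl_out"
    n_strains: int = 200
    n_markers: int = 2000
    n_chroms: int = 8
    n_parents: int = 8
    n_progeny: int = 400
    n_qtl: int = 20
    n_replicates: int = 2
    h2_additive: float = 0.4
    repeatability: float = 0.7
    coupling_tau: float = 0.0
    sign_bias_recent: float = 0.5
    rare_target: float = 0.278
    alpha: float = 0.05
    permutations: int = 200
    pics_sims: int = 200
    window_kb: float = 50.0
    maf_cutoff: float = 0.01
    seed_panel: int = 11
    seed_meiosis: int = 12
    seed_effects: int = 13
    seed_phenotypes: int = 14
    seed_scan: int = 15

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages}, indent=2, default=str))


@dataclass
class SimulatedExperiment:
    panel: simdata.PopulationPanel
    design: simdata.CrossDesign
    G: genotypes.GenotypeMatrix          # recoded joint matrix, all crosses
    phenotypes: simdata.PhenotypeTable
    truth: simdata.TruthSet

    def y_by_cross(self, use_means: bool = True) -> dict[str, np.ndarray]:
        y = self.phenotypes.segregant_means() if use_means \
            else self.phenotypes.values[:, 0]
        cross = np.asarray(self.G.cross)
        return {cid: y[cross == cid] for cid in pd.unique(cross)}


def simulate_experiment(config: PipelineConfig | None = None, **overrides
                        ) -> SimulatedExperiment:
    """Simulate a full round-robin experiment from a configuration."""
    cfg = config or PipelineConfig()
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    panel = simdata.simulate_panel(cfg.n_strains, cfg.n_markers, cfg.n_chroms,
                                   rare_target=cfg.rare_target, seed=cfg.seed_panel)
    design = simdata.build_round_robin(panel, cfg.n_parents)
    per_cross = simdata.simulate_design_genotypes(panel, design, cfg.n_progeny,
                                                  seed=cfg.seed_meiosis)
    alleles = np.vstack(list(per_cross.values()))
    cross = np.concatenate([[cid] * cfg.n_progeny for cid in per_cross])
    segregants = [f"{cid}_{i:04d}" for cid in per_cross for i in range(cfg.n_progeny)]
    parent_alleles = {
        cid: (panel.haplotypes[design.parent_rows[pa]],
              panel.haplotypes[design.parent_rows[pb]])
        for (pa, pb), cid in zip(design.crosses, design.cross_ids)
    }
    ref = panel.haplotypes[design.parent_rows[design.parents[0]]]
    G = genotypes.recode_biallelic(alleles, cross, segregants, panel.markers,
                                   parent_alleles, ref)
    segregating = np.flatnonzero(~np.all(np.isnan(G.values), axis=0))
    truth = simdata.assign_effects(panel, cfg.n_qtl, coupling_tau=cfg.coupling_tau,
                                   sign_bias_recent=cfg.sign_bias_recent,
                                   seed=cfg.seed_effects,
                                   h2_additive=cfg.h2_additive,
                                   repeatability=cfg.repeatability,
                                   candidate_markers=segregating)
    phen = simdata.simulate_phenotypes(G, truth, n_replicates=cfg.n_replicates,
                                       seed=cfg.seed_phenotypes)
    return SimulatedExperiment(panel=panel, design=design, G=G,
                               phenotypes=phen, truth=phen.truth)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage and write its outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    t0 = stage("simulate")
    exp = simulate_experiment(config)
    io.write_marker_map(exp.panel.markers, out / "markers.tsv")
    io.write_genotypes_tsv(exp.G, out / "genotypes.tsv", out / "samples.tsv")
    io.write_phenotypes(exp.phenotypes.long, out / "phenotypes.tsv")
    io.write_truth(exp.truth, out / "truth.json")
    manifest.record("simulate", seconds=time.time() - t0,
                    n_segregants=exp.G.n_segregants, n_markers=exp.G.n_markers)

    t0 = stage("scan")
    y_by_cross = exp.y_by_cross()
    cross = np.asarray(exp.G.cross)
    traces = {}
    rows = []
    for cid, y_c in y_by_cross.items():
        Gc = exp.G.subset_cross(cid)
        y_std = (y_c - y_c.mean()) / y_c.std()
        tr = scan.forward_stepwise(y_std, Gc, alpha=config.alpha,
                                   B=config.permutations, seed=config.seed_scan)
        tr = scan.relocalize_peaks(y_std, Gc, tr)
        traces[cid] = tr
        for _, r in tr.steps.iterrows():
            if r["step"] < len(tr.selected):
                idx = int(r["marker_index"])
                lo, hi = scan.lod_drop_interval(y_std, Gc, idx,
                                               covariates=[s for s in tr.selected
                                                           if s != idx])
                mkr = exp.G.markers.iloc[idx]
                rows.append({"cross": cid, "marker": r["marker"],
                             "chrom": mkr["chrom"], "pos_bp": int(mkr["pos_bp"]),
                             "p": r["p"], "forwardstop": r["forwardstop"],
                             "ci_left_bp": int(exp.G.markers["pos_bp"].iloc[lo]),
                             "ci_right_bp": int(exp.G.markers["pos_bp"].iloc[hi])})
    qtl_cols = ["cross", "marker", "chrom", "pos_bp", "p", "forwardstop",
                "ci_left_bp", "ci_right_bp"]
    within_qtl = pd.DataFrame(rows, columns=qtl_cols)
    within_qtl.to_csv(out / "within_cross_qtl.tsv", sep="\t", index=False)
    manifest.record("scan", seconds=time.time() - t0, n_qtl=len(within_qtl))

    t0 = stage("vc")
    vc_results = {}
    for cid, y_c in y_by_cross.items():
        Gc = exp.G.subset_cross(cid)
        M = genotypes.standardize_markers(Gc, scope="within-cross", warn=False)
        K = genotypes.gower_center(M)
        y_std = (y_c - y_c.mean()) / y_c.std()
        fit = vc.additive_model(y_std, K)
        h2, h2_se = vc.variance_share(fit, ["A"], denominator=["A", "E"])
        vc_results[cid] = {"h2": h2, "h2_se": h2_se, **fit.as_dict()}
    bins = genotypes.bin_markers_by_maf(exp.G.markers, edges=[config.maf_cutoff])
    kinships = genotypes.build_partitioned_kinships(exp.G, bins)
    y_all = np.concatenate([(y - y.mean()) / y.std() for y in y_by_cross.values()])
    part = vc.joint_maf_partition_model(y_all, cross, kinships,
                                        names=["rare", "common"])
    share, share_se = vc.variance_share(part, ["rare"],
                                        denominator=["rare", "common"])
    vc_results["joint_partition"] = {"rare_share": share,
                                     "rare_share_se": share_se, **part.as_dict()}
    (out / "vc.json").write_text(json.dumps(vc_results, indent=2))
    manifest.record("vc", seconds=time.time() - t0)

    t0 = stage("jointmap")
    joint_qtls = jointmap.joint_forward_stepwise(
        y_by_cross, exp.G, alpha=config.alpha, B=config.permutations,
        seed=config.seed_scan)
    jdf = pd.DataFrame([{**q.__dict__, "per_cross_beta": json.dumps(q.per_cross_beta)}
                        for q in joint_qtls],
                       columns=["trait", "marker_index", "marker", "chrom",
                                "pos_bp", "pooled_t", "n_informative", "pvalue",
                                "forwardstop", "per_cross_beta", "mean_beta",
                                "panel_maf"])
    jdf.to_csv(out / "joint_qtl.tsv", sep="\t", index=False)
    manifest.record("jointmap", seconds=time.time() - t0, n_qtl=len(jdf))

    t0 = stage("finemap")
    gene_rows = []
    windows: dict[tuple[str, str], finemap.PICSWindow] = {}
    thresh = popgen.effect_threshold_from_variance(0.02)
    if len(within_qtl):
        for cid in y_by_cross:
            Gc = exp.G.subset_cross(cid)
            y_c = y_by_cross[cid]
            y_std = (y_c - y_c.mean()) / y_c.std()
            sel = traces[cid].selected
            for idx in sel:
                X = np.column_stack([np.ones(len(y_std)),
                                     np.nan_to_num(Gc.values[:, sel], nan=0.0)])
                beta, *_ = np.linalg.lstsq(X, y_std, rcond=None)
                resid = y_std - X @ beta
                eff = float(beta[1 + sel.index(idx)])
                if abs(eff) < thresh:
                    continue
                w = finemap.pics_window(y_std, Gc, idx, eff, resid,
                                        n_sims=config.pics_sims,
                                        window_kb=config.window_kb,
                                        seed=config.seed_scan, cross=cid)
                windows[(cid, exp.G.markers["id"].iloc[idx])] = w
    genes = _gene_annotation(exp.panel.markers)
    if len(within_qtl):
        shared = exp.design.crosses_sharing_parent()
        q = within_qtl.assign(trait="trait",
                              effect=[windows.get((r["cross"], r["marker"]),
                                                  None).effect
                                      if (r["cross"], r["marker"]) in windows else np.nan
                                      for _, r in within_qtl.iterrows()])
        q = q.dropna(subset=["effect"]).reset_index(drop=True)
        for i, j in finemap.find_overlapping_qtl(q, shared):
            w1 = windows[(q["cross"].iloc[i], q["marker"].iloc[i])]
            w2 = windows[(q["cross"].iloc[j], q["marker"].iloc[j])]
            comb = finemap.combine_cross_pair(w1, w2)
            if comb is None:
                continue
            gene_rows.append(finemap.aggregate_to_genes(comb, exp.G.markers, genes))
    if gene_rows:
        ranked = finemap.gene_fdr(pd.concat(gene_rows, ignore_index=True))
    else:
        ranked = pd.DataFrame(columns=["gene", "ppc_gene", "rank", "fdr"])
    ranked.to_csv(out / "gene_fdr.tsv", sep="\t", index=False)
    manifest.record("finemap", seconds=time.time() - t0, n_windows=len(windows),
                    n_gene_scores=len(ranked))

    t0 = stage("popgen")
    annotated = popgen.annotate_markers(exp.panel.markers, cutoff=config.maf_cutoff)
    annotated.to_csv(out / "markers_annotated.tsv", sep="\t", index=False)
    if len(jdf):
        jq = jdf.merge(annotated[["id", "class", "derived_freq", "age_class"]],
                       left_on="marker", right_on="id", how="left")
        jq.to_csv(out / "joint_qtl_annotated.tsv", sep="\t", index=False)
        binned = popgen.bin_effects_by_frequency(jq, bin_size=max(len(jq) // 5, 1))
        binned.to_csv(out / "effects_by_frequency.tsv", sep="\t", index=False)
    manifest.record("popgen", seconds=time.time() - t0)

    manifest.write(out / "manifest.json")
    return manifest


def _gene_annotation(markers: pd.DataFrame, gene_span: int = 2000,
                     spacing: int = 5000) -> pd.DataFrame:
    """Synthetic regular gene grid used when no GFF/BED annotation is given."""
    rows = []
    for c in pd.unique(markers["chrom"]):
        last = int(markers.loc[markers["chrom"] == c, "pos_bp"].max())
        g = 0
        for start in range(1, last + spacing, spacing):
            rows.append({"gene": f"{c}_g{g:04d}", "chrom": c, "start_bp": start,
                         "end_bp": start + gene_span})
            g += 1
    return pd.DataFrame(rows)
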
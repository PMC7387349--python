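"""End-to-end orchestration: simulate/load -> filter -> impute -> annotate ->
diversity -> structure -> LD/blocks -> sweep scan, with a reproducible report.

A single :class:`PipelineConfig` carries either a VCF (+ optional GFF3 /
FASTA / population table) or a :class:`~gbspop.simpanel.SimulationConfig`,
plus every stage threshold.  One global seed fans out to per-stage seeds by
fixed offsets so any stage can be re-run in isolation; identical config and
seed give byte-identical outputs (the manifest records a checksum per file).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import ld as ldm
from . import simpanel as sp
from . import structure as st
from . import sweepscan as sw
from . import variants as va

logger = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {"simulate": 11, "impute": 23, "structure": 37, "tree": 53}


def _stage_seed(seed: int, stage: str) -> int:
    return int((seed * 9_973 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1))


@dataclass
class PipelineConfig:
    # exactly one input source
    simulation: sp.SimulationConfig | None = None
    vcf: str | None = None
    pops: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    # filter stage
    maf_min: float = 0.05
    het_max: float = 0.1
    depth_min: int = 4
    missing_max: float = 0.30
    # diversity stage
    window: int = 100_000
    # structure stage
    prune_r2: float = 0.1
    prune_window: int = 500_000
    k_min: int = 1
    k_max: int = 4
    replicates: int = 5
    q_threshold: float = 0.70
    tree_method: str = "nj"
    bootstrap_reps: int = 0
    # ld stage
    ld_window: int = 500_000
    ld_bin: int = 25_000
    r2_threshold: float = 0.1
    ld_alpha: float = 0.05
    # sweep stage
    loading_threshold: float = 0.02
    loading_component: int = 1
    fst_z: float = 3.0
    min_block_kb: float = 400
    min_evidence: int = 2
    # run
    seed: int = 0
    out_dir: str = "gbspop_run"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.vcf is None):
            raise ValueError("config must set exactly one of 'simulation' or 'vcf'")
        for name in ("maf_min", "het_max", "missing_max", "prune_r2", "q_threshold",
                     "r2_threshold", "ld_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("window", "ld_window", "ld_bin", "depth_min"):
            if getattr(self, name) < 0 or (name != "depth_min" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sweeps = tuple(sp.SweepSpec(**s) for s in sim.pop("sweep_specs", []))
            if "n_per_pop" in sim and isinstance(sim["n_per_pop"], list):
                sim["n_per_pop"] = tuple(sim["n_per_pop"])
            sim = sp.SimulationConfig(**sim, sweep_specs=sweeps)
        return cls(simulation=sim, **raw)


@dataclass
class StageRecord:
    name: str
    n_records: int
    seconds: float


@dataclass
class RunReport:
    stages: list[StageRecord] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)  # file -> sha256
    rois: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _emit(report: RunReport, path: Path) -> None:
    report.manifest[path.name] = _sha256(path)


def run_full(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in order; any failure aborts naming the stage."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(params={k: v for k, v in asdict(cfg).items() if k != "simulation"})
    if cfg.simulation is not None:
        report.params["simulation"] = asdict(cfg.simulation)
    stage = "input"
    try:
        t0 = time.perf_counter()
        if cfg.simulation is not None:
            panel = sp.simulate_panel(cfg.simulation)
            gm, vt, ann = panel.genotypes, panel.variants, panel.annotation
            labels = panel.pop_labels
        else:
            gm, vt = va.read_vcf(cfg.vcf)
            ann = va.GenomeAnnotation.from_files(cfg.gff3, cfg.fasta) if cfg.gff3 and cfg.fasta else None
            labels = None
            if cfg.pops:
                pops = pd.read_csv(cfg.pops, sep="\t")
                lookup = dict(zip(pops.iloc[:, 0].astype(str), pops.iloc[:, 1].astype(str)))
                labels = np.array([lookup.get(s, "unknown") for s in gm.sample_ids], dtype=object)
        report.stages.append(StageRecord(stage, gm.n_loci, time.perf_counter() - t0))
        logger.info("input: %d samples x %d loci", gm.n_samples, gm.n_loci)

        stage = "filter"
        t0 = time.perf_counter()
        gm, vt, frep = va.filter_snps(gm, vt, cfg.maf_min, cfg.het_max, cfg.depth_min, cfg.missing_max)
        frep.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        _emit(report, out / "filter_report.tsv")
        report.stages.append(StageRecord(stage, gm.n_loci, time.perf_counter() - t0))
        report.summary["n_snps_retained"] = gm.n_loci

        stage = "impute"
        t0 = time.perf_counter()
        gm = va.impute_missing(gm, vt, seed=_stage_seed(cfg.seed, "impute"))
        report.stages.append(StageRecord(stage, gm.n_loci, time.perf_counter() - t0))

        stage = "annotate"
        t0 = time.perf_counter()
        if ann is not None:
            vt = va.annotate_sites(vt, ann)
            vt = va.annotate_effects(vt, ann)
        va.write_vcf(gm, vt, out / "filtered.vcf")
        vt.to_csv(out / "variants.tsv", sep="\t", index=False)
        _emit(report, out / "filtered.vcf")
        _emit(report, out / "variants.tsv")
        report.stages.append(StageRecord(stage, gm.n_loci, time.perf_counter() - t0))

        stage = "diversity"
        t0 = time.perf_counter()
        chrom_lengths = ann.chrom_lengths if ann is not None else None
        wt = dv.windowed_diversity(gm, vt, window=cfg.window, labels=labels, chrom_lengths=chrom_lengths)
        wt.to_csv(out / "window_stats.tsv", sep="\t", index=False, float_format="%.6g")
        _emit(report, out / "window_stats.tsv")
        dv.allele_stats(gm, vt).to_csv(out / "locus_stats.tsv", sep="\t", index=False, float_format="%.6g")
        _emit(report, out / "locus_stats.tsv")
        if labels is not None:
            am = dv.amova(gm, labels)
            am.to_frame().to_csv(out / "amova.tsv", sep="\t", index=False, float_format="%.6g")
            _emit(report, out / "amova.tsv")
            fstats = dv.f_statistics(gm, labels)
            report.summary.update({f"wc_{k}": v for k, v in fstats.items()})
        kin = dv.kinship_matrix(gm)
        pd.DataFrame(kin, index=gm.sample_ids, columns=gm.sample_ids).to_csv(
            out / "kinship.tsv", sep="\t", float_format="%.5g")
        _emit(report, out / "kinship.tsv")
        report.stages.append(StageRecord(stage, len(wt), time.perf_counter() - t0))

        stage = "structure"
        t0 = time.perf_counter()
        pruned_idx = st.ld_prune(gm, vt, r2_max=cfg.prune_r2, window_bp=cfg.prune_window)
        gm_pruned = gm.take_loci(pruned_idx)
        report.summary["n_pruned_snps"] = len(pruned_idx)
        pca = st.run_pca(gm)
        seed_st = _stage_seed(cfg.seed, "structure")
        if cfg.k_max - cfg.k_min >= 2:
            ksel = st.select_k(gm_pruned, range(cfg.k_min, cfg.k_max + 1),
                               replicates=cfg.replicates, seed=seed_st)
            ksel.table.to_csv(out / "delta_k.tsv", sep="\t", index=False, float_format="%.6g")
            _emit(report, out / "delta_k.tsv")
            chosen = ksel.chosen_k or 2
        else:
            chosen = max(cfg.k_min, 2)
        adm = st.admixture_em(gm_pruned, chosen, seed=seed_st)
        qdf = st.write_q_table(adm, gm.sample_ids, out / "q_matrix.tsv", threshold=cfg.q_threshold)
        _emit(report, out / "q_matrix.tsv")
        report.summary["chosen_k"] = chosen
        report.summary["assignment_counts"] = qdf["label"].value_counts().to_dict()
        if gm.n_samples <= 300:  # tree output is for panels a figure can hold
            from Bio import Phylo
            tree, _ = st.build_tree(gm, method=cfg.tree_method,
                                    bootstrap_reps=cfg.bootstrap_reps,
                                    seed=_stage_seed(cfg.seed, "tree"))
            Phylo.write(tree, out / "tree.nwk", "newick")
            _emit(report, out / "tree.nwk")
        report.stages.append(StageRecord(stage, chosen, time.perf_counter() - t0))

        stage = "ld"
        t0 = time.perf_counter()
        pairs = ldm.pairwise_r2(gm, vt, window_bp=cfg.ld_window)
        decay = ldm.ld_decay(pairs, bin_bp=cfg.ld_bin, r2_threshold=cfg.r2_threshold, alpha=cfg.ld_alpha)
        decay.bins.to_csv(out / "ld_decay.tsv", sep="\t", index=False, float_format="%.6g")
        _emit(report, out / "ld_decay.tsv")
        report.summary["ld_decay_bp"] = decay.decay_distance_bp
        pairs = ldm.annotate_dprime(gm, pairs)
        pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False, float_format="%.6g")
        _emit(report, out / "ld_pairs.tsv")
        blocks = ldm.gabriel_blocks(pairs, vt)
        ldm.blocks_to_frame(blocks).to_csv(out / "blocks.tsv", sep="\t", index=False, float_format="%.6g")
        _emit(report, out / "blocks.tsv")
        report.summary["n_blocks"] = len(blocks)
        report.stages.append(StageRecord(stage, len(pairs), time.perf_counter() - t0))

        stage = "sweep"
        t0 = time.perf_counter()
        lregs = sw.loading_regions(pca, vt, component=cfg.loading_component,
                                   threshold=cfg.loading_threshold)
        try:
            fruns = sw.fst_outlier_windows(wt, z=cfg.fst_z)
        except ValueError:
            fruns = pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "max_fst"])
        rois = sw.integrate_roi(lregs, fruns, blocks, min_block_kb=cfg.min_block_kb,
                                min_evidence=cfg.min_evidence)
        if labels is not None:
            rois = [sw.regional_pca(gm, vt, r, labels) for r in rois]
        sw.rois_to_frame(rois).to_csv(out / "roi.tsv", sep="\t", index=False, float_format="%.6g")
        _emit(report, out / "roi.tsv")
        if ann is not None:
            sw.genes_in_regions(rois, ann, blocks).to_csv(
                out / "roi_genes.tsv", sep="\t", index=False)
            _emit(report, out / "roi_genes.tsv")
        report.rois = rois
        report.summary["n_rois"] = len(rois)
        report.stages.append(StageRecord(stage, len(rois), time.perf_counter() - t0))

        stage = "report"
        write_report(report, out, gm=gm, vt=vt, wt=wt, labels=labels,
                     pairs=pairs, blocks=blocks, decay=decay, cfg=cfg)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc


def _scoped_window_means(gm, vt, wt, scopes, window, labels, chrom_lengths):
    """Mean windowed pi / theta / D with loci restricted per scope."""
    rows = []
    for label, mask in scopes.items():
        if mask.sum() == 0:
            continue
        sub_vt = vt.loc[mask].reset_index(drop=True)
        sub_gm = gm.take_loci(np.flatnonzero(mask))
        swt = dv.windowed_diversity(sub_gm, sub_vt, window=window, chrom_lengths=chrom_lengths)
        occ = swt[swt["n_snps"] > 0]
        rows.append({
            "scope": label, "n_snps": int(mask.sum()),
            "pi": occ["pi"].mean(), "theta_w": occ["theta_w"].mean(),
            "tajima_d": occ["tajima_d"].mean(),
        })
    return pd.DataFrame(rows)


def write_report(report: RunReport, out_dir, *, gm, vt, wt, labels, pairs, blocks, decay, cfg) -> None:
    """Summary tables: diversity by scope, per-chromosome LD/blocks, ROI."""
    out = Path(out_dir)
    chrom = vt["chrom"].astype(str)
    chrom_lengths = None

    scopes: dict[str, np.ndarray] = {"BC": np.ones(len(vt), bool)}
    for pre in ("B", "C"):
        m = chrom.str.startswith(pre).to_numpy()
        if m.any():
            scopes[pre] = m
    for ctx in ("coding", "synonymous", "non-synonymous", "intron", "intergenic"):
        m = ((vt["context"] == ctx) | (vt["effect"] == ctx)).to_numpy()
        if m.any():
            scopes[ctx] = m
    tab1 = _scoped_window_means(gm, vt, wt, scopes, cfg.window, labels, chrom_lengths)
    if labels is not None:
        per_pop = []
        for pop in pd.unique(labels):
            idx = np.flatnonzero(labels == pop)
            if idx.size < 2:
                continue
            sub = gm.take_samples(idx)
            sub, svt = va.recompute_locus_stats(sub, vt)
            poly = (svt["maf"] > 0).to_numpy()
            row = _scoped_window_means(sub.take_loci(np.flatnonzero(poly)),
                                       vt.loc[poly].reset_index(drop=True), None,
                                       {str(pop): np.ones(int(poly.sum()), bool)},
                                       cfg.window, None, chrom_lengths)
            per_pop.append(row)
        if per_pop:
            tab1 = pd.concat([tab1] + per_pop, ignore_index=True)
    tab1.to_csv(out / "summary_diversity.tsv", sep="\t", index=False, float_format="%.4g")
    _emit(report, out / "summary_diversity.tsv")

    rows = []
    group_masks = {"BC": np.ones(len(vt), bool)}
    for pre in ("B", "C"):
        m = chrom.str.startswith(pre).to_numpy()
        if m.any():
            group_masks[pre] = m
    for c in pd.unique(chrom):
        group_masks[c] = (chrom == c).to_numpy()
    bl_frame = ldm.blocks_to_frame(blocks)
    for label, m in group_masks.items():
        sel_chroms = set(chrom[m])
        sub_pairs = pairs[pairs["chrom"].astype(str).isin(sel_chroms)]
        sub_decay = ldm.ld_decay(sub_pairs, bin_bp=cfg.ld_bin,
                                 r2_threshold=cfg.r2_threshold, alpha=cfg.ld_alpha)
        sub_blocks = bl_frame[bl_frame["chrom"].isin(sel_chroms)]
        rows.append({
            "scope": label, "n_snps": int(m.sum()),
            "decay_kb": sub_decay.decay_distance_bp / 1000 if np.isfinite(sub_decay.decay_distance_bp) else np.nan,
            "mean_r2": float(sub_pairs["r2"].mean()) if len(sub_pairs) else np.nan,
            "n_blocks": int(len(sub_blocks)),
            "max_block_kb": float(sub_blocks["size_kb"].max()) if len(sub_blocks) else np.nan,
        })
    pd.DataFrame(rows).to_csv(out / "summary_ld.tsv", sep="\t", index=False, float_format="%.4g")
    _emit(report, out / "summary_ld.tsv")

    sw.rois_to_frame(report.rois).to_csv(out / "summary_roi.tsv", sep="\t", index=False, float_format="%.6g")
    _emit(report, out / "summary_roi.tsv")

    payload = {
        "params": report.params,
        "summary": report.summary,
        "stages": [asdict(s) for s in report.stages],
        "manifest": report.manifest,
    }
    (out / "manifest.json").write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
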
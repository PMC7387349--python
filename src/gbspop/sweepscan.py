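"""Multi-evidence scan for genomic regions under selection.

Three independent tracks are computed genome-wide — clusters of SNPs with
high absolute PC loadings, runs of outlier windowed F_ST, and large
haplotype blocks — and intervals where at least ``min_evidence`` distinct
evidence types overlap are reported as regions of interest (ROI).  Each ROI
is then verified by a regional PCA: the variance captured by the leading
components and the silhouette of the population labels on the first two PCs
quantify how strongly the region separates the subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ld import HaplotypeBlock
from .structure import PcaResult, run_pca
from .variants import GenomeAnnotation, GenotypeMatrix, MISSING


@dataclass(frozen=True)
class LoadingRegion:
    chrom: str
    start: int
    end: int
    n_snps: int
    max_abs_loading: float


@dataclass
class ROI:
    chrom: str
    start: int
    end: int
    evidence: frozenset
    n_snps: int = 0
    pc2_var: float = np.nan
    pc5_var: float = np.nan
    silhouette: float = np.nan

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("ROI start must precede end")
        if not self.evidence:
            raise ValueError("ROI needs at least one evidence type")

    @property
    def length_mbp(self) -> float:
        return (self.end - self.start) / 1e6


def loading_regions(pca: PcaResult, vt: pd.DataFrame, component: int = 1,
                    threshold: float = 0.02, gap_bp: int = 500_000,
                    min_snps: int = 5) -> list[LoadingRegion]:
    """Cluster loci whose |PC loading| exceeds ``threshold`` into regions.

    ``component`` is 1-based.  High-loading loci on a chromosome are joined
    by single linkage with inter-locus gap <= ``gap_bp``; clusters with at
    least ``min_snps`` members are reported.  Loadings are unit-norm per
    component, so the threshold is on the same scale regardless of panel
    size; the sign is ignored (eigenvector sign is arbitrary).
    """
    if not 1 <= component <= pca.loadings.shape[1]:
        raise IndexError(f"component {component} out of range")
    load = np.zeros(len(vt))
    load[pca.locus_index] = pca.loadings[:, component - 1]
    high = np.abs(load) > threshold
    regions = []
    for chrom, sub in vt.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        hit = idx[high[idx]]
        if hit.size == 0:
            continue
        pos = vt.loc[hit, "pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > gap_bp)
        for seg in np.split(np.arange(len(hit)), breaks + 1):
            if len(seg) >= min_snps:
                regions.append(LoadingRegion(
                    str(chrom), int(pos[seg[0]]), int(pos[seg[-1]]), len(seg),
                    float(np.abs(load[hit[seg]]).max()),
                ))
    return regions


def fst_outlier_windows(wt: pd.DataFrame, z: float = 3.0) -> pd.DataFrame:
    """Windows with F_ST >= mean + z*sd, merged into runs of adjacent windows.

    Returns one row per run (chrom, start, end, n_windows, max_fst).  Fewer
    than 10 finite windowed values make the threshold unstable and raise; a
    zero-sd (constant) track yields an empty, flagged result.
    """
    fst = wt["fst"].to_numpy(float)
    finite = np.isfinite(fst)
    if finite.sum() < 10:
        raise ValueError("need at least 10 finite windowed F_ST values")
    mu, sd = fst[finite].mean(), fst[finite].std()
    out_cols = ["chrom", "start", "end", "n_windows", "max_fst"]
    if sd <= 1e-12 * max(abs(mu), 1.0):
        res = pd.DataFrame(columns=out_cols)
        res.attrs["degenerate"] = True
        return res
    thr = mu + z * sd
    rows = []
    hit = finite & (fst >= thr)
    for chrom, sub in wt.groupby("chrom", sort=False):
        sub_hit = hit[sub.index.to_numpy()]
        idx = sub.index.to_numpy()[sub_hit]
        if idx.size == 0:
            continue
        run_break = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(np.arange(len(idx)), run_break + 1):
            members = idx[seg]
            rows.append({
                "chrom": str(chrom),
                "start": int(wt.loc[members[0], "start"]),
                "end": int(wt.loc[members[-1], "end"]),
                "n_windows": len(members),
                "max_fst": float(np.nanmax(fst[members])),
            })
    res = pd.DataFrame(rows, columns=out_cols)
    res.attrs["threshold"] = thr
    return res


def integrate_roi(loadings: list[LoadingRegion], fst_runs: pd.DataFrame,
                  blocks: list[HaplotypeBlock], min_block_kb: float = 400,
                  min_evidence: int = 2) -> list[ROI]:
    """Overlap the three evidence tracks into regions of interest.

    Evidence intervals (loading-region spans, outlier-F_ST runs, haplotype
    blocks of at least ``min_block_kb``) are pooled per chromosome; each
    maximal connected overlap component with >= ``min_evidence`` distinct
    evidence types becomes an ROI spanning the union of its members.
    """
    items: list[tuple[str, int, int, str]] = []
    for lr in loadings:
        items.append((lr.chrom, lr.start, lr.end, "loading"))
    for row in fst_runs.itertuples():
        items.append((str(row.chrom), int(row.start), int(row.end), "fst"))
    for b in blocks:
        if b.size_kb >= min_block_kb:
            items.append((b.chrom, b.start, b.end, "block"))

    rois = []
    by_chrom: dict[str, list] = {}
    for chrom, s, e, kind in items:
        by_chrom.setdefault(chrom, []).append((s, e, kind))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        comp: list[tuple[int, int, str]] = []
        comp_end = -1
        for s, e, kind in ivs + [(np.iinfo(np.int64).max, 0, "sentinel")]:
            if comp and s > comp_end:
                kinds = frozenset(k for _, _, k in comp)
                if len(kinds) >= min_evidence:
                    rois.append(ROI(chrom, min(c[0] for c in comp), max(c[1] for c in comp), kinds))
                comp = []
            if kind == "sentinel":
                break
            comp.append((s, e, kind))
            comp_end = max(comp_end, e)
    rois.sort(key=lambda r: (r.chrom, r.start))
    return rois


def regional_pca(gm: GenotypeMatrix, vt: pd.DataFrame, roi: ROI, labels) -> ROI:
    """Verify an ROI by PCA restricted to its loci.

    Records the variance explained by the first 2 and first 5 components
    and the silhouette of ``labels`` on the first-2-PC scores; regions with
    fewer than two polymorphic loci get an NA summary.
    """
    from sklearn.metrics import silhouette_score

    in_roi = ((vt["chrom"] == roi.chrom) & (vt["pos"] >= roi.start) & (vt["pos"] <= roi.end)).to_numpy()
    roi = replace(roi, n_snps=int(in_roi.sum()))
    if roi.n_snps < 2:
        return roi
    sub = gm.take_loci(np.flatnonzero(in_roi))
    if np.any(sub.dosage == MISSING):
        # regional verification tolerates residual missingness by mean fill
        d = sub.dosage.astype(float)
        obs = sub.observed
        p = np.where(obs, d, 0).sum(0) / np.maximum(obs.sum(0), 1)
        d = np.where(obs, d, np.round(p))
        sub = GenotypeMatrix(d.astype(np.int16), np.maximum(sub.depth, 1), sub.sample_ids)
    try:
        pca = run_pca(sub, scaling="center_only")
    except ValueError:
        return roi
    ve = pca.variance_explained
    roi = replace(roi, pc2_var=float(ve[:2].sum()), pc5_var=float(ve[:5].sum()))
    labels = np.asarray(labels)
    if len(np.unique(labels)) >= 2 and pca.scores.shape[1] >= 2:
        roi = replace(roi, silhouette=float(silhouette_score(pca.scores[:, :2], labels)))
    return roi


def genes_in_regions(rois: list[ROI], ann: GenomeAnnotation,
                     blocks: list[HaplotypeBlock] | None = None,
                     min_block_kb: float = 200) -> pd.DataFrame:
    """Genes overlapping each ROI (and optionally each large block).

    Reports gene id, coordinates and the overlap length with the region.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in ann.genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    regions = [("roi", i, r.chrom, r.start, r.end) for i, r in enumerate(rois)]
    for b in blocks or []:
        if b.size_kb >= min_block_kb:
            regions.append(("block", None, b.chrom, b.start, b.end))
    rows = []
    for kind, ridx, chrom, start, end in regions:
        for iv in sorted(trees.get(chrom, IntervalTree()).overlap(start, end + 1)):
            g = iv.data
            rows.append({
                "region_type": kind, "region_index": ridx, "chrom": chrom,
                "region_start": start, "region_end": end, "gene_id": g.gene_id,
                "gene_start": g.start, "gene_end": g.end,
                "overlap_bp": min(end, g.end) - max(start, g.start) + 1,
            })
    return pd.DataFrame(rows, columns=["region_type", "region_index", "chrom", "region_start",
                                       "region_end", "gene_id", "gene_start", "gene_end", "overlap_bp"])


def rank_rois(rois: list[ROI]) -> list[ROI]:
    """Order ROIs by strength: evidence count, then marker support, then span."""
    return sorted(rois, key=lambda r: (len(r.evidence), r.n_snps, r.end - r.start), reverse=True)


def scan_panel(gm: GenotypeMatrix, vt: pd.DataFrame, labels, *,
               window: int = 100_000, chrom_lengths=None, ld_window: int = 500_000,
               loading_threshold: float = 0.02, loading_component: int = 1,
               fst_z: float = 3.0, min_block_kb: float = 400, min_evidence: int = 2,
               use_blocks: bool = True, pca_scaling: str = "center_only",
               impute_seed: int = 0) -> tuple[list[ROI], dict]:
    """Run the three evidence tracks on a filtered panel and integrate ROIs.

    Convenience wrapper over the individual operations: windowed F_ST
    outlier runs, PC-loading regions (on a frequency-imputed copy) and
    Gabriel blocks (on the raw matrix, pairwise-complete).  Returns the
    integrated ROI list plus the intermediate tracks.
    """
    from . import diversity as dv
    from . import ld as ldm
    from .variants import impute_missing

    wt = dv.windowed_diversity(gm, vt, window=window, labels=labels, chrom_lengths=chrom_lengths)
    gm_imp = impute_missing(gm, vt, seed=impute_seed) if np.any(gm.dosage == MISSING) else gm
    pca = run_pca(gm_imp, scaling=pca_scaling)
    lregs = loading_regions(pca, vt, component=loading_component, threshold=loading_threshold)
    try:
        fruns = fst_outlier_windows(wt, z=fst_z)
    except ValueError:
        fruns = pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "max_fst"])
    if use_blocks:
        pairs = ldm.annotate_dprime(gm, ldm.pairwise_r2(gm, vt, window_bp=ld_window))
        blocks = ldm.gabriel_blocks(pairs, vt)
    else:
        pairs, blocks = pd.DataFrame(), []
    rois = integrate_roi(lregs, fruns, blocks, min_block_kb=min_block_kb, min_evidence=min_evidence)
    rois = [regional_pca(gm_imp, vt, r, labels) for r in rois]
    tracks = {"windows": wt, "loading_regions": lregs, "fst_runs": fruns,
              "blocks": blocks, "pairs": pairs, "pca": pca}
    return rois, tracks


def rois_to_frame(rois: list[ROI]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end, "length_mbp": r.length_mbp,
          "evidence": "+".join(sorted(r.evidence)), "n_snps": r.n_snps,
          "pc2_var": r.pc2_var, "pc5_var": r.pc5_var, "silhouette": r.silhouette}
         for r in rois],
        columns=["chrom", "start", "end", "length_mbp", "evidence", "n_snps",
                 "pc2_var", "pc5_var", "silhouette"],
    )
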
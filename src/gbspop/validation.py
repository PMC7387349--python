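"""Simulation experiments that validate estimator calibration end to end.

Each function simulates panels under known truth with this package's own
generator, runs the corresponding estimator, and returns the recovered
quantity, so calibration can be checked against the generating parameters:
Weir–Cockerham multilocus F_ST against the Balding–Nichols differentiation
parameter, EM admixture memberships and Evanno ΔK against the true
two-population split, and the integrated sweep scan against a planted
selective sweep.
"""

from __future__ import annotations

import numpy as np

from . import structure as st
from . import sweepscan as sw
from .diversity import weir_cockerham_fst
from .simpanel import SimulationConfig, SweepSpec, simulate_panel
from .variants import filter_snps, impute_missing


def _seed(base: int, k: int) -> int:
    return int((base * 100_003 + k) % (2**31 - 1))


def bn_fst_recovery(n_seeds: int = 30, n_per_pop: int = 200, n_loci: int = 5000,
                    fst_param: float = 0.15, base_seed: int = 0) -> dict:
    """Multilocus WC F_ST across replicate Balding–Nichols panels."""
    values = []
    for k in range(n_seeds):
        cfg = SimulationConfig(n_per_pop=(n_per_pop, n_per_pop), n_chrom=2,
                               chrom_length=25_000_000, n_loci_per_chrom=n_loci // 2,
                               fst_param=fst_param, selfing_rate=0.0, missing_rate=0.0,
                               depth_mean=30, seed=_seed(base_seed, k), with_annotation=False)
        panel = simulate_panel(cfg)
        values.append(weir_cockerham_fst(panel.genotypes, panel.pop_labels))
    values = np.asarray(values)
    return {"mean": float(values.mean()), "sd": float(values.std()),
            "values": values.tolist(), "truth": fst_param, "n": n_seeds}


def _two_pop_panel(seed: int, n_per_pop=(100, 100), n_loci_per_chrom=1000,
                   fst_param=0.15):
    cfg = SimulationConfig(n_per_pop=n_per_pop, n_chrom=2, chrom_length=10_000_000,
                           n_loci_per_chrom=n_loci_per_chrom, fst_param=fst_param,
                           selfing_rate=0.82, missing_rate=0.05, depth_mean=10,
                           seed=seed, with_annotation=False)
    panel = simulate_panel(cfg)
    gm, vt, _ = filter_snps(panel.genotypes, panel.variants)
    gm = impute_missing(gm, vt, seed=seed + 1)
    return gm, vt, panel.pop_labels


def admixture_q_accuracy(n_seeds: int = 5, base_seed: int = 0) -> dict:
    """Mean |Q - truth| of the K=2 EM admixture fit after label alignment."""
    from scipy.optimize import linear_sum_assignment

    maes = []
    for k in range(n_seeds):
        gm, vt, labels = _two_pop_panel(_seed(base_seed, 40 + k))
        res = st.admixture_em(gm, K=2, seed=_seed(base_seed, 60 + k),
                              max_iter=500, tol=1e-4)
        truth = np.stack([(labels == "SP1").astype(float),
                          (labels == "SP2").astype(float)], axis=1)
        cost = np.array([[np.abs(res.Q[:, i] - truth[:, j]).mean() for j in range(2)]
                         for i in range(2)])
        r, c = linear_sum_assignment(cost)
        maes.append(float(cost[r, c].mean()))
    return {"mean": float(np.mean(maes)), "values": maes, "n": n_seeds}


def delta_k_selection_rate(n_trials: int = 10, base_seed: int = 0) -> dict:
    """Fraction of two-population panels for which Evanno ΔK picks K = 2."""
    hits = 0
    for t in range(n_trials):
        gm, vt, _ = _two_pop_panel(_seed(base_seed, 80 + t), n_per_pop=(60, 60),
                                   n_loci_per_chrom=300)
        sel = st.select_k(gm, range(1, 5), replicates=5,
                          seed=_seed(base_seed, 120 + t), max_iter=200, tol=1e-3)
        hits += sel.chosen_k == 2
    return {"rate": hits / n_trials, "n": n_trials}


SWEEP_INTERVAL = ("B3", 20_000_000, 21_000_000)


def _sweep_scan_panel(seed: int, with_sweep: bool):
    sweeps = ()
    if with_sweep:
        chrom, s, e = SWEEP_INTERVAL
        sweeps = (SweepSpec(chrom, s, e, target_pop=1, haplotype_fraction=0.9,
                            extra_loci=120),)
    cfg = SimulationConfig(n_per_pop=(100, 25), n_chrom=17, chrom_length=55_000_000,
                           n_loci_per_chrom=1200, fst_param=0.1, selfing_rate=0.82,
                           missing_rate=0.05, depth_mean=10, seed=seed,
                           with_annotation=False, sweep_specs=sweeps)
    panel = simulate_panel(cfg)
    gm, vt, _ = filter_snps(panel.genotypes, panel.variants)
    rois, _ = sw.scan_panel(gm, vt, panel.pop_labels, use_blocks=False,
                            chrom_lengths=panel.annotation.chrom_lengths,
                            impute_seed=seed + 1)
    return rois


def sweep_roi_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """How often the planted 1-Mb sweep is the top-ranked ROI (>= 2 evidence)."""
    chrom, s, e = SWEEP_INTERVAL
    hits, jaccards = 0, []
    for k in range(n_seeds):
        rois = _sweep_scan_panel(_seed(base_seed, 200 + k), with_sweep=True)
        ranked = sw.rank_rois(rois)
        if not ranked:
            jaccards.append(0.0)
            continue
        top = ranked[0]
        ok = (top.chrom == chrom and top.start < e and top.end > s
              and len(top.evidence) >= 2)
        hits += ok
        inter = max(0, min(top.end, e) - max(top.start, s))
        union = max(top.end, e) - min(top.start, s)
        jaccards.append(inter / union if ok else 0.0)
    return {"rate": hits / n_seeds, "mean_jaccard": float(np.mean(jaccards)), "n": n_seeds}


def null_roi_counts(n_seeds: int = 10, base_seed: int = 0) -> dict:
    """ROI counts on sweep-free panels (false-positive control)."""
    counts = [len(_sweep_scan_panel(_seed(base_seed, 300 + k), with_sweep=False))
              for k in range(n_seeds)]
    return {"mean": float(np.mean(counts)), "counts": counts, "n": n_seeds}
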
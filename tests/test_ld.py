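"""Linkage disequilibrium: r^2, decay, D' confidence intervals, Gabriel blocks."""

import numpy as np
import pandas as pd
import pytest

from gbspop.ld import (
    RECOMB_CI_HIGH,
    STRONG_LD_CI_HIGH,
    STRONG_LD_CI_LOW,
    annotate_dprime,
    blocks_to_frame,
    dprime_ci,
    gabriel_blocks,
    ld_decay,
    min_markers_for_gwas,
    pairwise_r2,
)
from gbspop.variants import recompute_locus_stats

from conftest import make_gm, make_vt


def _panel(dosage, positions):
    gm = make_gm(dosage)
    _, vt = recompute_locus_stats(gm, make_vt(positions))
    return gm, vt


# ---------------------------------------------------------------------------
# composite r^2
# ---------------------------------------------------------------------------

def test_r2_identical_and_repulsion_columns():
    rng = np.random.default_rng(0)
    col = rng.binomial(2, 0.5, 200)
    gm, vt = _panel(np.column_stack([col, col, 2 - col]), [100, 200, 300])
    pairs = pairwise_r2(gm, vt)
    assert len(pairs) == 3
    np.testing.assert_allclose(pairs["r2"], 1.0, atol=1e-12)
    assert (pairs["p_value"] < 1e-10).all()


def test_r2_independent_loci_at_noise_level():
    rng = np.random.default_rng(1)
    n = 500
    dosage = rng.binomial(2, 0.5, (n, 40))
    gm, vt = _panel(dosage, np.arange(40) * 1000 + 1)
    pairs = pairwise_r2(gm, vt)
    assert pairs["r2"].mean() == pytest.approx(1 / n, rel=0.5)


def test_r2_restricted_to_window_and_chromosome():
    rng = np.random.default_rng(2)
    dosage = rng.binomial(2, 0.5, (50, 4))
    gm = make_gm(dosage)
    vt = make_vt([1, 400_000, 900_000, 100])
    vt.loc[3, "chrom"] = "B2"
    _, vt = recompute_locus_stats(gm, vt)
    pairs = pairwise_r2(gm, vt, window_bp=500_000)
    got = set(zip(pairs["pos_i"], pairs["pos_j"]))
    assert got == {(1, 400_000), (400_000, 900_000)}  # 1-900000 too far; B2 separate


# ---------------------------------------------------------------------------
# decay
# ---------------------------------------------------------------------------

def _pair_table(dists, r2s, p=0.01):
    return pd.DataFrame({
        "chrom": "B1", "i": 0, "j": 1, "pos_i": 0, "pos_j": dists,
        "dist": dists, "n": 100, "r2": r2s, "p_value": p,
    })


def test_decay_at_first_bin_below_threshold():
    # bin means 0.5, 0.3, 0.09 -> decay at the third bin's left edge (50 kb)
    dists = [10_000, 30_000, 60_000]
    curve = ld_decay(_pair_table(dists, [0.5, 0.3, 0.09]))
    assert curve.decay_distance_bp == 50_000


def test_decay_never_below_threshold_is_na():
    curve = ld_decay(_pair_table([10_000, 40_000], [0.5, 0.4]))
    assert np.isnan(curve.decay_distance_bp)
    assert "never fell" in curve.message


def test_decay_requires_significant_pairs():
    curve = ld_decay(_pair_table([10_000], [0.5], p=0.9))
    assert np.isnan(curve.decay_distance_bp)
    assert "no significant pairs" in curve.message


def test_decay_monotone_in_threshold():
    # a higher r^2 threshold is crossed earlier, so the decay distance is
    # non-increasing in the threshold
    rng = np.random.default_rng(3)
    dists = rng.integers(0, 400_000, 2000)
    r2s = np.clip(0.6 * np.exp(-dists / 120_000) + rng.normal(0, 0.02, 2000), 0, 1)
    tab = _pair_table(dists, r2s)
    prev = np.inf
    for thr in (0.05, 0.1, 0.2, 0.4):
        d = ld_decay(tab, r2_threshold=thr).decay_distance_bp
        d = np.inf if np.isnan(d) else d
        assert d <= prev
        prev = d


# ---------------------------------------------------------------------------
# D' confidence intervals
# ---------------------------------------------------------------------------

def test_dprime_complete_ld():
    # only haplotypes AB and ab: half 0/0 pairs, half 2/2 pairs
    dosage = np.vstack([np.tile([0, 0], (250, 1)), np.tile([2, 2], (250, 1))])
    dp, lo, hi = dprime_ci(make_gm(dosage), 0, 1)
    assert dp == pytest.approx(1.0)
    assert lo >= 0.9 and hi == 1.0


def test_dprime_equilibrium_narrow_low_ci():
    rng = np.random.default_rng(4)
    dosage = rng.binomial(2, 0.5, (500, 2))
    dp, lo, hi = dprime_ci(make_gm(dosage), 0, 1)
    assert dp < 0.2
    assert hi < 0.9


def test_dprime_tiny_sample_wide_ci():
    rng = np.random.default_rng(5)
    dosage = rng.binomial(2, 0.5, (5, 2))
    dp, lo, hi = dprime_ci(make_gm(dosage), 0, 1)
    assert hi - lo > 0.5


def test_dprime_requires_polymorphic_loci():
    dosage = np.column_stack([np.zeros(20, int), np.random.default_rng(0).binomial(2, 0.5, 20)])
    with pytest.raises(ValueError):
        dprime_ci(make_gm(dosage), 0, 1)


# ---------------------------------------------------------------------------
# Gabriel blocks
# ---------------------------------------------------------------------------

def brute_force_blocks(pairs, vt):
    """Exhaustive enumeration of admissible intervals + the same
    largest-span-first, leftmost-tie-break overlap resolution."""
    classes = {}
    for row in pairs.itertuples():
        strong = row.ci_low >= STRONG_LD_CI_LOW and row.ci_high >= STRONG_LD_CI_HIGH
        recomb = row.ci_high < RECOMB_CI_HIGH
        classes[(row.i, row.j)] = "strong" if strong else ("recomb" if recomb else "none")
    loci = sorted(set(pairs["i"]) | set(pairs["j"]))
    admissible = []
    for a in loci:
        for b in loci:
            if b <= a or classes.get((a, b), "none") != "strong":
                continue
            inside = [c for (x, y), c in classes.items() if a <= x and y <= b and c != "none"]
            if inside and sum(c == "strong" for c in inside) / len(inside) >= 0.95:
                admissible.append((a, b))
    admissible.sort(key=lambda ab: (-(vt.loc[ab[1], "pos"] - vt.loc[ab[0], "pos"]), vt.loc[ab[0], "pos"]))
    taken = []
    for a, b in admissible:
        if all(b < s or a > e for s, e in taken):
            taken.append((a, b))
    return sorted(taken)


def _random_ci_pairs(rng, n_loci, positions):
    rows = []
    for i in range(n_loci):
        for j in range(i + 1, n_loci):
            hi = rng.choice([1.0, 0.99, 0.95, 0.8, 0.5])
            lo = max(0.0, hi - rng.choice([0.05, 0.3, 0.6]))
            rows.append({"chrom": "B1", "i": i, "j": j, "pos_i": positions[i],
                         "pos_j": positions[j], "dist": positions[j] - positions[i],
                         "n": 100, "r2": 0.5, "p_value": 0.01, "dprime": hi,
                         "ci_low": lo, "ci_high": hi, "informative": True,
                         "em_converged": True})
    return pd.DataFrame(rows)


def test_gabriel_matches_exhaustive_enumeration():
    rng = np.random.default_rng(6)
    for trial in range(25):
        n_loci = int(rng.integers(3, 13))
        positions = np.sort(rng.choice(np.arange(1, 2000), n_loci, replace=False))
        vt = make_vt(positions)
        pairs = _random_ci_pairs(rng, n_loci, positions)
        blocks = gabriel_blocks(pairs, vt)
        got = sorted((b.first, b.last) for b in blocks)
        assert got == brute_force_blocks(pairs, vt), f"trial {trial}"


def test_two_perfectly_linked_snps_one_block():
    dosage = np.vstack([np.tile([0, 0], (250, 1)), np.tile([2, 2], (250, 1))])
    gm, vt = _panel(dosage, [1000, 3000])
    pairs = annotate_dprime(gm, pairwise_r2(gm, vt))
    blocks = gabriel_blocks(pairs, vt)
    assert len(blocks) == 1 and blocks[0].n_snps == 2
    assert blocks[0].size_kb == pytest.approx(2.0)


def test_all_recombination_no_blocks():
    rng = np.random.default_rng(7)
    dosage = rng.binomial(2, 0.5, (500, 6))
    gm, vt = _panel(dosage, np.arange(6) * 500 + 1)
    pairs = annotate_dprime(gm, pairwise_r2(gm, vt))
    assert gabriel_blocks(pairs, vt) == []


def test_three_linked_two_independent():
    rng = np.random.default_rng(8)
    col = np.r_[np.zeros(250, int), np.full(250, 2)]
    noise = rng.binomial(2, 0.5, (500, 2))
    dosage = np.column_stack([col, col, col, noise])
    gm, vt = _panel(dosage, [100, 200, 300, 400, 500])
    pairs = annotate_dprime(gm, pairwise_r2(gm, vt))
    blocks = gabriel_blocks(pairs, vt)
    assert len(blocks) == 1
    assert (blocks[0].first, blocks[0].last) == (0, 2)


def test_planted_sweep_covered_by_outstanding_block():
    """On mosaic-background panels, the swept interval carries a haplotype
    block at least as large as the 95th percentile of background blocks."""
    from gbspop.simpanel import SimulationConfig, SweepSpec, simulate_panel
    from gbspop.variants import filter_snps

    n_seeds = 20
    hits = 0
    for seed in range(n_seeds):
        cfg = SimulationConfig(n_per_pop=(118, 2), n_chrom=1, chrom_length=10_000_000,
                               n_loci_per_chrom=600, fst_param=0.02, selfing_rate=0.9,
                               missing_rate=0.02, seed=seed, n_founder_haplotypes=6,
                               recomb_scale_bp=100_000, with_annotation=False,
                               sweep_specs=(SweepSpec("B1", 4_000_000, 5_000_000, 0, 0.9),))
        panel = simulate_panel(cfg)
        gm, vt, _ = filter_snps(panel.genotypes, panel.variants)
        pairs = annotate_dprime(gm, pairwise_r2(gm, vt))
        bf = blocks_to_frame(gabriel_blocks(pairs, vt))
        in_sweep = bf[(bf["start"] < 5_000_000) & (bf["end"] > 4_000_000)]
        outside = bf.drop(in_sweep.index)
        q95 = outside["size_kb"].quantile(0.95) if len(outside) else 0.0
        if len(in_sweep) and in_sweep["size_kb"].max() >= q95:
            hits += 1
    assert hits >= 0.9 * n_seeds


# ---------------------------------------------------------------------------
# marker sizing
# ---------------------------------------------------------------------------

def test_min_markers_examples():
    assert min_markers_for_gwas(1_284_000, 700) == 1834
    assert min_markers_for_gwas(1_544_000, 700) == 2206
    assert min_markers_for_gwas(1_000, 100) == 10


def test_min_markers_rejects_nonpositive():
    with pytest.raises(ValueError):
        min_markers_for_gwas(0, 700)
    with pytest.raises(ValueError):
        min_markers_for_gwas(1000, -1)
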
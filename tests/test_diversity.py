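"""Diversity statistics: locus summaries, windowed scans, F_ST, AMOVA, kinship."""

import numpy as np
import pytest

from gbspop.diversity import (
    allele_stats,
    amova,
    f_statistics,
    kinship_matrix,
    weir_cockerham_fst,
    windowed_diversity,
)
from conftest import make_gm, make_vt


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def test_allele_stats_hand_values():
    # locus 0: p = 0.5 -> He = 0.5, PIC = 0.5 - 2*(0.25^2) = 0.375
    # locus 1: monomorphic; locus 2: all heterozygotes
    dosage = np.array([[0, 0, 1], [2, 0, 1], [0, 0, 1], [2, 0, 1]])
    st = allele_stats(make_gm(dosage))
    assert st.loc[0, "he"] == pytest.approx(0.5)
    assert st.loc[0, "pic"] == pytest.approx(0.375)
    assert st.loc[1, "he"] == 0 and st.loc[1, "pic"] == 0
    assert st.loc[2, "ho"] == 1.0


def test_pic_never_exceeds_he(small_panel):
    st = allele_stats(small_panel.genotypes)
    ok = st.dropna()
    assert (ok["pic"] <= ok["he"] + 1e-12).all()
    poly = ok[ok["maf"] > 0]
    assert (poly["pic"] < poly["he"]).all()


# ---------------------------------------------------------------------------
# windowed diversity
# ---------------------------------------------------------------------------

def test_pi_two_haplotypes_three_differences():
    # one diploid sample heterozygous at 3 sites: its two gametes differ at
    # 3 positions -> k-hat = 3, pi = 3e-5 over a 100-kb window; and with
    # n = 2 Tajima's D is identically zero
    dosage = np.array([[1, 1, 1]])
    wt = windowed_diversity(make_gm(dosage), make_vt([10, 20, 30]), window=100_000)
    assert wt.loc[0, "pi"] == pytest.approx(3e-5)
    assert wt.loc[0, "S"] == 3
    assert wt.loc[0, "tajima_d"] == pytest.approx(0.0)


def test_watterson_theta_n4():
    # 2 diploids (n = 4), 5 segregating sites, 1-kb window:
    # a1 = 1 + 1/2 + 1/3 ; theta_w = 5 / (a1 * 1000) = 2.727e-3
    rng = np.random.default_rng(0)
    dosage = np.array([[1, 1, 0, 2, 1], [0, 1, 1, 1, 2]])
    wt = windowed_diversity(make_gm(dosage), make_vt([100, 200, 300, 400, 500]), window=1000)
    assert wt.loc[0, "theta_w"] == pytest.approx(5 / ((1 + 0.5 + 1 / 3) * 1000), rel=1e-9)


def brute_force_pi(dosage, window_length):
    """Mean pairwise difference count over expanded pseudo-haplotypes."""
    haps = []
    for row in dosage:
        h1 = (row >= 1).astype(int)   # one ALT copy goes to hap1
        h2 = (row == 2).astype(int)
        haps.append(h1)
        haps.append(h2)
    haps = np.array(haps)
    m = len(haps)
    total = sum(np.sum(haps[i] != haps[j]) for i in range(m) for j in range(i + 1, m))
    return total / (m * (m - 1) / 2) / window_length


def test_windowed_pi_matches_brute_force_pairwise_differences():
    rng = np.random.default_rng(42)
    for trial in range(5):
        n, L = rng.integers(4, 21), rng.integers(5, 51)
        dosage = rng.binomial(2, rng.uniform(0.1, 0.9, L), (n, L)).astype(np.int16)
        wt = windowed_diversity(make_gm(dosage), make_vt(np.arange(1, L + 1) * 10), window=10_000)
        assert wt.loc[0, "pi"] == pytest.approx(brute_force_pi(dosage, 10_000), rel=1e-9)


def test_windowed_diversity_tiles_and_empty_windows(small_panel):
    wt = windowed_diversity(small_panel.genotypes, small_panel.variants,
                            chrom_lengths=small_panel.annotation.chrom_lengths)
    for chrom, sub in wt.groupby("chrom"):
        starts = sub["start"].to_numpy()
        assert (np.diff(starts) == 100_000).all()
    empty = wt[wt["n_snps"] == 0]
    assert empty["pi"].isna().all()
    assert (wt["n_snps"].sum()) == small_panel.genotypes.n_loci
    occupied = wt[wt["n_snps"] > 0]
    assert (occupied["pi"] >= 0).all() and (occupied["theta_w"] >= 0).all()


def test_window_must_be_positive(small_panel):
    with pytest.raises(ValueError):
        windowed_diversity(small_panel.genotypes, small_panel.variants, window=0)


def test_tajima_d_negative_in_swept_windows():
    """A founder-haplotype sweep leaves rare recent variation: window D
    falls below the panel median in the large majority of replicates."""
    from gbspop.simpanel import SimulationConfig, SweepSpec, simulate_panel

    below = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = SimulationConfig(n_per_pop=(40, 40), n_chrom=1, chrom_length=5_000_000,
                               n_loci_per_chrom=250, fst_param=0.05, selfing_rate=0.5,
                               missing_rate=0.0, depth_mean=30, seed=seed,
                               with_annotation=False,
                               sweep_specs=(SweepSpec("B1", 1_000_000, 2_000_000, 0, 0.95),))
        panel = simulate_panel(cfg)
        wt = windowed_diversity(panel.genotypes, panel.variants,
                                chrom_lengths=panel.annotation.chrom_lengths)
        occ = wt[np.isfinite(wt["tajima_d"])]
        sweep_w = occ[(occ["start"] >= 1_000_000) & (occ["end"] <= 2_000_000)]
        if len(sweep_w) and sweep_w["tajima_d"].mean() < occ["tajima_d"].median():
            below += 1
    assert below >= 0.9 * n_seeds


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def test_fst_fixed_opposite_populations():
    dosage = np.array([[0] * 5, [0] * 5, [0] * 5, [2] * 5, [2] * 5, [2] * 5])
    labels = ["P1"] * 3 + ["P2"] * 3
    assert weir_cockerham_fst(make_gm(dosage), labels) == pytest.approx(1.0)


def test_fst_identical_populations_not_positive():
    rng = np.random.default_rng(3)
    block = rng.binomial(2, rng.uniform(0.2, 0.8, 300), (40, 300))
    dosage = np.vstack([block, block])
    labels = ["P1"] * 40 + ["P2"] * 40
    assert weir_cockerham_fst(make_gm(dosage), labels) <= 0


def test_fst_requires_two_populations(small_panel):
    with pytest.raises(ValueError):
        weir_cockerham_fst(small_panel.genotypes, ["P1"] * small_panel.genotypes.n_samples)


def test_fst_pairwise_mode(small_panel):
    out = weir_cockerham_fst(small_panel.genotypes, small_panel.pop_labels, mode="pairwise_pops")
    assert set(out.columns) == {"pop1", "pop2", "fst"}
    assert len(out) == 1
    assert 0 < out.loc[0, "fst"] < 1


def test_fis_reflects_inbreeding(small_panel):
    stats = f_statistics(small_panel.genotypes, small_panel.pop_labels)
    # selfing_rate 0.8 in the fixture drives a high within-population fixation index
    assert stats["fis"] > 0.5
    assert stats["fit"] >= stats["fst"]


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def test_amova_fixed_populations_all_among():
    dosage = np.array([[0] * 6] * 4 + [[2] * 6] * 4)
    labels = ["P1"] * 4 + ["P2"] * 4
    res = amova(make_gm(dosage), labels)
    assert res.percent["among_pops"] == pytest.approx(100.0)
    assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-6)


def test_amova_permuted_labels_small_among_component():
    rng = np.random.default_rng(11)
    dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 400), (200, 400))
    labels = np.array(["P1"] * 100 + ["P2"] * 100)
    rng.shuffle(labels)
    res = amova(make_gm(dosage), labels)
    assert res.percent["among_pops"] < 2.0
    assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-6)


def test_amova_excludes_singleton_population(small_panel):
    labels = np.array(list(small_panel.pop_labels), dtype=object)
    labels[0] = "LONER"
    with pytest.warns(UserWarning, match="single sample"):
        res = amova(small_panel.genotypes, labels)
    assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-6)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def test_kinship_duplicate_is_row_maximum():
    rng = np.random.default_rng(7)
    dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 500), (20, 500))
    dosage[1] = dosage[0]
    k = kinship_matrix(make_gm(dosage))
    off = k[0].copy(); off[0] = -np.inf
    assert np.argmax(off) == 1
    assert (k >= 0).all()  # negatives truncated


def test_kinship_unrelated_near_zero_and_truncated():
    rng = np.random.default_rng(8)
    dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 2000), (30, 2000))
    k = kinship_matrix(make_gm(dosage))
    off = k[~np.eye(30, dtype=bool)]
    assert off.min() >= 0
    assert np.median(off) < 0.02


def test_kinship_parent_offspring_quarter():
    rng = np.random.default_rng(9)
    L = 5000
    p = rng.uniform(0.2, 0.8, L)
    pool = rng.binomial(2, p, (40, L))
    parent = pool[0]
    # offspring: one gamete inherited from the parent, one from the population
    gam_p = np.where(parent == 1, rng.integers(0, 2, L), parent // 2)
    gam_m = rng.binomial(1, p)
    offspring = gam_p + gam_m
    dosage = np.vstack([pool, offspring])
    k = kinship_matrix(make_gm(dosage))
    assert k[0, -1] == pytest.approx(0.25, abs=0.05)


def test_kinship_monomorphic_panel_errors():
    with pytest.raises(ValueError):
        kinship_matrix(make_gm(np.zeros((5, 10), dtype=int)))
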
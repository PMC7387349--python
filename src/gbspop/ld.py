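"""Linkage disequilibrium: pairwise r^2, decay curves, D' CIs, haplotype blocks.

Two LD measures serve two purposes.  The decay analysis uses the composite
(dosage-correlation) r^2, computable directly from unphased genotypes and
fast enough for every within-window pair; significance comes from the
one-degree chi-square statistic N r^2.  Block detection needs |D'|
confidence intervals, so two-locus haplotype frequencies are estimated from
unphased genotype pairs by EM and the |D'| likelihood is profiled on a
0..1 grid; a flat prior turns the profile into a distribution whose 5th and
95th percentiles are the CI bounds.  Blocks follow the Gabriel CI rule:
"strong LD" pairs have ci_low >= 0.70 and ci_high >= 0.98, "strong
recombination" pairs have ci_high < 0.90, and a candidate block requires a
strong-LD endpoint pair with >= 95% of informative interior pairs strong.

The marker-count calculator turns a genome size and an LD-decay distance
into the minimum marker number for association mapping (one marker per
decay interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .variants import GenotypeMatrix

PAIR_COLUMNS = ["chrom", "i", "j", "pos_i", "pos_j", "dist", "n", "r2", "p_value"]

STRONG_LD_CI_LOW = 0.70
STRONG_LD_CI_HIGH = 0.98
RECOMB_CI_HIGH = 0.90
DPRIME_GRID = np.round(np.arange(0, 1.0001, 0.01), 2)


# ---------------------------------------------------------------------------
# composite r^2
# ---------------------------------------------------------------------------

def pairwise_r2(gm: GenotypeMatrix, vt: pd.DataFrame, window_bp: int = 500_000) -> pd.DataFrame:
    """Composite r^2 for all same-chromosome locus pairs within ``window_bp``.

    r^2 is the squared Pearson correlation of dosages over pairwise-complete
    samples; the p-value is P(chi2_1 >= N r^2).  Pairs where either locus is
    monomorphic in the complete subset are skipped (count attached as
    ``.attrs['n_skipped_monomorphic']``).
    """
    rows = []
    skipped = 0
    d = gm.dosage.astype(float)
    obs = gm.observed
    for chrom, sub in vt.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        for a in range(len(idx)):
            hi = np.searchsorted(pos, pos[a] + window_bp, side="right")
            js = idx[a + 1: hi]
            if js.size == 0:
                continue
            i = idx[a]
            m = obs[:, [i]] & obs[:, js]
            n = m.sum(axis=0).astype(float)
            xi = np.where(m, d[:, [i]], 0.0)
            xj = np.where(m, d[:, js], 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mi = xi.sum(0) / n
                mj = xj.sum(0) / n
                sij = (xi * xj).sum(0) / n - mi * mj
                vi = (xi**2).sum(0) / n - mi**2
                vj = (xj**2).sum(0) / n - mj**2
                r2 = sij**2 / (vi * vj)
            bad = (n < 2) | (vi <= 0) | (vj <= 0)
            skipped += int(bad.sum())
            for k in np.flatnonzero(~bad):
                j = js[k]
                rows.append((chrom, i, j, pos[a], int(vt.at[j, "pos"]),
                             int(vt.at[j, "pos"]) - int(pos[a]), int(n[k]),
                             float(r2[k]), float(chi2.sf(n[k] * r2[k], 1))))
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    out.attrs["n_skipped_monomorphic"] = skipped
    return out


@dataclass
class DecayCurve:
    bins: pd.DataFrame                 # bin_start, bin_mid, mean_r2, n_pairs
    decay_distance_bp: float           # NaN when mean r^2 never falls below threshold
    threshold: float
    message: str = ""


def ld_decay(pairs: pd.DataFrame, bin_bp: int = 25_000, r2_threshold: float = 0.1,
             alpha: float = 0.05) -> DecayCurve:
    """Bin significant pairs by distance and locate the decay distance.

    Distance bins are left-closed right-open starting at 0.  The decay
    distance is the left edge of the first bin (scanning outward) whose mean
    r^2 drops below ``r2_threshold``; NaN when LD never decays within the
    observed range ("extreme LD").
    """
    if pairs.empty:
        return DecayCurve(pd.DataFrame(columns=["bin_start", "bin_mid", "mean_r2", "n_pairs"]),
                          np.nan, r2_threshold, "empty pair table")
    sig = pairs[pairs["p_value"] <= alpha]
    if sig.empty:
        return DecayCurve(pd.DataFrame(columns=["bin_start", "bin_mid", "mean_r2", "n_pairs"]),
                          np.nan, r2_threshold, "no significant pairs")
    b = (sig["dist"].to_numpy() // bin_bp).astype(int)
    n_bins = b.max() + 1
    rows = []
    empty = 0
    for k in range(n_bins):
        m = b == k
        if not m.any():
            empty += 1
            continue
        rows.append({"bin_start": k * bin_bp, "bin_mid": k * bin_bp + bin_bp / 2,
                     "mean_r2": float(sig["r2"].to_numpy()[m].mean()), "n_pairs": int(m.sum())})
    if empty:
        warnings.warn(f"{empty} empty distance bin(s) skipped")
    bins = pd.DataFrame(rows)
    below = bins.index[bins["mean_r2"] < r2_threshold]
    decay = float(bins.loc[below[0], "bin_start"]) if len(below) else np.nan
    msg = "" if np.isfinite(decay) else "mean r2 never fell below threshold"
    return DecayCurve(bins, decay, r2_threshold, msg)


# ---------------------------------------------------------------------------
# D' and confidence intervals (EM on unphased genotype pairs)
# ---------------------------------------------------------------------------

def _pair_count_tables(gm: GenotypeMatrix, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair count tables for each (i, j) locus pair: (P, 3, 3)."""
    d = gm.dosage
    counts = np.zeros((len(ii), 3, 3), dtype=float)
    for g1 in range(3):
        a = (d[:, ii] == g1)
        for g2 in range(3):
            counts[:, g1, g2] = (a & (d[:, jj] == g2)).sum(axis=0)
    return counts


def _em_haplotype_freqs(counts: np.ndarray, max_iter: int = 1000, tol: float = 1e-10):
    """EM haplotype frequencies (f11, f10, f01, f00) per table; vectorized."""
    n = counts
    N = n.sum(axis=(1, 2))
    two_n = np.maximum(2 * N, 1e-300)
    p1 = (2 * n[:, 2, :].sum(1) + n[:, 1, :].sum(1)) / two_n
    p2 = (2 * n[:, :, 2].sum(1) + n[:, :, 1].sum(1)) / two_n
    # unambiguous haplotype counts
    base11 = 2 * n[:, 2, 2] + n[:, 2, 1] + n[:, 1, 2]
    base10 = 2 * n[:, 2, 0] + n[:, 2, 1] + n[:, 1, 0]
    base01 = 2 * n[:, 0, 2] + n[:, 0, 1] + n[:, 1, 2]
    base00 = 2 * n[:, 0, 0] + n[:, 0, 1] + n[:, 1, 0]
    dh = n[:, 1, 1]
    f11, f10 = p1 * p2, p1 * (1 - p2)
    f01, f00 = (1 - p1) * p2, (1 - p1) * (1 - p2)
    converged = np.zeros(len(n), dtype=bool)
    for _ in range(max_iter):
        cis = f11 * f00
        trans = f10 * f01
        w = np.where(cis + trans > 0, cis / np.maximum(cis + trans, 1e-300), 0.5)
        new11 = (base11 + dh * w) / two_n
        new10 = (base10 + dh * (1 - w)) / two_n
        new01 = (base01 + dh * (1 - w)) / two_n
        new00 = (base00 + dh * w) / two_n
        delta = np.abs(new11 - f11)
        f11, f10, f01, f00 = new11, new10, new01, new00
        converged |= delta < tol
        if converged.all():
            break
    return f11, f10, f01, f00, p1, p2, converged


def _genotype_logliks_on_grid(counts, p1, p2, sign):
    """Log-likelihood of each table on the |D'| grid (P, G)."""
    q1, q2 = 1 - p1, 1 - p2
    dmax_pos = np.minimum(p1 * q2, q1 * p2)
    dmax_neg = np.minimum(p1 * p2, q1 * q2)
    dmax = np.where(sign >= 0, dmax_pos, dmax_neg)
    D = sign[:, None] * DPRIME_GRID[None, :] * dmax[:, None]        # (P, G)
    f11 = np.clip(p1[:, None] * p2[:, None] + D, 0, 1)
    f10 = np.clip(p1[:, None] * q2[:, None] - D, 0, 1)
    f01 = np.clip(q1[:, None] * p2[:, None] - D, 0, 1)
    f00 = np.clip(q1[:, None] * q2[:, None] + D, 0, 1)
    lg = lambda x: np.log(np.maximum(x, 1e-300))
    n = counts
    ll = (
        n[:, 0, 0, None] * lg(f00**2)
        + n[:, 0, 1, None] * lg(2 * f00 * f01)
        + n[:, 0, 2, None] * lg(f01**2)
        + n[:, 1, 0, None] * lg(2 * f00 * f10)
        + n[:, 1, 1, None] * lg(2 * f11 * f00 + 2 * f10 * f01)
        + n[:, 1, 2, None] * lg(2 * f01 * f11)
        + n[:, 2, 0, None] * lg(f10**2)
        + n[:, 2, 1, None] * lg(2 * f10 * f11)
        + n[:, 2, 2, None] * lg(f11**2)
    )
    return ll


def dprime_ci_from_counts(counts: np.ndarray):
    """|D'| point estimates and profile-likelihood CIs for stacked tables.

    Returns arrays (dprime, ci_low, ci_high, converged).  The likelihood is
    profiled over |D'| in {0, 0.01, ..., 1} at the estimated allele
    frequencies and, with a flat prior, normalised into a distribution whose
    5th / 95th percentiles bound the CI.
    """
    f11, f10, f01, f00, p1, p2, converged = _em_haplotype_freqs(counts)
    D = f11 - p1 * p2
    q1, q2 = 1 - p1, 1 - p2
    dmax = np.where(D >= 0, np.minimum(p1 * q2, q1 * p2), np.minimum(p1 * p2, q1 * q2))
    with np.errstate(invalid="ignore", divide="ignore"):
        dprime = np.where(dmax > 0, np.abs(D) / dmax, np.nan)
    dprime = np.clip(dprime, 0, 1)
    sign = np.where(D >= 0, 1.0, -1.0)
    ll = _genotype_logliks_on_grid(counts, p1, p2, sign)
    post = np.exp(ll - ll.max(axis=1, keepdims=True))
    post /= post.sum(axis=1, keepdims=True)
    cdf = np.cumsum(post, axis=1)
    lo_idx = np.argmax(cdf >= 0.05, axis=1)
    hi_idx = np.argmax(cdf >= 0.95, axis=1)
    return dprime, DPRIME_GRID[lo_idx], DPRIME_GRID[hi_idx], converged


def dprime_ci(gm: GenotypeMatrix, i: int, j: int) -> tuple[float, float, float]:
    """|D'| and its CI for one locus pair (both loci must be polymorphic)."""
    counts = _pair_count_tables(gm, np.array([i]), np.array([j]))
    p1 = (2 * counts[0, 2, :].sum() + counts[0, 1, :].sum()) / max(2 * counts.sum(), 1)
    p2 = (2 * counts[0, :, 2].sum() + counts[0, :, 1].sum()) / max(2 * counts.sum(), 1)
    if p1 in (0, 1) or p2 in (0, 1):
        raise ValueError("both loci must be polymorphic in the complete subset")
    dp, lo, hi, _ = dprime_ci_from_counts(counts)
    return float(dp[0]), float(lo[0]), float(hi[0])


def annotate_dprime(gm: GenotypeMatrix, pairs: pd.DataFrame) -> pd.DataFrame:
    """Add dprime / ci_low / ci_high / informative columns to a pair table."""
    if pairs.empty:
        out = pairs.copy()
        for col in ("dprime", "ci_low", "ci_high", "informative", "em_converged"):
            out[col] = []
        return out
    ii = pairs["i"].to_numpy()
    jj = pairs["j"].to_numpy()
    counts = _pair_count_tables(gm, ii, jj)
    dp, lo, hi, conv = dprime_ci_from_counts(counts)
    out = pairs.copy()
    out["dprime"] = dp
    out["ci_low"] = lo
    out["ci_high"] = hi
    strong = (lo >= STRONG_LD_CI_LOW) & (hi >= STRONG_LD_CI_HIGH)
    recomb = hi < RECOMB_CI_HIGH
    out["informative"] = (strong | recomb) & conv
    out["em_converged"] = conv
    return out


# ---------------------------------------------------------------------------
# Gabriel haplotype blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeBlock:
    chrom: str
    first: int          # locus index into the variant table
    last: int
    start: int          # bp of first locus
    end: int            # bp of last locus
    n_snps: int

    @property
    def size_kb(self) -> float:
        return (self.end - self.start) / 1000


def gabriel_blocks(pairs: pd.DataFrame, vt: pd.DataFrame) -> list[HaplotypeBlock]:
    """Gabriel-rule haplotype blocks from a CI-annotated pair table.

    A candidate block [i..j] needs a strong-LD endpoint pair and >= 95% of
    the informative pairs with both members inside (endpoints included)
    strong.  Overlapping candidates are resolved largest-span-first with a
    leftmost tie-break; non-converged pairs are excluded throughout.
    """
    required = {"dprime", "ci_low", "ci_high", "informative"}
    if not required <= set(pairs.columns):
        raise ValueError("pair table lacks D' CI columns; run annotate_dprime first")
    blocks: list[HaplotypeBlock] = []
    usable = pairs[pairs.get("em_converged", True) == True]  # noqa: E712
    for chrom, sub in usable.groupby("chrom", sort=False):
        lo = sub["ci_low"].to_numpy()
        hi = sub["ci_high"].to_numpy()
        strong_arr = (lo >= STRONG_LD_CI_LOW) & (hi >= STRONG_LD_CI_HIGH)
        recomb_arr = hi < RECOMB_CI_HIGH
        ii = sub["i"].to_numpy()
        jj = sub["j"].to_numpy()
        info_mask = strong_arr | recomb_arr
        strong_pairs = {(a, b) for a, b in zip(ii[strong_arr], jj[strong_arr])}
        info_i = ii[info_mask]
        info_j = jj[info_mask]
        info_strong = strong_arr[info_mask]

        pos_of = vt["pos"]
        cand = []
        for a, b in strong_pairs:
            span = int(pos_of[b]) - int(pos_of[a])
            cand.append((span, int(pos_of[a]), a, b))
        cand.sort(key=lambda t: (-t[0], t[1]))
        taken: list[tuple[int, int]] = []
        for span, _, a, b in cand:
            if any(not (b < s or a > e) for s, e in taken):
                continue
            inside = (info_i >= a) & (info_j <= b)
            n_info = int(inside.sum())
            if n_info == 0:
                continue
            frac = info_strong[inside].mean()
            if frac >= 0.95:
                n_snps = int(((vt["chrom"] == chrom) & (vt.index >= a) & (vt.index <= b)).sum())
                blocks.append(HaplotypeBlock(str(chrom), a, b, int(pos_of[a]), int(pos_of[b]), n_snps))
                taken.append((a, b))
    blocks.sort(key=lambda bl: (bl.chrom, bl.start))
    return blocks


def blocks_to_frame(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": b.chrom, "start": b.start, "end": b.end, "n_snps": b.n_snps, "size_kb": b.size_kb}
         for b in blocks],
        columns=["chrom", "start", "end", "n_snps", "size_kb"],
    )


# ---------------------------------------------------------------------------
# marker sizing for association studies
# ---------------------------------------------------------------------------

def min_markers_for_gwas(genome_size_kb: float, decay_kb: float) -> int:
    """Minimum marker count: one marker per LD-decay interval of the genome."""
    if genome_size_kb <= 0 or decay_kb <= 0:
        raise ValueError("genome size and decay distance must be positive")
    return int(round(genome_size_kb / decay_kb))
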
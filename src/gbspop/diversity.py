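"""Diversity statistics: per-locus summaries, windowed scans, AMOVA, kinship.

Windowed statistics are computed in non-overlapping 100-kb windows from
unphased dosages with missing data: the mean pairwise difference count per
window is k-hat = sum_l (n_l/(n_l-1)) * 2 p_l q_l with n_l the allele count
(2 x non-missing samples) at locus l, pi = k-hat / window length, Watterson's
theta_w = S / (a1 * window length), and Tajima's D uses the standard
constants evaluated at the median per-site allele count of the window.
Denominators are the full window length, matching per-site reporting of
sparse reduced-representation panels (magnitudes ~1e-5).

F_ST follows the Weir & Cockerham (1984) variance-component estimator with
ratio-of-sums combination across loci; AMOVA partitions allele-level sums of
squares hierarchically (among populations / among individuals within
populations / within individuals) with negative components truncated to
zero; kinship is a Loiselle-type dosage-correlation estimator with negative
pairs truncated to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

WINDOW_COLUMNS = ["chrom", "start", "end", "n_snps", "S", "pi", "theta_w", "tajima_d", "fst", "mean_het"]


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def allele_stats(gm: GenotypeMatrix, vt: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-locus MAF, expected/observed heterozygosity and PIC.

    He = 2pq; Ho = observed heterozygote fraction; PIC = He - 2 p^2 q^2 for
    a biallelic locus.  All-missing loci yield NA rows.
    """
    obs = gm.observed
    n_obs = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, gm.dosage, 0).sum(axis=0) / (2 * n_obs)
        he = 2 * p * (1 - p)
        ho = (gm.dosage == 1).sum(axis=0) / n_obs
        pic = he - 2 * (p * (1 - p)) ** 2
        maf = np.minimum(p, 1 - p)
    out = pd.DataFrame({"maf": maf, "he": he, "ho": ho, "pic": pic, "n_obs": n_obs.astype(int)})
    out.loc[n_obs == 0, ["maf", "he", "ho", "pic"]] = np.nan
    if vt is not None:
        out.insert(0, "snp_name", vt["snp_name"].to_numpy())
    return out


def diversity_summary(gm: GenotypeMatrix, vt: pd.DataFrame, scopes: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Mean He / Ho / PIC and polymorphic count per locus scope.

    ``scopes`` maps a label to a boolean locus mask; by default the whole
    panel plus the B / C subgenomes (by chromosome-name prefix) and any
    annotation classes present are summarised.
    """
    stats = allele_stats(gm, vt)
    chrom = vt["chrom"].astype(str)
    if scopes is None:
        scopes = {"all": np.ones(len(vt), bool)}
        for pre in ("B", "C"):
            mask = chrom.str.startswith(pre).to_numpy()
            if mask.any():
                scopes[pre] = mask
        for ctx in ("coding", "intron", "intergenic"):
            mask = (vt["context"] == ctx).to_numpy()
            if mask.any():
                scopes[ctx] = mask
    rows = []
    for label, mask in scopes.items():
        sub = stats.loc[mask]
        rows.append({
            "scope": label,
            "n_snps": int(mask.sum()),
            "he": sub["he"].mean(),
            "ho": sub["ho"].mean(),
            "pic": sub["pic"].mean(),
            "n_polymorphic": int((sub["maf"] > 0).sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# windowed diversity
# ---------------------------------------------------------------------------

def _tajima_constants(n: int) -> tuple[float, float, float, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, e1, e2


def windowed_diversity(
    gm: GenotypeMatrix,
    vt: pd.DataFrame,
    window: int = 100_000,
    labels: np.ndarray | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tile chromosomes with half-open ``window``-bp windows and score each.

    Returns one row per window with S, pi, theta_w, Tajima's D, mean
    observed heterozygosity and (when ``labels`` is given) the windowed
    Weir–Cockerham F_ST.  Windows without SNPs carry NA statistics.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    obs = gm.observed
    n_l = 2 * obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, gm.dosage, 0).sum(axis=0) / n_l
    het = (gm.dosage == 1).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    if labels is not None:
        a_comp, b_comp, c_comp = weir_cockerham_components(gm, labels)

    rows = []
    for chrom, sub in vt.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        length = (chrom_lengths or {}).get(str(chrom), 0)
        n_win = max(int(np.ceil(max(length, pos.max()) / window)), 1)
        for w in range(n_win):
            start, end = w * window, (w + 1) * window
            in_w = idx[(pos >= start) & (pos < end)]
            row = {"chrom": chrom, "start": start, "end": end, "n_snps": len(in_w)}
            if len(in_w) == 0:
                row.update({"S": 0, "pi": np.nan, "theta_w": np.nan, "tajima_d": np.nan,
                            "fst": np.nan, "mean_het": np.nan})
                rows.append(row)
                continue
            nl = n_l[in_w]
            pl = p[in_w]
            usable = nl >= 2
            seg = usable & (pl > 0) & (pl < 1)
            S = int(seg.sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                khat = float(np.sum((nl[usable] / (nl[usable] - 1)) * 2 * pl[usable] * (1 - pl[usable])))
            pi = khat / window
            n_med = int(np.median(nl[usable])) if usable.any() else 0
            if n_med >= 2 and S >= 0:
                a1, a2, e1, e2 = _tajima_constants(n_med)
                theta_w = S / (a1 * window)
                if S <= 1:
                    taj = np.nan
                else:
                    var = e1 * S + e2 * S * (S - 1)
                    num = khat - S / a1
                    taj = 0.0 if var <= 0 and abs(num) < 1e-9 else (num / np.sqrt(var) if var > 0 else np.nan)
            else:
                theta_w, taj = np.nan, np.nan
            row.update({"S": S, "pi": pi, "theta_w": theta_w, "tajima_d": taj,
                        "mean_het": float(np.mean(het[in_w]))})
            if labels is not None:
                denom = (a_comp + b_comp + c_comp)[in_w]
                ok = denom > 0
                row["fst"] = float(a_comp[in_w][ok].sum() / denom[ok].sum()) if ok.any() else np.nan
            else:
                row["fst"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


# ---------------------------------------------------------------------------
# Weir-Cockerham F-statistics
# ---------------------------------------------------------------------------

def weir_cockerham_components(gm: GenotypeMatrix, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c).

    a: among populations; b: among individuals within populations; c: within
    individuals.  Loci where fewer than two populations have observed calls
    get NaN components.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != gm.n_samples:
        raise ValueError("labels length must equal sample count")
    pops = [labels == u for u in pd.unique(labels)]
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    obs = gm.observed
    L = gm.n_loci
    n_i = np.stack([(obs[m]).sum(axis=0) for m in pops]).astype(float)  # r x L
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.where(obs[m], gm.dosage[m], 0).sum(axis=0) for m in pops]) / (2 * n_i)
        h_i = np.stack([(gm.dosage[m] == 1).sum(axis=0) for m in pops]) / n_i

    has = n_i > 0
    r_l = has.sum(axis=0).astype(float)
    valid = r_l >= 2
    n_i = np.where(has, n_i, 0.0)
    p_i = np.where(has, p_i, 0.0)
    h_i = np.where(has, h_i, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = n_i.sum(axis=0)
        nbar = n_tot / r_l
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r_l - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r_l - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_tot
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r_l - 1) / r_l * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r_l - 1) / r_l * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = ~valid | (nbar <= 1) | ~np.isfinite(a)
    a, b, c = (np.where(bad, np.nan, x) for x in (a, b, c))
    return a, b, c


def weir_cockerham_fst(
    gm: GenotypeMatrix,
    labels,
    mode: str = "multilocus",
    vt: pd.DataFrame | None = None,
    window: int = 100_000,
):
    """WC84 F_ST in one of four modes.

    ``multilocus``: scalar ratio-of-sums over all loci.  ``per_locus``:
    array of per-locus a/(a+b+c).  ``windowed``: adds an ``fst`` column to a
    window table (requires ``vt``).  ``pairwise_pops``: DataFrame of
    multilocus estimates for every population pair.
    """
    labels = np.asarray(labels)
    if mode == "pairwise_pops":
        uniq = list(pd.unique(labels))
        rows = []
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                m = (labels == uniq[i]) | (labels == uniq[j])
                sub = gm.take_samples(np.flatnonzero(m))
                rows.append({"pop1": uniq[i], "pop2": uniq[j],
                             "fst": weir_cockerham_fst(sub, labels[m], "multilocus")})
        return pd.DataFrame(rows)

    a, b, c = weir_cockerham_components(gm, labels)
    denom = a + b + c
    ok = np.isfinite(denom) & (denom > 0)
    if mode == "multilocus":
        if not ok.any():
            raise ValueError("no locus with positive total variance")
        return float(a[ok].sum() / denom[ok].sum())
    if mode == "per_locus":
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ok, a / denom, np.nan)
    if mode == "windowed":
        if vt is None:
            raise ValueError("windowed mode requires the variant table")
        return windowed_diversity(gm, vt, window=window, labels=labels)
    raise ValueError(f"unknown mode {mode!r}")


def f_statistics(gm: GenotypeMatrix, labels) -> dict[str, float]:
    """F_IS, F_IT, F_ST from summed WC84 components (ratio of sums)."""
    a, b, c = weir_cockerham_components(gm, labels)
    ok = np.isfinite(a + b + c) & ((a + b + c) > 0)
    A, B, C = a[ok].sum(), b[ok].sum(), c[ok].sum()
    return {
        "fst": float(A / (A + B + C)),
        "fit": float(1 - C / (A + B + C)),
        "fis": float(1 - C / (B + C)),
    }


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    ss: dict[str, float]
    df: dict[str, float]
    variance: dict[str, float]  # truncated components
    percent: dict[str, float]
    phi_pt: float
    fis: float
    fit: float
    fst: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in ("among_pops", "among_ind_within_pops", "within_ind"):
            rows.append({"source": level, "ss": self.ss[level], "df": self.df[level],
                         "variance": self.variance[level], "percent": self.percent[level]})
        return pd.DataFrame(rows)


def amova(gm: GenotypeMatrix, labels) -> AmovaResult:
    """Allele-level hierarchical AMOVA on dosage data.

    Each diploid contributes two allele values (0/1) per observed locus.
    Sums of squares and degrees of freedom accumulate per locus (missing
    calls drop out), variance components come from the expected mean
    squares, negatives are truncated to zero before percentages.
    Populations of size one are excluded with a warning.
    """
    import warnings

    labels = np.asarray(labels)
    keep = np.ones(gm.n_samples, bool)
    for u in pd.unique(labels):
        if (labels == u).sum() < 2:
            warnings.warn(f"population {u!r} has a single sample; excluded from AMOVA")
            keep &= labels != u
    labels = labels[keep]
    gm = gm.take_samples(np.flatnonzero(keep))
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("AMOVA needs at least two populations of size >= 2")

    obs = gm.observed
    pop_masks = [labels == u for u in uniq]
    n_pop_l = np.stack([(obs[m]).sum(axis=0) for m in pop_masks]).astype(float)  # r x L
    r_l = (n_pop_l > 0).sum(axis=0)
    usable = r_l >= 2
    if not usable.any():
        raise ValueError("no locus observed in at least two populations")
    obs = obs[:, usable]
    x = gm.dosage[:, usable].astype(float) / 2  # individual allele mean
    n_pop_l = n_pop_l[:, usable]
    r_l = r_l[usable].astype(float)

    ss_wi = float(((gm.dosage[:, usable] == 1) * 0.5).sum())  # 0.5 per het locus
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pop = np.stack([np.where(obs[m], x[m], 0).sum(axis=0) for m in pop_masks]) / n_pop_l
        n_tot_l = n_pop_l.sum(axis=0)
        grand = (n_pop_l * np.nan_to_num(mean_pop)).sum(axis=0) / n_tot_l
    ss_ai = 0.0
    for m, mp in zip(pop_masks, mean_pop):
        dev = np.where(obs[m], x[m] - mp, 0.0)
        ss_ai += float((2 * dev**2).sum())
    with np.errstate(invalid="ignore"):
        ss_ap = float(np.nansum(2 * n_pop_l * (mean_pop - grand) ** 2))

    df_ap = float((r_l - 1).sum())
    df_ai = float((n_tot_l - r_l).sum())
    df_wi = float(n_tot_l.sum())

    ms_wi = ss_wi / df_wi
    ms_ai = ss_ai / df_ai
    ms_ap = ss_ap / df_ap
    # average coefficient for the among-pop expected mean square
    with np.errstate(invalid="ignore", divide="ignore"):
        n0_l = (n_tot_l - (n_pop_l**2).sum(axis=0) / n_tot_l) / np.maximum(r_l - 1, 1)
    n0 = float(np.mean(n0_l))

    var_wi = ms_wi
    var_ai = (ms_ai - ms_wi) / 2
    var_ap = (ms_ap - ms_ai) / (2 * n0)
    raw = {"among_pops": var_ap, "among_ind_within_pops": var_ai, "within_ind": var_wi}
    trunc = {k: max(v, 0.0) for k, v in raw.items()}
    total = sum(trunc.values())
    percent = {k: (100 * v / total if total > 0 else np.nan) for k, v in trunc.items()}
    sAP, sAI, sWI = trunc["among_pops"], trunc["among_ind_within_pops"], trunc["within_ind"]
    return AmovaResult(
        ss={"among_pops": ss_ap, "among_ind_within_pops": ss_ai, "within_ind": ss_wi},
        df={"among_pops": df_ap, "among_ind_within_pops": df_ai, "within_ind": df_wi},
        variance=trunc,
        percent=percent,
        phi_pt=(sAP / total if total > 0 else np.nan),
        fis=(sAI / (sAI + sWI) if sAI + sWI > 0 else np.nan),
        fit=((sAP + sAI) / total if total > 0 else np.nan),
        fst=(sAP / total if total > 0 else np.nan),
    )


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def kinship_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Loiselle-type pairwise kinship with panel allele frequencies.

    F_ij = sum_l (x_il - p_l)(x_jl - p_l) / sum_l p_l (1 - p_l) with
    x = dosage/2, sums over loci observed in both samples; negative
    off-diagonal values are truncated to zero (less related than random).
    """
    if gm.n_samples < 2:
        raise ValueError("kinship needs at least two samples")
    obs = gm.observed
    n_obs = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, gm.dosage, 0).sum(axis=0) / (2 * n_obs)
    w = p * (1 - p)
    if not np.any(w > 0):
        raise ValueError("panel is monomorphic; kinship denominator is zero")
    xc = np.where(obs, gm.dosage / 2 - p, 0.0)
    num = xc @ xc.T
    denom = (obs * w) @ obs.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = num / denom
    off = ~np.eye(gm.n_samples, dtype=bool)
    k[off & (k < 0)] = 0.0
    return k
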
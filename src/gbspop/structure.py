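"""Population-structure inference for unphased SNP panels.

The admixture model is the classical one: genotype g_il ~ Binomial(2, f_il)
with f_il = sum_k q_ik p_kl, Q the per-sample ancestry proportions on the
simplex and P the per-cluster ALT frequencies.  It is fitted here by EM
(maximum likelihood) rather than MCMC — the Q/P contract and the downstream
ΔK model selection and membership-threshold assignment are identical to the
Bayesian tooling this replaces, at a fraction of the runtime and fully
deterministic under a seed.

Also provided: greedy LD pruning to an "unlinked" marker set, PCA with
Patterson scaling, the Evanno ΔK second-difference statistic for choosing
the number of clusters, Q-threshold membership assignment, and
identity-by-state distance trees (UPGMA / neighbour-joining) with optional
locus-resampling bootstrap support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeMatrix

P_CLAMP = 1e-6


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _composite_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples."""
    m = (x != MISSING) & (y != MISSING)
    if m.sum() < 2:
        return np.nan
    xv, yv = x[m].astype(float), y[m].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, vt: pd.DataFrame, r2_max: float = 0.1,
             window_bp: int = 500_000, step: int | None = None) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns indices of retained loci.

    Scanning each chromosome in position order (ties broken keeping the
    higher-MAF locus first, then the smaller position), a locus is dropped
    as soon as its composite r^2 with any already-retained locus within
    ``window_bp`` exceeds ``r2_max``.
    """
    keep: list[int] = []
    for chrom, sub in vt.groupby("chrom", sort=False):
        order = sub.sort_values(["pos", "maf"], ascending=[True, False]).index.to_numpy()
        kept_here: list[int] = []
        for j in order:
            pos_j = vt.at[j, "pos"]
            ok = True
            for i in reversed(kept_here):
                if pos_j - vt.at[i, "pos"] > window_bp:
                    break
                r2 = _composite_r2(gm.dosage[:, i], gm.dosage[:, j])
                if np.isfinite(r2) and r2 > r2_max:
                    ok = False
                    break
            if ok:
                kept_here.append(j)
        keep.extend(kept_here)
    return np.array(sorted(keep))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray          # samples x components
    loadings: np.ndarray        # loci x components, unit-norm columns
    variance_explained: np.ndarray
    locus_index: np.ndarray     # indices of (polymorphic) loci used


def run_pca(gm: GenotypeMatrix, scaling: str = "patterson", n_components: int | None = None) -> PcaResult:
    """PCA of the dosage matrix, centered at 2p-hat per locus.

    ``patterson`` scaling divides each locus by sqrt(p(1-p)); monomorphic
    loci are dropped.  Component signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    if np.any(gm.dosage == MISSING):
        raise ValueError("run_pca requires an imputed (no-missing) matrix")
    if gm.n_samples < 2 or gm.n_loci < 2:
        raise ValueError("need at least 2 samples and 2 loci")
    d = gm.dosage.astype(float)
    p = d.mean(axis=0) / 2
    poly = (p > 0) & (p < 1) & (d.var(axis=0) > 0)
    if not poly.any():
        raise ValueError("matrix is constant; PCA undefined")
    x = d[:, poly] - 2 * p[poly]
    if scaling == "patterson":
        x = x / np.sqrt(p[poly] * (1 - p[poly]))
    elif scaling != "center_only":
        raise ValueError(f"unknown scaling {scaling!r}")
    u, s, vtm = np.linalg.svd(x, full_matrices=False)
    k = min(n_components or len(s), len(s))
    scores = u[:, :k] * s[:k]
    loadings = vtm[:k].T
    var = s**2
    varexp = var[:k] / var.sum()
    for c in range(k):
        if loadings[np.argmax(np.abs(loadings[:, c])), c] < 0:
            loadings[:, c] = -loadings[:, c]
            scores[:, c] = -scores[:, c]
    return PcaResult(scores, loadings, varexp, np.flatnonzero(poly))


# ---------------------------------------------------------------------------
# EM admixture
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray       # samples x K, rows on the simplex
    P: np.ndarray       # K x loci ALT frequencies
    loglik: float
    seed: int
    n_iter: int
    converged: bool


def _admixture_loglik(g: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    f = np.clip(Q @ P, P_CLAMP, 1 - P_CLAMP)
    return float(np.sum(g * np.log(f) + (2 - g) * np.log1p(-f)))


def admixture_em(gm: GenotypeMatrix, K: int, seed: int = 0,
                 max_iter: int = 2000, tol: float = 1e-6) -> AdmixtureResult:
    """Maximum-likelihood admixture fit by EM.

    E-step attributes each of the 2 allele copies at (i, l) to clusters in
    proportion to q_ik p_kl (ALT copies) and q_ik (1-p_kl) (REF copies);
    M-step renormalises.  The log-likelihood is monotone non-decreasing and
    iteration stops when its change falls below ``tol``.
    """
    if np.any(gm.dosage == MISSING):
        raise ValueError("admixture_em requires an imputed (no-missing) matrix")
    n, L = gm.n_samples, gm.n_loci
    if not 1 <= K <= n:
        raise ValueError(f"K must be in 1..{n}")
    g = gm.dosage.astype(float)
    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    phat = g.mean(axis=0) / 2
    P = np.clip(phat + rng.normal(0, 0.05, (K, L)), P_CLAMP, 1 - P_CLAMP)

    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        f = np.clip(Q @ P, P_CLAMP, 1 - P_CLAMP)          # n x L
        # expected ALT / REF copies attributed to each cluster
        alt_w = g / f                                      # n x L
        ref_w = (2 - g) / (1 - f)
        A = Q[:, :, None] * P[None, :, :] * alt_w[:, None, :]    # n x K x L
        R = Q[:, :, None] * (1 - P)[None, :, :] * ref_w[:, None, :]
        Q = (A + R).sum(axis=2)
        Q /= Q.sum(axis=1, keepdims=True)
        denom = (A + R).sum(axis=0)                        # K x L
        P = np.clip(A.sum(axis=0) / np.maximum(denom, 1e-300), P_CLAMP, 1 - P_CLAMP)
        ll = _admixture_loglik(g, Q, P)
        if ll < ll_prev - 1e-6:
            raise AssertionError(f"EM log-likelihood decreased at iteration {it}")
        if ll - ll_prev < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return AdmixtureResult(K, Q, P, ll_prev, seed, it, converged)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class KSelection:
    table: pd.DataFrame          # K, mean_loglik, sd_loglik, delta_k
    chosen_k: int | None
    ambiguous: bool
    replicate_logliks: dict[int, list[float]] = field(default_factory=dict)


def evanno_delta_k(logliks: dict[int, list[float]]) -> KSelection:
    """ΔK from replicate log-likelihoods per K.

    ΔK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)), defined
    for interior K only; zero replicate sd yields an infinite sentinel and a
    flag.  Chosen K maximises ΔK; an all-zero curve is flagged ambiguous.
    """
    ks = sorted(logliks)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values for ΔK")
    mean = {k: float(np.mean(logliks[k])) for k in ks}
    sd = {k: float(np.std(logliks[k], ddof=1)) if len(logliks[k]) > 1 else 0.0 for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk = np.nan
        else:
            num = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            dk = np.inf if sd[k] == 0 else num / sd[k]
        rows.append({"K": k, "mean_loglik": mean[k], "sd_loglik": sd[k], "delta_k": dk})
    table = pd.DataFrame(rows)
    interior = table["delta_k"].to_numpy()[1:-1]
    ambiguous = bool(np.all(np.nan_to_num(interior) == 0))
    chosen = None if ambiguous else int(table["K"].to_numpy()[1:-1][np.nanargmax(interior)])
    return KSelection(table, chosen, ambiguous, {k: list(map(float, logliks[k])) for k in ks})


def select_k(gm: GenotypeMatrix, k_range=range(1, 11), replicates: int = 5,
             seed: int = 0, max_iter: int = 500, tol: float = 1e-4) -> KSelection:
    """Fit the admixture model over ``k_range`` x ``replicates`` and pick K by ΔK."""
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least three values")
    if replicates < 2:
        raise ValueError("need >= 2 replicates for a standard deviation")
    logliks: dict[int, list[float]] = {}
    for k in ks:
        logliks[k] = [
            admixture_em(gm, k, seed=seed * 10_007 + 97 * k + r, max_iter=max_iter, tol=tol).loglik
            for r in range(replicates)
        ]
    return evanno_delta_k(logliks)


def assign_membership(Q: np.ndarray, threshold: float = 0.70, cluster_names=None) -> np.ndarray:
    """Assign each sample to its argmax cluster if max Q >= threshold, else 'admixed'."""
    Q = np.asarray(Q, float)
    names = cluster_names or [f"SP{k+1}" for k in range(Q.shape[1])]
    arg = Q.argmax(axis=1)
    labels = np.array([names[a] for a in arg], dtype=object)
    labels[Q.max(axis=1) < threshold] = "admixed"
    return labels


# ---------------------------------------------------------------------------
# distance trees
# ---------------------------------------------------------------------------

def ibs_distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """1 - identity-by-state allele-sharing proportion over shared loci."""
    obs = gm.observed
    shared = obs.astype(float) @ obs.T.astype(float)
    if np.any(shared == 0):
        raise ValueError("some sample pairs share zero observed loci")
    # sum over shared loci of |d_i - d_j| from dosage-class indicator products
    ind = [np.asarray(obs & (gm.dosage == k), float) for k in (0, 1, 2)]
    cross01 = ind[0] @ ind[1].T
    cross12 = ind[1] @ ind[2].T
    cross02 = ind[0] @ ind[2].T
    absdiff = cross01 + cross01.T + cross12 + cross12.T + 2 * (cross02 + cross02.T)
    dist = absdiff / (2 * shared)
    np.fill_diagonal(dist, 0.0)
    return dist


def build_tree(gm: GenotypeMatrix, method: str = "nj", bootstrap_reps: int = 0, seed: int = 0):
    """IBS-distance tree (UPGMA or NJ) with optional bootstrap support.

    Returns ``(tree, dist)`` where ``tree`` is a :class:`Bio.Phylo` tree
    whose internal-clade ``confidence`` holds bootstrap support (% of
    locus-resampled replicates containing the same bipartition) when
    ``bootstrap_reps > 0``.
    """
    if gm.n_samples < 3:
        raise ValueError("need at least three samples")
    if method not in ("nj", "upgma"):
        raise ValueError(f"unknown method {method!r}")
    dist = ibs_distance_matrix(gm)
    tree = _agglomerate(dist, gm.sample_ids, method)
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, gm.n_loci, gm.n_loci)
            bt = _agglomerate(ibs_distance_matrix(gm.take_loci(idx)), gm.sample_ids, method)
            for bp in _bipartitions(bt):
                counts[bp] = counts.get(bp, 0) + 1
        for clade, bp in _internal_clades(tree):
            clade.confidence = 100.0 * counts.get(bp, 0) / bootstrap_reps
    return tree, dist


def _agglomerate(dist: np.ndarray, names: list[str], method: str):
    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

    n = len(names)
    dm = DistanceMatrix(list(names), [[float(dist[i, j]) for j in range(i + 1)] for i in range(n)])
    ctor = DistanceTreeConstructor()
    return ctor.nj(dm) if method == "nj" else ctor.upgma(dm)


def _internal_clades(tree):
    all_terms = frozenset(t.name for t in tree.get_terminals())
    for clade in tree.get_nonterminals():
        terms = frozenset(t.name for t in clade.get_terminals())
        if 1 < len(terms) < len(all_terms):
            side = min(terms, all_terms - terms, key=lambda s: (len(s), sorted(s)))
            yield clade, side


def _bipartitions(tree):
    return {bp for _, bp in _internal_clades(tree)}


def write_q_table(result: AdmixtureResult, sample_ids, path, threshold: float = 0.70) -> pd.DataFrame:
    labels = assign_membership(result.Q, threshold)
    df = pd.DataFrame(result.Q, columns=[f"q{k+1}" for k in range(result.K)])
    df.insert(0, "sample_id", list(sample_ids))
    df["label"] = labels
    df.to_csv(path, sep="\t", index=False)
    return df
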
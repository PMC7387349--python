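# Methods

This note records the statistical models, estimator definitions, numerical
conventions and design choices behind `gbspop`, and what the synthetic data
do and do not establish about behaviour on real panels.

## The synthetic panel model

`simpanel` emulates a GBS diversity panel of a highly selfing allotetraploid
crop: several hundred diploid accessions from two diverged subpopulations,
~10⁴ biallelic SNPs on chromosomes named B1–B8 and C1–C9.

**Allele frequencies.** Ancestral frequencies are Uniform(0.05, 0.95).
Each subpopulation draws its locus frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F) — the Balding–Nichols model — whose
between-population variance equals F·p(1−p), so the parameter `fst_param`
is the expected Weir–Cockerham F_ST.  This closed-form calibration is why
Balding–Nichols was preferred over a coalescent simulator; it is verified
empirically (30 replicate panels at F = 0.15, n = 200/population, 5,000
loci recover 0.150 ± 0.003).

**Genotypes.** By default, loci are independent: g ~ Binomial(2, p_sub)
(linkage equilibrium).  Inbreeding converts each heterozygote to a random
homozygote with probability `selfing_rate` (default 0.82, chosen to match
the within-population fixation the package is designed around, F_IS ≈ 0.8);
the conversion preserves allele frequencies in expectation and makes
1 − H_O/H_E ≈ selfing_rate.

**Background LD (optional).** Independent loci carry no linkage
disequilibrium, so D′-based haplotype blocks cannot arise from the default
background — with all four two-locus haplotype classes abundant, |D′|
stays far from 1 regardless of sample size.  Setting
`n_founder_haplotypes = H > 0` instead builds each gamete as a mosaic of H
founder haplotypes per subpopulation (founders drawn per locus from the
subpopulation frequencies; the copied founder switches between consecutive
loci with probability 1 − exp(−d/`recomb_scale_bp`)).  r² then decays on
the `recomb_scale_bp` scale and small H produces Gabriel blocks, at the
cost of founder-pool drift adding ~1/H to realized differentiation — which
is why the mosaic is off by default and the F_ST/MAF calibration tests run
without it.  In mosaic mode inbreeding doubles a whole gamete (with
probability `selfing_rate` the individual is fully homozygous), because
per-locus heterozygote conversion would act like recombination and destroy
the haplotype structure the mosaic exists to create.

**Depth and missingness.** Depths are Poisson(`depth_mean`, default 8)
truncated to ≥ 1 for observed calls; missing calls (probability
`missing_rate`, default 0.10) carry depth 0, so "missing ⇔ depth 0" is an
invariant of the container.

**Sweeps.** `plant_sweep` copies a founder gamete homozygously into a
fraction of one subpopulation across all loci in an interval.  The founder
is one gamete of a randomly chosen existing target-population sample — a
sweep amplifies a haplotype that is already segregating; a novel random
haplotype would create differentiation but no coherent LD signal.
`SweepSpec.extra_loci` optionally densifies markers inside the interval:
in real reduced-representation data the swept regions of interest carry an
order of magnitude more discovered SNPs than the genome-wide average, and
the fixed evidence thresholds downstream (≥ 5 clustered high-loading SNPs)
presume that density; a 1-Mb interval at one SNP per ~50–90 kb holds too
few markers to clear them.

**Defaults as study conditions.** The flagship defaults are 549 + 41
samples, 17 chromosomes, 600 loci each (~10,200 SNPs), F = 0.148,
selfing 0.82, 10% missing, mean depth 8.  Chromosomes default to 5 Mb —
length-scaled so a full panel with reference sequence and gene models stays
desk-sized; the statistics see marker counts and densities, not absolute
genome size, and experiments where window geometry matters (sweep scan)
use 55-Mb chromosomes with `with_annotation=False` to skip sequence
generation.

**What the generator does not emulate.** Site-frequency-spectrum shape
beyond Beta-binomial (no demographic history), ascertainment bias of GBS
marker discovery (except the sweep-region density option), genotyping
error, paralog collapse (the heterozygosity-excess filter is exercised only
by sampling noise), and selection on coding sites — random substitutions
are ~75% non-synonymous, the reverse of natural panels.  Passing tests
therefore demonstrate estimator correctness and calibration under the
stated sampling model, not robustness to those real-data artefacts.

## Estimators

**Filters.** Per-call depth masking (depth < 4 → missing; calls with
unknown depth are exempt) precedes the per-locus rules, which are applied
in order — MAF strictly > 0.05, observed heterozygote fraction ≤ 0.1
(the per-locus reading: it targets collapsed paralogs, and a per-sample
reading would be vacuous at H_O ≈ 0.05), missingness ≤ 30% inclusive —
each counted against the post-masking matrix.  The chain is idempotent.

**Imputation** draws each missing call from Binomial(2, p̂ₗ) with p̂ₗ the
observed ALT frequency, which leaves frequencies unbiased — sufficient for
the moment-based statistics downstream.  LD statistics deliberately use the
*unimputed* matrix with pairwise-complete samples: frequency draws are
random recombinants and measurably dilute D′.

**Windowed diversity.** Windows are half-open 100-kb tiles.  With
site-specific allele counts nₗ (2 × non-missing samples),
k̂ = Σₗ (nₗ/(nₗ−1))·2p̂ₗq̂ₗ, π = k̂/window length (full window length in the
denominator, matching per-site reporting of sparse panels), θ_W = S/(a₁·L),
and Tajima's D uses the standard constants at n = the median per-site
allele count of the window (missing data make n site-specific; the median
is this package's convention).  S ≤ 1 ⇒ D is NA; when the variance term is
zero with a zero numerator (n = 2), D = 0 by the algebraic identity
k̂ = S/a₁.

**F-statistics.** Weir & Cockerham's (1984) per-locus components — a
(among populations), b (among individuals within), c (within individuals),
computed from observed heterozygote counts with population-size
corrections — are combined ratio-of-sums (Σa/Σ(a+b+c)) over loci, windows
or the genome; loci with non-positive total variance are excluded.
F_IS = 1 − Σc/Σ(b+c) and F_IT = 1 − Σc/Σ(a+b+c) come from the same
components for internal consistency.  AMOVA partitions allele-level sums
of squares (each diploid contributes two 0/1 allele values per observed
locus) with expected-mean-square extraction and negative components
truncated to zero before percentages.  Kinship is the dosage-correlation
estimator Fᵢⱼ = Σₗ(xᵢₗ−p̂ₗ)(xⱼₗ−p̂ₗ)/Σₗp̂ₗ(1−p̂ₗ) with x = dosage/2,
pairwise-complete sums, negatives truncated to zero (a parent–offspring
pair scores ≈ 0.25 under this scaling).

**Admixture.** The likelihood is g_il ~ Binomial(2, Σₖ q_ik p_kl).  EM
attributes ALT/REF allele copies to clusters in the E-step and
renormalises in the M-step; P is clamped to [10⁻⁶, 1−10⁻⁶]; the
log-likelihood is asserted non-decreasing every iteration.  Initialisation
is a seeded Dirichlet Q and perturbed pooled frequencies; replicate starts
supply the spread that Evanno's ΔK = |L(K+1) − 2L(K) + L(K−1)|/sd(L(K))
needs (zero sd yields an infinity sentinel and a flag; an all-zero ΔK
curve is reported ambiguous).  The 0.70 membership threshold is applied to
the single best run.  This maximum-likelihood EM replaces Bayesian MCMC
with the identical Q/P contract; burn-in/chain-length settings map to
`max_iter`/`tol`.

**PCA.** Loci centered at 2p̂; Patterson scaling (÷√(p̂(1−p̂))) for
structure inference, center-only for the sweep-scan loading track — the
genotype-PCA convention of the GWAS tooling this mirrors, and Patterson
scaling up-weights low-MAF noise enough to dilute sweep loadings below the
fixed 0.02 threshold.  Loading columns are unit-norm; component signs are
fixed (largest-magnitude loading positive) for reproducibility.

**LD.** Composite r² = corr(dosage_i, dosage_j)² over pairwise-complete
samples, p-value from χ²₁ at N·r²; pairs restricted to 500-kb
same-chromosome windows.  Decay curves average significant (p ≤ 0.05)
pairs in left-closed 25-kb bins from 0; the decay distance is the left
edge of the first bin whose mean falls below the threshold (hence
non-increasing in the threshold), NA when LD never decays.  |D′| comes
from EM haplotype frequencies on the 3×3 genotype-pair table (only the
double-heterozygote cell is ambiguous); its CI profiles the data
likelihood over |D′| ∈ {0, 0.01, …, 1} at the estimated allele
frequencies, normalised under a flat prior, taking the 5th/95th
percentiles.  Gabriel blocks: strong LD = (ci_low ≥ 0.70, ci_high ≥ 0.98),
strong recombination = ci_high < 0.90, candidate = strong endpoint pair
with ≥ 95% of informative interior pairs strong; overlaps resolved
largest-span-first with a leftmost tie-break (the plain Gabriel rule —
Haploview's size-dependent refinements are deliberately not implemented).
Non-converged EM pairs (1,000-iteration cap) are excluded from blocks.

**Sweep scan.** Three tracks: single-linkage clusters (gap ≤ 500 kb,
≥ 5 SNPs) of loci with |PC1 loading| > 0.02 (magnitude — eigenvector sign
is arbitrary); runs of windows with F_ST ≥ mean + 3·sd (z exposed; the
threshold errors out below 10 finite windows and flags a zero-sd track);
haplotype blocks ≥ 400 kb.  Pooled intervals form maximal connected
overlap components; components with ≥ 2 distinct evidence types become
ROIs (monotone in `min_evidence`), ranked by evidence count, then marker
support, then span.  Regional PCA records first-2/first-5-PC variance and
the silhouette of the provided labels on the first two PCs.

## Problem sizes used in validation

Calibration experiments run at: F_ST recovery — 30 panels, 200/population,
5,000 loci; admixture accuracy — 5 panels, 100/population, ~1,900 retained
loci, K = 2; ΔK selection — 10 panels, 60/population, ~570 loci, K = 1–4
with 5 replicate starts; sweep recovery — 20 panels of 125 samples,
17 × 55-Mb chromosomes, ~16,000 SNPs, one 1-Mb sweep (fraction 0.9,
minority subpopulation, locally densified markers), plus 10 sweep-free
panels for the false-positive control.  The block-detection oracle runs on
single-chromosome mosaic panels (H = 6, 100-kb scale) with the sweep in
the majority population, where the planted interval carries a block at or
above the 95th percentile of background block sizes.

## Known limitations

- Candidate blocks cannot span farther than the pairwise window (500 kb
  default), since the endpoint pair must be present in the table.
- A sweep confined to a small minority subpopulation produces loading and
  F_ST evidence but not pooled-panel haplotype blocks; block evidence
  requires the swept haplotype to dominate the pooled sample.
- AMOVA degrees of freedom accumulate per locus under missingness, which
  treats loci as independent strata; with complete data this reduces to
  the textbook design.
- The EM admixture model assumes Hardy–Weinberg within clusters; under
  strong selfing the binomial likelihood is misspecified, which widens
  membership error (still < 0.05 mean absolute error at the validation
  sizes) but does not bias the maximum-likelihood memberships
  asymptotically.
- Permutation significance for AMOVA/F_ST, LDhat-style recombination-rate
  estimation, haplotype-HMM imputation and orthologue annotation are out
  of scope.
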
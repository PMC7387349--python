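"""Synthetic GBS genotype-panel generator.

Emulates the statistical structure of a diploid SNP panel genotyped by
reduced-representation sequencing in a highly selfing allotetraploid crop:
two diverged subpopulations whose allele frequencies follow the
Balding–Nichols model (Beta-distributed around an ancestral frequency,
parameterised directly by F_ST), strong excess homozygosity, missing calls
with Poisson read depths, and optional planted selective sweeps — local
founder haplotypes copied homozygously into a fraction of one subpopulation,
which depresses regional diversity and inflates regional LD and F_ST.

The generator is the test bed for every downstream statistic: truth labels
and planted intervals are carried alongside the genotypes so that estimators
can be scored against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import (
    MISSING,
    Gene,
    GenomeAnnotation,
    GenotypeMatrix,
    recompute_locus_stats,
    write_vcf,
)

#: chromosome names of the B and C subgenomes, in panel order
CHROM_NAMES = [f"B{i}" for i in range(1, 9)] + [f"C{i}" for i in range(1, 10)]

POP_LABELS = ("SP1", "SP2")


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: founder haplotype fixed in part of one subpopulation.

    ``extra_loci`` places additional markers inside the interval before the
    sweep is applied; swept regions of real reduced-representation panels
    carry an order of magnitude more discovered SNPs than the genome-wide
    average, and the evidence thresholds downstream assume that density.
    """

    chrom: str
    start: int
    end: int
    target_pop: int = 1
    haplotype_fraction: float = 0.9
    extra_loci: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"sweep interval start must precede end ({self.chrom}:{self.start}-{self.end})")
        if not 0 < self.haplotype_fraction <= 1:
            raise ValueError("haplotype_fraction must be in (0, 1]")
        if self.target_pop not in (0, 1):
            raise ValueError("target_pop must be 0 or 1")
        if self.extra_loci < 0:
            raise ValueError("extra_loci must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Panel-level study conditions.

    Defaults mirror the data set the package is designed around: 590
    assignable lines split 549/41 between two subpopulations differentiated
    at F_ST ~ 0.148, ~10,200 SNPs over 17 chromosomes (B1–B8, C1–C9),
    strong inbreeding (selfing_rate ~ observed F_IS), GBS-like missingness
    and depth.  Chromosomes are length-scaled to keep the panel desk-sized;
    SNP density, not physical genome size, is what the statistics see.
    """

    n_per_pop: tuple[int, int] = (549, 41)
    n_chrom: int = 17
    chrom_length: int = 5_000_000
    n_loci_per_chrom: int = 600
    fst_param: float = 0.148
    selfing_rate: float = 0.82
    missing_rate: float = 0.10
    depth_mean: float = 8.0
    sweep_specs: tuple[SweepSpec, ...] = ()
    #: 0 = per-locus binomial sampling (no background LD, exact
    #: Balding–Nichols calibration); > 0 = each gamete is a recombining
    #: mosaic of this many founder haplotypes per subpopulation, giving
    #: distance-decaying background LD and haplotype blocks at the cost of
    #: founder-pool drift on top of fst_param.
    n_founder_haplotypes: int = 0
    recomb_scale_bp: int = 500_000
    #: generate a reference sequence and gene models (needed for site
    #: annotation and export); disable for large statistical simulations
    #: where only genotypes and coordinates matter.
    with_annotation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_pop, int):
            object.__setattr__(self, "n_per_pop", (self.n_per_pop, self.n_per_pop))
        for name in ("fst_param", "selfing_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1 or (name == "fst_param" and v >= 1):
                raise ValueError(f"{name} must lie in [0, 1) resp. [0, 1], got {v}")
        if self.n_loci_per_chrom < 2:
            raise ValueError("n_loci_per_chrom must be >= 2")
        if not 1 <= self.n_chrom <= len(CHROM_NAMES):
            raise ValueError(f"n_chrom must be in 1..{len(CHROM_NAMES)}")
        if self.chrom_length < 200_000:
            raise ValueError("chrom_length must cover at least two 100-kb windows")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_founder_haplotypes < 0 or self.recomb_scale_bp <= 0:
            raise ValueError("n_founder_haplotypes must be >= 0 and recomb_scale_bp > 0")
        object.__setattr__(self, "sweep_specs", tuple(self.sweep_specs))

    @property
    def chrom_names(self) -> list[str]:
        return CHROM_NAMES[: self.n_chrom]


@dataclass
class PanelBundle:
    """A simulated panel: genotypes, variant table, annotation and truth."""

    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    annotation: GenomeAnnotation
    pop_labels: np.ndarray  # per-sample truth subpopulation label
    sweep_intervals: list[SweepSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotypes.n_loci != len(self.variants):
            raise ValueError("genotype columns and variant rows disagree")
        for sw in self.sweep_intervals:
            if sw.end > self.annotation.chrom_lengths.get(sw.chrom, sw.end):
                raise ValueError(f"sweep {sw.chrom}:{sw.start}-{sw.end} exceeds chromosome bounds")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions, without materialising 1..length."""
    draw = np.unique(rng.integers(1, length + 1, size=int(2.2 * n) + 16))
    while draw.size < n:  # vanishingly rare unless n ~ length
        draw = np.unique(np.concatenate([draw, rng.integers(1, length + 1, size=2 * n)]))
    return np.sort(rng.choice(draw, size=n, replace=False))


def _generate_genes(rng: np.random.Generator, chrom: str, length: int) -> list[Gene]:
    """Tile simple gene models along a chromosome.

    Composition is tuned so that, for uniformly placed SNPs, roughly 45% fall
    in CDS, 25% in introns and 30% between genes — GBS panels in Brassica
    are genic-biased, and the classifier needs all three classes populated.
    """
    genes = []
    pos = 1
    idx = 0
    while True:
        pos += int(rng.integers(200, 1201))  # intergenic gap
        n_exons = int(rng.integers(2, 5))
        exon_lens = 3 * rng.integers(70, 151, n_exons)  # CDS length divisible by 3
        intron_lens = rng.integers(150, 601, n_exons - 1) if n_exons > 1 else np.array([], dtype=int)
        span = int(exon_lens.sum() + intron_lens.sum())
        if pos + span - 1 > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        exons, cds, phases = [], [], []
        cursor = pos
        cum = 0
        for i in range(n_exons):
            s, e = cursor, cursor + int(exon_lens[i]) - 1
            exons.append((s, e))
            cds.append((s, e))
            cursor = e + 1 + (int(intron_lens[i]) if i < n_exons - 1 else 0)
            cum += int(exon_lens[i])
        # phase per CDS segment in genomic order (phase 0 at translation start)
        if strand == "+":
            run = 0
            for s, e in cds:
                phases.append((3 - run % 3) % 3)
                run += e - s + 1
        else:
            run = 0
            ph_rev = []
            for s, e in reversed(cds):
                ph_rev.append((3 - run % 3) % 3)
                run += e - s + 1
            phases = list(reversed(ph_rev))
        idx += 1
        genes.append(Gene(f"{chrom}g{idx:05d}", chrom, pos, cursor - 1 if n_exons > 1 else exons[-1][1], strand, exons, cds, phases))
        pos = genes[-1].end
    return genes


@dataclass
class _GameteDraw:
    alleles: np.ndarray   # gametes x loci, 0/1
    founders: np.ndarray  # founder haplotype pool, H x loci


def _mosaic_gametes(rng: np.random.Generator, p: np.ndarray, positions: np.ndarray,
                    n_gametes: int, n_founders: int, scale_bp: float,
                    founders: np.ndarray | None = None) -> _GameteDraw:
    """Gametes as recombining mosaics of a founder-haplotype pool.

    Founders are drawn per locus from the subpopulation frequencies; each
    gamete copies one founder and switches to a random founder between
    consecutive loci with probability 1 - exp(-d / scale_bp).  Background
    LD therefore decays with physical distance on the ``scale_bp`` scale.
    """
    L = len(p)
    if founders is None:
        founders = rng.binomial(1, p, (n_founders, L)).astype(np.int8)
    gaps = np.diff(positions)
    p_switch = 1 - np.exp(-gaps / scale_bp)
    switch = rng.random((n_gametes, L - 1)) < p_switch
    seg = np.concatenate([np.zeros((n_gametes, 1), dtype=np.int64), np.cumsum(switch, axis=1)], axis=1)
    choice = rng.integers(0, n_founders, (n_gametes, L))
    fidx = np.take_along_axis(choice, seg, axis=1)
    alleles = founders[fidx, np.arange(L)[None, :]]
    return _GameteDraw(alleles, founders)


def simulate_panel(config: SimulationConfig) -> PanelBundle:
    """Draw a two-subpopulation Balding–Nichols genotype panel.

    Ancestral frequencies are Uniform(0.05, 0.95); each subpopulation draws
    locus frequencies from Beta(p(1-F)/F, (1-p)(1-F)/F) with F =
    ``fst_param`` (F = 0 degenerates to identical frequencies).  Genotypes
    are Binomial(2, p); inbreeding converts each heterozygote to a random
    homozygote with probability ``selfing_rate``; missingness and Poisson
    depths are applied; sweeps are planted last.  Fully deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_per_pop
    n = n1 + n2
    pop = np.array([0] * n1 + [1] * n2)
    labels = np.array([POP_LABELS[p] for p in pop], dtype=object)

    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    chroms_col, pos_col = [], []
    dosage_cols, pop_freqs = [], []
    F = config.fst_param
    for chrom in config.chrom_names:
        if config.with_annotation:
            sequences[chrom] = _random_sequence(rng, config.chrom_length)
            genes.extend(_generate_genes(rng, chrom, config.chrom_length))
        positions = _sample_positions(rng, config.chrom_length, config.n_loci_per_chrom)
        for spec in config.sweep_specs:
            if spec.chrom == chrom and spec.extra_loci > 0:
                span = spec.end - spec.start
                extra = _sample_positions(rng, span, min(spec.extra_loci, span - 1)) + spec.start
                positions = np.unique(np.concatenate([positions, extra]))
        L = positions.size
        anc = rng.uniform(0.05, 0.95, L)
        if F > 0:
            a, b = anc * (1 - F) / F, (1 - anc) * (1 - F) / F
            p_sub = np.stack([rng.beta(a, b), rng.beta(a, b)])
        else:
            p_sub = np.stack([anc, anc])
        if config.n_founder_haplotypes == 0:
            dos = rng.binomial(2, p_sub[pop][:, :])  # n x L, linkage equilibrium
        else:
            dos = np.empty((n, L), dtype=np.int64)
            for k, n_pop in enumerate((n1, n2)):
                rows = np.flatnonzero(pop == k)
                g1 = _mosaic_gametes(rng, p_sub[k], positions, n_pop,
                                     config.n_founder_haplotypes, config.recomb_scale_bp)
                g2 = _mosaic_gametes(rng, p_sub[k], positions, n_pop,
                                     config.n_founder_haplotypes, config.recomb_scale_bp,
                                     founders=g1.founders)
                # inbreeding in mosaic mode doubles a whole gamete, which
                # preserves haplotype structure (per-locus heterozygote
                # conversion would act like recombination)
                doubled = rng.random(n_pop) < config.selfing_rate
                g2.alleles[doubled] = g1.alleles[doubled]
                dos[rows] = g1.alleles + g2.alleles
        dosage_cols.append(dos)
        pop_freqs.append(p_sub)
        chroms_col.extend([chrom] * L)
        pos_col.extend(positions.tolist())

    dosage = np.concatenate(dosage_cols, axis=1).astype(np.int16)
    pop_freq = np.concatenate(pop_freqs, axis=1)  # 2 x total loci

    if config.n_founder_haplotypes == 0:
        # inbreeding: heterozygote -> random homozygote with prob selfing_rate
        het = dosage == 1
        convert = het & (rng.random(dosage.shape) < config.selfing_rate)
        dosage[convert] = 2 * rng.integers(0, 2, int(convert.sum())).astype(np.int16)

    depth = rng.poisson(config.depth_mean, dosage.shape).astype(np.int32)
    depth[depth < 1] = 1  # observed calls need at least one read
    miss = rng.random(dosage.shape) < config.missing_rate
    dosage[miss] = MISSING
    depth[miss] = 0

    chrom_len = {c: config.chrom_length for c in config.chrom_names}
    ann = GenomeAnnotation(sequences=sequences, genes=genes, chrom_lengths=chrom_len)
    pos_arr = np.asarray(pos_col)
    chrom_arr = np.asarray(chroms_col, dtype=object)
    if config.with_annotation:
        ref = np.array([sequences[c][p - 1] for c, p in zip(chrom_arr, pos_arr)])
    else:
        ref = np.array(list("ACGT"))[rng.integers(0, 4, len(pos_arr))]
    alt_choice = rng.integers(0, 3, len(pos_arr))
    alt = np.array([("ACGT".replace(r.upper(), ""))[i] for r, i in zip(ref, alt_choice)])

    vt = pd.DataFrame({
        "chrom": chrom_arr,
        "pos": pos_arr,
        "ref": ref,
        "alt": alt,
    })
    vt["snp_name"] = vt["chrom"].astype(str) + "_" + vt["pos"].astype(str)
    vt["context"] = "NA"
    vt["effect"] = "NA"

    gm = GenotypeMatrix(dosage, depth, [f"S{i+1:04d}" for i in range(n)])
    gm, vt = recompute_locus_stats(gm, vt)
    panel = PanelBundle(gm, vt, ann, labels, [], config.seed)
    panel._pop_freq = pop_freq  # internal: used by plant_sweep founder draw
    for k, sw in enumerate(config.sweep_specs):
        panel = plant_sweep(panel, sw, seed=_derive_seed(config.seed, 101 + k))
    return panel


def _derive_seed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31 - 1))


def plant_sweep(panel: PanelBundle, spec: SweepSpec, seed: int | None = None) -> PanelBundle:
    """Copy a founder haplotype homozygously into part of the target pop.

    All loci in ``[start, end]`` on ``spec.chrom`` are overwritten (where
    the call is not missing) with twice the founder allele for a random
    ``haplotype_fraction`` of target-subpopulation samples.  Regional
    diversity in the target pop collapses; regional LD and F_ST rise.
    """
    if spec.chrom not in panel.annotation.chrom_lengths:
        raise KeyError(f"unknown chromosome {spec.chrom!r}")
    vt = panel.variants
    in_iv = ((vt["chrom"] == spec.chrom) & (vt["pos"] >= spec.start) & (vt["pos"] <= spec.end)).to_numpy()
    loci = np.flatnonzero(in_iv)
    if loci.size < 2:
        raise ValueError(
            f"sweep interval {spec.chrom}:{spec.start}-{spec.end} contains {loci.size} loci; need >= 2"
        )
    rng = np.random.default_rng(_derive_seed(panel.seed, 7919) if seed is None else seed)
    target = np.flatnonzero(panel.pop_labels == POP_LABELS[spec.target_pop])
    n_carrier = int(np.ceil(spec.haplotype_fraction * target.size))
    carriers = rng.choice(target, size=n_carrier, replace=False)

    # the founder is one random gamete of an existing target-pop sample: a
    # sweep amplifies a haplotype already segregating, so regional diversity
    # collapses onto the background haplotype pool rather than onto a novel
    # random haplotype
    donor = int(rng.choice(target))
    donor_dos = panel.genotypes.dosage[donor, loci]
    founder = np.where(donor_dos == 1, rng.integers(0, 2, loci.size), donor_dos // 2)
    if np.any(donor_dos == MISSING):  # fill donor gaps from target-pop frequency
        sub = panel.genotypes.dosage[np.ix_(target, loci)]
        obs = sub != MISSING
        p = np.where(obs, sub, 0).sum(0) / np.maximum(2 * obs.sum(0), 1)
        gaps = donor_dos == MISSING
        founder[gaps] = rng.binomial(1, p[gaps])

    gm = panel.genotypes.copy()
    block = gm.dosage[np.ix_(carriers, loci)]
    block[block != MISSING] = np.broadcast_to(2 * founder.astype(np.int16), block.shape)[block != MISSING]
    gm.dosage[np.ix_(carriers, loci)] = block

    gm, vt = recompute_locus_stats(gm, panel.variants)
    out = PanelBundle(gm, vt, panel.annotation, panel.pop_labels,
                      panel.sweep_intervals + [spec], panel.seed)
    if hasattr(panel, "_pop_freq"):
        out._pop_freq = panel._pop_freq
    return out


def export_panel(panel: PanelBundle, out_dir) -> dict[str, Path]:
    """Write VCF (GT:DP), GFF3, FASTA reference and a truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "panel.vcf",
        "gff3": out / "genes.gff3",
        "fasta": out / "reference.fa",
        "truth": out / "truth.tsv",
    }
    write_vcf(panel.genotypes, panel.variants, paths["vcf"])
    panel.annotation.write_gff3(paths["gff3"])
    panel.annotation.write_fasta(paths["fasta"])
    truth = pd.DataFrame({"sample_id": panel.genotypes.sample_ids, "pop_label": panel.pop_labels})
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if panel.sweep_intervals:
        sw = pd.DataFrame([s.__dict__ for s in panel.sweep_intervals])
        sw_path = out / "sweeps.tsv"
        sw.to_csv(sw_path, sep="\t", index=False)
        paths["sweeps"] = sw_path
    return paths
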
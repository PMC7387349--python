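"""SNP panel I/O, quality filtering, imputation and site annotation.

The central container is :class:`GenotypeMatrix`: a samples x loci matrix of
alternate-allele dosages (0/1/2, ``-1`` for missing) with per-call read
depths, as produced by reduced-representation (GBS) genotyping.  Loci are
described by a *variant table*, a :class:`pandas.DataFrame` with one row per
locus (columns ``chrom, pos, ref, alt, snp_name, maf, het_rate,
missing_rate, context, effect``).

Quality control follows the standard GBS recipe: per-call depth masking
first, then per-locus removal on minor allele frequency, observed
heterozygote fraction (which flags collapsed paralogs in a selfing species)
and missingness.  Missing calls are imputed by drawing from the locus allele
frequency, which leaves frequencies unbiased in expectation.  Sites are
classified against gene models as coding / intron / intergenic, and coding
sites as synonymous / non-synonymous by codon substitution on the transcript
strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

MISSING = -1  # dosage sentinel
DEPTH_UNKNOWN = -1  # depth sentinel when the VCF carries no DP for a call

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "snp_name",
    "maf", "het_rate", "missing_rate", "context", "effect",
]


@dataclass
class GenotypeMatrix:
    """Samples x loci ALT-allele dosages with per-call depths.

    ``dosage`` holds 0/1/2 and ``MISSING`` (-1); ``depth`` holds read depths
    with 0 for missing calls and ``DEPTH_UNKNOWN`` (-1) where the source VCF
    had no DP field.
    """

    dosage: np.ndarray
    depth: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.dosage.shape != self.depth.shape:
            raise ValueError("dosage and depth shapes differ")
        if self.dosage.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def take_loci(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[:, idx], self.depth[:, idx], list(self.sample_ids))

    def take_samples(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[idx, :], self.depth[idx, :], [self.sample_ids[i] for i in np.atleast_1d(idx)])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.copy(), self.depth.copy(), list(self.sample_ids))


@dataclass
class Gene:
    """One gene model: 1-based closed intervals, CDS in genomic order."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    phases: list[int] = field(default_factory=list)

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GenomeAnnotation:
    """Reference sequences plus gene models for a (pseudo-)genome."""

    sequences: dict[str, str]
    genes: list[Gene]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            self.chrom_lengths.setdefault(chrom, len(seq))
        for g in self.genes:
            if g.cds and g.cds_length() % 3 != 0:
                raise ValueError(f"CDS length of {g.gene_id} not divisible by 3")

    def ref_base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    # ---- GFF3 / FASTA round trip -------------------------------------

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for g in self.genes:
                gid = g.gene_id
                fh.write(f"{g.chrom}\tgbspop\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n")
                fh.write(f"{g.chrom}\tgbspop\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={gid}.1;Parent={gid}\n")
                for i, (s, e) in enumerate(g.exons):
                    fh.write(f"{g.chrom}\tgbspop\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={gid}.1.exon{i+1};Parent={gid}.1\n")
                for (s, e), ph in zip(g.cds, g.phases):
                    fh.write(f"{g.chrom}\tgbspop\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\tID={gid}.1.cds;Parent={gid}.1\n")

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    @classmethod
    def from_files(cls, gff3_path, fasta_path) -> "GenomeAnnotation":
        import gffutils
        from pyfaidx import Fasta

        fa = Fasta(str(fasta_path))
        sequences = {name: str(fa[name][:]) for name in fa.keys()}
        db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True)
        genes = []
        for gf in db.features_of_type("gene"):
            exons, cds, phases = [], [], []
            for mr in db.children(gf, featuretype="mRNA"):
                for ex in db.children(mr, featuretype="exon", order_by="start"):
                    exons.append((ex.start, ex.end))
                for c in db.children(mr, featuretype="CDS", order_by="start"):
                    cds.append((c.start, c.end))
                    phases.append(int(c.frame) if c.frame not in (None, ".") else 0)
                break  # one mRNA per gene in this package's models
            genes.append(Gene(gf.id, gf.seqid, gf.start, gf.end, gf.strand, exons, cds, phases))
        return cls(sequences=sequences, genes=genes)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a diploid biallelic-SNP VCF into a genotype matrix + variant table.

    Non-SNP and multi-allelic records are skipped (count logged).  ``./.``
    becomes a missing call; absent DP becomes :data:`DEPTH_UNKNOWN` so the
    depth filter can skip that call.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosages, depths, rows = [], [], []
    skipped = 0
    for rec_no, var in enumerate(vcf, start=1):
        try:
            if len(var.ALT) != 1 or not var.is_snp:
                skipped += 1
                continue
            gt = np.asarray(var.gt_types)  # gts012: 0,1,2 dosage; 3 unknown
            dos = np.where(gt == 3, MISSING, gt).astype(np.int16)
            dp = var.format("DP")
            if dp is None:
                dpv = np.full(len(samples), DEPTH_UNKNOWN, dtype=np.int32)
            else:
                dpv = dp.astype(np.int64).reshape(len(samples)).astype(np.int32)
                dpv[dpv < 0] = DEPTH_UNKNOWN  # cyvcf2 encodes '.' as large negative
                dpv[dos == MISSING] = np.where(dpv[dos == MISSING] == DEPTH_UNKNOWN, 0, dpv[dos == MISSING])
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValueError(f"malformed VCF record #{rec_no} in {path}: {exc}") from exc
        dosages.append(dos)
        depths.append(dpv)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    gm = GenotypeMatrix(np.array(dosages).T, np.array(depths).T, samples)
    vt = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    vt["snp_name"] = vt["chrom"].astype(str) + "_" + vt["pos"].astype(str)
    vt["context"] = "NA"
    vt["effect"] = "NA"
    return recompute_locus_stats(gm, vt)


def write_vcf(gm: GenotypeMatrix, vt: pd.DataFrame, path) -> None:
    """Write a minimal VCF 4.2 with GT:DP, suitable for round-tripping."""
    gt_strings = np.array(["0/0", "0/1", "1/1", "./."])
    code = np.where(gm.dosage == MISSING, 3, gm.dosage)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        seen = dict.fromkeys(vt["chrom"].astype(str))
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.sample_ids) + "\n")
        for l in range(gm.n_loci):
            row = vt.iloc[l]
            cells = [
                f"{gt_strings[code[s, l]]}:{'.' if gm.depth[s, l] == DEPTH_UNKNOWN else gm.depth[s, l]}"
                for s in range(gm.n_samples)
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_name}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int
    n_calls_depth_masked: int
    removed_maf: int
    removed_het: int
    removed_missing: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def recompute_locus_stats(gm: GenotypeMatrix, vt: pd.DataFrame) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Refresh maf / het_rate / missing_rate columns from the matrix."""
    obs = gm.observed
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, gm.dosage, 0).sum(axis=0) / np.maximum(2 * n_obs, 1)
        maf = np.minimum(p, 1 - p)
        het = (gm.dosage == 1).sum(axis=0) / np.maximum(n_obs, 1)
    vt = vt.copy()
    vt["maf"] = np.where(n_obs > 0, maf, np.nan)
    vt["het_rate"] = np.where(n_obs > 0, het, np.nan)
    vt["missing_rate"] = (gm.n_samples - n_obs) / gm.n_samples
    return gm, vt


def filter_snps(
    gm: GenotypeMatrix,
    vt: pd.DataFrame,
    maf_min: float = 0.05,
    het_max: float = 0.1,
    depth_min: int = 4,
    missing_max: float = 0.30,
) -> tuple[GenotypeMatrix, pd.DataFrame, FilterReport]:
    """Apply the panel quality filters in a fixed order.

    First every call with known depth < ``depth_min`` is masked missing;
    then loci are removed when (computed on the masked matrix, rules in this
    order) MAF <= ``maf_min``, observed heterozygote fraction > ``het_max``,
    or missing fraction > ``missing_max`` (inclusive boundary retained).
    Calls whose depth is unknown are exempt from the depth mask.
    """
    for name, val in [("maf_min", maf_min), ("het_max", het_max), ("missing_max", missing_max)]:
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    if depth_min < 0:
        raise ValueError("depth_min must be non-negative")

    gm = gm.copy()
    mask = (gm.depth != DEPTH_UNKNOWN) & (gm.depth < depth_min) & (gm.dosage != MISSING)
    n_masked = int(mask.sum())
    gm.dosage[mask] = MISSING
    gm.depth[mask] = 0

    gm, vt = recompute_locus_stats(gm, vt)
    n_input = gm.n_loci

    keep = np.ones(n_input, dtype=bool)
    low_maf = (vt["maf"].to_numpy() <= maf_min) | vt["maf"].isna().to_numpy()
    removed_maf = int(low_maf.sum())
    keep &= ~low_maf
    high_het = keep & (vt["het_rate"].to_numpy() > het_max)
    removed_het = int(high_het.sum())
    keep &= ~high_het
    high_miss = keep & (vt["missing_rate"].to_numpy() > missing_max)
    removed_missing = int(high_miss.sum())
    keep &= ~high_miss

    report = FilterReport(
        n_input=n_input,
        n_calls_depth_masked=n_masked,
        removed_maf=removed_maf,
        removed_het=removed_het,
        removed_missing=removed_missing,
        n_retained=int(keep.sum()),
    )
    return gm.take_loci(keep), vt.loc[keep].reset_index(drop=True), report


def impute_missing(gm: GenotypeMatrix, vt: pd.DataFrame | None = None, seed: int = 0) -> GenotypeMatrix:
    """Fill missing calls with Binomial(2, p-hat) draws at the locus frequency.

    Observed calls are never altered; a locus with no observed calls cannot
    be imputed and raises.
    """
    rng = np.random.default_rng(seed)
    gm = gm.copy()
    obs = gm.observed
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        bad = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"locus {bad} has zero observed calls; cannot impute")
    p = np.where(obs, gm.dosage, 0).sum(axis=0) / (2 * n_obs)
    miss_s, miss_l = np.nonzero(~obs)
    if miss_s.size:
        gm.dosage[miss_s, miss_l] = rng.binomial(2, p[miss_l]).astype(np.int16)
    return gm


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_sites(vt: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Classify each site as coding / intron / intergenic.

    Coding wins over intron for overlapping genes; a site inside a gene but
    inside a non-coding (UTR) exon is not an intron and falls through to
    intergenic.
    """
    from intervaltree import IntervalTree

    cds_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for g in ann.genes:
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1)
        for s, e in g.cds:
            cds_trees.setdefault(g.chrom, IntervalTree()).addi(s, e + 1)
        for s, e in g.exons:
            exon_trees.setdefault(g.chrom, IntervalTree()).addi(s, e + 1)

    known = set(ann.chrom_lengths)
    contexts = []
    for chrom, pos in zip(vt["chrom"].astype(str), vt["pos"]):
        if chrom not in known:
            raise KeyError(f"chromosome {chrom!r} absent from annotation")
        if chrom in cds_trees and cds_trees[chrom].overlaps_point(pos):
            contexts.append("coding")
        elif (
            chrom in gene_trees
            and gene_trees[chrom].overlaps_point(pos)
            and not (chrom in exon_trees and exon_trees[chrom].overlaps_point(pos))
        ):
            contexts.append("intron")
        else:
            contexts.append("intergenic")
    vt = vt.copy()
    vt["context"] = contexts
    return vt


def _transcript_cds(gene: Gene, ann: GenomeAnnotation) -> tuple[str, list[int]]:
    """CDS sequence on the transcript strand + genomic position per base."""
    seq_parts: list[str] = []
    pos_map: list[int] = []
    segs = sorted(gene.cds)
    if gene.strand == "+":
        for s, e in segs:
            seq_parts.append(ann.sequences[gene.chrom][s - 1:e])
            pos_map.extend(range(s, e + 1))
    else:
        for s, e in reversed(segs):
            seg = ann.sequences[gene.chrom][s - 1:e]
            seq_parts.append(str(Seq(seg).reverse_complement()))
            pos_map.extend(range(e, s - 1, -1))
    return "".join(seq_parts), pos_map


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def classify_coding_effect(chrom: str, pos: int, ref: str, alt: str, ann: GenomeAnnotation) -> str:
    """Synonymous / non-synonymous call for a coding SNP.

    The ALT base is substituted into its codon on the transcript strand and
    translated with the standard code; a premature stop counts as
    non-synonymous.
    """
    if ann.ref_base(chrom, pos).upper() != ref.upper():
        raise ValueError(f"reference base mismatch at {chrom}:{pos} (expected {ref})")
    for gene in ann.genes_on(chrom):
        if not any(s <= pos <= e for s, e in gene.cds):
            continue
        tx, pos_map = _transcript_cds(gene, ann)
        offset = pos_map.index(pos)  # first CDS segment carries phase 0 in these models
        codon_i = offset // 3
        codon = tx[codon_i * 3: codon_i * 3 + 3]
        if len(codon) < 3:
            return "NA"
        alt_tx = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
        within = offset % 3
        new_codon = codon[:within] + alt_tx + codon[within + 1:]
        aa_old = str(Seq(codon).translate())
        aa_new = str(Seq(new_codon).translate())
        return "synonymous" if aa_old == aa_new else "non-synonymous"
    raise ValueError(f"{chrom}:{pos} is not inside any CDS")


def annotate_effects(vt: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Fill the ``effect`` column for coding sites (others stay ``NA``)."""
    vt = vt.copy()
    effects = []
    for row in vt.itertuples():
        if row.context == "coding":
            effects.append(classify_coding_effect(str(row.chrom), int(row.pos), row.ref, row.alt, ann))
        else:
            effects.append("NA")
    vt["effect"] = effects
    return vt
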
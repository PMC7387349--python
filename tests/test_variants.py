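"""VCF I/O, quality filtering, imputation and site annotation."""

import numpy as np
import pandas as pd
import pytest

from gbspop.variants import (
    DEPTH_UNKNOWN,
    MISSING,
    Gene,
    GenomeAnnotation,
    annotate_sites,
    classify_coding_effect,
    filter_snps,
    impute_missing,
    read_vcf,
    write_vcf,
)

from conftest import make_gm, make_vt


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    "##contig=<ID=B1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def test_read_vcf_dosage_depth_and_missing(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        VCF_HEADER
        + "B1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:12\t1/1:7\n"
        + "B1\t200\t.\tC\tT\t.\tPASS\t.\tGT:DP\t./.:0\t0/0:9\n"
        + "B1\t300\t.\tG\tA,C\t.\tPASS\t.\tGT:DP\t0/1:5\t0/0:5\n"   # multi-allelic: skipped
        + "B1\t400\t.\tGT\tG\t.\tPASS\t.\tGT:DP\t0/1:5\t0/0:5\n"    # indel: skipped
    )
    gm, vt = read_vcf(vcf)
    assert gm.n_loci == 2 and gm.n_samples == 2
    assert gm.dosage[0, 0] == 1 and gm.depth[0, 0] == 12
    assert gm.dosage[1, 0] == 2 and gm.depth[1, 0] == 7
    assert gm.dosage[0, 1] == MISSING and gm.depth[0, 1] == 0
    assert list(vt["snp_name"]) == ["B1_100", "B1_200"]


def test_read_vcf_rejects_empty(tmp_path):
    vcf = tmp_path / "empty.vcf"
    vcf.write_text(VCF_HEADER)
    with pytest.raises(ValueError, match="no usable"):
        read_vcf(vcf)


def test_write_read_roundtrip(tmp_path, small_panel):
    path = tmp_path / "panel.vcf"
    write_vcf(small_panel.genotypes, small_panel.variants, path)
    assert sum(1 for l in path.read_text().splitlines() if not l.startswith("#")) == small_panel.genotypes.n_loci
    gm, vt = read_vcf(path)
    np.testing.assert_array_equal(gm.dosage, small_panel.genotypes.dosage)
    np.testing.assert_array_equal(gm.depth, small_panel.genotypes.depth)
    assert list(vt["pos"]) == list(small_panel.variants["pos"])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_thresholds_and_order():
    # 10 samples; columns engineered against each rule
    n = 10
    low_maf = np.zeros(n); low_maf[0] = 1                      # maf 0.05 -> removed (strict >)
    ok_maf = np.zeros(n); ok_maf[0] = 2                        # maf 0.10, no hets -> kept
    high_het = np.array([1, 1, 1, 0, 0, 0, 0, 0, 2, 2])       # het 0.3 -> removed
    missing31 = np.array([0] * 7 + [2, 2, 2])
    dosage = np.stack([low_maf, ok_maf, high_het, missing31], axis=1)
    depth = np.full(dosage.shape, 30, dtype=np.int32)
    depth[:3, 3] = 3  # 3/10 calls masked at locus 3 -> 30% missing, retained
    gm = make_gm(dosage, depth)
    vt = make_vt([100, 200, 300, 400])

    fgm, fvt, rep = filter_snps(gm, vt)
    assert rep.n_calls_depth_masked == 3
    assert rep.removed_maf == 1 and rep.removed_het == 1 and rep.removed_missing == 0
    assert list(fvt["pos"]) == [200, 400]

    # push locus 4 to 31% missing (depth mask 3 calls + 1 hard missing)
    dosage2 = dosage.copy(); dosage2[3, 3] = MISSING
    depth2 = depth.copy(); depth2[3, 3] = 0
    _, fvt2, rep2 = filter_snps(make_gm(dosage2, depth2), vt)
    assert rep2.removed_missing == 1
    assert list(fvt2["pos"]) == [200]


def test_filter_is_idempotent(small_panel):
    gm1, vt1, _ = filter_snps(small_panel.genotypes, small_panel.variants)
    gm2, vt2, rep2 = filter_snps(gm1, vt1)
    assert rep2.n_retained == gm1.n_loci
    np.testing.assert_array_equal(gm1.dosage, gm2.dosage)
    pd.testing.assert_frame_equal(vt1, vt2)


def test_filter_rejects_bad_thresholds(small_panel):
    with pytest.raises(ValueError):
        filter_snps(small_panel.genotypes, small_panel.variants, maf_min=1.5)


def test_depth_unknown_calls_exempt_from_masking():
    dosage = np.array([[1, 0], [0, 1], [1, 1], [2, 0]])
    depth = np.full(dosage.shape, DEPTH_UNKNOWN, dtype=np.int32)
    gm, vt, rep = filter_snps(make_gm(dosage, depth), make_vt([10, 20]), depth_min=4)
    assert rep.n_calls_depth_masked == 0


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def test_impute_fixed_locus_and_identity():
    dosage = np.array([[2, MISSING], [2, 1], [MISSING, 1], [2, 1]])
    gm = impute_missing(make_gm(dosage), seed=1)
    assert gm.dosage[2, 0] == 2  # observed frequency 1.0
    assert not np.any(gm.dosage == MISSING)
    full = make_gm(np.array([[0, 1], [2, 1]]))
    out = impute_missing(full, seed=3)
    np.testing.assert_array_equal(out.dosage, full.dosage)


def test_impute_errors_on_all_missing_locus():
    with pytest.raises(ValueError, match="zero observed"):
        impute_missing(make_gm(np.array([[MISSING, 1], [MISSING, 0]])), seed=0)


def test_impute_holdout_concordance_beats_random_guess():
    # at p = 0.5 the frequency-draw baseline concordance is exactly 0.375;
    # a mixed-MAF panel must beat it
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.9, 400)
    dosage = rng.binomial(2, p, (60, 400)).astype(np.int16)
    mask = rng.random(dosage.shape) < 0.05
    holdout = dosage.copy()
    holdout[mask] = MISSING
    imputed = impute_missing(make_gm(holdout), seed=9)
    concordance = (imputed.dosage[mask] == dosage[mask]).mean()
    assert concordance > 0.375


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@pytest.fixture()
def toy_annotation():
    #            1         2         3         4
    #   123456789012345678901234567890123456789012345
    seq = "TTTATGGGTAAACCGTTTTAGTTTTTTTTTCATTTTACCCGGG" + "T" * 57
    # gene g1 (+): exons 4-12 (CDS) and 19-21 (CDS), intron 13-18
    g1 = Gene("g1", "B1", 4, 21, "+", exons=[(4, 12), (19, 21)],
              cds=[(4, 12), (19, 21)], phases=[0, 0])
    # gene g2 (-): single CDS 31-36 (transcript reads revcomp)
    g2 = Gene("g2", "B1", 25, 40, "-", exons=[(25, 27), (31, 36)],
              cds=[(31, 36)], phases=[0])
    return GenomeAnnotation(sequences={"B1": seq}, genes=[g1, g2])


def test_annotate_sites_classes(toy_annotation):
    vt = make_vt([5, 15, 23, 33, 26, 38])
    out = annotate_sites(vt, toy_annotation)
    assert list(out["context"]) == [
        "coding",      # in CDS of g1
        "intron",      # between g1 exons
        "intergenic",  # between genes
        "coding",      # CDS of g2 (minus strand)
        "intergenic",  # UTR exon of g2: not coding, not intron
        "intron",      # inside g2, outside exons
    ]


def test_annotate_sites_partitions_all_loci(small_panel):
    out = annotate_sites(small_panel.variants, small_panel.annotation)
    counts = out["context"].value_counts()
    assert counts.sum() == len(out)
    assert set(counts.index) <= {"coding", "intron", "intergenic"}


def test_annotate_sites_unknown_chromosome(toy_annotation):
    with pytest.raises(KeyError):
        annotate_sites(make_vt([5], chrom="Z9"), toy_annotation)


def test_coding_effect_standard_codons(toy_annotation):
    # g1 transcript CDS: ATGGGTAAA + TAG; codon 2 = GGT (Gly)
    assert classify_coding_effect("B1", 9, "T", "C", toy_annotation) == "synonymous"    # GGT->GGC
    assert classify_coding_effect("B1", 6, "G", "A", toy_annotation) == "non-synonymous"  # ATG->ATA (Met->Ile)


def test_coding_effect_minus_strand(toy_annotation):
    # g2 CDS genomic 31-36 = 'CATTTT'; transcript (revcomp) = AAAATG
    # genomic C31->T reads G->A on the transcript: AAAATG -> AAAATA (Met->Ile)
    assert classify_coding_effect("B1", 31, "C", "T", toy_annotation) == "non-synonymous"
    # genomic T34->C is transcript A->G at codon1 pos3: AAA->AAG (Lys->Lys)
    assert classify_coding_effect("B1", 34, "T", "C", toy_annotation) == "synonymous"


def test_coding_effect_ref_mismatch(toy_annotation):
    with pytest.raises(ValueError, match="mismatch"):
        classify_coding_effect("B1", 9, "A", "C", toy_annotation)


def test_effect_invariant_under_strand_representation():
    """Representing the same gene on the reverse-complemented reference must
    not change effect calls (metamorphic check)."""
    from Bio.Seq import Seq

    seq = "AATATGCCGTTTAAGTAAGG"
    L = len(seq)
    gene_fwd = Gene("gf", "B1", 4, 18, "+", exons=[(4, 18)], cds=[(4, 18)], phases=[0])
    ann_fwd = GenomeAnnotation({"B1": seq}, [gene_fwd])
    rc = str(Seq(seq).reverse_complement())
    gene_rev = Gene("gr", "B1", L - 18 + 1, L - 4 + 1, "-",
                    exons=[(L - 18 + 1, L - 4 + 1)], cds=[(L - 18 + 1, L - 4 + 1)], phases=[0])
    ann_rev = GenomeAnnotation({"B1": rc}, [gene_rev])

    for pos in range(4, 19):
        ref = seq[pos - 1]
        for alt in "ACGT".replace(ref, ""):
            eff_fwd = classify_coding_effect("B1", pos, ref, alt, ann_fwd)
            pos_rc = L - pos + 1
            ref_rc = rc[pos_rc - 1]
            alt_rc = str(Seq(alt).reverse_complement())
            eff_rev = classify_coding_effect("B1", pos_rc, ref_rc, alt_rc, ann_rev)
            assert eff_fwd == eff_rev, (pos, ref, alt)


def test_annotation_gff3_roundtrip(tmp_path, small_panel):
    ann = small_panel.annotation
    gff = tmp_path / "g.gff3"
    fa = tmp_path / "r.fa"
    ann.write_gff3(gff)
    ann.write_fasta(fa)
    back = GenomeAnnotation.from_files(gff, fa)
    assert back.chrom_lengths == ann.chrom_lengths
    assert len(back.genes) == len(ann.genes)
    g0, b0 = ann.genes[0], back.genes[0]
    assert (g0.start, g0.end, g0.strand, g0.cds) == (b0.start, b0.end, b0.strand, b0.cds)
    vt_a = annotate_sites(small_panel.variants, ann)
    vt_b = annotate_sites(small_panel.variants, back)
    assert list(vt_a["context"]) == list(vt_b["context"])
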
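"""Region and codon-consequence classification.

The toy fixture places the mini-CDS "ATG GCT TAA" on both strands so the
hand-derivable cases (synonymous third-position change, ATG loss, stop
loss/gain) are asserted literally; larger-scale correctness is checked
against a full-protein translation oracle on constructively planted SNPs.
"""

import pytest
from Bio.Seq import Seq

from polmutscan.effects import (
    GeneIndex,
    classify_variant,
    classify_variants,
    genes_with_min_nonsyn,
    summarize_effects,
)
from polmutscan.models import GeneModel, GenomeSequence, Transcript, VariantEffect, revcomp
from tests.conftest import snp


@pytest.fixture(scope="module")
def toy_index(toy_genes, toy_genome):
    return GeneIndex(toy_genes, toy_genome)


# --------------------------------------------------- plus-strand toy gene
# CDS (1-based 101..109) = ATG GCT TAA

@pytest.mark.parametrize(
    "pos,ref,alt,effect,codon_change",
    [
        (106, "T", "C", "synonymous", "GCT>GCC"),    # Ala -> Ala
        (106, "T", "A", "synonymous", "GCT>GCA"),    # Ala fourfold-degenerate
        (105, "C", "A", "nonsynonymous", "GCT>GAT"),  # Ala -> Asp
        (104, "G", "T", "nonsynonymous", "GCT>TCT"),  # Ala -> Ser
        (101, "A", "G", "start_loss", "ATG>GTG"),
        (107, "T", "C", "stop_loss", "TAA>CAA"),
    ],
)
def test_plus_strand_cds_snp_effects(
    toy_index, toy_genome, pos, ref, alt, effect, codon_change
):
    e = classify_variant(snp(pos, ref, alt), toy_index, toy_genome)
    assert e.region == "CDS" and e.gene_id == "gplus"
    assert e.coding_effect == effect and e.codon_change == codon_change


def test_stop_to_stop_counts_synonymous(toy_index, toy_genome):
    # TAA>TAG: both stops
    e = classify_variant(snp(109, "A", "G"), toy_index, toy_genome)
    assert e.coding_effect == "synonymous" and e.aa_change == "*3*"


def test_start_loss_takes_precedence_and_is_large_effect(toy_index, toy_genome):
    e = classify_variant(snp(103, "G", "A"), toy_index, toy_genome)  # ATG>ATA
    assert e.coding_effect == "start_loss" and e.large_effect


# --------------------------------------------------- minus-strand toy gene
# genomic [200,209) = TTAAGCCAT; transcript CDS = ATG GCT TAA

def test_minus_strand_start_loss(toy_index, toy_genome):
    # genomic 0-based 208 is the complement of the ATG 'A'
    e = classify_variant(snp(209, "T", "C"), toy_index, toy_genome)
    assert e.gene_id == "gminus"
    assert e.coding_effect == "start_loss" and e.codon_change == "ATG>GTG"


def test_minus_strand_synonymous_third_position(toy_index, toy_genome):
    # transcript GCT>GCC via genomic A->G at 0-based 203
    e = classify_variant(snp(204, "A", "G"), toy_index, toy_genome)
    assert e.coding_effect == "synonymous" and e.codon_change == "GCT>GCC"


def test_minus_strand_stop_loss(toy_index, toy_genome):
    # transcript TAA>CAA via genomic A->G at 0-based 202 (complement of T)
    e = classify_variant(snp(203, "A", "G"), toy_index, toy_genome)
    assert e.coding_effect == "stop_loss" and e.large_effect


# --------------------------------------------------- regions

@pytest.mark.parametrize(
    "pos,region,gene",
    [
        (50, "intergenic", None),
        (90, "UTR5", "gplus"),
        (115, "UTR3", "gplus"),
        (220, "UTR5", "gminus"),
        (190, "UTR3", "gminus"),
    ],
)
def test_region_assignment(toy_index, toy_genome, pos, region, gene):
    ref = toy_genome.seq("chr1")[pos - 1]
    alt = "A" if ref != "A" else "G"
    e = classify_variant(snp(pos, ref, alt), toy_index, toy_genome)
    assert e.region == region and e.gene_id == gene
    assert e.coding_effect == "NA"


def test_intron_region():
    seq = list(("ACGT" * 100)[:400])
    seq[100:106] = "ATGGCT"
    seq[150:153] = "TAA"
    genome = GenomeSequence({"chr1": "".join(seq)})
    gene = GeneModel(
        "g1", "chr1", "+", 100, 153,
        [Transcript("g1.t1", exons=[(100, 106), (150, 153)],
                    cds=[(100, 106), (150, 153)])],
    )
    idx = GeneIndex([gene], genome)
    ref = genome.seq("chr1")[120]
    e = classify_variant(snp(121, ref, "A" if ref != "A" else "C"), idx, genome)
    assert e.region == "intron" and e.coding_effect == "NA"
    # codon spanning the junction: CDS = ATGGCT|TAA, pos 151 is 2nd stop base
    e2 = classify_variant(snp(152, "A", "G"), idx, genome)
    assert e2.region == "CDS" and e2.codon_change == "TAA>TGA"
    assert e2.coding_effect == "synonymous"


def test_indels_in_cds_frameshift_vs_inframe(toy_index, toy_genome):
    from polmutscan.models import Variant

    ref3 = toy_genome.seq("chr1")[103:107]  # 0-based 103..106
    fs = Variant("chr1", 104, ref3[0], ref3[0] + "TT", qual=40, depth=20)
    inf = Variant("chr1", 104, ref3, ref3[0], qual=40, depth=20)  # 3-bp deletion
    e_fs = classify_variant(fs, toy_index, toy_genome)
    e_in = classify_variant(inf, toy_index, toy_genome)
    assert e_fs.coding_effect == "frameshift"
    assert e_in.coding_effect == "inframe_indel"


# --------------------------------------------------- oracle + properties

def _protein_oracle(cds_ref: str, cds_alt: str) -> str:
    """Independent classification from full-protein translation."""
    if cds_alt[:3] != "ATG":
        return "start_loss"
    rp = str(Seq(cds_ref).translate())
    ap = str(Seq(cds_alt).translate())
    if ap == rp:
        return "synonymous"
    r_stop = rp.index("*") if "*" in rp else len(rp)
    a_stop = ap.index("*") if "*" in ap else len(ap)
    if a_stop < r_stop:
        return "stop_gain"
    if a_stop > r_stop:
        return "stop_loss"
    return "nonsynonymous"


def test_classifier_agrees_with_protein_oracle_on_planted_snps(small_sim):
    _, genome, genes, variants, _, truth = small_sim
    index = GeneIndex(genes, genome)
    frames = {g.gene_id: index.frame(g) for g in genes}
    checked = 0
    for v in variants:
        key = (v.chrom, v.pos, v.ref, v.alt)
        if key not in truth.variant_effects:
            continue
        e = classify_variant(v, index, genome)
        assert e.coding_effect == truth.variant_effects[key]
        fr = frames[e.gene_id]
        idx = fr.cds_index(v.start0)
        alt_t = v.alt if fr.gene.strand == "+" else revcomp(v.alt)
        cds_alt = fr.cds_seq[:idx] + alt_t + fr.cds_seq[idx + 1 :]
        assert _protein_oracle(fr.cds_seq, cds_alt) == e.coding_effect
        checked += 1
    assert checked == len(truth.variant_effects) > 0


def test_strand_symmetry(small_sim):
    """Reverse-complementing genome, annotation and variants keeps labels."""
    _, genome, genes, variants, _, truth = small_sim
    flipped_genome = GenomeSequence(
        {c: revcomp(genome.seq(c)) for c in genome.chrom_names}
    )

    def flip_iv(iv, L):
        return (L - iv[1], L - iv[0])

    flipped_genes = []
    for g in genes:
        L = genome.length(g.chrom)
        t = g.transcripts[0]
        flipped_genes.append(
            GeneModel(
                g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                L - g.end, L - g.start,
                [
                    Transcript(
                        t.transcript_id,
                        exons=sorted(flip_iv(iv, L) for iv in t.exons),
                        cds=sorted(flip_iv(iv, L) for iv in t.cds),
                        utr5=sorted(flip_iv(iv, L) for iv in t.utr5),
                        utr3=sorted(flip_iv(iv, L) for iv in t.utr3),
                    )
                ],
            )
        )
    planted = [
        v for v in variants
        if (v.chrom, v.pos, v.ref, v.alt) in truth.variant_effects and v.is_snp
    ]
    flipped_variants = [
        snp(
            genome.length(v.chrom) - v.start0,  # 1-based pos of the mirrored base
            revcomp(v.ref),
            revcomp(v.alt),
            chrom=v.chrom,
        )
        for v in planted
    ]
    orig = classify_variants(planted, genes, genome)
    flip = classify_variants(flipped_variants, flipped_genes, flipped_genome)
    assert [e.coding_effect for e in orig] == [e.coding_effect for e in flip]
    assert [e.region for e in orig] == [e.region for e in flip]


def test_region_partition_and_summary(small_sim):
    _, genome, genes, variants, *_ = small_sim
    effects = classify_variants(variants, genes, genome)
    n_snp = sum(1 for v in variants if v.is_snp)
    summary = summarize_effects(effects, genome)
    assert summary.n_total == n_snp
    assert summary.n_genic + summary.n_intergenic == n_snp
    # per-chromosome rows sum to the totals
    pc = summary.per_chrom
    assert int(pc["CDS"].sum()) == summary.n_cds
    assert int(pc["intergenic"].sum()) == summary.n_intergenic


def test_genes_with_min_nonsyn_counting(toy_genome):
    v = snp(1, "A", "G")
    effs = [
        VariantEffect(v, "CDS", "nonsynonymous", gene_id="g1"),
        VariantEffect(v, "CDS", "nonsynonymous", gene_id="g1"),
        VariantEffect(v, "CDS", "nonsynonymous", gene_id="g1"),
        VariantEffect(v, "CDS", "nonsynonymous", gene_id="g2"),
        VariantEffect(v, "CDS", "synonymous", gene_id="g2"),
    ]
    assert genes_with_min_nonsyn(effs, min_count=2) == 1
    assert genes_with_min_nonsyn(effs, min_count=1) == 2
    with pytest.raises(Exception):
        genes_with_min_nonsyn(effs, min_count=0)
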
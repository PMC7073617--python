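"""BH adjustment, DEG calling, promoters and promoter-variant intersection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polmutscan.expression import (
    DEGSummary,
    bh_adjust,
    call_degs,
    extract_promoters,
    intersect_promoter_variants,
)
from polmutscan.models import (
    ExpressionRecord,
    GeneModel,
    GenomeSequence,
    ModelError,
    Transcript,
    Variant,
)
from tests.conftest import snp


def bh_oracle(ps):
    """Textbook BH step-up written independently of the implementation."""
    n = len(ps)
    order = sorted(range(n), key=lambda i: ps[i])
    adj = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, ps[i] * n / rank)
        adj[i] = prev
    return adj


def test_bh_hand_example():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_single_value_identity():
    assert bh_adjust([0.5]) == [0.5]


def test_bh_rejects_out_of_range():
    with pytest.raises(ModelError):
        bh_adjust([0.1, 1.2])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_matches_independent_oracle(ps):
    assert bh_adjust(ps) == pytest.approx(bh_oracle(ps))


# ------------------------------------------------------------- DEG calls

def rec(gid, lfc, p=None, padj=None):
    return ExpressionRecord(gene_id=gid, log2fc=lfc, pvalue=p, padj=padj)


def test_deg_thresholds_are_strict():
    out = call_degs([rec("g1", 1.0, padj=0.01), rec("g2", 1.5, padj=0.04),
                     rec("g3", -2.0, padj=0.05), rec("g4", -1.2, padj=0.001)])
    assert [r.deg_status for r in out] == ["not_deg", "up", "not_deg", "down"]


def test_deg_calling_adjusts_raw_pvalues():
    out = call_degs([rec("g1", 2.0, p=0.001)] + [rec(f"n{i}", 0.0, p=0.9) for i in range(9)])
    assert out[0].padj == pytest.approx(0.01) and out[0].deg_status == "up"


def test_deg_missing_both_p_fields_is_error():
    with pytest.raises(ModelError):
        call_degs([rec("g1", 2.0)])


def test_deg_permutation_invariance():
    rows = [rec(f"g{i}", lfc, p=p) for i, (lfc, p) in enumerate(
        [(2.0, 1e-4), (0.5, 0.3), (-1.5, 1e-3), (1.2, 0.2), (-3.0, 1e-5)]
    )]
    fwd = {r.gene_id: r.deg_status for r in call_degs(rows)}
    rev = {r.gene_id: r.deg_status for r in call_degs(rows[::-1])}
    assert fwd == rev


def test_deg_set_shrinks_as_thresholds_tighten(small_sim):
    *_, expression, _ = small_sim
    loose = {r.gene_id for r in call_degs(expression) if r.deg_status != "not_deg"}
    tight = {
        r.gene_id
        for r in call_degs(expression, lfc_threshold=2.0, padj_threshold=0.01)
        if r.deg_status != "not_deg"
    }
    assert tight <= loose


def test_planted_degs_recovered_exactly(small_sim):
    cfg, _, _, _, expression, truth = small_sim
    called = {r.gene_id: r.deg_status for r in call_degs(expression)}
    assert called == truth.deg_status
    summary = DEGSummary.from_records(call_degs(expression))
    assert summary.n_up == cfg.n_deg_up and summary.n_down == cfg.n_deg_down
    assert summary.n_total == cfg.n_genes


def test_deg_summary_additivity():
    s = DEGSummary(n_up=3, n_down=4, n_not_deg=13)
    assert s.n_deg == 7 and s.n_total == 20


# ------------------------------------------------------------- promoters

def _gene(gid, strand, t_start, t_end, chrom="chr1"):
    return GeneModel(
        gid, chrom, strand, t_start, t_end,
        [Transcript(f"{gid}.t1", exons=[(t_start, t_end)], cds=[])],
    )


def test_promoter_plus_strand():
    g = GenomeSequence({"chr1": "A" * 10_000})
    (p,) = extract_promoters([_gene("g1", "+", 5000, 6000)], g)
    assert (p.start, p.end, p.clipped) == (3000, 5000, False)


def test_promoter_minus_strand():
    g = GenomeSequence({"chr1": "A" * 10_000})
    (p,) = extract_promoters([_gene("g1", "-", 7000, 8000)], g)
    assert (p.start, p.end, p.clipped) == (8000, 10_000, False)


def test_promoter_clipped_at_chromosome_edge():
    g = GenomeSequence({"chr1": "A" * 10_000})
    (p,) = extract_promoters([_gene("g1", "+", 500, 900)], g)
    assert (p.start, p.end, p.clipped) == (0, 500, True)


def test_promoters_never_overlap_own_gene(small_sim):
    _, genome, genes, *_ = small_sim
    by_id = {g.gene_id: g for g in genes}
    for p in extract_promoters(genes, genome):
        assert p.end - p.start <= 2000
        g = by_id[p.gene_id]
        span = g.transcripts[0].span
        assert p.end <= span[0] or p.start >= span[1]


# ------------------------------------------------------------- intersection

def test_intersection_empty_variants():
    g = GenomeSequence({"chr1": "A" * 10_000})
    genes = [_gene("g1", "+", 5000, 6000)]
    proms = extract_promoters(genes, g)
    degs = [rec("g1", 2.0, padj=0.001)]
    degs = call_degs(degs)
    s = intersect_promoter_variants(degs, proms, [])
    assert (s.n_deg_with_promoter_snp, s.pct_snp) == (0, 0.0)


def test_intersection_counts_gene_once_per_class():
    g = GenomeSequence({"chr1": "A" * 10_000})
    genes = [_gene("g1", "+", 5000, 6000)]
    proms = extract_promoters(genes, g)
    degs = call_degs([rec("g1", 2.0, padj=0.001)])
    vs = [
        snp(3500, "A", "G"),
        snp(4000, "A", "C"),  # second promoter SNP: still one hit gene
        Variant("chr1", 4500, "AA", "A", qual=40, depth=20),
        snp(5500, "A", "G"),  # inside the gene, not the promoter
    ]
    s = intersect_promoter_variants(degs, proms, vs)
    assert s.n_deg_with_promoter_snp == 1 and s.n_deg_with_promoter_indel == 1
    assert s.pct_snp == 100.0


def test_intersection_missing_annotation_warns_and_excludes(caplog):
    g = GenomeSequence({"chr1": "A" * 10_000})
    proms = extract_promoters([_gene("g1", "+", 5000, 6000)], g)
    degs = call_degs([rec("g1", 2.0, padj=0.001), rec("ghost", -2.0, padj=0.001)])
    with caplog.at_level("WARNING", logger="polmutscan"):
        s = intersect_promoter_variants(degs, proms, [])
    assert s.n_missing_annotation == 1 and s.n_deg == 1
    assert "ghost" in caplog.text


def test_intersection_matches_bruteforce_oracle(small_sim):
    _, genome, genes, variants, expression, _ = small_sim
    degs = call_degs(expression)
    proms = extract_promoters(genes, genome)
    s = intersect_promoter_variants(degs, proms, variants)
    # O(n*m) nested-loop oracle
    prom_by_gene = {p.gene_id: p for p in proms}
    exp_snp, exp_indel = set(), set()
    for r in degs:
        if r.deg_status == "not_deg" or r.gene_id not in prom_by_gene:
            continue
        p = prom_by_gene[r.gene_id]
        for v in variants:
            if v.chrom == p.chrom and p.start <= v.start0 < p.end:
                (exp_snp if v.is_snp else exp_indel).add(r.gene_id)
    assert set(s.snp_hit_genes) == exp_snp
    assert set(s.indel_hit_genes) == exp_indel


def test_planted_promoter_variants_recovered(small_sim):
    _, genome, genes, variants, expression, truth = small_sim
    degs = call_degs(expression)
    proms = extract_promoters(genes, genome)
    s = intersect_promoter_variants(degs, proms, variants)
    deg_ids = {r.gene_id for r in degs if r.deg_status != "not_deg"}
    # every planted promoter-SNP gene that is also a DEG must be a hit
    assert truth.promoter_snp_genes & deg_ids <= set(s.snp_hit_genes)
    assert truth.promoter_indel_genes & deg_ids <= set(s.indel_hit_genes)
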
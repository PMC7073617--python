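"""Simulator: determinism, structural validity of generated gene models,
substitution model, planted truth."""

import numpy as np
import pytest
from Bio.Seq import Seq

from polmutscan import io
from polmutscan.models import ModelError
from polmutscan.simulate import (
    SimulationConfig,
    generate_expression,
    generate_genome,
    inject_variants,
)


def test_generation_is_byte_identical_under_seed(tmp_path):
    cfg = SimulationConfig(seed=7, n_chrom=1, chrom_length=100_000, n_genes=10,
                           n_deg_up=2, n_deg_down=2)
    for i, d in enumerate(("a", "b")):
        g, genes = generate_genome(cfg)
        (tmp_path / d).mkdir()
        io.write_fasta(g, tmp_path / d / "g.fa")
        io.write_gff3(genes, tmp_path / d / "g.gff3")
    assert (tmp_path / "a/g.fa").read_bytes() == (tmp_path / "b/g.fa").read_bytes()
    assert (tmp_path / "a/g.gff3").read_bytes() == (tmp_path / "b/g.gff3").read_bytes()


def test_zero_genes_gives_empty_annotation():
    cfg = SimulationConfig(seed=1, n_chrom=1, chrom_length=50_000, n_genes=0,
                           n_deg_up=0, n_deg_down=0)
    g, genes = generate_genome(cfg)
    assert genes == [] and g.length("chr1") == 50_000


def test_too_many_genes_is_capacity_error():
    cfg = SimulationConfig(seed=1, n_chrom=1, chrom_length=40_000, n_genes=50,
                           n_deg_up=0, n_deg_down=0)
    with pytest.raises(ModelError, match="capacity"):
        generate_genome(cfg)


def test_generated_cds_translate_cleanly(small_sim):
    """Translation oracle: ATG start, single terminal stop, no internal stop."""
    _, genome, genes, *_ = small_sim
    n_with_intron = 0
    for g in genes:
        t = g.transcripts[0]
        if len(t.exons) > 1:
            n_with_intron += 1
        parts = [genome.seq(g.chrom)[s:e] for s, e in t.cds]
        cds = "".join(parts)
        if g.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        assert len(cds) % 3 == 0
        prot = str(Seq(cds).translate())
        assert cds.startswith("ATG")
        assert prot.endswith("*") and "*" not in prot[:-1]
        # exons cover all cds and utr segments, inside the gene span
        for seg in t.cds + t.utr5 + t.utr3:
            assert any(s <= seg[0] and seg[1] <= e for s, e in t.exons)
        assert t.exons[0][0] >= g.start and t.exons[-1][1] <= g.end
    assert n_with_intron >= len(genes) / 2


def test_genes_do_not_overlap(small_sim):
    _, _, genes, *_ = small_sim
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for spans in by_chrom.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


def test_zero_rates_and_no_plants_give_no_variants():
    cfg = SimulationConfig(seed=2, n_chrom=1, chrom_length=50_000, n_genes=2,
                           snp_rate=0.0, indel_rate=0.0,
                           promoter_variant_fraction=0.0,
                           n_deg_up=0, n_deg_down=0)
    g, genes = generate_genome(cfg)
    vs, truth = inject_variants(g, genes, cfg)
    assert vs == [] and truth.variant_effects == {}


def test_variants_match_reference_and_do_not_overlap(small_sim):
    _, genome, _, variants, *_ = small_sim
    prev_end = {}
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        assert genome.seq(v.chrom)[v.start0 : v.end0] == v.ref
        assert v.start0 >= prev_end.get(v.chrom, 0)
        prev_end[v.chrom] = v.end0
        if v.is_indel:
            assert 1 <= abs(len(v.alt) - len(v.ref)) <= 10


def test_transition_draw_matches_binomial_expectation():
    """Empirical Ts fraction over many SNPs ~ w/(w+2) (law of large numbers)."""
    cfg = SimulationConfig(seed=3, n_chrom=1, chrom_length=2_000_000, n_genes=0,
                           snp_rate=5e-3, indel_rate=0.0,
                           promoter_variant_fraction=0.0,
                           n_deg_up=0, n_deg_down=0)
    g, genes = generate_genome(cfg)
    vs, _ = inject_variants(g, genes, cfg)
    ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    n_ts = sum(1 for v in vs if ts[v.ref] == v.alt)
    p_hat = n_ts / len(vs)
    p = 4.76 / 6.76
    se = np.sqrt(p * (1 - p) / len(vs))
    assert abs(p_hat - p) < 4 * se


def test_planted_filter_failures_fraction():
    cfg = SimulationConfig(seed=4, n_chrom=1, chrom_length=2_000_000, n_genes=0,
                           snp_rate=2e-3, indel_rate=0.0,
                           promoter_variant_fraction=0.0,
                           fail_filter_fraction=0.25,
                           n_deg_up=0, n_deg_down=0)
    g, genes = generate_genome(cfg)
    vs, truth = inject_variants(g, genes, cfg)
    from polmutscan.variants import filter_variants

    kept = filter_variants(vs)
    # truth bookkeeping is consistent with the actual filter
    expected = {k for k, ok in truth.passes_filter.items() if ok}
    assert {(v.chrom, v.pos, v.ref, v.alt) for v in kept} == expected
    frac_failed = 1 - len(kept) / len(vs)
    assert 0.18 < frac_failed < 0.32


def test_impossible_effect_plant_raises():
    cfg = SimulationConfig(seed=5, n_chrom=1, chrom_length=100_000, n_genes=1,
                           n_deg_up=0, n_deg_down=0,
                           snp_rate=0.0, indel_rate=0.0,
                           promoter_variant_fraction=0.0,
                           n_effect_plants=50, effect_mix={"start_loss": 1.0})
    g, genes = generate_genome(cfg)
    # one gene has only 3 ATG positions; 50 start_loss plants cannot fit
    with pytest.raises(ModelError, match="start_loss"):
        inject_variants(g, genes, cfg)


def test_expression_table_deterministic_and_planted():
    cfg = SimulationConfig(seed=6, n_chrom=1, chrom_length=300_000, n_genes=30,
                           n_deg_up=5, n_deg_down=5)
    _, genes = generate_genome(cfg)
    ex1, t1 = generate_expression(genes, cfg)
    ex2, t2 = generate_expression(genes, cfg)
    assert [(r.gene_id, r.log2fc, r.pvalue) for r in ex1] == [
        (r.gene_id, r.log2fc, r.pvalue) for r in ex2
    ]
    assert t1.deg_status == t2.deg_status
    n_up = sum(1 for s in t1.deg_status.values() if s == "up")
    assert n_up == 5
    for r in ex1:
        if t1.deg_status[r.gene_id] != "not_deg":
            assert abs(r.log2fc) > 1 and r.pvalue < 1e-5
        else:
            assert r.pvalue >= 0.5  # strict-null mode


def test_no_planted_degs_means_no_calls():
    from polmutscan.expression import call_degs

    cfg = SimulationConfig(seed=8, n_chrom=1, chrom_length=300_000, n_genes=40,
                           n_deg_up=0, n_deg_down=0)
    _, genes = generate_genome(cfg)
    ex, _ = generate_expression(genes, cfg)
    assert all(r.deg_status == "not_deg" for r in call_degs(ex))
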
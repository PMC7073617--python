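"""DEG calling and promoter-variant intersection.

A gene is differentially expressed when |log2FC| > 1 with BH-adjusted
p < 0.05 (strict inequalities).  Promoters are the <= 2 kb immediately
upstream of the transcription start site, strand-aware; the intersection
stage counts DEGs carrying at least one SNP and/or at least one InDel in
their promoter.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .models import (
    ExpressionRecord,
    GeneModel,
    GenomeSequence,
    ModelError,
    PromoterInterval,
    Variant,
)

logger = logging.getLogger("polmutscan")


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ModelError("p-values must lie in [0,1]")
    return list(multipletests(p, method="fdr_bh")[1])


def call_degs(
    records: Iterable[ExpressionRecord],
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> list[ExpressionRecord]:
    """Return new records with padj filled (BH over the table when absent)
    and deg_status set to up / down / not_deg.

    Thresholds are strict: log2FC must exceed the threshold in magnitude
    and adjusted p must be below padj_threshold.
    """
    recs = list(records)
    if any(r.padj is None for r in recs):
        missing_p = [r.gene_id for r in recs if r.pvalue is None]
        if missing_p:
            raise ModelError(
                f"records without pvalue or padj: {missing_p[:5]}"
                + ("..." if len(missing_p) > 5 else "")
            )
        adj = bh_adjust([r.pvalue for r in recs])
        recs = [replace(r, padj=a) for r, a in zip(recs, adj)]
    out = []
    for r in recs:
        if r.padj < padj_threshold and r.log2fc > lfc_threshold:
            status = "up"
        elif r.padj < padj_threshold and r.log2fc < -lfc_threshold:
            status = "down"
        else:
            status = "not_deg"
        out.append(replace(r, deg_status=status))
    return out


@dataclass
class DEGSummary:
    """Bookkeeping of a DEG call: up + down must equal the DEG total."""

    n_up: int
    n_down: int
    n_not_deg: int = 0

    @property
    def n_deg(self) -> int:
        return self.n_up + self.n_down

    @property
    def n_total(self) -> int:
        return self.n_deg + self.n_not_deg

    @classmethod
    def from_records(cls, records: Iterable[ExpressionRecord]) -> "DEGSummary":
        up = down = other = 0
        for r in records:
            if r.deg_status == "up":
                up += 1
            elif r.deg_status == "down":
                down += 1
            else:
                other += 1
        return cls(n_up=up, n_down=down, n_not_deg=other)


def extract_promoters(
    genes: Iterable[GeneModel], genome: GenomeSequence, length: int = 2000
) -> list[PromoterInterval]:
    """Strand-aware upstream promoter intervals, clipped at chromosome edges.

    The TSS is the 5'-most transcribed coordinate of the gene's longest
    transcript.  On '+' the promoter is [TSS-length, TSS); on '-' it is
    [span_end, span_end + length) in genome coordinates.
    """
    if length <= 0:
        raise ModelError("promoter length must be > 0")
    out = []
    for g in genes:
        t = g.longest_transcript()
        span = t.span if t is not None else (g.start, g.end)
        if g.strand == "+":
            start, end = span[0] - length, span[0]
            clipped = start < 0
            start = max(start, 0)
        else:
            chrom_len = genome.length(g.chrom)
            start, end = span[1], span[1] + length
            clipped = end > chrom_len
            end = min(end, chrom_len)
        if end <= start:
            # TSS at the very chromosome edge: no upstream sequence at all
            out.append(
                PromoterInterval(g.gene_id, g.chrom, start, start, g.strand, True)
            )
            continue
        out.append(PromoterInterval(g.gene_id, g.chrom, start, end, g.strand, clipped))
    return out


def _pct1(num: int, den: int) -> float:
    if den == 0:
        return 0.0
    return math.floor(1000.0 * num / den + 0.5) / 10


@dataclass
class PromoterHitSummary:
    n_deg: int
    n_deg_with_promoter_snp: int
    n_deg_with_promoter_indel: int
    snp_hit_genes: list[str] = field(default_factory=list)
    indel_hit_genes: list[str] = field(default_factory=list)
    n_missing_annotation: int = 0

    @property
    def pct_snp(self) -> float:
        """Percent of DEGs with >= 1 promoter SNP, one decimal."""
        return _pct1(self.n_deg_with_promoter_snp, self.n_deg)

    @property
    def pct_indel(self) -> float:
        return _pct1(self.n_deg_with_promoter_indel, self.n_deg)


def intersect_promoter_variants(
    degs: Iterable[ExpressionRecord],
    promoters: Iterable[PromoterInterval],
    variants: Iterable[Variant],
) -> PromoterHitSummary:
    """Count DEGs with at least one promoter SNP and/or promoter InDel.

    A DEG counts once per variant class no matter how many variants hit;
    DEGs absent from the annotation are excluded with a warning and
    reported in n_missing_annotation.
    """
    prom_by_gene = {p.gene_id: p for p in promoters}
    deg_genes = [r.gene_id for r in degs if r.deg_status in ("up", "down")]

    snp_pos: dict[str, list[int]] = {}
    indel_pos: dict[str, list[int]] = {}
    for v in variants:
        (snp_pos if v.is_snp else indel_pos).setdefault(v.chrom, []).append(v.start0)
    for d in (snp_pos, indel_pos):
        for poss in d.values():
            poss.sort()

    snp_hits, indel_hits = [], []
    missing = 0
    for gid in deg_genes:
        p = prom_by_gene.get(gid)
        if p is None:
            logger.warning("DEG %s has no promoter in the annotation; excluded", gid)
            missing += 1
            continue
        for poss, hits in ((snp_pos, snp_hits), (indel_pos, indel_hits)):
            arr = poss.get(p.chrom, [])
            if bisect_right(arr, p.end - 1) - bisect_left(arr, p.start) > 0:
                hits.append(gid)
    n_deg = len(deg_genes) - missing
    return PromoterHitSummary(
        n_deg=n_deg,
        n_deg_with_promoter_snp=len(snp_hits),
        n_deg_with_promoter_indel=len(indel_hits),
        snp_hit_genes=snp_hits,
        indel_hit_genes=indel_hits,
        n_missing_annotation=missing,
    )
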
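"""Region and coding-consequence classification of variants.

Each SNP is assigned exactly one region (intergenic / CDS / UTR5 / UTR3 /
intron) against a representative transcript per gene (the longest CDS),
and CDS SNPs get a codon-level consequence by translating the reference
and mutated codons with the standard genetic code, strand-aware and
across exon junctions.  Effect precedence for CDS SNPs:

    start_loss > stop_loss > stop_gain > nonsynonymous > synonymous

(a stop-to-stop change counts as synonymous).  CDS InDels are frameshift
when the length change is not a multiple of 3, else inframe_indel.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio.Seq import Seq

from .models import (
    GeneModel,
    GenomeSequence,
    ModelError,
    Transcript,
    Variant,
    VariantEffect,
    revcomp,
)

logger = logging.getLogger("polmutscan")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


class GeneIndex:
    """Position -> gene lookup with cached spliced-CDS frames."""

    def __init__(self, genes: Iterable[GeneModel], genome: GenomeSequence):
        self.genome = genome
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.gene_id))
            self._starts[chrom] = [g.start for g in gs]
            self._max_len[chrom] = max((g.end - g.start for g in gs), default=0)
        self._frames: dict[str, "_CdsFrame"] = {}

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        gs = self._by_chrom.get(chrom, [])
        if not gs:
            return []
        starts = self._starts[chrom]
        i = bisect_right(starts, pos)
        lo = pos - self._max_len[chrom]
        out = []
        j = i - 1
        while j >= 0 and starts[j] > lo:
            g = gs[j]
            if g.start <= pos < g.end:
                out.append(g)
            j -= 1
        out.reverse()
        return out

    def frame(self, gene: GeneModel) -> Optional["_CdsFrame"]:
        if gene.gene_id not in self._frames:
            t = gene.longest_cds_transcript()
            self._frames[gene.gene_id] = (
                _CdsFrame(gene, t, self.genome) if t is not None else None
            )
        return self._frames[gene.gene_id]


@dataclass
class _CdsFrame:
    """Spliced CDS of one transcript in translation orientation."""

    gene: GeneModel
    transcript: Transcript
    genome: GenomeSequence
    cds_seq: str = field(init=False)
    _cumlen: list[int] = field(init=False)

    def __post_init__(self):
        seq = self.genome.seq(self.gene.chrom)
        parts = [seq[s:e] for s, e in self.transcript.cds]
        plus = "".join(parts)
        self.cds_seq = plus if self.gene.strand == "+" else revcomp(plus)
        self._cumlen = []
        total = 0
        for s, e in self.transcript.cds:
            self._cumlen.append(total)
            total += e - s

    def cds_index(self, pos: int) -> Optional[int]:
        """Translation-frame index of a genomic position, None if not in CDS."""
        for (s, e), cum in zip(self.transcript.cds, self._cumlen):
            if s <= pos < e:
                plus_idx = cum + (pos - s)
                if self.gene.strand == "+":
                    return plus_idx
                return len(self.cds_seq) - 1 - plus_idx
        return None

    def genomic_pos(self, idx: int) -> int:
        """Inverse of cds_index: genomic position of a translation-frame index."""
        plus_idx = idx if self.gene.strand == "+" else len(self.cds_seq) - 1 - idx
        for (s, e), cum in zip(self.transcript.cds, self._cumlen):
            if cum <= plus_idx < cum + (e - s):
                return s + (plus_idx - cum)
        raise IndexError(idx)


def _region_for(transcript: Transcript, pos: int) -> str:
    for s, e in transcript.cds:
        if s <= pos < e:
            return "CDS"
    for s, e in transcript.utr5:
        if s <= pos < e:
            return "UTR5"
    for s, e in transcript.utr3:
        if s <= pos < e:
            return "UTR3"
    return "intron"


def classify_variant(
    variant: Variant, index: GeneIndex, genome: GenomeSequence
) -> VariantEffect:
    pos = variant.start0
    genes = index.genes_at(variant.chrom, pos)
    if not genes:
        return VariantEffect(variant=variant, region="intergenic")
    # With overlapping genes, prefer one where the position is coding.
    chosen, region = None, None
    for g in genes:
        fr = index.frame(g)
        t = fr.transcript if fr else g.longest_transcript()
        if t is None:
            continue
        r = _region_for(t, pos)
        if chosen is None or (r == "CDS" and region != "CDS"):
            chosen, region = g, r
    if chosen is None:
        return VariantEffect(variant=variant, region="intergenic")

    if region != "CDS":
        return VariantEffect(
            variant=variant, region=region, coding_effect="NA", gene_id=chosen.gene_id
        )

    if variant.is_indel:
        delta = len(variant.alt) - len(variant.ref)
        effect = "frameshift" if delta % 3 != 0 else "inframe_indel"
        return VariantEffect(
            variant=variant, region="CDS", coding_effect=effect, gene_id=chosen.gene_id
        )

    fr = index.frame(chosen)
    idx = fr.cds_index(pos)
    if idx is None:  # CDS by annotation but not in the representative frame
        logger.warning(
            "variant %s:%d inside gene %s but outside the representative "
            "transcript frame; classified intron",
            variant.chrom,
            variant.pos,
            chosen.gene_id,
        )
        return VariantEffect(
            variant=variant, region="intron", gene_id=chosen.gene_id
        )

    strand = chosen.strand
    alt_t = variant.alt if strand == "+" else _COMP[variant.alt]
    ref_t = variant.ref if strand == "+" else _COMP[variant.ref]
    if fr.cds_seq[idx] != ref_t:
        raise ModelError(
            f"{variant.chrom}:{variant.pos}: REF {variant.ref!r} inconsistent "
            f"with CDS of {chosen.gene_id}"
        )

    codon_i, within = divmod(idx, 3)
    codon_start = codon_i * 3
    ref_codon = fr.cds_seq[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        logger.warning(
            "variant %s:%d falls in a partial trailing codon of incomplete "
            "transcript %s; classified nonsynonymous",
            variant.chrom,
            variant.pos,
            fr.transcript.transcript_id,
        )
        return VariantEffect(
            variant=variant,
            region="CDS",
            coding_effect="nonsynonymous",
            gene_id=chosen.gene_id,
        )
    alt_codon = ref_codon[:within] + alt_t + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)

    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        effect = "start_loss"
    elif ref_aa == "*" and alt_aa != "*":
        effect = "stop_loss"
    elif ref_aa != "*" and alt_aa == "*":
        effect = "stop_gain"
    elif ref_aa != alt_aa:
        effect = "nonsynonymous"
    else:
        effect = "synonymous"

    return VariantEffect(
        variant=variant,
        region="CDS",
        coding_effect=effect,
        gene_id=chosen.gene_id,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{ref_aa}{codon_i + 1}{alt_aa}",
    )


def classify_variants(
    variants: Iterable[Variant],
    genes: Iterable[GeneModel],
    genome: GenomeSequence,
) -> list[VariantEffect]:
    index = GeneIndex(genes, genome)
    return [classify_variant(v, index, genome) for v in variants]


def _pct(num: int, den: int, decimals: int = 0) -> float:
    """Percentage with deterministic half-up rounding."""
    if den == 0:
        return 0.0
    x = 100.0 * num / den
    scale = 10 ** decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass
class EffectSummary:
    """Genome-wide and per-chromosome tallies of SNP effect classes.

    Region percentages are printed to the nearest integer, matching the
    precision the analysis reports them at.
    """

    n_total: int
    n_cds: int
    n_utr: int
    n_intron: int
    n_intergenic: int
    n_synonymous: int = 0
    n_nonsynonymous: int = 0
    n_stop_gain: int = 0
    n_start_loss: int = 0
    n_stop_loss: int = 0
    per_chrom: Optional[pd.DataFrame] = None

    @property
    def n_genic(self) -> int:
        return self.n_cds + self.n_utr + self.n_intron

    @property
    def pct_genic(self) -> float:
        return _pct(self.n_genic, self.n_total)

    @property
    def pct_intergenic(self) -> float:
        return _pct(self.n_intergenic, self.n_total)

    @property
    def pct_cds_of_genic(self) -> float:
        return _pct(self.n_cds, self.n_genic)

    @property
    def pct_utr_of_genic(self) -> float:
        return _pct(self.n_utr, self.n_genic)

    @property
    def pct_intron_of_genic(self) -> float:
        return _pct(self.n_intron, self.n_genic)

    @property
    def n_cds_classified(self) -> int:
        return (
            self.n_synonymous
            + self.n_nonsynonymous
            + self.n_stop_gain
            + self.n_start_loss
            + self.n_stop_loss
        )

    @property
    def pct_synonymous_of_cds(self) -> float:
        return _pct(self.n_synonymous, self.n_cds_classified)

    @property
    def pct_nonsynonymous_of_cds(self) -> float:
        return _pct(self.n_nonsynonymous, self.n_cds_classified)

    @property
    def n_large_effect(self) -> int:
        return self.n_stop_gain + self.n_start_loss + self.n_stop_loss

    @classmethod
    def from_counts(
        cls, total: int, cds: int, utr: int, intron: int
    ) -> "EffectSummary":
        """Build a summary directly from printed region counts."""
        genic = cds + utr + intron
        return cls(
            n_total=total,
            n_cds=cds,
            n_utr=utr,
            n_intron=intron,
            n_intergenic=total - genic,
        )


_EFFECT_COLS = ("synonymous", "nonsynonymous", "stop_gain", "start_loss", "stop_loss")


def summarize_effects(
    effects: Iterable[VariantEffect], genome: GenomeSequence
) -> EffectSummary:
    """Tally SNP effects per chromosome and genome-wide.

    Only SNP effects enter the region partition (the published taxonomy is
    SNP-based); per-chromosome rows also carry per-Mb frequencies of
    synonymous / nonsynonymous / large-effect SNPs.
    """
    rows: dict[str, dict[str, int]] = {
        c: {k: 0 for k in ("CDS", "UTR5", "UTR3", "intron", "intergenic", *_EFFECT_COLS)}
        for c in genome.chrom_names
    }
    for e in effects:
        if not e.variant.is_snp:
            continue
        d = rows.setdefault(
            e.variant.chrom,
            {k: 0 for k in ("CDS", "UTR5", "UTR3", "intron", "intergenic", *_EFFECT_COLS)},
        )
        d[e.region] += 1
        if e.coding_effect in _EFFECT_COLS:
            d[e.coding_effect] += 1

    per_chrom = pd.DataFrame.from_dict(rows, orient="index").rename_axis("chrom")
    for col in ("synonymous", "nonsynonymous"):
        per_chrom[f"{col}_per_mb"] = [
            rows[c][col] / genome.length(c) * 1e6 for c in per_chrom.index
        ]
    per_chrom["large_effect_per_mb"] = [
        (rows[c]["stop_gain"] + rows[c]["start_loss"] + rows[c]["stop_loss"])
        / genome.length(c)
        * 1e6
        for c in per_chrom.index
    ]

    tot = per_chrom[list(per_chrom.columns)].sum()
    return EffectSummary(
        n_total=int(
            tot["CDS"] + tot["UTR5"] + tot["UTR3"] + tot["intron"] + tot["intergenic"]
        ),
        n_cds=int(tot["CDS"]),
        n_utr=int(tot["UTR5"] + tot["UTR3"]),
        n_intron=int(tot["intron"]),
        n_intergenic=int(tot["intergenic"]),
        n_synonymous=int(tot["synonymous"]),
        n_nonsynonymous=int(tot["nonsynonymous"]),
        n_stop_gain=int(tot["stop_gain"]),
        n_start_loss=int(tot["start_loss"]),
        n_stop_loss=int(tot["stop_loss"]),
        per_chrom=per_chrom.reset_index(),
    )


def genes_with_min_nonsyn(
    effects: Iterable[VariantEffect], min_count: int = 2
) -> int:
    """Number of distinct genes carrying at least `min_count` nonsynonymous SNPs."""
    if min_count < 1:
        raise ModelError("min_count must be >= 1")
    tally: dict[str, int] = {}
    for e in effects:
        if e.coding_effect == "nonsynonymous" and e.gene_id:
            tally[e.gene_id] = tally.get(e.gene_id, 0) + 1
    return sum(1 for n in tally.values() if n >= min_count)
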
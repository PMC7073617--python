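"""Domain types shared across the pipeline.

Coordinate convention: every interval held in these types is 0-based
half-open ``[start, end)``.  1-based conventions (VCF ``POS``, GFF3
``start``/``end``) are converted at the I/O boundary and nowhere else.
The single exception is :attr:`Variant.pos`, which deliberately keeps the
1-based VCF position because variants are quoted back to users in VCF
terms; the 0-based accessors :attr:`Variant.start0`/:attr:`Variant.end0`
are what internal code uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

Interval = tuple[int, int]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ModelError(ValueError):
    """Structurally invalid gene model, variant or parameter."""


COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class GenomeSequence:
    """An ordered collection of named chromosome sequences.

    Sequences are plain uppercase strings over {A, C, G, T, N}; this is
    the coordinate frame for every downstream interval.
    """

    def __init__(self, seqs: dict[str, str]):
        if not seqs:
            raise FormatError("no records")
        for name, s in seqs.items():
            if not s:
                raise FormatError(f"empty sequence for chromosome {name!r}")
        self._seqs = dict(seqs)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def seq(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self._seqs == other._seqs

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())


@dataclass
class Transcript:
    """One mRNA: exon structure plus the coding and untranslated segments.

    All segment lists are sorted by genomic start and pairwise disjoint,
    regardless of strand.  ``complete`` is False when the summed CDS
    length is not divisible by 3 (truncated or mis-annotated model).
    """

    transcript_id: str
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    complete: bool = True

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int   # 0-based
    end: int     # half-open
    transcripts: list[Transcript] = field(default_factory=list)

    def longest_cds_transcript(self) -> Optional[Transcript]:
        """Representative transcript: the one with the longest total CDS.

        Complete transcripts win over incomplete ones of any length; ties
        break on transcript_id for determinism.
        """
        coding = [t for t in self.transcripts if t.cds]
        if not coding:
            return None
        return max(coding, key=lambda t: (t.complete, t.cds_length(), t.transcript_id))

    def longest_transcript(self) -> Optional[Transcript]:
        if not self.transcripts:
            return None
        return max(self.transcripts, key=lambda t: (t.exon_length(), t.transcript_id))


@dataclass(frozen=True)
class Variant:
    """One called variant in VCF terms (pos is 1-based, alleles literal)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    depth: Optional[int] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ModelError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ModelError("empty allele")
        if self.qual < 0:
            raise ModelError("negative QUAL")
        if self.depth is not None and self.depth < 0:
            raise ModelError("negative depth")

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        if len(self.alt) > len(self.ref):
            return "INS"
        return "DEL"

    @property
    def is_snp(self) -> bool:
        return self.vtype == "SNP"

    @property
    def is_indel(self) -> bool:
        return self.vtype != "SNP"

    @property
    def start0(self) -> int:
        return self.pos - 1

    @property
    def end0(self) -> int:
        """End of the reference footprint, 0-based half-open."""
        return self.pos - 1 + len(self.ref)


REGIONS = ("intergenic", "CDS", "UTR5", "UTR3", "intron")
CODING_EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "stop_gain",
    "start_loss",
    "stop_loss",
    "frameshift",
    "inframe_indel",
    "NA",
)
LARGE_EFFECTS = frozenset({"stop_gain", "start_loss", "stop_loss"})


@dataclass
class VariantEffect:
    variant: Variant
    region: str
    coding_effect: str = "NA"
    gene_id: Optional[str] = None
    codon_change: Optional[str] = None  # e.g. "GCT>GCC"
    aa_change: Optional[str] = None     # e.g. "A2A"

    @property
    def large_effect(self) -> bool:
        return self.coding_effect in LARGE_EFFECTS


@dataclass
class ExpressionRecord:
    gene_id: str
    log2fc: float
    pvalue: Optional[float] = None
    padj: Optional[float] = None
    deg_status: str = "not_deg"  # up / down / not_deg

    def __post_init__(self):
        for name, p in (("pvalue", self.pvalue), ("padj", self.padj)):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ModelError(f"{name} outside [0,1] for {self.gene_id}: {p}")


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    snp_count: int
    indel_count: int

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def snp_density(self) -> float:
        """SNPs per 100 kb, normalised by actual window width."""
        return self.snp_count / self.width * 1e5

    @property
    def indel_density(self) -> float:
        return self.indel_count / self.width * 1e5


@dataclass
class HMRegion:
    """A hypermutation region: merged run of outlier-density windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_density: float
    zscore: float


@dataclass
class PromoterInterval:
    """Strand-aware putative promoter: <= `length` bp upstream of the TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    clipped: bool = False


@dataclass
class EnrichmentResult:
    term_id: str
    k: int   # study genes carrying the term
    n: int   # study-set size
    K: int   # universe genes carrying the term
    N: int   # universe size
    p: float
    fdr: float = float("nan")
    direction: str = ""
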
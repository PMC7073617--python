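"""Readers and writers for the standard formats the pipeline touches.

This is the only module that converts coordinates: GFF3 and VCF are
1-based inclusive on disk, everything in memory is 0-based half-open,
BED is 0-based half-open on disk already.  Readers validate against the
genome where one is supplied; writers round-trip with the readers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import cyvcf2
import gffutils
import pandas as pd
from Bio import SeqIO

from .models import (
    ExpressionRecord,
    FormatError,
    GeneModel,
    GenomeSequence,
    ModelError,
    Transcript,
    Variant,
)

logger = logging.getLogger("polmutscan")

_VALID_BASES = frozenset("ACGTN")


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> GenomeSequence:
    """Load a FASTA file, uppercasing sequences and rejecting duplicates."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate chromosome {rec.id!r}")
        s = str(rec.seq).upper()
        bad = set(s) - _VALID_BASES
        if bad:
            raise FormatError(
                f"non-IUPAC character(s) {sorted(bad)} in record {rec.id!r}"
            )
        seqs[rec.id] = s
    if not seqs:
        raise FormatError(f"no records in {path}")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            s = genome.seq(chrom)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------- GFF3

def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(cover: list[tuple[int, int]], holes: list[tuple[int, int]]):
    """Set difference of sorted disjoint interval lists (exon minus CDS)."""
    out = []
    for s, e in cover:
        cur = s
        for hs, he in holes:
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
        if cur < e:
            out.append((cur, e))
    return out


def read_gff3(path, genome: GenomeSequence) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS(/UTR) features into validated GeneModels.

    UTRs are derived as exon-minus-CDS when not annotated, assigned to
    the 5' or 3' side of the CDS span by strand.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.seqid not in genome:
            raise ModelError(f"gene {g.id} on unknown chromosome {g.seqid!r}")
        if g.strand not in ("+", "-"):
            raise ModelError(f"gene {g.id} has unknown strand {g.strand!r}")
        gm = GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand, start=g.start - 1, end=g.end
        )
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            exons = _merge_intervals(
                [(f.start - 1, f.end) for f in db.children(t, featuretype="exon")]
            )
            cds = _merge_intervals(
                [(f.start - 1, f.end) for f in db.children(t, featuretype="CDS")]
            )
            utr5 = _merge_intervals(
                [
                    (f.start - 1, f.end)
                    for f in db.children(
                        t, featuretype=("five_prime_UTR", "five_prime_utr")
                    )
                ]
            )
            utr3 = _merge_intervals(
                [
                    (f.start - 1, f.end)
                    for f in db.children(
                        t, featuretype=("three_prime_UTR", "three_prime_utr")
                    )
                ]
            )
            if not exons:
                exons = _merge_intervals(cds + utr5 + utr3)
            # CDS must fall inside the exon set
            uncovered = _subtract(cds, exons)
            if uncovered:
                raise ModelError(
                    f"transcript {t.id}: CDS segment(s) {uncovered} outside exons"
                )
            if cds and not utr5 and not utr3:
                non_cds = _subtract(exons, cds)
                cds_lo, cds_hi = cds[0][0], cds[-1][1]
                left = [iv for iv in non_cds if iv[1] <= cds_lo]
                right = [iv for iv in non_cds if iv[0] >= cds_hi]
                utr5, utr3 = (left, right) if g.strand == "+" else (right, left)
            complete = True
            clen = sum(e - s for s, e in cds)
            if cds and clen % 3 != 0:
                logger.warning(
                    "transcript %s: CDS length %d not divisible by 3; "
                    "flagged incomplete",
                    t.id,
                    clen,
                )
                complete = False
            gm.transcripts.append(
                Transcript(
                    transcript_id=t.id,
                    exons=exons,
                    cds=cds,
                    utr5=utr5,
                    utr3=utr3,
                    complete=complete,
                )
            )
        for tr in gm.transcripts:
            for s, e in tr.exons:
                if s < gm.start or e > gm.end:
                    raise ModelError(
                        f"transcript {tr.transcript_id} exon ({s},{e}) outside "
                        f"gene span of {gm.gene_id}"
                    )
        genes.append(gm)
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Emit gene/mRNA/exon/CDS/UTR features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpolmutscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tpolmutscan\tmRNA\t{t.span[0] + 1}\t{t.span[1]}\t.\t"
                    f"{g.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for kind, segs in (
                    ("exon", t.exons),
                    ("five_prime_UTR", t.utr5),
                    ("CDS", t.cds),
                    ("three_prime_UTR", t.utr3),
                ):
                    # CDS phase: bases to skip to reach the next codon start
                    phases = _cds_phases(t, g.strand) if kind == "CDS" else {}
                    for s, e in segs:
                        phase = str(phases.get((s, e), ".")) if kind == "CDS" else "."
                        fh.write(
                            f"{g.chrom}\tpolmutscan\t{kind}\t{s + 1}\t{e}\t.\t"
                            f"{g.strand}\t{phase}\t"
                            f"ID={t.transcript_id}.{kind}.{s};Parent={t.transcript_id}\n"
                        )


def _cds_phases(t: Transcript, strand: str) -> dict[tuple[int, int], int]:
    segs = t.cds if strand == "+" else list(reversed(t.cds))
    phases, consumed = {}, 0
    for s, e in segs:
        phases[(s, e)] = (3 - consumed % 3) % 3
        consumed += e - s
    return phases


# ---------------------------------------------------------------- VCF

def read_vcf(path, genome: Optional[GenomeSequence] = None) -> list[Variant]:
    """Read VCF 4.x; multi-allelic records are split one Variant per ALT.

    DP is taken from INFO, falling back to the first sample's FORMAT
    field; a missing DP leaves depth=None (which the coverage filter
    treats as failing).  REF alleles are cross-checked against `genome`
    when given.
    """
    variants: list[Variant] = []
    vcf = cyvcf2.VCF(str(path))
    for rec in vcf:
        dp = rec.INFO.get("DP")
        if dp is None and rec.num_called > 0:
            try:
                fmt = rec.format("DP")
                if fmt is not None:
                    dp = int(fmt[0][0])
            except KeyError:
                dp = None
        # cyvcf2 surfaces QUAL as float32; quantize to 4 decimals so that
        # write_vcf -> read_vcf round-trips exactly at VCF-typical precision
        qual = round(float(rec.QUAL), 4) if rec.QUAL is not None else 0.0
        if genome is not None:
            if rec.CHROM not in genome:
                raise FormatError(
                    f"{rec.CHROM}:{rec.POS}: chromosome not in reference"
                )
            expected = genome.seq(rec.CHROM)[rec.POS - 1 : rec.POS - 1 + len(rec.REF)]
            if expected != rec.REF:
                raise FormatError(
                    f"{rec.CHROM}:{rec.POS}: REF {rec.REF!r} does not match "
                    f"reference {expected!r}"
                )
        for alt in rec.ALT:
            variants.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    qual=qual,
                    depth=int(dp) if dp is not None else None,
                )
            )
    return variants


def write_vcf(variants: Iterable[Variant], path, genome: Optional[GenomeSequence] = None) -> None:
    """Write a sites-only VCF 4.2 with DP in INFO (round-trips with read_vcf)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if genome is not None:
            for chrom in genome.chrom_names:
                fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        else:
            for chrom in sorted({v.chrom for v in variants}):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            info = f"DP={v.depth}" if v.depth is not None else "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:g}\t.\t{info}\n"
            )


# ---------------------------------------------------------------- tables

def read_expression_table(path) -> list[ExpressionRecord]:
    """TSV with header: gene_id, log2fc, then pvalue and/or padj columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "log2fc"}
    if not required <= set(df.columns):
        raise FormatError(
            f"expression table must contain columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    if "pvalue" not in df.columns and "padj" not in df.columns:
        raise FormatError("expression table needs a 'pvalue' or 'padj' column")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        d = row._asdict()
        try:
            rec = ExpressionRecord(
                gene_id=d["gene_id"],
                log2fc=float(d["log2fc"]),
                pvalue=_opt_float(d.get("pvalue")),
                padj=_opt_float(d.get("padj")),
            )
        except (TypeError, ValueError, ModelError) as exc:
            raise FormatError(f"{path} line {i}: {exc}") from exc
        records.append(rec)
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "log2fc": r.log2fc,
            "pvalue": "" if r.pvalue is None else r.pvalue,
            "padj": "" if r.padj is None else r.padj,
            "deg_status": r.deg_status,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and pd.isna(x)) or x == "":
        return None
    if isinstance(x, str) and x.strip().lower() in ("", "na", "nan", "."):
        return None
    return float(x)


def read_term_map(path) -> dict[str, set[str]]:
    """Long-format TSV (term_id, gene_id) -> {term: {genes}}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term_id", "gene_id"} <= set(df.columns):
        raise FormatError("term map needs columns term_id, gene_id")
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term_id"], df["gene_id"]):
        out.setdefault(term, set()).add(gene)
    return out


def read_bed(path) -> list[tuple[str, int, int]]:
    """BED3 intervals, 0-based half-open as on disk."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            if end <= start:
                raise FormatError(f"{path} line {lineno}: end <= start")
            out.append((parts[0], start, end))
    return out


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write BED; extra tuple elements beyond (chrom, start, end) become columns."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_tsv_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
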
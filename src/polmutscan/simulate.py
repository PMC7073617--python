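"""Synthetic genomes, gene models, variants and expression tables with
planted, machine-readable truth.

The generator emulates the study conditions of a resequenced mutagenized
line against its parent: uniform random chromosomes carrying strand-mixed
intron-containing gene models, SNPs at a configurable per-bp density with
a transition-weighted substitution model, 1-10 bp InDels, optional
high-density ("hypermutation") windows, constructively planted codon-level
effect classes, and an expression table with planted DEGs.  Default rates
follow the profile of the analysed rice line: 30.3 SNPs and 10.8 InDels
per 100 kb and an expected Ts/Tv of 2.38 (transition weight 4.76 against
two transversions of weight 1 each).

Every operation is deterministic under a fixed seed; each generator stage
draws from its own stream derived from (seed, stage index), so stages are
reproducible whether run standalone or through the combined `simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .effects import _CdsFrame, translate_codon
from .models import (
    ExpressionRecord,
    GeneModel,
    GenomeSequence,
    ModelError,
    Transcript,
    Variant,
    revcomp,
)

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "C": ("A", "G"),
    "G": ("C", "T"),
    "T": ("A", "G"),
}
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

EFFECT_CLASSES = ("synonymous", "nonsynonymous", "stop_gain", "start_loss", "stop_loss")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study profile."""

    seed: int = 0
    n_chrom: int = 3
    chrom_length: int = 1_000_000
    n_genes: int = 120
    cds_codons: tuple[int, int] = (60, 300)     # incl. start and stop codons
    intron_length: tuple[int, int] = (50, 500)
    utr5_length: tuple[int, int] = (100, 300)
    utr3_length: tuple[int, int] = (100, 300)
    min_gene_gap: int = 3000                     # leaves promoter room
    snp_rate: float = 3.03e-4                    # SNPs per bp (30.3 / 100 kb)
    indel_rate: float = 1.08e-4                  # InDels per bp (10.8 / 100 kb)
    transition_weight: float = 4.76              # expected Ts/Tv = w / 2
    indel_len: tuple[int, int] = (1, 10)
    window_size: int = 100_000
    planted_hmr: list[tuple[str, int, float]] = field(default_factory=list)
    n_effect_plants: int = 0
    effect_mix: dict[str, float] = field(default_factory=dict)
    fail_filter_fraction: float = 0.1
    n_deg_up: int = 10
    n_deg_down: int = 12
    deg_log2fc: tuple[float, float] = (1.2, 4.0)
    null_log2fc_sd: float = 0.3
    strict_null: bool = True
    promoter_variant_fraction: float = 0.2
    promoter_length: int = 2000

    def validate(self) -> None:
        if self.seed < 0:
            raise ModelError("seed must be >= 0")
        for name in ("snp_rate", "indel_rate", "fail_filter_fraction"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")
        if self.transition_weight < 0:
            raise ModelError("transition_weight must be >= 0")
        if self.effect_mix:
            unknown = set(self.effect_mix) - set(EFFECT_CLASSES)
            if unknown:
                raise ModelError(f"unknown effect classes {sorted(unknown)}")
            if sum(self.effect_mix.values()) > 1 + 1e-9:
                raise ModelError("effect_mix proportions must sum to <= 1")
        if self.n_deg_up + self.n_deg_down > self.n_genes:
            raise ModelError("more planted DEGs than genes")
        if self.cds_codons[0] < 4:
            raise ModelError("need at least 4 codons per CDS")

    def plant_counts(self) -> dict[str, int]:
        return {
            cls: int(round(self.n_effect_plants * frac))
            for cls, frac in self.effect_mix.items()
        }

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class TruthSet:
    """Planted ground truth, keyed the same way pipeline outputs are."""

    variant_effects: dict[tuple[str, int, str, str], str] = field(default_factory=dict)
    passes_filter: dict[tuple[str, int, str, str], bool] = field(default_factory=dict)
    hmr_windows: list[tuple[str, int, int]] = field(default_factory=list)
    deg_status: dict[str, str] = field(default_factory=dict)
    promoter_snp_genes: set[str] = field(default_factory=set)
    promoter_indel_genes: set[str] = field(default_factory=set)

    def merge(self, other: "TruthSet") -> "TruthSet":
        return TruthSet(
            variant_effects={**self.variant_effects, **other.variant_effects},
            passes_filter={**self.passes_filter, **other.passes_filter},
            hmr_windows=self.hmr_windows + other.hmr_windows,
            deg_status={**self.deg_status, **other.deg_status},
            promoter_snp_genes=self.promoter_snp_genes | other.promoter_snp_genes,
            promoter_indel_genes=self.promoter_indel_genes | other.promoter_indel_genes,
        )


# ------------------------------------------------------------- genome

def _random_seq(rng: np.random.Generator, n: int) -> str:
    codes = rng.integers(0, 4, size=n)
    return np.frombuffer(b"ACGT", dtype="S1")[codes].tobytes().decode()


def _build_gene(
    rng: np.random.Generator, cfg: SimulationConfig, gene_id: str, force_intron: bool
) -> tuple[str, dict]:
    """One gene in transcript orientation: sequence plus segment layout."""
    n_codons = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
    internal = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    cds = "ATG" + "".join(_SENSE_CODONS[i] for i in internal)
    cds += _STOPS[int(rng.integers(0, len(_STOPS)))]
    cds_len = len(cds)

    if force_intron:
        n_introns = int(rng.integers(1, 3))
    else:
        n_introns = int(rng.integers(0, 3))
    # introns interrupt the CDS at arbitrary bases (codons may span junctions)
    breaks = sorted(
        int(b) for b in rng.choice(np.arange(1, cds_len), size=n_introns, replace=False)
    )
    chunks = [cds[s:e] for s, e in zip([0] + breaks, breaks + [cds_len])]
    introns = [
        _random_seq(rng, int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1)))
        for _ in range(n_introns)
    ]
    u5 = _random_seq(rng, int(rng.integers(cfg.utr5_length[0], cfg.utr5_length[1] + 1)))
    u3 = _random_seq(rng, int(rng.integers(cfg.utr3_length[0], cfg.utr3_length[1] + 1)))

    seq_parts, layout, t = [u5], {"utr5": [(0, len(u5))], "cds": [], "intron": []}, len(u5)
    for i, chunk in enumerate(chunks):
        seq_parts.append(chunk)
        layout["cds"].append((t, t + len(chunk)))
        t += len(chunk)
        if i < len(introns):
            seq_parts.append(introns[i])
            layout["intron"].append((t, t + len(introns[i])))
            t += len(introns[i])
    seq_parts.append(u3)
    layout["utr3"] = [(t, t + len(u3))]
    return "".join(seq_parts), layout


def _to_genomic(
    segs: list[tuple[int, int]], gene_start: int, glen: int, strand: str
) -> list[tuple[int, int]]:
    if strand == "+":
        out = [(gene_start + s, gene_start + e) for s, e in segs]
    else:
        out = [(gene_start + glen - e, gene_start + glen - s) for s, e in segs]
    return sorted(out)


def generate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Random genome with non-overlapping, strand-mixed gene models.

    Every CDS starts with ATG, ends with a stop codon and contains no
    internal stop; at least half the genes carry >= 1 intron.
    """
    config.validate()
    rng = config._rng(0)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    seqs = {c: bytearray(_random_seq(rng, config.chrom_length).encode()) for c in chrom_names}

    genes: list[GeneModel] = []
    cursors = {c: config.min_gene_gap for c in chrom_names}
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chrom]
        gene_id = f"gene{gi + 1:04d}"
        # force introns on even-indexed genes so that >= 50% have one
        t_seq, layout = _build_gene(rng, config, gene_id, force_intron=(gi % 2 == 0))
        glen = len(t_seq)
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(config.min_gene_gap, 2 * config.min_gene_gap))
        start = cursors[chrom] + gap
        end = start + glen
        if end > config.chrom_length - config.min_gene_gap:
            raise ModelError(
                f"genes requested exceed placeable capacity on {chrom} "
                f"(gene {gene_id})"
            )
        cursors[chrom] = end
        g_seq = t_seq if strand == "+" else revcomp(t_seq)
        seqs[chrom][start:end] = g_seq.encode()

        cds = _to_genomic(layout["cds"], start, glen, strand)
        utr5 = _to_genomic(layout["utr5"], start, glen, strand)
        utr3 = _to_genomic(layout["utr3"], start, glen, strand)
        # exons = transcribed span minus introns
        introns = _to_genomic(layout["intron"], start, glen, strand)
        exons, cur = [], start
        for s, e in introns:
            exons.append((cur, s))
            cur = e
        exons.append((cur, end))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                transcripts=[
                    Transcript(
                        transcript_id=f"{gene_id}.t1",
                        exons=exons,
                        cds=cds,
                        utr5=utr5,
                        utr3=utr3,
                    )
                ],
            )
        )
    genome = GenomeSequence({c: bytes(seqs[c]).decode() for c in chrom_names})
    return genome, genes


# ------------------------------------------------------------- variants

def _sample_positions(
    rng: np.random.Generator, length: int, n: int, occupied: set[int]
) -> list[int]:
    """~n distinct unoccupied positions, uniform on [0, length)."""
    if n <= 0:
        return []
    pos = np.unique(rng.integers(0, length, size=n))
    # top up the (few) duplicate losses
    for _ in range(4):
        if len(pos) >= n:
            break
        extra = rng.integers(0, length, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    out = [int(p) for p in pos[:n] if int(p) not in occupied]
    return out


def _draw_alt(rng: np.random.Generator, ref: str, w: float) -> str:
    if rng.random() < w / (w + 2.0):
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][int(rng.integers(0, 2))]


def _plant_effect(
    rng: np.random.Generator,
    cls: str,
    frames: list[_CdsFrame],
    occupied: dict[str, set[int]],
) -> Optional[tuple[str, int, str, str]]:
    """Constructively edit one codon so that the SNP has effect `cls`.

    Returns (chrom, pos0, ref, alt) in genome coordinates, or None when no
    CDS position admits the class (caller raises).
    """
    order = rng.permutation(len(frames))
    for fi in order:
        fr = frames[int(fi)]
        L = len(fr.cds_seq)
        n_codons = L // 3
        if cls == "start_loss":
            codon_choices = [0]
        elif cls == "stop_loss":
            codon_choices = [n_codons - 1]
        else:
            codon_choices = list(rng.permutation(np.arange(1, n_codons - 1)))
        for ci in codon_choices:
            ci = int(ci)
            ref_codon = fr.cds_seq[ci * 3 : ci * 3 + 3]
            ref_aa = translate_codon(ref_codon)
            for within in rng.permutation(3):
                within = int(within)
                idx = ci * 3 + within
                pos = fr.genomic_pos(idx)
                if pos in occupied[fr.gene.chrom]:
                    continue
                for alt_t in rng.permutation(list("ACGT")):
                    if alt_t == ref_codon[within]:
                        continue
                    alt_codon = (
                        ref_codon[:within] + alt_t + ref_codon[within + 1 :]
                    )
                    alt_aa = translate_codon(alt_codon)
                    ok = (
                        (cls == "synonymous" and alt_aa == ref_aa and ref_aa != "*")
                        or (
                            cls == "nonsynonymous"
                            and alt_aa != ref_aa
                            and "*" not in (ref_aa, alt_aa)
                        )
                        or (cls == "stop_gain" and ref_aa != "*" and alt_aa == "*")
                        or (cls == "start_loss" and ci == 0)
                        or (cls == "stop_loss" and ref_aa == "*" and alt_aa != "*")
                    )
                    if not ok:
                        continue
                    strand = fr.gene.strand
                    g_ref = fr.cds_seq[idx] if strand == "+" else _comp(fr.cds_seq[idx])
                    g_alt = alt_t if strand == "+" else _comp(alt_t)
                    occupied[fr.gene.chrom].add(pos)
                    return (fr.gene.chrom, pos, g_ref, g_alt)
    return None


def _comp(b: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[b]


def inject_variants(
    genome: GenomeSequence,
    genes: list[GeneModel],
    config: SimulationConfig,
) -> tuple[list[Variant], TruthSet]:
    """Plant effect-class SNPs, promoter variants, background SNPs
    (Poisson per chromosome, hot windows multiplied) and 1-10 bp InDels.

    Planted entities always pass the quality filters; a configurable
    fraction of background variants is given QUAL/DP values that fail
    them.  The alternate allele of every SNP is the transition with
    probability w/(w+2), else one of the two transversions equiprobably.
    """
    config.validate()
    rng = config._rng(1)
    truth = TruthSet()
    w = config.transition_weight
    occupied: dict[str, set[int]] = {c: set() for c in genome.chrom_names}
    planted: list[tuple[str, int, str, str, str]] = []  # +class tag

    # --- constructive effect plants
    counts = config.plant_counts()
    if any(counts.values()):
        frames = []
        for g in genes:
            t = g.longest_cds_transcript()
            if t is not None and t.complete:
                frames.append(_CdsFrame(g, t, genome))
        for cls in EFFECT_CLASSES:
            for _ in range(counts.get(cls, 0)):
                hit = _plant_effect(rng, cls, frames, occupied)
                if hit is None:
                    raise ModelError(
                        f"cannot plant effect class {cls!r}: no CDS space left"
                    )
                chrom, pos, ref, alt = hit
                planted.append((chrom, pos, ref, alt, cls))
                truth.variant_effects[(chrom, pos + 1, ref, alt)] = cls

    # --- promoter plants (fraction of genes, strand-aware upstream window)
    if config.promoter_variant_fraction > 0 and genes:
        from .expression import extract_promoters

        promoters = {
            p.gene_id: p
            for p in extract_promoters(genes, genome, config.promoter_length)
        }
        for g in genes:
            p = promoters[g.gene_id]
            if p.end - p.start < 20:
                continue
            if rng.random() < config.promoter_variant_fraction:
                pos = _free_pos(rng, p.start, p.end, occupied[g.chrom])
                if pos is not None:
                    ref = genome.seq(g.chrom)[pos]
                    alt = _draw_alt(rng, ref, w)
                    planted.append((g.chrom, pos, ref, alt, "promoter_snp"))
                    truth.promoter_snp_genes.add(g.gene_id)
            if rng.random() < config.promoter_variant_fraction:
                # 1-5 bp deletion fully inside the promoter
                dlen = int(rng.integers(1, 6))
                pos = _free_pos(rng, p.start, p.end - dlen - 1, occupied[g.chrom])
                if pos is not None and all(
                    q not in occupied[g.chrom] for q in range(pos, pos + dlen + 1)
                ):
                    occupied[g.chrom].update(range(pos, pos + dlen + 1))
                    ref = genome.seq(g.chrom)[pos : pos + dlen + 1]
                    planted.append((g.chrom, pos, ref, ref[0], "promoter_indel"))
                    truth.promoter_indel_genes.add(g.gene_id)

    # --- background SNPs (uniform; hot windows get multiplied rate)
    hot = {(c, wi): mult for c, wi, mult in config.planted_hmr}
    snps: list[tuple[str, int, str, str]] = []
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        n = int(rng.poisson(config.snp_rate * L))
        positions = _sample_positions(rng, L, n, occupied[chrom])
        for (c, wi), mult in hot.items():
            if c != chrom:
                continue
            ws, we = wi * config.window_size, min((wi + 1) * config.window_size, L)
            truth.hmr_windows.append((chrom, ws, we))
            extra = int(rng.poisson(config.snp_rate * (mult - 1.0) * (we - ws)))
            taken = set(positions) | occupied[chrom]
            added = 0
            while added < extra:
                p = int(rng.integers(ws, we))
                if p not in taken:
                    taken.add(p)
                    positions.append(p)
                    added += 1
        seq = genome.seq(chrom)
        for pos in positions:
            ref = seq[pos]
            if ref == "N":
                continue
            snps.append((chrom, pos, ref, _draw_alt(rng, ref, w)))
            occupied[chrom].add(pos)

    # --- InDels
    indels: list[tuple[str, int, str, str]] = []
    lo, hi = config.indel_len
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        n = int(rng.poisson(config.indel_rate * L))
        seq = genome.seq(chrom)
        made = attempts = 0
        while made < n and attempts < 20 * n + 100:
            attempts += 1
            length = int(rng.integers(lo, hi + 1))
            is_ins = rng.random() < 0.5
            pos = int(rng.integers(0, L - length - 1))
            span = range(pos, pos + 1 + (0 if is_ins else length))
            if any(q in occupied[chrom] for q in span):
                continue
            occupied[chrom].update(span)
            if is_ins:
                ref = seq[pos]
                alt = ref + _random_seq(rng, length)
            else:
                ref = seq[pos : pos + 1 + length]
                alt = ref[0]
            indels.append((chrom, pos, ref, alt))
            made += 1

    # --- QUAL / DP assignment
    variants: list[Variant] = []

    def qual_dp(force_pass: bool) -> tuple[float, Optional[int]]:
        if not force_pass and rng.random() < config.fail_filter_fraction:
            mode = rng.integers(0, 3)
            if mode == 0:
                return round(float(rng.uniform(0, 29.9)), 1), int(rng.integers(10, 101))
            if mode == 1:
                return round(float(rng.uniform(30, 60)), 1), int(rng.integers(0, 10))
            return round(float(rng.uniform(30, 60)), 1), int(rng.integers(101, 400))
        return round(float(rng.uniform(30, 60)), 1), int(rng.integers(10, 101))

    for chrom, pos, ref, alt, _cls in planted:
        q, d = qual_dp(force_pass=True)
        v = Variant(chrom, pos + 1, ref, alt, qual=q, depth=d)
        truth.passes_filter[(chrom, pos + 1, ref, alt)] = True
        variants.append(v)
    for chrom, pos, ref, alt in snps + indels:
        q, d = qual_dp(force_pass=False)
        v = Variant(chrom, pos + 1, ref, alt, qual=q, depth=d)
        truth.passes_filter[(chrom, pos + 1, ref, alt)] = (
            q >= 30 and d is not None and 10 <= d <= 100
        )
        variants.append(v)

    order = {c: i for i, c in enumerate(genome.chrom_names)}
    variants.sort(key=lambda v: (order[v.chrom], v.pos))
    return variants, truth


def _free_pos(
    rng: np.random.Generator, start: int, end: int, occupied: set[int]
) -> Optional[int]:
    if end <= start:
        return None
    for _ in range(50):
        p = int(rng.integers(start, end))
        if p not in occupied:
            occupied.add(p)
            return p
    return None


# ------------------------------------------------------------- expression

def generate_expression(
    genes: list[GeneModel], config: SimulationConfig
) -> tuple[list[ExpressionRecord], TruthSet]:
    """Per-gene log2FC and raw p with planted up-/down-regulated DEGs.

    Planted DEGs draw |log2FC| from the configured band (> 1) and raw p
    small enough that BH adjustment keeps them under 0.05 at any table
    size; nulls draw log2FC ~ Normal(0, sd) and, in strict-null mode,
    p ~ Uniform(0.5, 1) so no null can ever be called (BH-adjusted p is
    never below the raw p).
    """
    config.validate()
    rng = config._rng(2)
    gene_ids = [g.gene_id for g in genes]
    if config.n_deg_up + config.n_deg_down > len(gene_ids):
        raise ModelError("more planted DEGs than genes")
    perm = rng.permutation(len(gene_ids))
    up_ids = {gene_ids[int(i)] for i in perm[: config.n_deg_up]}
    down_ids = {
        gene_ids[int(i)]
        for i in perm[config.n_deg_up : config.n_deg_up + config.n_deg_down]
    }
    truth = TruthSet()
    records = []
    lo, hi = config.deg_log2fc
    for gid in gene_ids:
        if gid in up_ids or gid in down_ids:
            mag = float(rng.uniform(lo, hi))
            lfc = mag if gid in up_ids else -mag
            p = float(10 ** (-rng.uniform(6, 12)))
            truth.deg_status[gid] = "up" if gid in up_ids else "down"
        else:
            lfc = float(rng.normal(0.0, config.null_log2fc_sd))
            if config.strict_null:
                p = float(rng.uniform(0.5, 1.0))
            else:
                p = float(rng.uniform(0.0, 1.0))
            truth.deg_status[gid] = "not_deg"
        records.append(ExpressionRecord(gene_id=gid, log2fc=lfc, pvalue=p))
    return records, truth


# ------------------------------------------------------------- combined

def simulate(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], list[Variant], list[ExpressionRecord], TruthSet]:
    """Run all three generators under one seed and merge their truth."""
    genome, genes = generate_genome(config)
    variants, truth_v = inject_variants(genome, genes, config)
    expression, truth_e = generate_expression(genes, config)
    return genome, genes, variants, expression, truth_v.merge(truth_e)
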
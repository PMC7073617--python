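"""Variant filtering, substitution spectrum and pseudo-reference construction.

The pseudo-reference ("theoretical reference genome") is the parent
sequence with every accepted variant applied; a CoordinateMap records how
original coordinates lift onto the edited sequence so downstream
intervals stay comparable.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .models import GenomeSequence, ModelError, Variant

# The six unordered substitution classes; A<->G and C<->T are transitions.
SPECTRUM_CLASSES = ("A<->G", "C<->T", "A<->C", "A<->T", "C<->G", "G<->T")
_TS = frozenset({"A<->G", "C<->T"})


def _sub_class(ref: str, alt: str) -> str:
    a, b = sorted((ref, alt))
    return f"{a}<->{b}"


@dataclass
class SubstitutionSpectrum:
    """Counts of the 6 unordered SNP classes and the derived Ts/Tv ratio."""

    counts: dict[str, int]
    scope: str = "genome"

    @property
    def ts_count(self) -> int:
        return sum(self.counts[c] for c in SPECTRUM_CLASSES if c in _TS)

    @property
    def tv_count(self) -> int:
        return sum(self.counts[c] for c in SPECTRUM_CLASSES if c not in _TS)

    @property
    def n_snp(self) -> int:
        return self.ts_count + self.tv_count

    @property
    def ts_tv_ratio(self) -> float:
        """Ts/Tv; NaN when there are no transversions (undefined)."""
        if self.tv_count == 0:
            return math.nan
        return self.ts_count / self.tv_count


def filter_variants(
    variants: Iterable[Variant],
    min_qual: float = 30.0,
    min_dp: int = 10,
    max_dp: int = 100,
) -> list[Variant]:
    """Keep variants with qual >= min_qual and min_dp <= depth <= max_dp.

    Boundaries are inclusive; a variant with unknown depth fails the
    coverage requirement.  Order is preserved and the input not mutated.
    """
    if min_qual < 0 or min_dp < 0 or max_dp < 0:
        raise ModelError("filter thresholds must be >= 0")
    return [
        v
        for v in variants
        if v.qual >= min_qual
        and v.depth is not None
        and min_dp <= v.depth <= max_dp
    ]


def substitution_spectrum(
    variants: Iterable[Variant], scope: str = "genome"
) -> SubstitutionSpectrum:
    """Tally SNP substitution classes; InDels are ignored.

    scope="genome" uses all SNPs; any other value restricts to that
    chromosome.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for v in variants:
        if not v.is_snp:
            continue
        if scope != "genome" and v.chrom != scope:
            continue
        counts[_sub_class(v.ref, v.alt)] += 1
    return SubstitutionSpectrum(counts=counts, scope=scope)


def per_chromosome_spectra(
    variants: list[Variant],
) -> dict[str, SubstitutionSpectrum]:
    chroms = sorted({v.chrom for v in variants if v.is_snp})
    return {c: substitution_spectrum(variants, scope=c) for c in chroms}


def compare_counts(variants: Iterable[Variant]) -> dict:
    """SNP/InDel totals plus per-chromosome breakdown."""
    per_chrom: dict[str, dict[str, int]] = {}
    n_snp = n_indel = 0
    for v in variants:
        d = per_chrom.setdefault(v.chrom, {"n_snp": 0, "n_indel": 0})
        if v.is_snp:
            n_snp += 1
            d["n_snp"] += 1
        else:
            n_indel += 1
            d["n_indel"] += 1
    return {"n_snp": n_snp, "n_indel": n_indel, "per_chrom": per_chrom}


def normalize_variant(variant: Variant, genome: GenomeSequence) -> Variant:
    """Trim shared allele ends and left-shift pure indels through repeats.

    Suffix then prefix bases common to REF and ALT are removed (always
    keeping one base), then an insertion/deletion sharing only its anchor
    base is slid left while the reference repeats allow it.
    """
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    seq = genome.seq(variant.chrom)
    # left-shift an indel: while both alleles end with the same base, drop
    # it and prepend the preceding reference base
    while pos > 1 and len(ref) != len(alt) and ref[-1] == alt[-1]:
        prev = seq[pos - 2]
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    if (ref, alt, pos) == (variant.ref, variant.alt, variant.pos):
        return variant
    return Variant(variant.chrom, pos, ref, alt, variant.qual, variant.depth)


@dataclass
class CoordinateMap:
    """Lift original (pre-edit) coordinates onto the pseudo-reference.

    Per chromosome: sorted offset breakpoints [(src_pos, offset)] meaning
    positions >= src_pos shift by offset (until the next breakpoint), and
    a list of deleted source intervals that have no image.
    """

    breakpoints: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    deleted: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def lift(self, chrom: str, pos: int) -> Optional[int]:
        """Map a 0-based source position; None if the base was deleted."""
        for s, e in self.deleted.get(chrom, []):
            if s <= pos < e:
                return None
        bps = self.breakpoints.get(chrom, [])
        i = bisect_right(bps, (pos, float("inf")))
        offset = bps[i - 1][1] if i else 0
        return pos + offset


def build_pseudo_reference(
    genome: GenomeSequence, variants: Iterable[Variant]
) -> tuple[GenomeSequence, CoordinateMap]:
    """Apply all variants to the genome, producing the edited sequence
    and the coordinate lift-over map.

    Variants must be non-overlapping on their reference footprints and
    their REF alleles must match the genome; violations raise ModelError
    naming the offending records.
    """
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        if v.chrom not in genome:
            raise ModelError(f"variant on unknown chromosome {v.chrom!r}")
        by_chrom.setdefault(v.chrom, []).append(v)

    new_seqs: dict[str, str] = {}
    cmap = CoordinateMap()
    for chrom in genome.chrom_names:
        seq = genome.seq(chrom)
        vs = sorted(by_chrom.get(chrom, []), key=lambda v: v.pos)
        pieces: list[str] = []
        bps: list[tuple[int, int]] = []
        dels: list[tuple[int, int]] = []
        cursor, offset = 0, 0
        prev: Optional[Variant] = None
        for v in vs:
            if prev is not None and v.start0 < prev.end0:
                raise ModelError(
                    f"overlapping variants on {chrom}: "
                    f"{prev.pos}:{prev.ref}>{prev.alt} and {v.pos}:{v.ref}>{v.alt}"
                )
            if seq[v.start0 : v.end0] != v.ref:
                raise ModelError(
                    f"{chrom}:{v.pos}: REF {v.ref!r} does not match genome "
                    f"{seq[v.start0:v.end0]!r}"
                )
            pieces.append(seq[cursor : v.start0])
            pieces.append(v.alt)
            cursor = v.end0
            delta = len(v.alt) - len(v.ref)
            if delta != 0:
                if len(v.ref) > 1:
                    # bases after the anchor are treated as having no image
                    dels.append((v.start0 + 1, v.end0))
                offset += delta
                bps.append((v.end0, offset))
            prev = v
        pieces.append(seq[cursor:])
        new_seqs[chrom] = "".join(pieces)
        cmap.breakpoints[chrom] = bps
        cmap.deleted[chrom] = dels
        expected_delta = sum(len(v.alt) - len(v.ref) for v in vs)
        assert len(new_seqs[chrom]) == len(seq) + expected_delta
    return GenomeSequence(new_seqs), cmap
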
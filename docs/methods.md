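# Methods

## Scope and model

The package reconstructs, as a reusable pipeline, the comparative-genomics
workflow applied to a mutagenized plant line resequenced against its
parent: quality filtering of called variants, construction of the edited
("pseudo") reference, substitution-spectrum summaries, window-based
hypermutation scanning, codon-level variant-effect classification,
threshold-based DEG calling, promoter-variant × DEG intersection and
hypergeometric term enrichment. Read alignment and variant *calling*
themselves are out of scope: the pipeline consumes a VCF and a per-gene
differential-expression table produced upstream, and likewise consumes a
term→gene map rather than any ontology database.

## Coordinates

All in-memory intervals are 0-based half-open; GFF3 and VCF coordinates
are converted once, at the I/O boundary (`polmutscan.io`), and BED is
passed through unchanged. `Variant.pos` retains the 1-based VCF value for
user-facing reporting; internal code uses its 0-based accessors. A
consequence worth noting: the last base of the first 100-kb window is VCF
position 100,000 (0-based 99,999); VCF position 100,001 opens window 2.

## Variant filtering

`filter_variants` keeps variants with QUAL ≥ 30 and 10 ≤ DP ≤ 100
(inclusive boundaries, configurable). A variant whose DP cannot be read
from INFO or the first sample's FORMAT has unknown coverage and fails the
coverage requirement rather than being guessed — the filter is a positive
evidence requirement. The operation is order-preserving, pure and
idempotent.

## Pseudo-reference and lift-over

`build_pseudo_reference` applies every variant to the reference.
Variants must be non-overlapping on their reference footprints
(`[pos-1, pos-1+len(ref))`); overlaps raise an error naming the colliding
pair rather than attempting to compose edits. `normalize_variant`
provides the standard canonicalisation for InDels: shared allele
prefix/suffix bases are trimmed (always keeping the anchor base) and pure
insertions/deletions are left-shifted through reference repeats by
repeatedly dropping the shared terminal base and prepending the preceding
reference base.

The `CoordinateMap` records, per chromosome, offset breakpoints at the
end of each length-changing edit plus the deleted source intervals.
`lift(chrom, pos)` maps any original position to the edited sequence, or
`None` for a deleted base. The deliberate convention for a deletion is
that only the anchor base keeps an image; the removed bases have none.
Per chromosome the length change equals Σ(len(alt) − len(ref)), asserted
internally.

## Substitution spectrum

The 12 directed SNP exchanges are collapsed to 6 unordered classes;
A↔G and C↔T are transitions. Ts/Tv is reported genome-wide and per
chromosome (both, since summaries of this kind are ambiguous between the
two). A spectrum with zero transversions reports NaN rather than raising.

## Window scan and HMR calling

Windows default to non-overlapping 100-kb tiles ("sliding window at
100-kb intervals" read as step = width; an overlapping step ≤ width is
supported). The final window of a chromosome may be short; densities are
normalised to per-100-kb by the *actual* window width, and window counts
conserve chromosome totals.

No quantitative definition of a "hypermutation region" exists in the
source analysis, so the package uses the simplest defensible outlier
rule: a window qualifies when its SNP density strictly exceeds
mean + k·SD (population SD, k = 2 by default) of all windows genome-wide;
adjacent qualifying windows merge into one region carrying the peak
density and its z-score. When all windows are identical (SD = 0) no
region can qualify and no division error occurs. A top-quantile rule
(`method="quantile"`) is available as an alternative. The rule is
monotone in k by construction. Overlap with externally supplied regions
(e.g. domestication loci) is an exhaustive pairwise intersection with
overlap length ≥ 1 bp.

## Effect classification

Each gene is represented by its longest-CDS transcript (complete
transcripts preferred; ties broken by id). A SNP gets exactly one region:
CDS, then UTR5/UTR3, then intron within the gene span, else intergenic;
when overlapping genes disagree, a CDS assignment wins. The spliced CDS
is assembled across exon junctions and reverse-complemented on the minus
strand, so codons spanning junctions and minus-strand alleles are handled
uniformly. Consequences follow the precedence

    start_loss > stop_loss > stop_gain > nonsynonymous > synonymous

with a stop→stop exchange counted synonymous. CDS InDels are frameshift
when |len(alt) − len(ref)| mod 3 ≠ 0, else inframe_indel. Two degenerate
cases are classified conservatively with a logged warning: a position
inside a gene span that falls outside the representative transcript's
partition is called intron, and a SNP in the trailing partial codon of an
incomplete (length ∤ 3) CDS is called nonsynonymous, since the region
contract requires a concrete coding label for CDS positions.

Summary percentages are printed at the precision the analysis genre uses:
region shares to the nearest integer, promoter percentages to one
decimal; rounding is deterministic half-up. `genes_with_min_nonsyn`
defaults to ≥ 2 ("more than one" read literally) with the threshold
exposed.

## Expression integration

DEG calling is strict-threshold: up if log2FC > 1 and adjusted p < 0.05,
down if log2FC < −1 and adjusted p < 0.05. When the table carries raw
p-values only, Benjamini–Hochberg adjustment (via
`statsmodels.stats.multitest`) is applied over the whole table; "adjusted
p" without a named method is taken as BH, the default of the usual
differential-expression tools. Promoters are the ≤ 2000 bp immediately
upstream of the TSS — the 5'-most transcribed coordinate of the longest
transcript — i.e. `[TSS−2000, TSS)` on plus, `[span_end, span_end+2000)`
on minus, clipped (and flagged) at chromosome edges. A DEG counts once
per variant class no matter how many promoter variants hit; DEGs missing
from the annotation are excluded with a warning and reported. The
denominator used for every percentage is reported alongside it.

## Enrichment

For each term: K carriers among N universe genes, k carriers among the n
study genes; p = hypergeometric upper tail P(X ≥ k) via
`scipy.stats.hypergeom.sf`, BH across all terms tested in the batch,
terms with k = 0 skipped. No parent-term propagation is applied; the map
is taken as given. The pipeline uses the expression table's gene set as
the universe (the natural "expressed genes" background); standalone calls
accept any universe.

## Simulator

The generator's defaults are the study profile: SNP rate 3.03×10⁻⁴/bp
(30.3 per 100 kb), InDel rate 1.08×10⁻⁴/bp (10.8 per 100 kb), transition
weight w = 4.76 so the expected Ts/Tv is w/2 = 2.38. The substitution
model is a per-site categorical draw — transition with probability
w/(w+2), else one of the two transversions equiprobably — not a full rate
matrix, since only the Ts/Tv summary constrains it. InDel lengths are
uniform on 1–10 bp (no published length spectrum), insertions and
deletions equiprobable.

Chromosome sequences are i.i.d. uniform A/C/G/T. Genes are placed
non-overlapping on random strands with ≥ 3 kb spacing (room for 2-kb
promoters); every CDS is built as ATG + random sense codons + stop, so it
translates with no internal stop by construction; introns (0–2, forced on
every second gene so ≥ 50% have one) interrupt the CDS at arbitrary bases,
deliberately producing junction-spanning codons; UTRs flank both ends.
Gene count/length defaults (120 genes of 60–300 codons on 3 × 1 Mb) keep
the default profile desk-sized while exercising every structural case.

Background SNP counts are Poisson(rate × length) per chromosome with
uniform positions; planted hot windows receive additional
Poisson(rate × (multiplier−1) × width) SNPs. Effect-class plants are
*constructive*: a codon position and alternate base are searched for
which the translated consequence equals the requested class, so the truth
labels are exact rather than sampled, and an impossible request (e.g.
more start-loss plants than ATG positions) raises an error naming the
class. Planted entities (effect and promoter variants) always receive
passing QUAL/DP so truth recovery is not confounded with filtering; a
configurable fraction (default 0.1) of background variants receives
failing QUAL or DP. Expression tables plant n_up/n_down DEGs with
|log2FC| ∈ [1.2, 4] and raw p ≤ 10⁻⁶ (BH-safe at any table size); nulls
draw log2FC ~ N(0, 0.3) and, in the default strict-null mode,
p ~ U(0.5, 1), which makes planted-DEG recovery exact because a BH-adjusted
p is never below the raw p. A realistic mode (p ~ U(0,1)) exists for
statistical exercises.

Determinism: one seed; each generator stage draws from
`default_rng([seed, stage])` so stages reproduce identically whether run
standalone or through the combined `simulate`.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: sequencing error and alignment artefacts,
non-uniform base composition and repeat structure, linkage between
variants, chromosome-specific density heterogeneity beyond planted hot
windows, overlapping genes and alternative transcripts, and count-model
noise in expression (the table is consumed downstream of model fitting).

## Problem sizes and numerical choices

Stochastic validation uses sizes at which the law-of-large-numbers
tolerances are comfortably resolvable on a laptop: the Ts/Tv recovery
uses ~200,000 SNPs (binomial SE of the ratio ≈ 0.012, tolerance ±0.05),
the density recovery a 20-Mb genome (200 windows, 3 SE ≈ 1.1 SNPs/100 kb
around 30.3), and the hot-window recovery 20 replicates of a 4-Mb genome
with multiplier 6. Percent rounding is half-up to avoid banker's-rounding
surprises in printed summaries. QUAL values are quantized to 4 decimals
on VCF read so write→read round-trips are exact at VCF-typical precision
despite float32 storage in the parser.

## Known limitations

- Effect classification uses one representative transcript per gene;
  isoform-specific consequences are not reported.
- The pseudo-reference rejects overlapping variants instead of composing
  them; callers producing overlapping records must pre-merge.
- `normalize_variant` canonicalises simple InDels; complex
  multi-nucleotide substitutions are passed through after prefix/suffix
  trimming.
- HMR calling is a genome-wide outlier rule; it does not model
  per-chromosome baselines. Centromeric or other confounding regions can
  be excluded with the optional `mask` argument of `detect_hmr` (off by
  default).
- Enrichment treats terms independently; no ontology hierarchy or
  term-term correlation is modelled.
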
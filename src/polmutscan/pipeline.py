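"""End-to-end orchestration: simulate or load inputs, then filter,
pseudo-reference, spectrum, window/HMR scan, effect annotation, DEG
calling, promoter intersection and term enrichment, with one
human-readable summary report.

Every stage writes a plain-text artifact into the output directory and
the report is rendered *from those artifacts*, so each printed number can
be re-derived from the emitted files.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io
from .effects import classify_variants, genes_with_min_nonsyn, summarize_effects
from .enrichment import hypergeom_enrich
from .expression import (
    DEGSummary,
    call_degs,
    extract_promoters,
    intersect_promoter_variants,
)
from .models import ModelError
from .simulate import SimulationConfig, simulate
from .variants import (
    build_pseudo_reference,
    compare_counts,
    filter_variants,
    per_chromosome_spectra,
    substitution_spectrum,
    SPECTRUM_CLASSES,
)
from .windows import detect_hmr, overlap_regions, window_densities

logger = logging.getLogger("polmutscan")

#: stage parameter defaults = the published analysis profile
DEFAULT_PARAMS = {
    "min_qual": 30.0,
    "min_dp": 10,
    "max_dp": 100,
    "window_size": 100_000,
    "hmr_method": "mean_sd",
    "hmr_k": 2.0,
    "promoter_length": 2000,
    "lfc_threshold": 1.0,
    "padj_threshold": 0.05,
    "min_nonsyn": 2,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    inputs: dict = field(default_factory=dict)  # fasta/gff3/vcf/expression/term_map/regions
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = None
        if "simulate" in raw and raw["simulate"] is not None:
            sim_kwargs = dict(raw["simulate"])
            if "planted_hmr" in sim_kwargs:
                sim_kwargs["planted_hmr"] = [
                    (str(c), int(w), float(m)) for c, w, m in sim_kwargs["planted_hmr"]
                ]
            for key in ("cds_codons", "intron_length", "utr5_length", "utr3_length",
                        "indel_len", "deg_log2fc"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            sim = SimulationConfig(**sim_kwargs)
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            simulate=sim,
            inputs=dict(raw.get("inputs", {})),
            params=dict(raw.get("params", {})),
        )
        if cfg.simulate is not None:
            cfg.simulate.seed = cfg.seed
        for key, p in cfg.inputs.items():
            if not Path(p).exists():
                raise ModelError(f"input {key!r}: no such file {p}")
        return cfg


@dataclass
class ReportBundle:
    outdir: Path
    report: str
    files: dict[str, Path]


def _kv(path: Path, pairs: list[tuple[str, object]]) -> None:
    pd.DataFrame(pairs, columns=["metric", "value"]).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, outdir) -> ReportBundle:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    p = config.params

    def out(name: str) -> Path:
        files[name] = outdir / name
        return files[name]

    # ---------------- stage 0: inputs
    expression = None
    term_map = None
    regions = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        logger.info("simulate: seed=%d profile=%s", config.seed, sim)
        genome, genes, variants, expression, truth = simulate(sim)
        io.write_fasta(genome, out("genome.fa"))
        io.write_gff3(genes, out("genes.gff3"))
        io.write_vcf(variants, out("variants.vcf"), genome)
        io.write_expression_table(expression, out("expression.tsv"))
        _write_truth(truth, outdir, files)
    else:
        if "fasta" not in config.inputs or "gff3" not in config.inputs or "vcf" not in config.inputs:
            raise ModelError("inputs must provide fasta, gff3 and vcf (or a simulate block)")
        genome = io.read_fasta(config.inputs["fasta"])
        genes = io.read_gff3(config.inputs["gff3"], genome)
        variants = io.read_vcf(config.inputs["vcf"], genome)
        if "expression" in config.inputs:
            expression = io.read_expression_table(config.inputs["expression"])
    if config.inputs.get("term_map"):
        term_map = io.read_term_map(config.inputs["term_map"])
    if config.inputs.get("regions"):
        regions = io.read_bed(config.inputs["regions"])

    counts_in = compare_counts(variants)

    # ---------------- stage 1: filter
    filtered = filter_variants(
        variants, min_qual=p["min_qual"], min_dp=p["min_dp"], max_dp=p["max_dp"]
    )
    logger.info(
        "filter: qual>=%s dp in [%s,%s]; %d -> %d variants",
        p["min_qual"], p["min_dp"], p["max_dp"], len(variants), len(filtered),
    )
    io.write_vcf(filtered, out("filtered.vcf"), genome)
    counts_f = compare_counts(filtered)
    _kv(
        out("counts.tsv"),
        [
            ("n_input", len(variants)),
            ("n_input_snp", counts_in["n_snp"]),
            ("n_input_indel", counts_in["n_indel"]),
            ("n_filtered", len(filtered)),
            ("n_filtered_snp", counts_f["n_snp"]),
            ("n_filtered_indel", counts_f["n_indel"]),
        ],
    )

    # ---------------- stage 2: pseudo-reference
    pseudo, cmap = build_pseudo_reference(genome, filtered)
    io.write_fasta(pseudo, out("pseudo_reference.fa"))
    rows = [
        {"chrom": c, "src_end": s, "offset": o}
        for c, bps in cmap.breakpoints.items()
        for s, o in bps
    ]
    pd.DataFrame(rows, columns=["chrom", "src_end", "offset"]).to_csv(
        out("liftover.tsv"), sep="\t", index=False
    )
    logger.info("pseudo-reference: %d liftover breakpoints", len(rows))

    # ---------------- stage 3: substitution spectrum
    spec_rows = []
    genome_spec = substitution_spectrum(filtered)
    for scope, s in [("genome", genome_spec)] + sorted(
        per_chromosome_spectra(filtered).items()
    ):
        spec_rows.append(
            {
                "scope": scope,
                **{c: s.counts[c] for c in SPECTRUM_CLASSES},
                "ts": s.ts_count,
                "tv": s.tv_count,
                "ts_tv_ratio": s.ts_tv_ratio,
            }
        )
    pd.DataFrame(spec_rows).to_csv(out("spectrum.tsv"), sep="\t", index=False)

    # ---------------- stage 4: windows + HMR
    wins = window_densities(filtered, genome, window_size=p["window_size"])
    pd.DataFrame(
        [
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "snp_count": w.snp_count, "indel_count": w.indel_count,
                "snp_density": w.snp_density, "indel_density": w.indel_density,
            }
            for w in wins
        ]
    ).to_csv(out("windows.tsv"), sep="\t", index=False)
    hmrs = detect_hmr(wins, method=p["hmr_method"], k=p["hmr_k"])
    io.write_bed(
        [
            (h.chrom, h.start, h.end, f"HMR_{i+1}", f"{h.zscore:.3f}")
            for i, h in enumerate(hmrs)
        ],
        out("hmr.bed"),
    )
    logger.info("windows: %d windows, %d HMRs", len(wins), len(hmrs))
    if regions:
        ov = overlap_regions(hmrs, regions)
        pd.DataFrame(
            [
                {
                    "hmr_chrom": h.chrom, "hmr_start": h.start, "hmr_end": h.end,
                    "region_chrom": r[0], "region_start": r[1], "region_end": r[2],
                    "overlap_bp": bp,
                }
                for h, r, bp in ov
            ],
            columns=[
                "hmr_chrom", "hmr_start", "hmr_end",
                "region_chrom", "region_start", "region_end", "overlap_bp",
            ],
        ).to_csv(out("hmr_region_overlap.tsv"), sep="\t", index=False)

    # ---------------- stage 5: effect annotation
    effects = classify_variants(filtered, genes, genome)
    pd.DataFrame(
        [
            {
                "chrom": e.variant.chrom, "pos": e.variant.pos,
                "ref": e.variant.ref, "alt": e.variant.alt,
                "vtype": e.variant.vtype, "region": e.region,
                "coding_effect": e.coding_effect,
                "gene_id": e.gene_id or "",
                "codon_change": e.codon_change or "",
                "aa_change": e.aa_change or "",
                "large_effect": e.large_effect,
            }
            for e in effects
        ]
    ).to_csv(out("effects.tsv"), sep="\t", index=False)
    summary = summarize_effects(effects, genome)
    summary.per_chrom.to_csv(out("effect_summary.tsv"), sep="\t", index=False)
    n_multi_nonsyn = genes_with_min_nonsyn(effects, min_count=p["min_nonsyn"])
    _kv(
        out("effect_totals.tsv"),
        [
            ("n_snp_total", summary.n_total),
            ("n_genic", summary.n_genic),
            ("n_intergenic", summary.n_intergenic),
            ("n_cds", summary.n_cds),
            ("n_utr", summary.n_utr),
            ("n_intron", summary.n_intron),
            ("n_synonymous", summary.n_synonymous),
            ("n_nonsynonymous", summary.n_nonsynonymous),
            ("n_stop_gain", summary.n_stop_gain),
            ("n_start_loss", summary.n_start_loss),
            ("n_stop_loss", summary.n_stop_loss),
            ("min_nonsyn", p["min_nonsyn"]),
            ("n_genes_min_nonsyn", n_multi_nonsyn),
        ],
    )

    # ---------------- stage 6-8: expression-dependent stages
    skipped = []
    if expression is not None:
        degs = call_degs(
            expression,
            lfc_threshold=p["lfc_threshold"],
            padj_threshold=p["padj_threshold"],
        )
        io.write_expression_table(degs, out("degs.tsv"))
        promoters = extract_promoters(genes, genome, length=p["promoter_length"])
        io.write_bed(
            [(pr.chrom, pr.start, pr.end, pr.gene_id, ".", pr.strand) for pr in promoters],
            out("promoters.bed"),
        )
        hits = intersect_promoter_variants(degs, promoters, filtered)
        _kv(
            out("promoter_hits.tsv"),
            [
                ("n_deg", hits.n_deg),
                ("n_deg_with_promoter_snp", hits.n_deg_with_promoter_snp),
                ("n_deg_with_promoter_indel", hits.n_deg_with_promoter_indel),
                ("n_missing_annotation", hits.n_missing_annotation),
            ],
        )
        io.write_tsv_report(
            pd.DataFrame(
                [{"gene_id": g, "variant_class": "SNP"} for g in hits.snp_hit_genes]
                + [{"gene_id": g, "variant_class": "InDel"} for g in hits.indel_hit_genes],
                columns=["gene_id", "variant_class"],
            ),
            out("promoter_hit_genes.tsv"),
        )
        if term_map is not None:
            universe = [r.gene_id for r in degs]
            enr_rows = []
            for direction, status in (("up", "up"), ("down", "down")):
                study = [r.gene_id for r in degs if r.deg_status == status]
                if study:
                    for r in hypergeom_enrich(study, term_map, universe, direction=direction):
                        enr_rows.append(dataclasses.asdict(r))
            pd.DataFrame(
                enr_rows,
                columns=["term_id", "k", "n", "K", "N", "p", "fdr", "direction"],
            ).to_csv(out("enrichment.tsv"), sep="\t", index=False)
        else:
            skipped.append("enrichment (no term map)")
    else:
        skipped.extend(
            [
                "DEG calling (no expression table)",
                "promoter intersection (no expression table)",
                "enrichment (no expression table)",
            ]
        )
    if skipped:
        (outdir / "skipped_stages.txt").write_text("\n".join(skipped) + "\n")
        files["skipped_stages.txt"] = outdir / "skipped_stages.txt"

    report = render_report(outdir)
    (outdir / "report.txt").write_text(report)
    files["report.txt"] = outdir / "report.txt"
    return ReportBundle(outdir=outdir, report=report, files=files)


def _write_truth(truth, outdir: Path, files: dict) -> None:
    pd.DataFrame(
        [
            {
                "chrom": c, "pos": pos, "ref": r, "alt": a,
                "true_effect": truth.variant_effects.get((c, pos, r, a), ""),
                "passes_filter": pf,
            }
            for (c, pos, r, a), pf in sorted(truth.passes_filter.items())
        ],
        columns=["chrom", "pos", "ref", "alt", "true_effect", "passes_filter"],
    ).to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_id": g,
                "true_deg_status": s,
                "promoter_snp": g in truth.promoter_snp_genes,
                "promoter_indel": g in truth.promoter_indel_genes,
            }
            for g, s in sorted(truth.deg_status.items())
        ],
        columns=["gene_id", "true_deg_status", "promoter_snp", "promoter_indel"],
    ).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    io.write_bed(sorted(truth.hmr_windows), outdir / "truth_hmr.bed")
    for name in ("truth_variants.tsv", "truth_genes.tsv", "truth_hmr.bed"):
        files[name] = outdir / name


# ------------------------------------------------------------- report

def _fmt_pct(num: int, den: int, decimals: int = 0) -> str:
    if den == 0:
        return f"0% ({num:,}/{den:,})"
    pct = 100.0 * num / den
    return f"{pct:.{decimals}f}% ({num:,}/{den:,})"


def render_report(outdir) -> str:
    """Compose the summary report purely from the stage artifacts on disk."""
    outdir = Path(outdir)
    lines = ["polmutscan summary report", "=" * 28, ""]

    def kv(name: str) -> dict:
        df = pd.read_csv(outdir / name, sep="\t")
        return dict(zip(df["metric"], df["value"]))

    counts = kv("counts.tsv")
    lines += [
        "Variant counts",
        f"  input: {counts['n_input']:,} "
        f"({counts['n_input_snp']:,} SNPs, {counts['n_input_indel']:,} InDels)",
        f"  after filtering: {counts['n_filtered']:,} "
        f"({counts['n_filtered_snp']:,} SNPs, {counts['n_filtered_indel']:,} InDels)",
        "",
    ]

    spec = pd.read_csv(outdir / "spectrum.tsv", sep="\t")
    g = spec[spec["scope"] == "genome"].iloc[0]
    lines += [
        "Substitution spectrum (genome-wide)",
        f"  transitions: {int(g['ts']):,}  transversions: {int(g['tv']):,}  "
        f"Ts/Tv: {g['ts_tv_ratio']:.2f}" if g["tv"] > 0 else
        "  transitions only; Ts/Tv undefined",
    ]
    per = spec[spec["scope"] != "genome"]
    if len(per):
        ratios = ", ".join(
            f"{r.scope}: {r.ts_tv_ratio:.2f}" if r.tv > 0 else f"{r.scope}: NA"
            for r in per.itertuples()
        )
        lines.append(f"  per chromosome: {ratios}")
    lines.append("")

    wins = pd.read_csv(outdir / "windows.tsv", sep="\t")
    lines += [
        "Window scan",
        f"  windows: {len(wins):,}  "
        f"mean SNP density: {wins['snp_density'].mean():.1f}/100 kb  "
        f"mean InDel density: {wins['indel_density'].mean():.1f}/100 kb",
    ]
    hmr_path = outdir / "hmr.bed"
    n_hmr = sum(1 for _ in open(hmr_path)) if hmr_path.exists() else 0
    lines += [f"  hypermutation regions: {n_hmr}", ""]

    et = kv("effect_totals.tsv")
    tot, genic, inter = int(et["n_snp_total"]), int(et["n_genic"]), int(et["n_intergenic"])
    lines += [
        "SNP effect classification",
        f"  genic {_fmt_pct(genic, tot)}   intergenic {_fmt_pct(inter, tot)}",
        f"  of genic: CDS {_fmt_pct(int(et['n_cds']), genic)}  "
        f"UTR {_fmt_pct(int(et['n_utr']), genic)}  "
        f"intron {_fmt_pct(int(et['n_intron']), genic)}",
    ]
    n_cds_classified = int(et["n_synonymous"]) + int(et["n_nonsynonymous"]) + \
        int(et["n_stop_gain"]) + int(et["n_start_loss"]) + int(et["n_stop_loss"])
    lines += [
        f"  of CDS SNPs: synonymous "
        f"{_fmt_pct(int(et['n_synonymous']), n_cds_classified)}  nonsynonymous "
        f"{_fmt_pct(int(et['n_nonsynonymous']), n_cds_classified)}",
        f"  large-effect: stop_gain {int(et['n_stop_gain']):,}  "
        f"start_loss {int(et['n_start_loss']):,}  stop_loss {int(et['n_stop_loss']):,}",
        f"  genes with >= {int(et['min_nonsyn'])} nonsynonymous SNPs: "
        f"{int(et['n_genes_min_nonsyn']):,}",
        "",
    ]

    if (outdir / "degs.tsv").exists():
        degs = pd.read_csv(outdir / "degs.tsv", sep="\t")
        n_up = int((degs["deg_status"] == "up").sum())
        n_down = int((degs["deg_status"] == "down").sum())
        lines += [
            "Differential expression",
            f"  DEGs: {n_up + n_down:,} of {len(degs):,} "
            f"({n_up:,} up, {n_down:,} down)",
        ]
        ph = kv("promoter_hits.tsv")
        n_deg = int(ph["n_deg"])
        lines += [
            f"  DEGs with promoter SNP: "
            f"{_fmt_pct(int(ph['n_deg_with_promoter_snp']), n_deg, 1)}",
            f"  DEGs with promoter InDel: "
            f"{_fmt_pct(int(ph['n_deg_with_promoter_indel']), n_deg, 1)}",
            "",
        ]
    if (outdir / "enrichment.tsv").exists():
        enr = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
        lines.append("Term enrichment (top terms by FDR)")
        if len(enr):
            for r in enr.sort_values(["fdr", "term_id"]).head(5).itertuples():
                lines.append(
                    f"  {r.term_id} [{r.direction}]: k={r.k}/{r.n} K={r.K}/{r.N} "
                    f"p={r.p:.3g} FDR={r.fdr:.3g}"
                )
        else:
            lines.append("  no overlapping terms")
        lines.append("")
    if (outdir / "skipped_stages.txt").exists():
        lines.append("Skipped stages")
        for s in (outdir / "skipped_stages.txt").read_text().splitlines():
            lines.append(f"  - {s}")
        lines.append("")
    return "\n".join(lines) + "\n"
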
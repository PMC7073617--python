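"""Window-based variant-density scan and hypermutation-region calling.

Chromosomes are tiled into fixed-size windows (default 100 kb,
non-overlapping; an overlapping step is available), per-window SNP and
InDel counts are normalised to per-100-kb densities, and hypermutation
regions (HMRs) are called as runs of windows whose SNP density exceeds an
outlier threshold over the genome-wide window distribution.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .models import GenomeSequence, HMRegion, ModelError, Variant, WindowStat


def window_densities(
    variants: Iterable[Variant],
    genome: GenomeSequence,
    window_size: int = 100_000,
    step: Optional[int] = None,
) -> list[WindowStat]:
    """Per-window SNP/InDel counts across every chromosome.

    Windows are half-open [start, start+window_size) clipped at the
    chromosome end; a variant belongs to the window(s) containing its
    0-based position.  With the default step == window_size the windows
    tile the chromosome and counts conserve totals.
    """
    if window_size <= 0:
        raise ModelError("window_size must be > 0")
    step = window_size if step is None else step
    if step <= 0 or step > window_size:
        raise ModelError("step must satisfy 0 < step <= window_size")

    snp_pos: dict[str, list[int]] = {}
    indel_pos: dict[str, list[int]] = {}
    for v in variants:
        (snp_pos if v.is_snp else indel_pos).setdefault(v.chrom, []).append(v.start0)

    out: list[WindowStat] = []
    for chrom in genome.chrom_names:
        length = genome.length(chrom)
        snps = np.sort(np.asarray(snp_pos.get(chrom, []), dtype=np.int64))
        indels = np.sort(np.asarray(indel_pos.get(chrom, []), dtype=np.int64))
        for start in range(0, length, step):
            end = min(start + window_size, length)
            ns = int(np.searchsorted(snps, end) - np.searchsorted(snps, start))
            ni = int(np.searchsorted(indels, end) - np.searchsorted(indels, start))
            out.append(WindowStat(chrom, start, end, ns, ni))
            if end == length:
                break
    return out


def detect_hmr(
    windows: list[WindowStat],
    method: str = "mean_sd",
    k: float = 2.0,
    q: float = 0.01,
    mask: Optional[list[tuple[str, int, int]]] = None,
) -> list[HMRegion]:
    """Call hypermutation regions from the window SNP densities.

    method="mean_sd": a window qualifies when its SNP density exceeds
    mean + k*SD of all windows genome-wide (population SD; if SD is 0 no
    window can qualify).  method="quantile": the top q fraction qualify.
    Adjacent qualifying windows on a chromosome are merged into one region;
    each region's z-score is taken at its peak window.  Windows touching a
    `mask` interval (e.g. centromeres, BED-style tuples) are excluded from
    both the background statistics and the calls.
    """
    if mask:
        windows = [
            w
            for w in windows
            if not any(
                c == w.chrom and min(w.end, e) - max(w.start, s) > 0
                for c, s, e in mask
            )
        ]
    if len(windows) < 2:
        raise ModelError("need at least 2 windows")
    dens = np.array([w.snp_density for w in windows])
    mean = float(dens.mean())
    sd = float(dens.std(ddof=0))
    if method == "mean_sd":
        threshold = mean + k * sd
    elif method == "quantile":
        if not 0 < q < 1:
            raise ModelError("q must be in (0,1)")
        threshold = float(np.quantile(dens, 1 - q))
    else:
        raise ModelError(f"unknown HMR method {method!r}")

    regions: list[HMRegion] = []
    run: list[WindowStat] = []

    def flush():
        if not run:
            return
        peak = max(w.snp_density for w in run)
        z = (peak - mean) / sd if sd > 0 else 0.0
        regions.append(
            HMRegion(
                chrom=run[0].chrom,
                start=run[0].start,
                end=run[-1].end,
                n_windows=len(run),
                peak_density=peak,
                zscore=z,
            )
        )
        run.clear()

    for w in windows:
        if w.snp_density > threshold:
            if run and (w.chrom != run[-1].chrom or w.start != run[-1].end):
                flush()
            run.append(w)
        else:
            flush()
    flush()
    return regions


def overlap_regions(
    hmrs: list[HMRegion], regions: list[tuple[str, int, int]]
) -> list[tuple[HMRegion, tuple[str, int, int], int]]:
    """All (HMR, region) pairs overlapping by >= 1 bp, with overlap length."""
    out = []
    for h in hmrs:
        for r in regions:
            chrom, s, e = r[0], r[1], r[2]
            if chrom != h.chrom:
                continue
            ov = min(h.end, e) - max(h.start, s)
            if ov >= 1:
                out.append((h, r, ov))
    return out


def plot_density_tracks(windows: list[WindowStat], path) -> None:
    """Simple per-chromosome SNP-density track plot (one panel per chromosome)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({w.chrom for w in windows})
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.6 * len(chroms)), squeeze=False, sharey=True
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        ws = [w for w in windows if w.chrom == chrom]
        ax.plot(
            [(w.start + w.end) / 2 / 1e6 for w in ws],
            [w.snp_density for w in ws],
            lw=0.8,
        )
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.suptitle("SNP density per 100 kb")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
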
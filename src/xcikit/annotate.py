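"""Build the genomic region universe for windowed Polycomb-mark analysis.

Four region classes are produced from gene models and H3K27ac peak calls in
uninduced (noDOX) cells:

* *initially active promoters* — ±2 kb around the TSS of genes whose
  transcript TSS overlaps an H3K27ac peak before induction;
* *initially active gene bodies* — those genes' spans minus the first 2 kb
  downstream of the TSS;
* *intergenic windows* — fixed-size tiles free of any gene, any gene's
  ±2 kb promoter region, and any H3K27ac peak;
* *fixed windows* — plain genome tiles for chromosome-wide views.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .genome import (
    ActiveGeneSpan,
    GenomicInterval,
    RegionSet,
    TranscriptModel,
    merge_intervals,
    position_in_any,
)

logger = logging.getLogger(__name__)

__all__ = [
    "define_initially_active_genes",
    "build_promoters",
    "build_gene_bodies",
    "build_intergenic_windows",
    "build_fixed_windows",
]


def define_initially_active_genes(
    transcripts: Sequence[TranscriptModel],
    h3k27ac_peaks: Sequence[GenomicInterval],
) -> list[ActiveGeneSpan]:
    """Flag genes whose transcript TSS lies inside an H3K27ac peak.

    A gene is initially active iff at least one of its transcripts has its
    TSS (single-base test) inside a peak. The active span runs from the
    minimum start to the maximum end over the *active* transcripts only;
    inactive genes get the union span of all their transcripts.
    """
    if not transcripts:
        raise ValueError("empty transcript list")
    in_peak = position_in_any(list(h3k27ac_peaks))

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tm in transcripts:
        by_gene.setdefault(tm.gene_name, []).append(tm)

    spans: list[ActiveGeneSpan] = []
    for gene in sorted(by_gene):
        tms = by_gene[gene]
        chroms = {tm.chrom for tm in tms}
        if len(chroms) > 1:
            # keep transcripts on the majority chromosome; rare annotation noise
            chrom = max(chroms, key=lambda c: sum(tm.chrom == c for tm in tms))
            tms = [tm for tm in tms if tm.chrom == chrom]
        active_tms = [tm for tm in tms if in_peak(tm.chrom, tm.tss)]
        members = active_tms if active_tms else tms
        strand = members[0].strand
        spans.append(
            ActiveGeneSpan(
                gene_name=gene,
                chrom=members[0].chrom,
                strand=strand,
                start=min(tm.tx_start for tm in members),
                end=max(tm.tx_end for tm in members),
                is_active=bool(active_tms),
            )
        )
    return spans


def _check_chroms(genes: Sequence[ActiveGeneSpan], chrom_sizes: dict[str, int]) -> None:
    missing = sorted({g.chrom for g in genes} - set(chrom_sizes))
    if missing:
        raise ValueError(f"genes on chromosomes absent from chrom_sizes: {missing}")


def build_promoters(
    active_genes: Sequence[ActiveGeneSpan],
    chrom_sizes: dict[str, int],
    flank_bp: int = 2000,
) -> RegionSet:
    """±flank_bp windows around the TSS of initially active genes.

    Width is 2*flank_bp regardless of strand, clipped at chromosome bounds.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    active = [g for g in active_genes if g.is_active]
    _check_chroms(active, chrom_sizes)
    rs = RegionSet(region_class="active_promoter")
    for g in active:
        size = chrom_sizes[g.chrom]
        if not (0 <= g.tss < size):
            raise ValueError(
                f"gene {g.gene_name}: TSS {g.tss} outside chromosome "
                f"{g.chrom} of length {size}"
            )
        start = max(0, g.tss - flank_bp)
        end = min(size, g.tss + flank_bp)
        rs.add(f"promoter:{g.gene_name}", GenomicInterval(g.chrom, start, end), g.gene_name)
    return rs


def build_gene_bodies(
    active_genes: Sequence[ActiveGeneSpan],
    trim_bp: int = 2000,
) -> RegionSet:
    """Active gene spans minus the first trim_bp downstream of the TSS.

    Genes shorter than or equal to trim_bp are omitted (logged, not fatal).
    """
    if trim_bp < 0:
        raise ValueError("trim_bp must be >= 0")
    rs = RegionSet(region_class="active_gene_body")
    for g in active_genes:
        if not g.is_active:
            continue
        if g.end - g.start <= trim_bp:
            logger.info("gene %s shorter than trim (%d bp); omitted", g.gene_name, trim_bp)
            continue
        if g.strand == "+":
            iv = GenomicInterval(g.chrom, g.start + trim_bp, g.end)
        else:
            iv = GenomicInterval(g.chrom, g.start, g.end - trim_bp)
        rs.add(f"genebody:{g.gene_name}", iv, g.gene_name)
    return rs


def build_intergenic_windows(
    all_genes: Sequence[ActiveGeneSpan],
    h3k27ac_peaks: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    window_bp: int = 10_000,
    promoter_flank_bp: int = 2000,
) -> RegionSet:
    """Fixed tiles with zero overlap to genes, their ±2 kb promoters, or peaks.

    Each chromosome is tiled with non-overlapping windows of ``window_bp``
    anchored at 0; trailing partial windows are discarded so all windows
    have identical length. A window is kept only if it does not overlap the
    exclusion set = all gene spans (active or not) ∪ TSS±promoter_flank_bp
    of every gene ∪ the H3K27ac peaks.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    _check_chroms(all_genes, chrom_sizes)

    exclusion: list[GenomicInterval] = []
    for g in all_genes:
        exclusion.append(GenomicInterval(g.chrom, g.start, g.end))
        size = chrom_sizes[g.chrom]
        ps = max(0, g.tss - promoter_flank_bp)
        pe = min(size, g.tss + promoter_flank_bp)
        if ps < pe:
            exclusion.append(GenomicInterval(g.chrom, ps, pe))
    exclusion.extend(h3k27ac_peaks)
    excl = merge_intervals(exclusion) if exclusion else []
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in excl:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)

    rs = RegionSet(region_class="intergenic")
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        ivs = excl_by_chrom.get(chrom, [])
        for start in range(0, size - window_bp + 1, window_bp):
            win = GenomicInterval(chrom, start, start + window_bp)
            if any(win.overlaps(e) for e in ivs):
                continue
            rs.add(f"intergenic:{chrom}:{start}", win)
    return rs


def build_fixed_windows(chrom_sizes: dict[str, int], window_bp: int = 10_000) -> RegionSet:
    """Plain genome tiling for chromosome-wide analysis (partial tiles dropped)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rs = RegionSet(region_class="fixed_window")
    for chrom in sorted(chrom_sizes):
        for start in range(0, chrom_sizes[chrom] - window_bp + 1, window_bp):
            rs.add(f"window:{chrom}:{start}", GenomicInterval(chrom, start, start + window_bp))
    return rs
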
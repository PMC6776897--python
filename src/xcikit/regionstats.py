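"""Promoter classification, silencing bins, CpG metrics and group tests.

A promoter "accumulates" a Polycomb mark when its DOX − noDOX normalized
signal exceeds a data-derived threshold: the mean + SD of the accumulation
over *autosomal* promoters, where Xist cannot act, so the threshold is the
upper edge of the no-effect distribution. A gene's promoter is in the
``accumulation`` category when one or both repressive marks (H3K27me3,
H2AK119ub) exceed their thresholds, else ``no_or_little``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ActiveGeneSpan

__all__ = [
    "accumulation_threshold",
    "classify_promoters",
    "silencing_bins",
    "SILENCING_BIN_LABELS",
    "cpg_metrics",
    "rank_sum_compare",
    "tss_metaprofile",
    "integrate_silencing_accumulation",
]

SILENCING_BIN_LABELS = ("(-inf,-1.5]", "(-1.5,-1]", "(-1,-0.5]", "(-0.5,inf)")


def accumulation_threshold(autosomal_accumulations: Sequence[float]) -> float:
    """mean + sample SD of autosomal promoter accumulations."""
    x = np.asarray(autosomal_accumulations, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 autosomal accumulation values")
    return float(x.mean() + x.std(ddof=1))


def classify_promoters(
    accumulations: pd.DataFrame,
    thresholds: Mapping[str, float],
) -> pd.DataFrame:
    """Per-mark and combined accumulation classes for each promoter.

    ``accumulations`` is genes x marks; a promoter exceeds a mark's
    threshold only strictly (ties fall in ``no_or_little``). The combined
    class is ``accumulation`` iff at least one mark exceeds.
    """
    missing = [m for m in accumulations.columns if m not in thresholds]
    if missing:
        raise ValueError(f"no threshold for mark(s): {missing}")
    if accumulations.isna().any().any():
        bad = accumulations.index[accumulations.isna().any(axis=1)]
        raise ValueError(f"missing accumulation values for: {list(bad)[:5]}")
    out = pd.DataFrame(index=accumulations.index)
    exceeds = pd.DataFrame(index=accumulations.index)
    for mark in accumulations.columns:
        ex = accumulations[mark] > thresholds[mark]
        exceeds[mark] = ex
        out[f"class_{mark}"] = np.where(ex, "accumulation", "no_or_little")
        out[f"accum_{mark}"] = accumulations[mark]
    out["combined"] = np.where(exceeds.any(axis=1), "accumulation", "no_or_little")
    return out


def silencing_bins(logfc: pd.Series | Sequence[float]) -> pd.Series:
    """Assign each gene's RNA log2 fold change to one of four silencing bins.

    Bins: (-inf,-1.5], (-1.5,-1], (-1,-0.5], (-0.5,inf) — upper-bound
    inclusive for the three leftmost bins.
    """
    s = pd.Series(logfc, dtype=float)
    if s.isna().any():
        raise ValueError("NaN log2 fold changes cannot be binned")
    edges = [-np.inf, -1.5, -1.0, -0.5, np.inf]
    cut = pd.cut(s, bins=edges, right=True, labels=SILENCING_BIN_LABELS)
    return cut.astype(str).rename("silencing_bin")


def cpg_metrics(sequences: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Length, G+C fraction, CG-dinucleotide count and density per sequence.

    CG dinucleotides are counted scanning with step 1 (a "CG" match cannot
    overlap itself); density divides by length−1, the number of
    dinucleotide positions. ``N`` bases are excluded from the GC-fraction
    denominator.
    """
    rows = []
    for name, seq in sequences:
        if not seq:
            raise ValueError(f"empty sequence: {name}")
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{name}: unexpected characters {sorted(bad)}")
        n_acgt = sum(seq.count(b) for b in "ACGT")
        gc = (seq.count("G") + seq.count("C")) / n_acgt if n_acgt else np.nan
        cg = seq.count("CG")
        density = cg / (len(seq) - 1) if len(seq) > 1 else 0.0
        rows.append((name, len(seq), gc, cg, density))
    return pd.DataFrame(
        rows, columns=["name", "length", "gc_fraction", "cg_count", "cg_density"]
    ).set_index("name")


def rank_sum_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    paired: bool = False,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank comparison between two groups.

    Unpaired: Mann–Whitney rank-sum. Paired: Wilcoxon signed-rank on
    matched observations. The exact null distribution is used for
    n <= 25 without ties; otherwise the normal approximation with
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length groups")
        diff = a - b
        if np.all(diff == 0):
            return 0.0, 1.0
        nz = diff[diff != 0]
        has_ties = len(np.unique(np.abs(nz))) < len(nz)
        method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
        res = stats.wilcoxon(
            a, b, alternative=alternative, method=method, correction=(method == "approx")
        )
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = max(len(a), len(b)) <= 25 and not has_ties
    res = stats.mannwhitneyu(
        a,
        b,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def tss_metaprofile(
    signal: Sequence[tuple[str, int, int, float]],
    active_genes: Sequence[ActiveGeneSpan],
    span_bp: int = 5000,
    bin_bp: int = 100,
) -> pd.DataFrame:
    """Strand-oriented mean signal in bins around active-gene TSSs.

    ``signal`` is piecewise constant: (chrom, start, end, value) pieces.
    Per gene, each bin over [TSS−span, TSS+span) gets the coverage-weighted
    mean of overlapping pieces (orientation flipped for − strand); bins
    with no data are missing and excluded from the cross-gene mean.
    """
    genes = [g for g in active_genes if g.is_active]
    if not genes:
        raise ValueError("no active genes for metaprofile")
    if span_bp % bin_bp != 0:
        raise ValueError("span_bp must be a multiple of bin_bp")
    n_bins = 2 * span_bp // bin_bp
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, s, e, v in signal:
        by_chrom.setdefault(chrom, []).append((s, e, float(v)))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    profiles = np.full((len(genes), n_bins), np.nan)
    for gi, g in enumerate(genes):
        pieces = by_chrom.get(g.chrom, [])
        window_start = g.tss - span_bp
        sums = np.zeros(n_bins)
        cov = np.zeros(n_bins)
        for s, e, v in pieces:
            s2 = max(s, window_start)
            e2 = min(e, g.tss + span_bp)
            if s2 >= e2:
                continue
            b0 = (s2 - window_start) // bin_bp
            b1 = (e2 - 1 - window_start) // bin_bp
            for b in range(b0, b1 + 1):
                bs = window_start + b * bin_bp
                be = bs + bin_bp
                ov = min(e2, be) - max(s2, bs)
                if ov > 0:
                    sums[b] += v * ov
                    cov[b] += ov
        with np.errstate(invalid="ignore"):
            prof = np.where(cov > 0, sums / np.maximum(cov, 1e-300), np.nan)
        if g.strand == "-":
            prof = prof[::-1]
        profiles[gi] = prof

    offsets = np.arange(-span_bp, span_bp, bin_bp)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(profiles, axis=0)
    return pd.DataFrame({"offset": offsets, "mean_signal": mean}).set_index("offset")


def integrate_silencing_accumulation(
    rna_logfc: Mapping[str, pd.Series],
    promoter_accum: Mapping[str, pd.DataFrame],
    classification: pd.DataFrame,
    cpg: pd.DataFrame | None = None,
) -> dict:
    """Joint report of silencing bins, mark accumulation and CpG content.

    ``rna_logfc`` maps genotype -> per-gene (corrected) log2 FC;
    ``promoter_accum`` maps genotype -> genes x marks accumulation values;
    ``classification`` is the ΔB+C-derived promoter classification applied
    to the shared gene universe. Produces, per silencing bin, the
    accumulation distributions per genotype with rank tests between
    genotypes; per accumulation category, the logFC distributions with
    paired/unpaired comparisons; and, when ``cpg`` is given, the CpG
    comparison between categories.
    """
    genotypes = sorted(rna_logfc)
    shared = classification.index
    for gt in genotypes:
        shared = shared.intersection(rna_logfc[gt].index)
        if gt in promoter_accum:
            shared = shared.intersection(promoter_accum[gt].index)
    if len(shared) == 0:
        raise ValueError("empty intersection of gene universes")
    shared = list(shared)
    report: dict = {"n_genes": len(shared)}

    # silencing-bin x genotype accumulation distributions (per mark)
    bin_rows = []
    ref_gt = genotypes[0]
    bins = silencing_bins(rna_logfc[ref_gt].loc[shared])
    for label in SILENCING_BIN_LABELS:
        genes_in = [g for g in shared if bins.loc[g] == label]
        row: dict = {"bin": label, "n": len(genes_in)}
        if genes_in and len(promoter_accum) >= 2:
            gts = [g for g in genotypes if g in promoter_accum]
            for mark in promoter_accum[gts[0]].columns:
                vals = {
                    gt: promoter_accum[gt].loc[genes_in, mark].to_numpy() for gt in gts
                }
                for gt in gts:
                    row[f"median_{mark}_{gt}"] = float(np.median(vals[gt]))
                if len(genes_in) >= 2:
                    _, p = rank_sum_compare(
                        vals[gts[0]], vals[gts[1]], paired=True
                    )
                    row[f"p_{mark}"] = p
        bin_rows.append(row)
    report["by_silencing_bin"] = pd.DataFrame(bin_rows).set_index("bin")

    # accumulation-category logFC distributions
    cat_rows = []
    for cat in ("no_or_little", "accumulation"):
        genes_in = [g for g in shared if classification.loc[g, "combined"] == cat]
        row = {"category": cat, "n": len(genes_in)}
        for gt in genotypes:
            if genes_in:
                row[f"median_logfc_{gt}"] = float(
                    np.median(rna_logfc[gt].loc[genes_in])
                )
        if len(genes_in) >= 2 and len(genotypes) >= 2:
            _, p = rank_sum_compare(
                rna_logfc[genotypes[0]].loc[genes_in].to_numpy(),
                rna_logfc[genotypes[1]].loc[genes_in].to_numpy(),
                paired=True,
            )
            row["p_between_genotypes"] = p
        cat_rows.append(row)
    report["by_category"] = pd.DataFrame(cat_rows).set_index("category")

    # unpaired comparison of categories within each genotype
    cats = classification.loc[shared, "combined"]
    within = {}
    for gt in genotypes:
        lo = rna_logfc[gt].loc[[g for g in shared if cats.loc[g] == "no_or_little"]]
        hi = rna_logfc[gt].loc[[g for g in shared if cats.loc[g] == "accumulation"]]
        if len(lo) and len(hi):
            _, p = rank_sum_compare(lo.to_numpy(), hi.to_numpy(), paired=False)
            within[gt] = p
    report["category_vs_logfc_p"] = within

    if cpg is not None:
        lo_genes = [g for g in shared if cats.loc[g] == "no_or_little" and g in cpg.index]
        hi_genes = [g for g in shared if cats.loc[g] == "accumulation" and g in cpg.index]
        if lo_genes and hi_genes:
            lo = cpg.loc[lo_genes, "cg_density"].to_numpy()
            hi = cpg.loc[hi_genes, "cg_density"].to_numpy()
            _, p = rank_sum_compare(hi, lo, paired=False, alternative="greater")
            report["cpg"] = {
                "median_cg_density_no_or_little": float(np.median(lo)),
                "median_cg_density_accumulation": float(np.median(hi)),
                "p_accumulation_greater": p,
            }
    return report
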
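"""Windowed ChIP quantification and autosome-anchored normalization.

The normalization strategy mirrors differential ChIP practice for systems
where the treatment (Xist induction) changes total signal on one chromosome:
between-sample scaling factors are computed by trimmed mean of M-values
(TMM) restricted to consensus peaks on autosomes, where no change is
expected, and the resulting normalized tracks are compared as
DOX − noDOX differences ("accumulation").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval, RegionSet, merge_intervals

__all__ = [
    "SampleInfo",
    "CountMatrix",
    "count_fragments_in_windows",
    "consensus_peaks",
    "tmm_factors",
    "filter_outlier_windows",
    "accumulation_signal",
    "reads_fraction_by_chrom",
    "read_sample_sheet",
    "write_sample_sheet",
]

NORM_SCALE = 1e7  # normalized counts are per 10 million library fragments


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sequencing sample.

    ``induction_fraction`` is the fraction of cells with an Xist cloud by
    RNA FISH, on [0, 1]; it is 0 exactly when condition is noDOX.
    """

    sample_id: str
    clone: str
    condition: str  # noDOX | DOX
    mark: str  # H3K27me3 | H2AK119ub | input | RNA
    induction_fraction: float = 0.0
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.condition not in ("noDOX", "DOX"):
            raise ValueError(f"{self.sample_id}: condition must be noDOX or DOX")
        if not 0.0 <= self.induction_fraction <= 1.0:
            raise ValueError(f"{self.sample_id}: induction_fraction outside [0,1]")
        if (self.condition == "noDOX") != (self.induction_fraction == 0.0):
            raise ValueError(
                f"{self.sample_id}: induction_fraction must be 0 iff condition is noDOX"
            )


class CountMatrix:
    """Integer counts over regions × samples with per-sample library sizes."""

    def __init__(
        self,
        region_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
        library_sizes: Sequence[float] | None = None,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(region_ids), len(sample_ids)):
            raise ValueError("counts shape does not match region/sample ids")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.region_ids = list(region_ids)
        self.sample_ids = list(sample_ids)
        self.counts = counts
        if library_sizes is None:
            library_sizes = counts.sum(axis=0).astype(float)
        self.library_sizes = np.asarray(library_sizes, dtype=float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.region_ids, columns=self.sample_ids)

    def subset_regions(self, region_ids: Sequence[str]) -> "CountMatrix":
        idx = {r: i for i, r in enumerate(self.region_ids)}
        missing = [r for r in region_ids if r not in idx]
        if missing:
            raise KeyError(f"unknown regions: {missing[:5]}")
        rows = [idx[r] for r in region_ids]
        return CountMatrix(
            list(region_ids), self.sample_ids, self.counts[rows, :], self.library_sizes
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(
            self.region_ids, list(sample_ids), self.counts[:, cols], self.library_sizes[cols]
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "region_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, library_sizes: Sequence[float] | None = None
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(), library_sizes)


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "clone", "condition", "mark", "induction_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                clone=str(row["clone"]),
                condition=str(row["condition"]),
                mark=str(row["mark"]),
                induction_fraction=float(row["induction_fraction"]),
                genotype=str(row.get("genotype", "")),
            )
        )
    return out


def write_sample_sheet(path: str | Path, samples: Sequence[SampleInfo]) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "clone": [s.clone for s in samples],
            "condition": [s.condition for s in samples],
            "mark": [s.mark for s in samples],
            "induction_fraction": [s.induction_fraction for s in samples],
            "genotype": [s.genotype for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def count_fragments_in_windows(
    fragments: Mapping[str, Sequence[GenomicInterval]],
    regions: RegionSet,
) -> CountMatrix:
    """Count fragments per region by midpoint assignment.

    A fragment is assigned to the single region containing its midpoint
    (integer division); when regions of the set overlap, the region that is
    first by (start, end, region_id) order wins, deterministically.
    Fragments whose midpoint falls in no region are left uncounted; the
    per-sample library size is the *total* fragment count, counted or not.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(regions.intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    sample_ids = list(fragments)
    counts = np.zeros((len(regions.region_ids), len(sample_ids)), dtype=np.int64)
    lib = np.zeros(len(sample_ids))
    for j, sid in enumerate(sample_ids):
        lib[j] = len(fragments[sid])
        tree = None
        for frag in fragments[sid]:
            tree = trees.get(frag.chrom)
            if tree is None:
                continue
            mid = (frag.start + frag.end) // 2
            hits = tree[mid]
            if not hits:
                continue
            i = min(
                hits, key=lambda h: (h.begin, h.end, regions.region_ids[h.data])
            ).data
            counts[i, j] += 1
    if (lib == 0).any():
        lib[lib == 0] = 1.0  # empty sample: keep matrix constructible
    return CountMatrix(regions.region_ids, sample_ids, counts, lib)


def consensus_peaks(
    peak_sets: Sequence[Sequence[GenomicInterval]],
    min_support: int = 2,
    min_fold_change: float = 3.0,
    fold_changes: Sequence[Sequence[float]] | None = None,
) -> list[GenomicInterval]:
    """Sub-regions covered by at least ``min_support`` of the peak sets.

    Optionally pre-filters each set to peaks with fold change >=
    ``min_fold_change`` (applied only when per-peak fold changes are given).
    The genome is partitioned at all peak boundaries; maximal runs of
    sub-regions with support >= min_support are merged (bookended pieces
    join).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support > len(peak_sets):
        raise ValueError("min_support exceeds number of peak sets")
    sets: list[list[GenomicInterval]] = []
    for i, peaks in enumerate(peak_sets):
        if fold_changes is not None:
            fcs = fold_changes[i]
            if len(fcs) != len(peaks):
                raise ValueError(f"set {i}: fold_changes length mismatch")
            peaks = [p for p, fc in zip(peaks, fcs) if fc >= min_fold_change]
        sets.append(list(peaks))

    chroms = {p.chrom for peaks in sets for p in peaks}
    out: list[GenomicInterval] = []
    for chrom in sorted(chroms):
        events: list[tuple[int, int]] = []  # (pos, +1/-1)
        for peaks in sets:
            # overlapping peaks within one set still count as one set's coverage
            per_set = [p for p in peaks if p.chrom == chrom]
            if not per_set:
                continue
            for p in merge_intervals(per_set):
                events.append((p.start, 1))
                events.append((p.end, -1))
        if not events:
            continue
        events.sort()
        pos = np.array([e[0] for e in events])
        delta = np.array([e[1] for e in events])
        bounds = np.unique(pos)
        cov_at = np.zeros(len(bounds) - 1, dtype=int)
        running = 0
        bi = 0
        for p, d in zip(pos, delta):
            while bi < len(bounds) - 1 and bounds[bi] < p:
                cov_at[bi] = running
                bi += 1
            running += d
        while bi < len(bounds) - 1:
            cov_at[bi] = running
            bi += 1
        keep = cov_at >= min_support
        i = 0
        while i < len(keep):
            if keep[i]:
                j = i
                while j + 1 < len(keep) and keep[j + 1]:
                    j += 1
                out.append(GenomicInterval(chrom, int(bounds[i]), int(bounds[j + 1])))
                i = j + 1
            else:
                i += 1
    return out


def _tmm_ref_index(frac: np.ndarray) -> int:
    """Reference sample: 75th-percentile count fraction closest to the mean."""
    f75 = np.percentile(frac, 75, axis=0)
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factors(
    counts: np.ndarray | CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    library_sizes: Sequence[float] | None = None,
    weighted: bool = True,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    By default library sizes are the column sums of the supplied matrix
    (restricted to the anchoring regions, e.g. autosomal consensus peaks);
    pass the full per-sample ``library_sizes`` to anchor the correction on
    the supplied regions while normalizing whole libraries — required when
    the factors will rescale totals that include regions with real signal
    change (e.g. chrX under induction). For each sample against the
    reference: M = log2 ratio of count fractions, A = mean log2 abundance
    over regions nonzero in both; M is trimmed two-sided by ``trim_m`` and
    A by ``trim_a``; the factor is 2**(weighted mean of the doubly-trimmed
    M) with inverse asymptotic-variance weights.

    With ``weighted=False`` the trimmed M are averaged unweighted; that
    variant is exactly invariant to rescaling a single column (the
    variance weights depend on absolute counts, so the default weighted
    factors are only approximately so).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a regions x samples matrix with >=2 samples")
    if library_sizes is not None:
        n_lib = np.asarray(library_sizes, dtype=float)
        if n_lib.shape != (counts.shape[1],):
            raise ValueError("library_sizes must have one entry per sample")
    else:
        n_lib = counts.sum(axis=0)
    if (n_lib <= 0).any():
        raise ValueError("every sample needs a nonzero total over the supplied regions")
    frac = counts / n_lib
    ref = _tmm_ref_index(frac)

    log_factors = np.zeros(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        y_k, y_r = counts[:, k], counts[:, ref]
        ok = (y_k > 0) & (y_r > 0)
        if not ok.any():
            continue
        fk, fr = frac[ok, k], frac[ok, ref]
        m = np.log2(fk / fr)
        a = 0.5 * np.log2(fk * fr)
        w = 1.0 / (
            (n_lib[k] - y_k[ok]) / (n_lib[k] * y_k[ok])
            + (n_lib[ref] - y_r[ok]) / (n_lib[ref] * y_r[ok])
        )
        n = len(m)
        lo_m, lo_a = int(np.floor(n * trim_m)), int(np.floor(n * trim_a))
        rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
        rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable")
        keep = (
            (rank_m >= lo_m)
            & (rank_m < n - lo_m)
            & (rank_a >= lo_a)
            & (rank_a < n - lo_a)
        )
        if keep.sum() < 2:
            warnings.warn(
                "fewer than 2 regions left after trimming; using untrimmed weighted mean",
                RuntimeWarning,
                stacklevel=2,
            )
            keep = np.ones(n, dtype=bool)
        if weighted:
            log_factors[k] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        else:
            log_factors[k] = np.mean(m[keep])

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def filter_outlier_windows(
    input_counts: CountMatrix,
    k: float = 1.5,
) -> list[str]:
    """Regions whose input counts lie within mean ± k·SD in *every* input sample.

    The mean and sample (n−1) SD are computed per input column over all
    regions; boundary values are retained. This removes accessibility or
    mappability outliers before accumulation analysis.
    """
    if len(input_counts.region_ids) == 0:
        raise ValueError("empty count matrix")
    x = input_counts.counts.astype(float)
    keep = np.ones(x.shape[0], dtype=bool)
    for j in range(x.shape[1]):
        col = x[:, j]
        mu = col.mean()
        sd = col.std(ddof=1) if len(col) > 1 else 0.0
        keep &= (col >= mu - k * sd) & (col <= mu + k * sd)
    return [r for r, ok in zip(input_counts.region_ids, keep) if ok]


def normalized_counts(
    counts: CountMatrix, factors: np.ndarray, scale: float = NORM_SCALE
) -> pd.DataFrame:
    """Counts rescaled to ``scale`` fragments per effective library."""
    factors = np.asarray(factors, dtype=float)
    eff = counts.library_sizes * factors
    return pd.DataFrame(
        counts.counts * (scale / eff),
        index=counts.region_ids,
        columns=counts.sample_ids,
    )


def accumulation_signal(
    counts: CountMatrix,
    factors: np.ndarray,
    samples: Sequence[SampleInfo],
) -> pd.DataFrame:
    """Per-region normalized DOX − noDOX signal, per clone and clone-averaged.

    Returns a DataFrame indexed by region_id with one ``accum_<clone>``
    column per clone and an ``accum_mean`` column.
    """
    by_id = {s.sample_id: s for s in samples}
    missing = [sid for sid in counts.sample_ids if sid not in by_id]
    if missing:
        raise ValueError(f"samples missing metadata: {missing}")
    norm = normalized_counts(counts, factors)
    clones = sorted({by_id[sid].clone for sid in counts.sample_ids})
    out = pd.DataFrame(index=pd.Index(counts.region_ids, name="region_id"))
    for clone in clones:
        dox = [
            sid
            for sid in counts.sample_ids
            if by_id[sid].clone == clone and by_id[sid].condition == "DOX"
        ]
        nodox = [
            sid
            for sid in counts.sample_ids
            if by_id[sid].clone == clone and by_id[sid].condition == "noDOX"
        ]
        if not dox or not nodox:
            raise ValueError(f"clone {clone}: missing DOX or noDOX sample")
        out[f"accum_{clone}"] = norm[dox].mean(axis=1) - norm[nodox].mean(axis=1)
    out["accum_mean"] = out[[f"accum_{c}" for c in clones]].mean(axis=1)
    return out


def reads_fraction_by_chrom(
    counts: CountMatrix,
    chrom_of: Mapping[str, str],
    chrom: str,
) -> pd.Series:
    """Per-sample fraction of counted reads on one chromosome (e.g. chrX)."""
    unknown = [r for r in counts.region_ids if r not in chrom_of]
    if unknown:
        raise ValueError(f"regions with unknown chromosome: {unknown[:5]}")
    on = np.array([chrom_of[r] == chrom for r in counts.region_ids])
    total = counts.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        frac = counts.counts[on, :].sum(axis=0) / total
    return pd.Series(frac, index=counts.sample_ids, name=f"fraction_{chrom}")


def write_bedgraph(
    path: str | Path,
    regions: RegionSet,
    values: Mapping[str, float],
) -> None:
    """4-column bedGraph (0-based half-open) for a per-region signal."""
    with open(path, "w") as fh:
        for rid, iv in regions:
            if rid in values:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{values[rid]:.6g}\n")
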
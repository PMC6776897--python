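"""Genomic interval primitives and plain-text I/O.

All coordinates are 0-based half-open (BED convention); refFlat transcript
coordinates are natively in this convention. The strand-aware transcription
start site (TSS) of a feature on ``+`` is its start, and on ``-`` the last
base before its end (``end - 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "ActiveGeneSpan",
    "RegionSet",
    "read_refflat",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_fasta",
    "read_fasta",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One refFlat transcript row.

    ``tss`` is the strand-aware 5' end: ``tx_start`` on ``+``,
    ``tx_end - 1`` on ``-`` (0-based).
    """

    gene_name: str
    tx_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...] = ()
    exon_ends: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.tx_name}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"transcript {self.tx_name}: tx_start >= tx_end")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def exonic_length(self) -> int:
        return int(sum(e - s for s, e in zip(self.exon_starts, self.exon_ends)))


@dataclass(frozen=True)
class ActiveGeneSpan:
    """Union span of a gene's transcripts with its initial-activity flag.

    For an initially active gene the span covers only transcripts whose TSS
    overlapped an H3K27ac peak; for inactive genes it covers all transcripts.
    """

    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    is_active: bool

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_name}: start >= end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


REGION_CLASSES = ("active_promoter", "active_gene_body", "intergenic", "fixed_window")


@dataclass
class RegionSet:
    """An ordered collection of named regions of one region class."""

    region_class: str
    region_ids: list[str] = field(default_factory=list)
    intervals: list[GenomicInterval] = field(default_factory=list)
    gene_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if len(self.region_ids) != len(self.intervals):
            raise ValueError("region_ids and intervals length mismatch")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")

    def __len__(self) -> int:
        return len(self.region_ids)

    def __iter__(self):
        return iter(zip(self.region_ids, self.intervals))

    def add(self, region_id: str, interval: GenomicInterval, gene_name: str | None = None):
        self.region_ids.append(region_id)
        self.intervals.append(interval)
        if gene_name is not None:
            self.gene_names[region_id] = gene_name

    def chrom_of(self) -> dict[str, str]:
        return {rid: iv.chrom for rid, iv in self}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "region_id": self.region_ids,
                "gene_name": [self.gene_names.get(r, "") for r in self.region_ids],
                "region_class": self.region_class,
            }
        )

    def to_bed(self, path: str | Path) -> None:
        """Write regions as BED with the region_id in the name column."""
        with open(path, "w") as fh:
            for rid, iv in self:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rid}\n")

    @classmethod
    def from_bed(cls, path: str | Path, region_class: str) -> "RegionSet":
        rs = cls(region_class=region_class)
        for iv, name in read_bed(path, with_names=True):
            rs.add(name, iv)
        return rs


def read_refflat(path: str | Path) -> list[TranscriptModel]:
    """Parse a UCSC refFlat (11-column) annotation file.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds. Exon coordinate lists are retained for
    downstream exon-length computation (TPM).
    """
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=11 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                exon_starts = tuple(
                    int(x) for x in fields[9].rstrip(",").split(",") if x
                )
                exon_ends = tuple(
                    int(x) for x in fields[10].rstrip(",").split(",") if x
                )
                tm = TranscriptModel(
                    gene_name=fields[0],
                    tx_name=fields[1],
                    chrom=fields[2],
                    strand=fields[3],
                    tx_start=int(fields[4]),
                    tx_end=int(fields[5]),
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append(tm)
    return out


def read_bed(path: str | Path, with_names: bool = False):
    """Read BED3/BED6 intervals; returns intervals, optionally with names."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if with_names:
                name = fields[3] if len(fields) >= 4 else f"region_{lineno}"
                out.append((iv, name))
            else:
                out.append(iv)
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV (chrom, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(path) as fh:
        return [(name.split()[0], seq.upper()) for name, seq in SimpleFastaParser(fh)]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def position_in_any(
    intervals: Sequence[GenomicInterval],
) -> "callable":
    """Return a fast membership test ``f(chrom, pos) -> bool`` over intervals."""
    merged = merge_intervals(intervals) if intervals else []
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {iv.chrom for iv in merged}:
        ivs = [iv for iv in merged if iv.chrom == chrom]
        starts[chrom] = np.array([iv.start for iv in ivs])
        ends[chrom] = np.array([iv.end for iv in ivs])

    def _test(chrom: str, pos: int) -> bool:
        if chrom not in starts:
            return False
        i = int(np.searchsorted(starts[chrom], pos, side="right")) - 1
        return i >= 0 and pos < ends[chrom][i]

    return _test
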
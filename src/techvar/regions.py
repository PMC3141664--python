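"""Analysis units on the genome: collapsed exonic regions and consensus contigs.

All internal coordinates are 0-based half-open; the GFF3 reader is the only
place 1-based arithmetic occurs.  Overlapping annotated exons on the same
chromosome are collapsed into their maximal genomic union (strand ignored),
so alternative start/end sites of a shared exon become one region.
Bookended intervals (zero shared bases) stay separate.

Consensus contigs are the annotation-free alternative: maximal runs of
positions whose depth is at least ``min_depth`` in *every* lane of an
experiment, i.e. regions the data itself supports in all replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    region_id: str = ""
    source: str = "annotation"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if not self.region_id:
            object.__setattr__(
                self, "region_id", f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def read_annotation(path: str | Path, format: str) -> list[tuple[str, int, int]]:
    """Read exon intervals from a GFF3 or BED file.

    GFF3 coordinates (1-based closed) are converted to the internal 0-based
    half-open convention; BED intervals pass through unchanged.  For GFF3
    only features of type ``exon`` are kept.

    Returns raw ``(chrom, start, end)`` tuples; feed them to
    :func:`collapse_overlapping` to obtain analysis regions.
    """
    if format not in {"gff3", "bed"}:
        raise ValueError(f"unknown annotation format: {format!r}")
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "gff3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    if fields[2].lower() != "exon":
                        continue
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                    end = int(fields[4])
                else:
                    if len(fields) < 3:
                        raise ValueError("expected >= 3 BED columns")
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}, line {lineno}: invalid interval {start}-{end}"
                )
            intervals.append((chrom, start, end))
    return intervals


def collapse_overlapping(
    exons: Iterable[tuple[str, int, int]],
) -> list[GenomicRegion]:
    """Merge overlapping intervals per chromosome into maximal unions.

    Merging requires at least one shared base; bookended intervals remain
    separate.  Output is sorted by (chromosome, start) and non-overlapping.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in exons:
        by_chrom.setdefault(chrom, []).append((start, end))
    regions: list[GenomicRegion] = []
    for chrom in sorted(by_chrom):
        merged: list[list[int]] = []
        for start, end in sorted(by_chrom[chrom]):
            if merged and start < merged[-1][1]:  # overlap needs a shared base
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        regions.extend(
            GenomicRegion(chrom, s, e, source="annotation") for s, e in merged
        )
    return regions


def consensus_contigs(
    tracks: Sequence["CoverageTrack"], min_depth: int = 3
) -> list[GenomicRegion]:
    """Maximal runs of positions with depth >= min_depth in every lane.

    Lanes covering disjoint chromosome sets yield an empty result with a
    warning rather than an error.
    """
    from .quantitation import CoverageTrack  # noqa: F401  (type reference)

    if not tracks:
        raise ValueError("at least one coverage track required")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    chrom_sets = [set(t.chromosomes()) for t in tracks]
    common = set.intersection(*chrom_sets)
    if not common and any(chrom_sets):
        logger.warning(
            "coverage tracks share no chromosomes; no consensus contigs called"
        )
        return []
    regions: list[GenomicRegion] = []
    for chrom in sorted(common):
        length = max(t.chrom_length(chrom) for t in tracks)
        ok = np.ones(length, dtype=bool)
        for t in tracks:
            depths = t.depth_array(chrom, length)
            ok &= depths >= min_depth
        # run-length extraction of True runs
        padded = np.concatenate(([False], ok, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        for i, (s, e) in enumerate(zip(starts, ends), start=1):
            regions.append(
                GenomicRegion(
                    chrom,
                    int(s),
                    int(e),
                    region_id=f"{chrom}_contig{i}",
                    source="consensus",
                )
            )
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as 4-column BED (chrom, start, end, region_id)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")
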
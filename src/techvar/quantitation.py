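"""Per-region detection and expression measures from per-base depth.

The quantitation starts from pileup-style depth tracks, one per lane.  For
each region and lane it computes:

* ``detected`` — at least one position in the region has depth >= 1 (i.e.
  at least one read maps there);
* ``apn`` — average reads per nucleotide: mean depth over *all* positions
  of the region, zeros included;
* ``sd`` / ``cv`` — the sample (n-1) standard deviation of per-base depth
  and the coefficient of variation sd/apn (undefined when apn == 0);
* ``read_count`` — reads reconstructed from depth as round(sum(depth) /
  read_length), exact when reads are fully contained in the region;
* ``rpkm`` — (read_count / region length) * C / mappable reads, with
  C = 1e9 giving the usual reads-per-kilobase-per-million-mapped scale.

Two pileup text dialects are read: the classic 6-column samtools pileup
(chrom, 1-based pos, ref base, depth, read bases, qualities) and a minimal
3-column TSV (chrom, 1-based pos, depth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicRegion

DEFAULT_RPKM_CONSTANT = 1e9


class CoverageTrack:
    """One lane's per-base read depth plus lane metadata.

    Depth is stored densely per chromosome; positions never mentioned have
    depth 0.  Positions are 0-based internally.
    """

    def __init__(
        self,
        lane_id: str,
        mappable_reads: int,
        read_length: int,
        depths: dict[str, np.ndarray] | None = None,
    ):
        if mappable_reads < 0:
            raise ValueError("mappable_reads must be >= 0")
        if read_length < 1:
            raise ValueError("read_length must be >= 1")
        self.lane_id = lane_id
        self.mappable_reads = int(mappable_reads)
        self.read_length = int(read_length)
        self._depths: dict[str, np.ndarray] = {}
        for chrom, arr in (depths or {}).items():
            arr = np.asarray(arr)
            if (arr < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            self._depths[chrom] = arr.astype(np.int32)

    def chromosomes(self) -> list[str]:
        return sorted(self._depths)

    def chrom_length(self, chrom: str) -> int:
        return len(self._depths.get(chrom, ()))

    def depth_array(self, chrom: str, length: int | None = None) -> np.ndarray:
        """Dense depth vector for a chromosome, zero-padded to ``length``."""
        arr = self._depths.get(chrom, np.zeros(0, dtype=np.int32))
        if length is not None and len(arr) < length:
            arr = np.pad(arr, (0, length - len(arr)))
        return arr

    def depth(self, chrom: str, pos: int) -> int:
        arr = self._depths.get(chrom)
        if arr is None or pos < 0 or pos >= len(arr):
            return 0
        return int(arr[pos])

    def region_depths(self, region: GenomicRegion) -> np.ndarray:
        """Per-base depths over a region (absent positions are 0)."""
        arr = self.depth_array(region.chrom, region.end)
        return arr[region.start : region.end]


@dataclass(frozen=True)
class RegionQuant:
    """Detection and expression statistics for one region in one lane."""

    region_id: str
    lane_id: str
    detected: bool
    apn: float
    sd: float
    cv: float  # NaN when undefined (apn == 0)
    read_count: int
    rpkm: float
    length: int = 0


def read_pileup(
    path: str | Path,
    dialect: str = "samtools6",
    lane_id: str | None = None,
    mappable_reads: int | None = None,
    read_length: int | None = None,
) -> CoverageTrack:
    """Parse a pileup text file into a CoverageTrack.

    File positions are 1-based and converted to the internal 0-based
    convention.  ``mappable_reads`` and ``read_length`` must come from
    header comment lines (``#mappable_reads=N`` / ``#read_length=L``) or
    the corresponding arguments — they are never inferred from the depths.
    """
    if dialect not in {"samtools6", "tsv3"}:
        raise ValueError(f"unknown pileup dialect: {dialect!r}")
    depth_col = 3 if dialect == "samtools6" else 2
    min_cols = 4 if dialect == "samtools6" else 3
    per_chrom: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "mappable_reads" and mappable_reads is None:
                    mappable_reads = int(value)
                elif key == "read_length" and read_length is None:
                    read_length = int(value)
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ValueError(
                    f"{path}, line {lineno}: expected >= {min_cols} columns"
                )
            chrom = fields[0]
            try:
                pos = int(fields[1]) - 1
                depth = int(fields[depth_col])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            if depth < 0:
                raise ValueError(f"{path}, line {lineno}: negative depth")
            chrom_map = per_chrom.setdefault(chrom, {})
            if pos in chrom_map:
                raise ValueError(
                    f"{path}, line {lineno}: duplicate position {chrom}:{pos + 1}"
                )
            chrom_map[pos] = depth
    if mappable_reads is None:
        raise ValueError(
            "mappable_reads not given and no '#mappable_reads=' header found"
        )
    if read_length is None:
        raise ValueError(
            "read_length not given and no '#read_length=' header found"
        )
    depths = {}
    for chrom, posmap in per_chrom.items():
        arr = np.zeros(max(posmap) + 1, dtype=np.int32)
        positions = np.fromiter(posmap.keys(), dtype=np.int64, count=len(posmap))
        values = np.fromiter(posmap.values(), dtype=np.int32, count=len(posmap))
        arr[positions] = values
        depths[chrom] = arr
    return CoverageTrack(
        lane_id=lane_id or Path(path).stem,
        mappable_reads=mappable_reads,
        read_length=read_length,
        depths=depths,
    )


def rpkm(
    read_count: float,
    region_length: int,
    mappable_reads: int,
    c_constant: float = DEFAULT_RPKM_CONSTANT,
) -> float:
    """Reads per kilobase of region per million mappable reads.

    (read_count / region_length) * C / mappable_reads; the default
    C = 1e9 (reads x bases) yields the standard RPKM unit.  Invariant under
    joint scaling of read_count and mappable_reads.
    """
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    if mappable_reads < 1:
        raise ValueError("mappable_reads must be >= 1")
    return (read_count / region_length) * c_constant / mappable_reads


def region_stats(
    track: CoverageTrack,
    region: GenomicRegion,
    c_constant: float = DEFAULT_RPKM_CONSTANT,
) -> RegionQuant:
    """Detection and expression statistics for one region in one lane."""
    depths = track.region_depths(region).astype(np.float64)
    n = len(depths)
    apn = float(depths.mean())
    sd = float(depths.std(ddof=1)) if n > 1 else 0.0
    cv = sd / apn if apn > 0 else math.nan
    detected = bool((depths >= 1).any())
    read_count = int(round(depths.sum() / track.read_length))
    value = (
        rpkm(read_count, n, track.mappable_reads, c_constant)
        if track.mappable_reads >= 1
        else math.nan
    )
    return RegionQuant(
        region_id=region.region_id,
        lane_id=track.lane_id,
        detected=detected,
        apn=apn,
        sd=sd,
        cv=cv,
        read_count=read_count,
        rpkm=value,
        length=n,
    )


def quantify_experiment(
    tracks: Sequence[CoverageTrack],
    regions: Sequence[GenomicRegion],
    c_constant: float = DEFAULT_RPKM_CONSTANT,
) -> pd.DataFrame:
    """Complete region x lane grid of RegionQuant rows as a DataFrame.

    Regions with no coverage in a lane appear as detected=False rows; the
    grid is never ragged.
    """
    if not tracks or not regions:
        raise ValueError("need at least one track and one region")
    rows = []
    for track in tracks:
        # per-chromosome prefix sums make region aggregation O(1) per region
        cums: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in {r.chrom for r in regions}:
            length = max(r.end for r in regions if r.chrom == chrom)
            d = track.depth_array(chrom, length).astype(np.float64)
            cums[chrom] = (
                np.concatenate(([0.0], np.cumsum(d))),
                np.concatenate(([0.0], np.cumsum(d * d))),
                np.concatenate(([0], np.cumsum(d >= 1))),
            )
        for region in regions:
            csum, csq, cdet = cums[region.chrom]
            s, e = region.start, region.end
            n = e - s
            total = csum[e] - csum[s]
            sqtotal = csq[e] - csq[s]
            apn = total / n
            var = (sqtotal - n * apn * apn) / (n - 1) if n > 1 else 0.0
            sd = math.sqrt(max(var, 0.0))
            cv = sd / apn if apn > 0 else math.nan
            detected = (cdet[e] - cdet[s]) > 0
            read_count = int(round(total / track.read_length))
            rows.append(
                {
                    "region_id": region.region_id,
                    "lane_id": track.lane_id,
                    "detected": bool(detected),
                    "apn": apn,
                    "sd": sd,
                    "cv": cv,
                    "read_count": read_count,
                    "rpkm": rpkm(read_count, n, track.mappable_reads, c_constant),
                    "length": n,
                }
            )
    return pd.DataFrame(rows)
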
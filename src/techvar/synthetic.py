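"""Synthetic genomes and pileups with the structure the analysis assumes.

Real inputs to the pipeline are per-lane pileups over an annotated genome.
This module manufactures both from a library model: a genome of disjoint
single-exon gene regions, and per-replicate coverage tracks in which each
of a gene's reads starts uniformly within the gene and is fully contained
in it.  Full containment makes the depth-to-read-count round trip exact
(sum of depth == reads * read_length per gene), which the test suite
exploits.  No sequencing error, junctions, or partial overlaps are
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .library_sim import ReplicateCounts
from .quantitation import CoverageTrack
from .regions import GenomicRegion, write_bed


@dataclass(frozen=True)
class SyntheticGenome:
    """Disjoint single-exon gene regions on synthetic chromosomes."""

    chrom_sizes: dict[str, int]
    gene_regions: list[GenomicRegion]
    read_length: int


def generate_genome(
    n_genes: int,
    min_len: int = 100,
    max_len: int = 500,
    read_length: int = 36,
    gap: int = 10,
    seed: int = 0,
    chrom: str = "chrSim",
) -> SyntheticGenome:
    """Tile ``n_genes`` disjoint gene regions along one synthetic chromosome.

    Gene lengths are uniform on [min_len, max_len]; consecutive genes are
    separated by ``gap`` bases so regions never touch.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if min_len < read_length:
        raise ValueError("min_len must be >= read_length")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_len, max_len + 1, size=n_genes)
    starts = np.concatenate(([0], np.cumsum(lengths[:-1] + gap)))
    regions = [
        GenomicRegion(
            chrom, int(s), int(s + l), region_id=f"gene{i + 1:05d}", source="annotation"
        )
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]
    chrom_size = int(starts[-1] + lengths[-1] + gap)
    return SyntheticGenome(
        chrom_sizes={chrom: chrom_size},
        gene_regions=regions,
        read_length=read_length,
    )


def generate_pileups(
    genome: SyntheticGenome,
    replicate_counts: list[ReplicateCounts],
    seed: int = 0,
) -> list[CoverageTrack]:
    """Turn per-gene read tallies into per-lane coverage tracks.

    For each gene, each read's start is uniform on
    [gene start, gene end - read_length]; depth is incremented over
    read_length bases.  ``mappable_reads`` is set to the replicate's total.
    """
    n_genes = len(genome.gene_regions)
    tracks: list[CoverageTrack] = []
    read_len = genome.read_length
    for rep_idx, rep in enumerate(replicate_counts):
        if len(rep.read_counts) != n_genes:
            raise ValueError(
                f"replicate {rep.replicate_id}: {len(rep.read_counts)} genes "
                f"in counts but {n_genes} in genome"
            )
        rng = np.random.default_rng(seed + rep_idx)
        # difference-array trick: +1 at read start, -1 past read end, cumsum
        delta: dict[str, np.ndarray] = {
            chrom: np.zeros(size + 1, dtype=np.int64)
            for chrom, size in genome.chrom_sizes.items()
        }
        for region, count in zip(genome.gene_regions, rep.read_counts):
            if count == 0:
                continue
            if region.length < read_len:
                raise ValueError(
                    f"region {region.region_id} shorter than read length"
                )
            starts = rng.integers(
                region.start, region.end - read_len + 1, size=int(count)
            )
            d = delta[region.chrom]
            np.add.at(d, starts, 1)
            np.add.at(d, starts + read_len, -1)
        depths = {
            chrom: np.cumsum(d[:-1]).astype(np.int32) for chrom, d in delta.items()
        }
        tracks.append(
            CoverageTrack(
                lane_id=rep.replicate_id,
                mappable_reads=int(rep.n_reads),
                read_length=read_len,
                depths=depths,
            )
        )
    return tracks


def write_pileup(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as classic 6-column pileup text (non-zero positions).

    Header comments carry the lane metadata so :func:`read_pileup` can
    round-trip the file without extra arguments.  Reference base and
    base/quality columns are placeholders.
    """
    with open(path, "w") as fh:
        fh.write(f"#mappable_reads={track.mappable_reads}\n")
        fh.write(f"#read_length={track.read_length}\n")
        for chrom in track.chromosomes():
            arr = track.depth_array(chrom)
            nz = np.flatnonzero(arr)
            cols = pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": nz + 1,  # pileup text is 1-based
                    "ref": "N",
                    "depth": arr[nz],
                    "bases": "*",
                    "quals": "*",
                }
            )
            cols.to_csv(fh, sep="\t", header=False, index=False)


def write_truth_table(
    genome: SyntheticGenome,
    molecule_counts: np.ndarray,
    replicate_counts: list[ReplicateCounts],
    path: str | Path,
) -> None:
    """TSV of per-gene molecule counts and planted reads per replicate."""
    data = {
        "gene_id": [r.region_id for r in genome.gene_regions],
        "molecules": molecule_counts,
    }
    for rep in replicate_counts:
        data[f"{rep.replicate_id}_reads"] = rep.read_counts
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_genome_bed(genome: SyntheticGenome, path: str | Path) -> None:
    write_bed(genome.gene_regions, path)
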
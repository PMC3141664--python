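"""End-to-end orchestration: inputs -> regions -> quantitation -> agreement.

The pipeline runs in one of two input modes:

* ``simulate`` — build a library model, draw technical replicates, and
  synthesize pileup-level coverage for them (no external data needed);
* ``pileups`` — read per-lane pileup files plus an exon annotation or call
  consensus contigs from the coverage itself.

Outputs are plain TSVs: a per-lane summary (mappable reads, regions
detected, regions above an APN threshold), one pairwise agreement report
covering all replicate pairs, per-pair contingency tables, Bland-Altman
tables and per-lane CV profiles.  Every output carries the config hash and
seed in a header comment; identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, concordance, library_sim, quantitation, synthetic
from .regions import GenomicRegion, collapse_overlapping, consensus_contigs, read_annotation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # simulate | pileups
    # simulate mode
    n_genes: int = 20_000
    total_molecules: int = library_sim.DEFAULT_TOTAL_MOLECULES
    gamma_shape: float = 2.0
    gamma_scale: float = 1.0
    support_max: int = 17
    n_reads: int = 300_000
    n_replicates: int = 2
    min_gene_len: int = 100
    max_gene_len: int = 500
    read_length: int = 36
    # pileups mode
    pileup_paths: list[str] = field(default_factory=list)
    pileup_dialect: str = "samtools6"
    annotation_path: str = ""
    annotation_format: str = "bed"
    region_source: str = "annotation"  # annotation | consensus
    min_depth: int = 3
    mappable_reads: list[int] = field(default_factory=list)
    # analysis
    binning_scheme: str = "nine"
    kappa_weights: str = "linear"
    log_base: float = float(np.e)
    apn_threshold: float = 5.0
    seed: int = 1
    outdir: str = "techvar_out"

    def config_hash(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat key=value (or key<TAB>value) config file."""
    cfg = PipelineConfig()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = (
                line.partition("=") if "=" in line else line.partition("\t")
            )
            key, value = key.strip(), value.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"{path}, line {lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, list):
                parsed = [type(current[0])(v) if current else v for v in value.split(",")]
                if key == "mappable_reads":
                    parsed = [int(v) for v in value.split(",")]
                setattr(cfg, key, parsed)
            elif isinstance(current, bool):
                setattr(cfg, key, value.lower() in {"1", "true", "yes"})
            else:
                setattr(cfg, key, type(current)(value))
    return cfg


def lane_summary(
    quants: pd.DataFrame,
    tracks: list[quantitation.CoverageTrack],
    apn_threshold: float = 5.0,
) -> pd.DataFrame:
    """Per-lane table: mappable reads, regions detected, regions above APN."""
    rows = []
    for track in tracks:
        q = quants[quants.lane_id == track.lane_id]
        rows.append(
            {
                "lane_id": track.lane_id,
                "mappable_reads": track.mappable_reads,
                "regions_detected": int(q.detected.sum()),
                f"regions_apn_gt_{apn_threshold:g}": int(
                    (q.apn > apn_threshold).sum()
                ),
            }
        )
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def _build_inputs(
    config: PipelineConfig,
) -> tuple[list[quantitation.CoverageTrack], list[GenomicRegion]]:
    if config.mode == "simulate":
        library = library_sim.build_library(
            n_genes=config.n_genes,
            total_molecules=config.total_molecules,
            gamma_shape=config.gamma_shape,
            gamma_scale=config.gamma_scale,
            support_max=config.support_max,
            seed=config.seed,
        )
        reps = library_sim.simulate_experiment(
            library, config.n_replicates, config.n_reads, base_seed=config.seed + 1
        )
        genome = synthetic.generate_genome(
            config.n_genes,
            min_len=config.min_gene_len,
            max_len=config.max_gene_len,
            read_length=config.read_length,
            seed=config.seed,
        )
        tracks = synthetic.generate_pileups(genome, reps, seed=config.seed + 1000)
        regions = genome.gene_regions
    elif config.mode == "pileups":
        if not config.pileup_paths:
            raise ValueError("pileups mode requires pileup_paths")
        tracks = []
        for i, p in enumerate(config.pileup_paths):
            mr = config.mappable_reads[i] if i < len(config.mappable_reads) else None
            tracks.append(
                quantitation.read_pileup(
                    p,
                    dialect=config.pileup_dialect,
                    mappable_reads=mr,
                    read_length=config.read_length if mr is not None else None,
                )
            )
        if config.region_source == "annotation":
            if not config.annotation_path:
                raise ValueError("annotation region source requires annotation_path")
            exons = read_annotation(config.annotation_path, config.annotation_format)
            regions = collapse_overlapping(exons)
        elif config.region_source == "consensus":
            regions = consensus_contigs(tracks, min_depth=config.min_depth)
        else:
            raise ValueError(f"unknown region_source: {config.region_source!r}")
    else:
        raise ValueError(f"unknown mode: {config.mode!r}")
    if not tracks:
        raise ValueError("no replicates configured")
    return tracks, regions


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; writes TSVs under config.outdir.

    Returns a dict with the in-memory results: ``lane_summary``,
    ``comparisons`` (list of ComparisonReport), ``quants``, and per-pair
    ``contingency`` tables, ``bland_altman`` results and ``cv_profiles``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# techvar config_hash={config.config_hash()} seed={config.seed}\n"

    tracks, regions = _build_inputs(config)
    logger.info("quantifying %d regions x %d lanes", len(regions), len(tracks))
    quants = quantitation.quantify_experiment(tracks, regions)

    summary = lane_summary(quants, tracks, config.apn_threshold)
    _write_tsv(summary, outdir / "lane_summary.tsv", header)

    lanes = [t.lane_id for t in tracks]
    if len(lanes) < 2:
        logger.warning("single replicate: lane summary only")
        return {
            "lane_summary": summary,
            "quants": quants,
            "comparisons": [],
            "contingency": {},
            "bland_altman": {},
            "cv_profiles": {},
        }

    comparisons = []
    contingencies = {}
    ba_results = {}
    for lane_a, lane_b in itertools.combinations(lanes, 2):
        report = agreement.compare_replicates(
            quants, lane_a, lane_b, log_base=config.log_base
        )
        comparisons.append(report)
        qa = quants[quants.lane_id == lane_a].set_index("region_id").sort_index()
        qb = quants[quants.lane_id == lane_b].set_index("region_id").sort_index()
        k = 9 if config.binning_scheme == "nine" else 3
        table = agreement.contingency_table(
            agreement.bin_rpkm_series(qa.rpkm, qa.detected, config.binning_scheme),
            agreement.bin_rpkm_series(qb.rpkm, qb.detected, config.binning_scheme),
            k,
        )
        contingencies[(lane_a, lane_b)] = table
        tdf = pd.DataFrame(table.counts, columns=list(table.labels))
        tdf.insert(0, "category", list(table.labels))
        _write_tsv(tdf, outdir / f"contingency_{lane_a}_vs_{lane_b}.tsv", header)
        ba = concordance.bland_altman(
            qa.rpkm.to_numpy(), qb.rpkm.to_numpy(), scale="natural_log"
        )
        ba_results[(lane_a, lane_b)] = ba
        _write_tsv(ba.pairs, outdir / f"bland_altman_{lane_a}_vs_{lane_b}.tsv", header)

    report_df = pd.DataFrame(
        [
            {
                "replicate_a": r.pair[0],
                "replicate_b": r.pair[1],
                "n_common": r.n_common,
                "n_only_one": r.n_only_one,
                "kappa_detection": r.kappa_detection,
                "kappa_3level": r.kappa_3level,
                "kappa_3level_weighted": r.kappa_3level_weighted,
                "kappa_9level_weighted": r.kappa_9level_weighted,
                "n_disagree_ge1log": r.n_disagree_ge1log,
                "n_disagree_gt2log": r.n_disagree_gt2log,
            }
            for r in comparisons
        ]
    )
    _write_tsv(report_df, outdir / "comparison_report.tsv", header)

    cv_profiles = {}
    for track in tracks:
        prof = concordance.cv_profile(quants[quants.lane_id == track.lane_id])
        cv_profiles[track.lane_id] = prof
        _write_tsv(prof, outdir / f"cv_profile_{track.lane_id}.tsv", header)

    return {
        "lane_summary": summary,
        "quants": quants,
        "comparisons": comparisons,
        "contingency": contingencies,
        "bland_altman": ba_results,
        "cv_profiles": cv_profiles,
    }
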
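"""End-to-end orchestration: discover FASTQ inputs, extract and group UMIs,
clean, correct, merge, and write corrected FASTQ plus a summary table.

Each output record is one deduplicated molecule. Its identifier encodes the
cluster's representative UMI and pooled read count (``umi=<UMI>;reads=<n>``)
so downstream tools keep the provenance, while ``summary_table.csv`` maps
every output sequence back to the barcodes it came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from . import fastq_io
from .fastq_io import ReadPair, ReadRecord, corrected_name
from .grouping import RunConfig, clean_groups, extract_umi, group_by_umi
from .merging import MergeCluster, correct_groups, merge_umi_groups

logger = logging.getLogger(__name__)

_FASTQ_EXTS = (".fastq", ".fq", ".fastq.gz", ".fq.gz")
SUMMARY_NAME = "summary_table.csv"


@dataclass
class RunSummaryRow:
    """One row of summary_table.csv — one output (consensus) sequence."""

    input_file_root: str
    representative_umi: str
    absorbed_umis: str  # semicolon-joined, empty if none
    n_umis_merged: int
    pooled_count: int
    consensus_r1: str
    mean_quality_r1: float
    consensus_r2: str = ""
    mean_quality_r2: float | str = ""


@dataclass
class RunStats:
    """Per-sample stage counts, logged at INFO."""

    input_file_root: str = ""
    input_reads: int = 0
    reads_after_cleaning: int = 0
    umis_start: int = 0
    umis_after_cleaning: int = 0
    umis_after_merging: int = 0


@dataclass
class RunResult:
    output_files: list[Path] = field(default_factory=list)
    summary_path: Path | None = None
    stats: list[RunStats] = field(default_factory=list)
    clusters: dict[str, list[MergeCluster]] = field(default_factory=dict)


def _is_fastq(path: Path) -> bool:
    return path.name.lower().endswith(_FASTQ_EXTS)


def discover_inputs(config: RunConfig) -> list[tuple[Path, Path | None]]:
    """Find input FASTQ files; pair R1 with R2 by the file-name token."""
    files = sorted(p for p in config.input_dir.iterdir() if _is_fastq(p))
    if not files:
        raise FileNotFoundError(f"no FASTQ files in {config.input_dir}")
    if not config.pairedData:
        return [(p, None) for p in files]
    pairs = []
    for p in files:
        if "R1" not in p.name:
            continue
        mate = p.with_name(p.name.replace("R1", "R2", 1))
        if not mate.exists():
            raise FileNotFoundError(f"R1 file {p.name} has no matching R2 file")
        pairs.append((p, mate))
    if not pairs:
        raise FileNotFoundError(
            f"pairedData=True but no file in {config.input_dir} carries an 'R1' token"
        )
    return pairs


def _mean_quality(qualities: tuple[int, ...]) -> float:
    return round(sum(qualities) / len(qualities), 2)


def _validated_extract(
    reads: Iterator[ReadRecord | ReadPair], config: RunConfig
) -> Iterator[tuple[str, ReadRecord | ReadPair]]:
    n = config.sequenceLength
    for read in reads:
        key, insert = extract_umi(read, config)
        if isinstance(insert, ReadPair):
            lengths = (len(insert.r1), len(insert.r2))
        else:
            lengths = (len(insert),)
        if any(length != n for length in lengths):
            raise ValueError(
                f"insert length {lengths} != sequenceLength {n} "
                f"(read {getattr(read, 'r1', read).read_id!r})"
            )
        yield key, insert


def process_sample(
    r1_path: Path, r2_path: Path | None, config: RunConfig
) -> tuple[list[MergeCluster], RunStats]:
    """Run extract -> group -> clean -> correct -> merge for one sample."""
    root = r1_path.name
    for ext in _FASTQ_EXTS:
        if root.lower().endswith(ext):
            root = root[: -len(ext)]
            break
    stats = RunStats(input_file_root=root)

    if r2_path is None:
        reads: Iterator[ReadRecord | ReadPair] = fastq_io.read_fastq(r1_path)
    else:
        reads = fastq_io.read_fastq_paired(r1_path, r2_path)

    groups = group_by_umi(_validated_extract(reads, config))
    stats.input_reads = sum(g.count for g in groups)
    stats.umis_start = len(groups)

    cleaned = clean_groups(groups, config.countsCutoff)
    stats.reads_after_cleaning = sum(g.count for g in cleaned)
    stats.umis_after_cleaning = len(cleaned)

    clusters = merge_umi_groups(correct_groups(cleaned), config)
    stats.umis_after_merging = len(clusters)

    logger.info(
        "%s: %d reads / %d UMIs -> cleaning (cutoff %d): %d reads / %d UMIs "
        "-> merging: %d molecules",
        root,
        stats.input_reads,
        stats.umis_start,
        config.countsCutoff,
        stats.reads_after_cleaning,
        stats.umis_after_cleaning,
        stats.umis_after_merging,
    )
    for cl in clusters:
        logger.debug(
            "cluster %s: +%d merged UMIs, %d reads",
            cl.representative_umi,
            len(cl.absorbed_umis),
            cl.pooled_count,
        )
    return clusters, stats


def write_summary(rows: list[RunSummaryRow], path: str | Path) -> int:
    """Write the per-output-sequence summary CSV; returns the row count."""
    columns = [
        "input_file_root",
        "representative_umi",
        "absorbed_umis",
        "n_umis_merged",
        "pooled_count",
        "consensus_r1",
        "mean_quality_r1",
        "consensus_r2",
        "mean_quality_r2",
    ]
    frame = pd.DataFrame([vars(r) for r in rows], columns=columns)
    frame.to_csv(path, index=False, encoding="utf-8")
    return len(rows)


def run(config: RunConfig) -> RunResult:
    """Execute the full workflow over every sample in ``config.input_dir``."""
    inputs = discover_inputs(config)  # validates before any processing
    config.output_dir.mkdir(parents=True, exist_ok=True)

    result = RunResult()
    summary_rows: list[RunSummaryRow] = []
    for r1_path, r2_path in inputs:
        clusters, stats = process_sample(r1_path, r2_path, config)
        result.stats.append(stats)
        result.clusters[stats.input_file_root] = clusters

        r1_records, r2_records = [], []
        for cl in clusters:
            read_id = f"umi={cl.representative_umi};reads={cl.pooled_count}"
            r1_records.append(cl.final_r1.to_record(read_id))
            if cl.final_r2 is not None:
                r2_records.append(cl.final_r2.to_record(read_id))
            summary_rows.append(
                RunSummaryRow(
                    input_file_root=stats.input_file_root,
                    representative_umi=cl.representative_umi,
                    absorbed_umis=";".join(cl.absorbed_umis),
                    n_umis_merged=1 + len(cl.absorbed_umis),
                    pooled_count=cl.pooled_count,
                    consensus_r1=cl.final_r1.sequence,
                    mean_quality_r1=_mean_quality(cl.final_r1.qualities),
                    consensus_r2=cl.final_r2.sequence if cl.final_r2 else "",
                    mean_quality_r2=(
                        _mean_quality(cl.final_r2.qualities) if cl.final_r2 else ""
                    ),
                )
            )

        out_r1 = config.output_dir / corrected_name(r1_path)
        fastq_io.write_fastq(r1_records, out_r1)
        result.output_files.append(out_r1)
        if r2_path is not None:
            out_r2 = config.output_dir / corrected_name(r2_path)
            fastq_io.write_fastq(r2_records, out_r2)
            result.output_files.append(out_r2)

    summary_path = config.output_dir / SUMMARY_NAME
    write_summary(summary_rows, summary_path)
    result.summary_path = summary_path
    return result
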
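"""Evaluation statistics: reads kept, phred quality, per-base coverage.

Coverage is computed exactly from the simulator's ground-truth origin
intervals instead of by remapping filtered reads with an aligner — the
one deliberate substitution in the evaluation pipeline; the statistic
itself (per-base coverage with P10 / mean / P90 / max summaries) is
unchanged. P10 is reported because for assembly the question is whether
*poorly* covered loci survive normalization, which the mean hides.

Percentiles use the nearest-rank convention (the smallest value whose
cumulative rank reaches p% of positions) and are taken over *all*
genome positions, zeros included — dropping uncovered positions would
make P10 blind to starved loci, which is exactly what it must detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ReadRecord, read_fastq

__all__ = [
    "CoverageReport",
    "QualityReport",
    "nearest_rank_percentile",
    "coverage_from_truth",
    "quality_report",
    "compare_runs",
]


def nearest_rank_percentile(values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: sorted value at rank ``ceil(p/100 * N)``."""
    if len(values) == 0:
        raise ValueError("percentile of empty array")
    if not 0 < p <= 100:
        raise ValueError("p must lie in (0, 100]")
    rank = max(1, math.ceil(p / 100.0 * len(values)))
    return float(np.sort(values, kind="stable")[rank - 1])


@dataclass(frozen=True)
class CoverageReport:
    """Per-base coverage of one read set plus its percentile summary."""

    per_base: np.ndarray
    p10: float
    mean: float
    p90: float
    max: float

    @classmethod
    def from_per_base(cls, per_base: np.ndarray) -> "CoverageReport":
        return cls(
            per_base=per_base,
            p10=nearest_rank_percentile(per_base, 10),
            mean=float(per_base.mean()),
            p90=nearest_rank_percentile(per_base, 90),
            max=float(per_base.max()),
        )

    @property
    def median(self) -> float:
        return nearest_rank_percentile(self.per_base, 50)


def coverage_from_truth(
    accepted_ids: Iterable[str],
    truth: dict[str, tuple[str, int, int, str]],
    genome_length: int,
) -> CoverageReport:
    """Exact per-base coverage of the accepted reads' origin intervals.

    ``truth`` maps read_id -> (ref_id, start, end, strand) as loaded by
    :func:`bignorm.io.read_truth`. Raises ``KeyError`` for an accepted
    id missing from the truth set.
    """
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    for rid in accepted_ids:
        if rid not in truth:
            raise KeyError(f"accepted read {rid!r} not present in the truth set")
        _, start, end, _ = truth[rid]
        diff[start] += 1
        diff[end] -= 1
    return CoverageReport.from_per_base(np.cumsum(diff[:-1]))


@dataclass(frozen=True)
class QualityReport:
    """Grand-mean phred plus the per-position mean curve."""

    mean_phred: float | None
    per_position_mean: np.ndarray
    n_reads: int


def quality_report(source) -> QualityReport:
    """Quality summary of a FASTQ file (or iterable of records).

    The grand mean runs over every base of every read; the per-position
    curve averages, at each position, the reads long enough to reach it.
    An empty input yields ``mean_phred = None``.
    """
    records = (
        read_fastq(source) if isinstance(source, (str, Path)) else source
    )
    total = 0
    n_bases = 0
    n_reads = 0
    pos_sum = np.zeros(0, dtype=np.int64)
    pos_n = np.zeros(0, dtype=np.int64)
    for rec in records:
        q = np.asarray(rec.phreds, dtype=np.int64)
        if len(q) > len(pos_sum):
            pos_sum = np.concatenate([pos_sum, np.zeros(len(q) - len(pos_sum), np.int64)])
            pos_n = np.concatenate([pos_n, np.zeros(len(q) - len(pos_n), np.int64)])
        pos_sum[: len(q)] += q
        pos_n[: len(q)] += 1
        total += int(q.sum())
        n_bases += len(q)
        n_reads += 1
    mean = total / n_bases if n_bases else None
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(pos_n > 0, pos_sum / np.maximum(pos_n, 1), np.nan)
    return QualityReport(mean_phred=mean, per_position_mean=curve, n_reads=n_reads)


def _run_row(
    dataset: str,
    algorithm: str,
    fastq: str | Path,
    truth: dict[str, tuple[str, int, int, str]],
    genome_length: int,
    n_raw_reads: int,
) -> dict:
    ids = []
    total_phred = 0
    n_bases = 0
    for rec in read_fastq(fastq):
        ids.append(rec.id)
        total_phred += int(np.asarray(rec.phreds, dtype=np.int64).sum())
        n_bases += len(rec)
    cov = coverage_from_truth(ids, truth, genome_length)
    return {
        "dataset": dataset,
        "algorithm": algorithm,
        "reads": len(ids),
        "percent_kept": 100.0 * len(ids) / n_raw_reads if n_raw_reads else 0.0,
        "mean_phred": total_phred / n_bases if n_bases else float("nan"),
        "cov_p10": cov.p10,
        "cov_mean": cov.mean,
        "cov_p90": cov.p90,
        "cov_max": cov.max,
    }


def compare_runs(
    raw_fastq: str | Path,
    truth: dict[str, tuple[str, int, int, str]],
    genome_length: int,
    filtered: Sequence[tuple[str, str | Path]],
    dataset: str = "synthetic",
) -> pd.DataFrame:
    """One row per (dataset, algorithm): kept %, mean phred, coverage summary.

    ``filtered`` lists ``(algorithm_name, fastq_path)`` pairs; the raw
    input appears as algorithm ``"raw"`` with percent_kept 100.
    """
    n_raw = sum(1 for _ in read_fastq(raw_fastq))
    rows = [_run_row(dataset, "raw", raw_fastq, truth, genome_length, n_raw)]
    for name, path in filtered:
        rows.append(_run_row(dataset, name, path, truth, genome_length, n_raw))
    return pd.DataFrame(rows)
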
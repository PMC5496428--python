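"""The accept/reject engine for digital normalization.

Two decision rules share one streaming loop:

* **bignorm** (quality-gated count-vector rule). For each read, the
  k-mer windows that are N-free *and* whose bases all reach the phred
  threshold Q0 are queried against the counter; the read is accepted
  iff at least ``n_min`` of those high-quality k-mers are still *novel*,
  i.e. have an estimated count below the abundance target A. Reads with
  no assessable (high-quality) k-mer are rejected outright, which is
  what makes the filter quality-aware.

* **diginorm** (median rule, for comparison). Every N is first coerced
  to A — faithfully reproducing the behavior this rule is criticized
  for — and the read is accepted iff the median of the counts of *all*
  its k-mers is strictly below A. Quality never enters the decision.
  The median of an even number of counts is the lower median (the
  ⌈n/2⌉-th order statistic), so it is always an attained count.

Only accepted reads feed the counter: in bignorm mode all N-free
windows are inserted (optionally only the high-quality ones), in
diginorm mode all windows of the N→A-substituted sequence. A single
pass over the stream therefore both decides and counts, keeping the
memory bound of the sketch.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import IO, Iterable

import numpy as np

from .io import ReadRecord
from .kmer import scan_read
from .sketch import CmsConfig, CountMinSketch, ExactCounter

__all__ = [
    "FilterParams",
    "CountVector",
    "Reason",
    "Decision",
    "RunStats",
    "build_count_vector",
    "bignorm_decide",
    "diginorm_decide",
    "decide_read",
    "admit",
    "filter_stream",
]


@dataclass(frozen=True)
class FilterParams:
    """Tunables of the filter.

    k
        k-mer length (default 20).
    q0
        Phred threshold gating which k-mers count as evidence
        (default 20, the recommended operating point).
    abundance
        Target count A: a k-mer seen >= A times is redundant
        (default 20, the usual normalization threshold).
    n_min
        Minimum number of novel high-quality k-mers required to accept
        a read in bignorm mode (heuristic default 3).
    mode
        ``"bignorm"`` or ``"diginorm"``.
    paired_policy
        ``"independent"`` (each mate judged alone) or
        ``"either-mate-rescues"`` (pair kept in full if either mate is
        accepted, and both mates are then counted).
    insert_hq_only
        If True, only high-quality windows of accepted reads are
        inserted (bignorm mode); default inserts every N-free window.
    """

    k: int = 20
    q0: int = 20
    abundance: int = 20
    n_min: int = 3
    mode: str = "bignorm"
    paired_policy: str = "independent"
    insert_hq_only: bool = False

    def __post_init__(self) -> None:
        if self.k < 1 or self.q0 < 0 or self.abundance < 1 or self.n_min < 1:
            raise ValueError("require k >= 1, q0 >= 0, abundance >= 1, n_min >= 1")
        if self.mode not in ("bignorm", "diginorm"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.paired_policy not in ("independent", "either-mate-rescues"):
            raise ValueError(f"unknown paired policy {self.paired_policy!r}")


@dataclass(frozen=True)
class CountVector:
    """Per-read decision evidence in bignorm mode.

    ``counts`` holds the counter estimates of the high-quality windows
    in read order; ``n_novel`` is how many of them fall below the
    abundance target.
    """

    counts: np.ndarray
    n_windows: int
    n_valid: int
    n_high_quality: int
    n_novel: int


class Reason(str, enum.Enum):
    """Why a read was accepted or rejected."""

    NOVEL_ENOUGH = "NOVEL_ENOUGH"
    TOO_ABUNDANT = "TOO_ABUNDANT"
    NO_ASSESSABLE_KMERS = "NO_ASSESSABLE_KMERS"
    TOO_SHORT = "TOO_SHORT"
    MEDIAN_BELOW = "MEDIAN_BELOW"
    MEDIAN_AT_OR_ABOVE = "MEDIAN_AT_OR_ABOVE"
    MATE_RESCUED = "MATE_RESCUED"


@dataclass(frozen=True)
class Decision:
    accept: bool
    reason: Reason
    n_windows: int = 0
    n_valid: int = 0
    n_high_quality: int = 0
    #: n_novel in bignorm mode, the median count in diginorm mode
    evidence: int = 0


@dataclass
class RunStats:
    """Aggregate statistics of one filtering pass."""

    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0
    phred_sum_in: int = 0
    phred_sum_out: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def percent_kept(self) -> float:
        return 100.0 * self.reads_out / self.reads_in if self.reads_in else 0.0

    @property
    def mean_phred_in(self) -> float | None:
        return self.phred_sum_in / self.bases_in if self.bases_in else None

    @property
    def mean_phred_out(self) -> float | None:
        return self.phred_sum_out / self.bases_out if self.bases_out else None

    def _tally(self, read: ReadRecord, decision: Decision) -> None:
        self.reads_in += 1
        self.bases_in += len(read)
        self.phred_sum_in += int(read.phreds.sum())
        self.reasons[decision.reason.value] = (
            self.reasons.get(decision.reason.value, 0) + 1
        )
        if decision.accept:
            self.reads_out += 1
            self.bases_out += len(read)
            self.phred_sum_out += int(read.phreds.sum())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["percent_kept"] = self.percent_kept
        d["mean_phred_in"] = self.mean_phred_in
        d["mean_phred_out"] = self.mean_phred_out
        return d

    def to_json(self, fh: IO[str]) -> None:
        json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


_N_TO_A = {i: "A" for i in range(128)}
for _c in "ACGT":
    _N_TO_A[ord(_c)] = _c


def _substitute_n(bases: str) -> str:
    """Coerce every non-ACGT symbol to A (the diginorm behavior)."""
    return bases.upper().translate(_N_TO_A)


def build_count_vector(read: ReadRecord, counter, params: FilterParams) -> CountVector:
    """Scan a read and query its high-quality k-mers against the counter."""
    codes, mask = scan_read(read.bases, read.phreds, params.k, params.q0)
    hq_codes = codes[mask.high_quality]
    counts = counter.query_many(hq_codes)
    return CountVector(
        counts=counts,
        n_windows=mask.n_windows,
        n_valid=mask.n_valid,
        n_high_quality=mask.n_high_quality,
        n_novel=int((counts < params.abundance).sum()),
    )


def bignorm_decide(cv: CountVector, params: FilterParams) -> Decision:
    """Accept iff >= n_min high-quality k-mers have count < A."""
    if cv.n_windows == 0:
        return Decision(False, Reason.TOO_SHORT)
    if cv.n_high_quality == 0:
        return Decision(
            False, Reason.NO_ASSESSABLE_KMERS, cv.n_windows, cv.n_valid, 0, 0
        )
    accept = cv.n_novel >= params.n_min
    return Decision(
        accept,
        Reason.NOVEL_ENOUGH if accept else Reason.TOO_ABUNDANT,
        cv.n_windows,
        cv.n_valid,
        cv.n_high_quality,
        cv.n_novel,
    )


def _lower_median(counts: np.ndarray) -> int:
    """⌈n/2⌉-th order statistic from below — always an attained value."""
    i = (len(counts) - 1) // 2
    return int(np.partition(counts, i)[i])


def _diginorm_codes(bases: str, k: int) -> np.ndarray:
    seq = _substitute_n(bases)
    codes, mask = scan_read(seq, np.zeros(len(seq), dtype=np.int16), k, 0)
    return codes  # all windows valid after N→A


def diginorm_decide(bases: str, counter, k: int, abundance: int) -> Decision:
    """Median rule on the N→A-substituted read; quality plays no role."""
    codes = _diginorm_codes(bases, k)
    n = len(codes)
    if n == 0:
        return Decision(False, Reason.TOO_SHORT)
    med = _lower_median(counter.query_many(codes))
    accept = med < abundance
    return Decision(
        accept,
        Reason.MEDIAN_BELOW if accept else Reason.MEDIAN_AT_OR_ABOVE,
        n,
        n,
        n,
        med,
    )


def decide_read(read: ReadRecord, counter, params: FilterParams) -> Decision:
    """Dispatch on mode; never mutates the counter."""
    if params.mode == "diginorm":
        return diginorm_decide(read.bases, counter, params.k, params.abundance)
    return bignorm_decide(build_count_vector(read, counter, params), params)


def admit(read: ReadRecord, counter, params: FilterParams) -> None:
    """Insert an accepted read's countable k-mers into the counter.

    bignorm mode: every N-free window (or only high-quality windows if
    ``insert_hq_only``); diginorm mode: all windows of the N→A
    substituted sequence. Rejected reads must never reach here.
    """
    if params.mode == "diginorm":
        counter.update(_diginorm_codes(read.bases, params.k))
        return
    codes, mask = scan_read(read.bases, read.phreds, params.k, params.q0)
    keep = mask.high_quality if params.insert_hq_only else mask.valid
    counter.update(codes[keep])


def make_counter(params_or_config=None, **kwargs) -> CountMinSketch:
    """Convenience constructor for a sketch-backed counter."""
    if isinstance(params_or_config, CmsConfig):
        return CountMinSketch(params_or_config)
    return CountMinSketch(CmsConfig(**kwargs))


def filter_stream(
    reads: Iterable[ReadRecord] | Iterable[tuple[ReadRecord, ReadRecord]],
    params: FilterParams,
    counter=None,
    output: IO[str] | None = None,
    decision_log: IO[str] | None = None,
    paired: bool = False,
) -> RunStats:
    """Single-pass filter: scan → decide → (admit + emit) per read.

    Parameters
    ----------
    reads
        Iterable of records, or of mate pairs when ``paired``.
    counter
        A :class:`~bignorm.sketch.CountMinSketch`,
        :class:`~bignorm.sketch.ExactCounter`, or anything with
        ``query_many``/``update``; a fresh test-scale sketch by default.
    output
        Text sink receiving accepted reads as FASTQ; pass None to
        discard.
    decision_log
        Optional TSV sink: read_id, mode, accept, reason, n_windows,
        n_valid, n_high_quality, n_novel_or_median.

    Returns
    -------
    stats
        :class:`RunStats` for the pass.
    """
    if counter is None:
        counter = CountMinSketch(CmsConfig())
    stats = RunStats()
    if decision_log is not None:
        decision_log.write(
            "read_id\tmode\taccept\treason\tn_windows\tn_valid"
            "\tn_high_quality\tn_novel_or_median\n"
        )

    def _log(read: ReadRecord, d: Decision) -> None:
        if decision_log is not None:
            decision_log.write(
                f"{read.id}\t{params.mode}\t{int(d.accept)}\t{d.reason.value}"
                f"\t{d.n_windows}\t{d.n_valid}\t{d.n_high_quality}\t{d.evidence}\n"
            )

    def _emit(read: ReadRecord) -> None:
        if output is not None:
            output.write(f"@{read.id}\n{read.bases}\n+\n{read.quality_string}\n")

    if not paired or params.paired_policy == "independent":
        flat = (
            (r for pair in reads for r in pair) if paired else reads
        )
        for read in flat:
            d = decide_read(read, counter, params)
            if d.accept:
                admit(read, counter, params)
                _emit(read)
            stats._tally(read, d)
            _log(read, d)
        return stats

    # either-mate-rescues: keep the pair if at least one mate passes,
    # and count both mates' k-mers when the pair is kept.
    for r1, r2 in reads:
        d1 = decide_read(r1, counter, params)
        d2 = decide_read(r2, counter, params)
        keep = d1.accept or d2.accept
        if keep:
            if not d1.accept:
                d1 = Decision(True, Reason.MATE_RESCUED, d1.n_windows,
                              d1.n_valid, d1.n_high_quality, d1.evidence)
            if not d2.accept:
                d2 = Decision(True, Reason.MATE_RESCUED, d2.n_windows,
                              d2.n_valid, d2.n_high_quality, d2.evidence)
            admit(r1, counter, params)
            admit(r2, counter, params)
            _emit(r1)
            _emit(r2)
        stats._tally(r1, d1)
        stats._tally(r2, d2)
        _log(r1, d1)
        _log(r2, d2)
    return stats
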
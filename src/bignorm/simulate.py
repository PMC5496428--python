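"""Synthetic single-cell-like sequencing datasets with ground truth.

Single-cell libraries prepared by multiple displacement amplification
(MDA) show wildly uneven coverage: some loci are amplified thousands of
times while others are barely touched, so the maximum per-base coverage
sits orders of magnitude above the mean. The generator reproduces that
regime with the simplest mechanism that produces it — a block-wise
lognormal amplification field: the genome is tiled into ~1 kb blocks,
each block gets weight ``exp(N(0, sigma^2))``, and read start positions
are drawn proportional to the weight of their block. ``sigma = 0``
recovers uniform (whole-genome-shotgun-like) sampling.

Base qualities decline linearly along the read from ``q_start`` to
``q_end`` (plus Gaussian jitter, clamped to [2, 41], the Illumina 1.8+
range), mimicking the within-read phred decay of real Illumina data.
Substitution errors are drawn per base with the phred-defined
probability ``10**(-q/10)``, so low-quality tails are genuinely
error-rich; a small fraction of bases is additionally masked to N.
Indels and chimeras are not modeled — k-mer-count filtering only needs
the substitution-driven erroneous-k-mer regime.

Every read records its true origin interval (before errors) so coverage
can later be computed exactly from truth instead of by remapping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ReadRecord

__all__ = ["SimConfig", "TruthSet", "make_genome", "assign_qualities", "sample_reads"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PHRED_MIN, _PHRED_MAX = 2, 41
_BLOCK = 1000  # bp per amplification block


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a small MDA-amplified bacterial single-cell
    library: 100 bp reads at 200x mean coverage of a 100 kb genome,
    strong coverage skew (sigma=2), qualities declining from 38 to 20
    along the read with jitter sd 3, and 1 N call per 1000 bases.
    """

    genome_length: int = 100_000
    gc: float = 0.5
    n_reads: int = 200_000
    read_length: int = 100
    coverage_skew_sigma: float = 2.0
    q_start: int = 38
    q_end: int = 20
    jitter_sd: float = 3.0
    n_rate: float = 0.001
    seed: int = 42
    reference_id: str = "synthetic_genome"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")
        if self.coverage_skew_sigma < 0:
            raise ValueError("coverage_skew_sigma must be >= 0")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        if not (_PHRED_MIN <= self.q_start <= _PHRED_MAX
                and _PHRED_MIN <= self.q_end <= _PHRED_MAX):
            raise ValueError(f"q_start/q_end must lie in [{_PHRED_MIN}, {_PHRED_MAX}]")

    @property
    def mean_coverage(self) -> float:
        return self.n_reads * self.read_length / self.genome_length


@dataclass(frozen=True)
class TruthSet:
    """Per-read origin intervals plus the error-free genome."""

    reference_id: str
    genome: str
    read_ids: list[str]
    starts: np.ndarray  # 0-based inclusive
    ends: np.ndarray  # exclusive
    strands: np.ndarray  # '+' or '-'

    def rows(self):
        """Iterate (ref_id, start, end, read_id, strand) TSV rows."""
        for rid, s, e, st in zip(self.read_ids, self.starts, self.ends, self.strands):
            yield self.reference_id, int(s), int(e), rid, str(st)


def make_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random genome with P(G) + P(C) = gc; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def assign_qualities(
    read_length: int,
    q_start: int,
    q_end: int,
    jitter_sd: float,
    seed_or_rng,
    n_reads: int = 1,
) -> np.ndarray:
    """Phred matrix (n_reads, read_length): linear q_start→q_end + jitter.

    Position 0 has mean ``q_start``, the last position mean ``q_end``;
    values are rounded to integers and clamped to [2, 41].
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if read_length == 1:
        line = np.array([float(q_start)])
    else:
        line = np.linspace(q_start, q_end, read_length)
    q = np.broadcast_to(line, (n_reads, read_length)).copy()
    if jitter_sd > 0:
        q += rng.normal(0.0, jitter_sd, size=q.shape)
    return np.clip(np.rint(q), _PHRED_MIN, _PHRED_MAX).astype(np.int16)


def _block_position_weights(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-start-position sampling probabilities from block amplification."""
    n_starts = config.genome_length - config.read_length + 1
    if config.coverage_skew_sigma == 0:
        return np.full(n_starts, 1.0 / n_starts)
    n_blocks = -(-config.genome_length // _BLOCK)
    w_block = np.exp(rng.normal(0.0, config.coverage_skew_sigma, size=n_blocks))
    w = w_block[np.arange(n_starts) // _BLOCK]
    return w / w.sum()


def sample_reads(
    genome: str, config: SimConfig
) -> tuple[list[ReadRecord], TruthSet]:
    """Draw reads from a genome under the configured MDA-like model.

    Returns the reads (errors and N-masking applied) and the matching
    :class:`TruthSet` of pre-error origin intervals. Deterministic for a
    given ``config.seed``.
    """
    if config.read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(config.seed)
    L, rl, n = len(genome), config.read_length, config.n_reads

    p = _block_position_weights(replace(config, genome_length=L), rng)
    starts = rng.choice(len(p), size=n, p=p)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    g = np.frombuffer(genome.upper().encode("ascii"), dtype=np.uint8)
    mat = g[starts[:, None] + np.arange(rl)[None, :]]

    # orient minus-strand reads: reverse complement of the genome slice
    comp = np.zeros(256, dtype=np.uint8)
    comp[_BASES] = _BASES[::-1]
    minus = strands == "-"
    mat[minus] = comp[mat[minus][:, ::-1]]

    quals = assign_qualities(rl, config.q_start, config.q_end, config.jitter_sd, rng, n)

    # substitution errors with phred-defined probability 10^(-q/10)
    p_err = 10.0 ** (-quals / 10.0)
    err = rng.random((n, rl)) < p_err
    # substitute with one of the three other bases, uniformly
    code = np.searchsorted(_BASES, mat)  # ACGT are sorted ASCII
    shifted = (code + rng.integers(1, 4, size=(n, rl))) % 4
    mat = np.where(err, _BASES[shifted], mat)

    if config.n_rate > 0:
        nmask = rng.random((n, rl)) < config.n_rate
        mat[nmask] = ord("N")
        quals[nmask] = _PHRED_MIN  # no-call bases carry the floor quality

    width = max(7, len(str(n)))
    read_ids = [f"sim_{i:0{width}d}" for i in range(n)]
    reads = [
        ReadRecord(
            id=read_ids[i],
            bases=mat[i].tobytes().decode("ascii"),
            phreds=quals[i],
            truth=(config.reference_id, int(starts[i]), int(starts[i] + rl),
                   str(strands[i])),
        )
        for i in range(n)
    ]
    truth = TruthSet(
        reference_id=config.reference_id,
        genome=genome,
        read_ids=read_ids,
        starts=starts.astype(np.int64),
        ends=(starts + rl).astype(np.int64),
        strands=strands,
    )
    return reads, truth
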
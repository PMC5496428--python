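"""Approximate k-mer counting with a count-min sketch (CMS).

The sketch is ``t`` tables of ``w`` saturating 8-bit counters; each table
has its own seeded 64-bit avalanche hash. An insert increments one
counter per table (capped at 255); a query returns the minimum across
tables, which can overestimate but never undercounts — the classic
one-sided CMS guarantee.

Sizing follows the convention that ``m`` is the per-table size in MiB of
1-byte counters, so ``w = m * 2**20`` and the total footprint is
``m * t`` MiB. The production configuration ``m=1024, t=10`` therefore
occupies 10 GiB; the test-scale default here is ``m=4, t=4``.

:class:`ExactCounter` is an exact associative counter with the same
interface, used as the collision-free reference backend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CmsConfig", "CountMinSketch", "ExactCounter", "hash_row", "mix64"]

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)


def mix64(x) -> np.ndarray:
    """Splitmix64 finalizer: full-avalanche bijective mix of 64-bit words.

    Accepts a scalar or array; always computes on uint64 arrays (wrapping
    multiplication is the intended modular arithmetic).
    """
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=np.uint64))
    x = (x ^ (x >> np.uint64(30))) * _M1
    x = (x ^ (x >> np.uint64(27))) * _M2
    x = x ^ (x >> np.uint64(31))
    return x[0] if scalar else x


def _row_keys(seed: int, t: int) -> np.ndarray:
    """Derive t independent 64-bit row keys from the base seed."""
    s = np.uint64(seed & 0xFFFFFFFFFFFFFFFF)
    return mix64(s + _GOLDEN * (np.arange(1, t + 1, dtype=np.uint64)))


def hash_row(code: int, row: int, seed: int, width: int) -> int:
    """Table index of ``code`` in row ``row``: mix(code ^ row_key) mod width.

    Deterministic across runs and platforms for a given seed.
    """
    key = _row_keys(seed, row + 1)[row]
    return int(mix64(np.uint64(code) ^ key) % np.uint64(width))


@dataclass(frozen=True)
class CmsConfig:
    """Sketch dimensions: ``mib_per_table`` (m) MiB per table, ``n_tables`` (t)."""

    mib_per_table: int = 4
    n_tables: int = 4
    seed: int = 42

    def __post_init__(self) -> None:
        if self.mib_per_table < 1 or self.n_tables < 1:
            raise ValueError("CMS dimensions must be >= 1")

    @property
    def width(self) -> int:
        """Counters per table: m * 2**20 one-byte counters."""
        return self.mib_per_table << 20

    @property
    def total_bytes(self) -> int:
        return self.width * self.n_tables


class CountMinSketch:
    """t x w matrix of saturating 8-bit counters with seeded row hashes."""

    #: counters saturate here; far above any abundance threshold in use
    CAP = 255

    def __init__(self, config: CmsConfig | None = None, **kwargs) -> None:
        self.config = config or CmsConfig(**kwargs)
        self._w = np.uint64(self.config.width)
        self._keys = _row_keys(self.config.seed, self.config.n_tables)
        self.tables = np.zeros(
            (self.config.n_tables, self.config.width), dtype=np.uint8
        )
        self.n_inserts = 0

    def _indices(self, codes: np.ndarray) -> np.ndarray:
        """(t, n) table indices for an array of codes."""
        codes = np.asarray(codes, dtype=np.uint64)
        return mix64(codes[None, :] ^ self._keys[:, None]) % self._w

    def add(self, code: int) -> int:
        """Insert one code; returns its estimated count after the insert."""
        return int(self.add_many(np.asarray([code], dtype=np.uint64))[0])

    def update(self, codes: np.ndarray) -> None:
        """Insert many codes (duplicates allowed) without querying back."""
        codes = np.asarray(codes, dtype=np.uint64)
        if codes.size == 0:
            return
        idx = self._indices(codes)
        for r in range(idx.shape[0]):
            u, c = np.unique(idx[r], return_counts=True)
            row = self.tables[r]
            row[u] = np.minimum(row[u].astype(np.int64) + c, self.CAP)
        self.n_inserts += codes.size

    def add_many(self, codes: np.ndarray) -> np.ndarray:
        """Insert many codes (duplicates allowed); returns their new estimates."""
        codes = np.asarray(codes, dtype=np.uint64)
        if codes.size == 0:
            return np.empty(0, dtype=np.int64)
        self.update(codes)
        return self.query_many(codes)

    def query(self, code: int) -> int:
        """Estimated count: min over rows. Never undercounts (up to 255)."""
        return int(self.query_many(np.asarray([code], dtype=np.uint64))[0])

    def query_many(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=np.uint64)
        if codes.size == 0:
            return np.empty(0, dtype=np.int64)
        idx = self._indices(codes)
        rows = np.arange(idx.shape[0])[:, None]
        return self.tables[rows, idx].min(axis=0).astype(np.int64)


class ExactCounter:
    """Exact dictionary-backed counter with the sketch interface.

    Unbounded counts, no collisions; the reference backend against which
    sketch-backed filtering runs are compared.
    """

    def __init__(self) -> None:
        self._counts: dict[int, int] = {}
        self.n_inserts = 0

    def add(self, code: int) -> int:
        c = self._counts.get(int(code), 0) + 1
        self._counts[int(code)] = c
        self.n_inserts += 1
        return c

    def update(self, codes: np.ndarray) -> None:
        counts = self._counts
        for code in np.asarray(codes, dtype=np.uint64):
            code = int(code)
            counts[code] = counts.get(code, 0) + 1
        self.n_inserts += len(codes)

    def add_many(self, codes: np.ndarray) -> np.ndarray:
        self.update(codes)
        return self.query_many(codes)

    def query(self, code: int) -> int:
        return self._counts.get(int(code), 0)

    def query_many(self, codes: np.ndarray) -> np.ndarray:
        g = self._counts.get
        return np.fromiter(
            (g(int(c), 0) for c in np.asarray(codes, dtype=np.uint64)),
            dtype=np.int64,
            count=len(codes),
        )

    def __len__(self) -> int:
        return len(self._counts)
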
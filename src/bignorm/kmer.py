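"""Canonical 2-bit k-mer encoding and per-read window scanning.

A k-mer is packed into an unsigned integer, two bits per base
(A=0, C=1, G=2, T=3), most-significant bits first. Counting is done on
*canonical* codes: the numeric minimum of the forward code and the code
of the reverse complement, so that counts are strand-independent.

Windows (k-mer start positions) of a read are classified as

* ``valid``        — no undetermined base (``N`` or any other non-ACGT
  symbol) inside the window; only valid windows carry a code and are
  ever counted,
* ``high_quality`` — valid *and* every base in the window has phred
  score >= the quality threshold Q0; only high-quality windows count as
  evidence when deciding whether a read is novel.

Windows are indexed 0-based; window ``i`` covers bases ``[i, i+k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "INVALID",
    "encode_base",
    "encode_kmer",
    "decode_kmer",
    "revcomp_code",
    "canonical",
    "WindowMask",
    "scan_read",
]

#: Sentinel 2-bit code for any non-ACGT symbol.
INVALID = 4

# 256-entry lookup: ASCII byte -> 2-bit code or INVALID. Lower case accepted.
_BASE_LUT = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


def encode_base(symbol: str) -> int:
    """Encode a single IUPAC character to its 2-bit code.

    Returns ``INVALID`` (4) for ``N`` and every other ambiguity code;
    total function, never raises on valid single characters.
    """
    return int(_BASE_LUT[ord(symbol)])


def encode_kmer(kmer: str) -> int:
    """Pack an N-free k-mer string into its forward 2-bit code."""
    code = 0
    for ch in kmer:
        b = _BASE_LUT[ord(ch)]
        if b == INVALID:
            raise ValueError(f"cannot encode ambiguous base {ch!r}")
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Reverse-complement a packed 2-bit k-mer code."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical(code: int, k: int) -> int:
    """Canonical form: ``min(code, revcomp(code))``. Idempotent."""
    return min(code, revcomp_code(code, k))


@dataclass(frozen=True)
class WindowMask:
    """Validity / quality classification of every k-mer window of a read."""

    n_windows: int
    valid: np.ndarray  # bool, shape (n_windows,)
    high_quality: np.ndarray  # bool, shape (n_windows,); implies valid

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def n_high_quality(self) -> int:
        return int(self.high_quality.sum())


_EMPTY_CODES = np.empty(0, dtype=np.uint64)
_EMPTY_BOOL = np.empty(0, dtype=bool)


def _sliding_all(flags: np.ndarray, k: int) -> np.ndarray:
    """Windows of length k in which every flag is True, via cumulative sums."""
    cs = np.concatenate(([0], np.cumsum(flags, dtype=np.int64)))
    return (cs[k:] - cs[:-k]) == k


def scan_read(
    bases: str,
    phreds: np.ndarray,
    k: int,
    q0: int,
) -> tuple[np.ndarray, WindowMask]:
    """Compute canonical codes and the window mask for one read.

    Parameters
    ----------
    bases
        Read sequence; lower case accepted, any non-ACGT symbol is
        treated as N.
    phreds
        Integer phred scores, one per base.
    k
        k-mer length.
    q0
        Phred threshold: a window is high-quality only if every one of
        its bases scores >= ``q0``.

    Returns
    -------
    codes, mask
        ``codes`` is a uint64 array of length ``mask.n_windows`` holding
        the canonical code per window; entries at windows with
        ``mask.valid == False`` are meaningless (set to 0) and must be
        ignored. Reads shorter than k yield zero windows.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31] (codes are packed into 64 bits)")
    if len(bases) != len(phreds):
        raise ValueError(
            f"malformed record: {len(bases)} bases but {len(phreds)} quality values"
        )
    n = len(bases)
    if n < k:
        return _EMPTY_CODES, WindowMask(0, _EMPTY_BOOL, _EMPTY_BOOL)

    b2 = _BASE_LUT[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    ok = b2 != INVALID
    valid = _sliding_all(ok, k)
    hq = valid & _sliding_all(np.asarray(phreds) >= q0, k)

    # forward and reverse-complement codes for every window, vectorized:
    # windows x k matrix of 2-bit codes dotted with the base-4 place values.
    fb = np.where(ok, b2, 0).astype(np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(fb, k)
    pw = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = win @ pw
    rc = (np.uint64(3) - win) @ pw[::-1]
    codes = np.minimum(fwd, rc)
    codes[~valid] = 0
    return codes, WindowMask(len(codes), valid, hq)
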
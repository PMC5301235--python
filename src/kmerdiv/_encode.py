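"""Bit-packed k-mer encoding.

A k-mer (k <= 31) is packed into a uint64 with two bits per base
(A=0, C=1, G=2, T=3), first base in the highest-order position. Any
non-ACGT character encodes to the sentinel 4 and invalidates every
window that covers it. The canonical form of a k-mer is the
lexicographic minimum of the k-mer and its reverse complement, which
under this encoding is simply the numeric minimum of the two codes.
"""

from __future__ import annotations

import numpy as np

SENTINEL = 4

_BASE_CODE = np.full(256, SENTINEL, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_CODE_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str | bytes) -> np.ndarray:
    """Map a DNA string to a uint8 array of 2-bit codes (4 = invalid)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _BASE_CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_seq` (sentinel decodes to N)."""
    return _CODE_BASE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT upper case only)."""
    return decode_seq(3 - encode_seq(seq)[::-1])


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward codes and validity mask for every length-k window.

    Returns ``(fwd, valid)`` where ``fwd[i]`` packs ``codes[i:i+k]`` and
    ``valid[i]`` is False whenever the window contains a non-ACGT base.
    Packing doubles segment widths (1, 2, 4, ... bases) and composes k
    from its binary decomposition, so the work is O(n log k) array ops.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    segs = {1: codes.astype(np.uint64) & np.uint64(3)}
    w = 1
    while w * 2 <= k:
        a = segs[w]
        segs[w * 2] = (a[:-w] << np.uint64(2 * w)) | a[w:]
        w *= 2
    fwd = None
    offset, remaining = 0, k
    for w in sorted(segs, reverse=True):
        if w > remaining:
            continue
        part = segs[w][offset : offset + n]
        fwd = part if fwd is None else (fwd << np.uint64(2 * w)) | part
        offset += w
        remaining -= w
    bad = (codes >= SENTINEL).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return fwd, valid


# per-byte reversal of the four 2-bit fields, for fast reverse complement
_REV2 = np.array(
    [((b & 3) << 6) | (((b >> 2) & 3) << 4) | (((b >> 4) & 3) << 2)
     | ((b >> 6) & 3) for b in range(256)], dtype=np.uint8)


def revcomp_codes(fwd: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed codes without unpacking to bases.

    Complementing is a bitwise NOT (A<->T, C<->G are two-bit
    complements); reversing the 2-bit fields is a byte reversal plus a
    per-byte field-reversal table; the result is right-aligned by
    shifting out the unused high bits.
    """
    x = np.ascontiguousarray(~np.asarray(fwd, dtype=np.uint64))
    b = _REV2[x.view(np.uint8).reshape(-1, 8)[:, ::-1]]
    rc = np.ascontiguousarray(b).view(np.uint64).reshape(x.shape)
    return rc >> np.uint64(64 - 2 * k)


def canonical_codes(fwd: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(fwd, revcomp_codes(fwd, k))


def encode_kmer(kmer: str) -> int:
    """Pack a single k-mer string (must be pure ACGT) into an int code."""
    codes = encode_seq(kmer)
    if codes.size == 0 or (codes >= SENTINEL).any():
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    fwd, _ = window_codes(codes, codes.size)
    return int(fwd[0])


def canonical_kmer(kmer: str) -> str:
    """Canonical (lexicographically smaller strand) form of a k-mer."""
    rc = revcomp(kmer.upper())
    up = kmer.upper()
    return min(up, rc)


def decode_kmers(codes: np.ndarray, k: int) -> list[str]:
    """Unpack an array of uint64 k-mer codes to strings."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.empty((codes.size, k), dtype=np.uint8)
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        out[:, j] = ((codes >> shift) & np.uint64(3)).astype(np.uint8)
    flat = _CODE_BASE[out].tobytes().decode("ascii")
    return [flat[i * k : (i + 1) * k] for i in range(codes.size)]
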
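"""Canonical k-mer counting, abundance spectra, and spectrum-derived statistics.

The central objects are :class:`KmerCountTable`, a per-sample map from
canonical k-mer to count backed by sorted packed-integer arrays, and
:class:`KmerSpectrum`, the histogram of k-mer abundances. From the
spectrum we estimate sequencing depth of single-copy sequence (the main
peak), genome size (total k-mer instances above the error trough divided
by the peak depth), and the single-copy abundance band used to select
single-copy k-mers for cross-genotype sharing summaries and
depth normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from ._encode import (
    SENTINEL,
    canonical_codes,
    decode_kmers,
    encode_kmer,
    encode_seq,
    window_codes,
)

__all__ = [
    "KmerCountTable",
    "KmerSpectrum",
    "count_kmers",
    "spectrum",
    "merge_tables",
    "find_peak_and_trough",
    "estimate_genome_size",
    "single_copy_band",
    "select_single_copy",
    "sharing_summary",
    "cumulative_contribution",
]


@dataclass
class KmerCountTable:
    """Canonical k-mer -> count map for one sequencing library.

    Counts are stored as a pair of parallel arrays (``codes`` sorted
    ascending, ``counts``) so that set operations across tables are
    vectorized merges rather than dict walks.
    """

    k: int
    codes: np.ndarray  # uint64, sorted ascending, unique
    counts: np.ndarray  # int64, aligned with codes
    library_bases: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must be aligned")

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def n_distinct(self) -> int:
        return len(self)

    @property
    def total_instances(self) -> int:
        """Total counted k-mer instances (library size in k-mer space)."""
        return int(self.counts.sum())

    def get(self, kmer: str | int, default: int = 0) -> int:
        code = encode_kmer(kmer) if isinstance(kmer, str) else int(kmer)
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        return default

    def __contains__(self, kmer: str | int) -> bool:
        return self.get(kmer, 0) > 0

    def get_many(self, codes: np.ndarray, default: int = 0) -> np.ndarray:
        """Counts for an array of packed codes (vectorized lookup)."""
        codes = np.asarray(codes, dtype=np.uint64)
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.clip(idx, 0, max(self.codes.size - 1, 0))
        out = np.full(codes.size, default, dtype=np.int64)
        if self.codes.size:
            hit = self.codes[idx_c] == codes
            out[hit] = self.counts[idx_c[hit]]
        return out

    def kmers(self) -> list[str]:
        return decode_kmers(self.codes, self.k)

    def items(self) -> Iterator[tuple[str, int]]:
        for s, c in zip(self.kmers(), self.counts):
            yield s, int(c)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    @classmethod
    def from_dict(
        cls,
        d: Mapping[str, int],
        k: int | None = None,
        library_bases: int = 0,
        sample_id: str = "",
    ) -> "KmerCountTable":
        if not d:
            return cls(k or 0, np.empty(0, np.uint64), np.empty(0, np.int64),
                       library_bases, sample_id)
        keys = list(d)
        k = k or len(keys[0])
        codes = np.array([encode_kmer(s) for s in keys], dtype=np.uint64)
        counts = np.array([d[s] for s in keys], dtype=np.int64)
        order = np.argsort(codes)
        return cls(k, codes[order], counts[order], library_bases, sample_id)


@dataclass
class KmerSpectrum:
    """Histogram of k-mer abundances: abundance -> number of distinct k-mers."""

    histogram: dict[int, int]
    k: int = 25
    sample_id: str = ""
    peak_depth: int | None = None
    trough_depth: int | None = None
    genome_size_estimate: int | None = None
    single_copy_band: tuple[int, int] | None = field(default=None)

    @property
    def n_distinct(self) -> int:
        return sum(self.histogram.values())

    @property
    def total_instances(self) -> int:
        return sum(a * n for a, n in self.histogram.items())

    def dense(self) -> np.ndarray:
        """Histogram as a dense array indexed by abundance (index 0 unused)."""
        amax = max(self.histogram)
        h = np.zeros(amax + 1, dtype=np.int64)
        for a, n in self.histogram.items():
            h[a] = n
        return h


def _reads_to_code_array(reads: Iterable[str]) -> tuple[np.ndarray, int]:
    """Concatenate reads into one code array, sentinel-separated."""
    if isinstance(reads, str):
        raise TypeError("reads must be an iterable of sequences, not a string")
    joined = "N".join(r for r in reads)
    codes = encode_seq(joined)
    bases = int((codes < SENTINEL).sum())
    return codes, bases


def count_kmers(
    reads,
    k: int = 25,
    min_count_filter: int = 1,
    sample_id: str = "",
) -> KmerCountTable:
    """Count canonical k-mers over every clean length-k window of a read set.

    ``reads`` may be an iterable of sequence strings or any object with a
    ``sequences`` attribute (e.g. a simulated :class:`~kmerdiv.simulate.ReadSet`).
    Windows containing a non-ACGT character are skipped. Entries with
    count below ``min_count_filter`` are dropped; with shotgun reads this
    removes most error-derived k-mers (the stand-in for upstream read
    error correction).
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    if hasattr(reads, "sequences"):
        reads = reads.sequences
    reads = list(reads)
    if not reads:
        raise ValueError("reads must be non-empty")
    codes, bases = _reads_to_code_array(reads)
    fwd, valid = window_codes(codes, k)
    if not valid.any():
        warnings.warn(f"no read contains a clean window of length k={k}")
        return KmerCountTable(k, np.empty(0, np.uint64), np.empty(0, np.int64),
                              bases, sample_id)
    canon = canonical_codes(fwd[valid], k)
    uniq, cnt = np.unique(canon, return_counts=True)
    if min_count_filter > 1:
        keep = cnt >= min_count_filter
        uniq, cnt = uniq[keep], cnt[keep]
    return KmerCountTable(k, uniq, cnt.astype(np.int64), bases, sample_id)


def spectrum(table: KmerCountTable) -> KmerSpectrum:
    """Abundance histogram of a count table."""
    if len(table) == 0:
        raise ValueError("empty count table has no spectrum")
    abund, n = np.unique(table.counts, return_counts=True)
    return KmerSpectrum({int(a): int(c) for a, c in zip(abund, n)},
                        k=table.k, sample_id=table.sample_id)


def merge_tables(tables: Sequence[KmerCountTable]) -> KmerCountTable:
    """Sum counts over tables (union of keys); all tables must share k."""
    if not tables:
        raise ValueError("no tables to merge")
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ValueError(f"cannot merge tables with mixed k: {sorted(ks)}")
    codes = np.concatenate([t.codes for t in tables])
    counts = np.concatenate([t.counts for t in tables])
    uniq, inv = np.unique(codes, return_inverse=True)
    summed = np.zeros(uniq.size, dtype=np.int64)
    np.add.at(summed, inv, counts)
    return KmerCountTable(
        tables[0].k, uniq, summed,
        library_bases=sum(t.library_bases for t in tables),
        sample_id="+".join(t.sample_id for t in tables if t.sample_id),
    )


def _smooth3(h: np.ndarray) -> np.ndarray:
    """3-bin moving average with shrinking window at the edges."""
    kernel = np.ones(3)
    num = np.convolve(h, kernel, mode="same")
    den = np.convolve(np.ones_like(h, dtype=float), kernel, mode="same")
    return num / den


def find_peak_and_trough(
    spec: KmerSpectrum, search_min: int = 1
) -> tuple[int, int]:
    """Locate the error trough and the single-copy peak of a spectrum.

    The histogram is smoothed with a 3-bin moving average; the trough is
    the abundance minimizing the smoothed histogram between 1 and the
    first local maximum at or above ``search_min``, and the peak is the
    smoothed argmax above the trough. Returns ``(trough, peak)``.
    """
    h = spec.dense().astype(float)[1:]  # abundances 1..amax; no zero bin
    s1 = _smooth3(h)  # s1[a-1] = smoothed histogram at abundance a
    amax = h.size
    s = np.concatenate(([np.nan], s1))  # 1-based indexing
    first_max = None
    # a boundary at abundance 1 is the error tail, not a peak: require a
    # strict rise from the left
    for a in range(max(search_min, 2), amax + 1):
        right = s[a + 1] if a + 1 <= amax else -np.inf
        if s[a] > s[a - 1] and s[a] >= right:
            first_max = a
            break
    if first_max is None:
        raise ValueError("no peak: smoothed histogram has no local maximum")
    trough = int(np.argmin(s[1 : first_max + 1]) + 1)
    peak = int(np.argmax(s[trough + 1 :]) + trough + 1) if trough < amax else trough
    spec.trough_depth, spec.peak_depth = trough, peak
    return trough, peak


def estimate_genome_size(spec: KmerSpectrum) -> int:
    """Spectrum-based genome size: instances above the error trough / peak depth."""
    if spec.peak_depth is None or spec.trough_depth is None:
        find_peak_and_trough(spec)
    total = sum(a * n for a, n in spec.histogram.items() if a >= spec.trough_depth)
    size = int(round(total / spec.peak_depth))
    spec.genome_size_estimate = size
    return size


def single_copy_band(
    spec: KmerSpectrum,
    lo_frac: float = 0.55,
    hi_frac: float = 1.35,
    override: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Abundance interval treated as single-copy, inclusive on both ends.

    By default the band brackets the spectrum peak at
    ``[round(lo_frac * peak), round(hi_frac * peak)]``; an explicit
    ``override`` such as ``(20, 50)`` reproduces fixed published bounds.
    """
    if override is not None:
        lo, hi = int(override[0]), int(override[1])
    else:
        if spec.peak_depth is None:
            find_peak_and_trough(spec)
        lo = int(round(lo_frac * spec.peak_depth))
        hi = int(round(hi_frac * spec.peak_depth))
    if lo >= hi:
        raise ValueError(f"degenerate single-copy band [{lo}, {hi}]")
    spec.single_copy_band = (lo, hi)
    return lo, hi


def select_single_copy(
    table: KmerCountTable, band: tuple[int, int]
) -> np.ndarray:
    """Packed codes of k-mers whose count lies in the band (inclusive)."""
    lo, hi = band
    mask = (table.counts >= lo) & (table.counts <= hi)
    return table.codes[mask]


def sharing_summary(
    table_a: KmerCountTable,
    table_b: KmerCountTable,
    band_a: tuple[int, int],
    band_b: tuple[int, int],
    mode: str = "presence",
) -> dict[str, float]:
    """Sharing of single-copy k-mers between two genotypes.

    In the default ``presence`` mode a single-copy k-mer of one genotype
    counts as shared when it occurs at any count in the other genotype's
    table; in ``band`` mode it must be single-copy in both.
    """
    if table_a.k != table_b.k:
        raise ValueError("tables have different k")
    sc_a = select_single_copy(table_a, band_a)
    sc_b = select_single_copy(table_b, band_b)
    other_a = table_b.codes if mode == "presence" else sc_b
    other_b = table_a.codes if mode == "presence" else sc_a
    shared_a = int(np.isin(sc_a, other_a, assume_unique=False).sum())
    shared_b = int(np.isin(sc_b, other_b, assume_unique=False).sum())
    out = {
        "n_single_copy_A": int(sc_a.size),
        "n_single_copy_B": int(sc_b.size),
        "shared_A": shared_a,
        "shared_B": shared_b,
        "specific_A": int(sc_a.size) - shared_a,
        "specific_B": int(sc_b.size) - shared_b,
    }
    out["pct_shared_A"] = 100.0 * shared_a / sc_a.size if sc_a.size else float("nan")
    out["pct_shared_B"] = 100.0 * shared_b / sc_b.size if sc_b.size else float("nan")
    return out


def cumulative_contribution(spec: KmerSpectrum) -> np.ndarray:
    """Curve (abundance, cumulative fraction of k-mer instances <= abundance).

    The fraction at the maximum abundance is exactly 1; the curve is the
    cumulative share of the genome contributed by k-mers up to each
    abundance, so high-copy repeat families appear as late jumps.
    """
    if not spec.histogram:
        raise ValueError("empty spectrum")
    abund = np.array(sorted(spec.histogram), dtype=np.int64)
    mass = np.array([a * spec.histogram[int(a)] for a in abund], dtype=float)
    frac = np.cumsum(mass) / mass.sum()
    return np.column_stack([abund.astype(float), frac])
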
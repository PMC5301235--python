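"""Allele-specific rRNA expression from paired polymorphic k-mers.

A single-nucleotide variant inside a conserved repeat (e.g. the 26S
rRNA gene of the 45S rDNA unit) yields pairs of k-mers identical except
at the variant base. Counting both members of such a pair in RNA-seq
libraries measures allelic expression without alignment: the per-sample
log2 ratio of the two members tracks allelic balance, and pooled
maternal:paternal count ratios across a kernel/endosperm time course
reveal parental dosage effects (2:1 in triploid endosperm) and
nucleolar dominance (maternal-only expression at 0 days after
pollination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._encode import canonical_kmer, revcomp
from .kmers import KmerCountTable

__all__ = [
    "KmerPair",
    "find_snv_pairs",
    "pair_counts",
    "log2_ratio",
    "parental_ratio_timecourse",
]


@dataclass
class KmerPair:
    """Two canonical k-mers whose aligned forms differ at exactly one base.

    ``allele_a_kmer`` is the member enriched in genotype A relative to
    genotype B (and vice versa); per-sample counts are attached by
    :func:`pair_counts`.
    """

    allele_a_kmer: str
    allele_b_kmer: str
    locus: str = ""
    counts: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a, b = self.allele_a_kmer, self.allele_b_kmer
        if len(a) != len(b):
            raise ValueError("pair members must share one length")
        if _aligned_hamming(a, b) != 1:
            raise ValueError("pair members must differ at exactly one base "
                             "in some orientation")


def _aligned_hamming(a: str, b: str) -> int:
    """Minimum Hamming distance over the two relative orientations."""
    d_fwd = sum(x != y for x, y in zip(a, b))
    d_rc = sum(x != y for x, y in zip(a, revcomp(b)))
    return min(d_fwd, d_rc)


def _hamming1_neighbors(kmer: str) -> list[str]:
    """Canonical forms of all single-base substitutions of a k-mer."""
    out = set()
    for i, base in enumerate(kmer):
        for alt in "ACGT":
            if alt != base:
                out.add(canonical_kmer(kmer[:i] + alt + kmer[i + 1:]))
    out.discard(canonical_kmer(kmer))
    return sorted(out)


def find_snv_pairs(
    table_a: KmerCountTable,
    table_b: KmerCountTable,
    min_high: int = 100,
    max_other: int = 10,
    locus_prefix: str = "SNV",
) -> list[KmerPair]:
    """Detect allele-discriminating k-mer pairs from two genotype tables.

    A pair (x, y) qualifies when x and y differ at exactly one base in
    some orientation, x is abundant (>= ``min_high``) in one genotype
    but near-absent (<= ``max_other``) in the other — a genotype-
    restricted allele — and y is abundant in that other genotype, so the
    pair jointly covers both genotypes. Pairs are formed greedily by
    abundance and each k-mer joins at most one pair. Output order is
    independent of input ordering (sorted by descending peak abundance).
    """
    if table_a.k != table_b.k:
        raise ValueError("tables have different k")
    cand = []
    for table, other, tag in ((table_a, table_b, "A"), (table_b, table_a, "B")):
        mask = (table.counts >= min_high)
        for code, cnt in zip(table.codes[mask], table.counts[mask]):
            if other.get(int(code)) <= max_other:
                cand.append((int(cnt), tag, int(code)))
    cand.sort(key=lambda t: (-t[0], t[2]))
    from ._encode import decode_kmers

    used: set[str] = set()
    pairs: list[KmerPair] = []
    for _, tag, code in cand:
        kmer = decode_kmers(np.array([code], dtype=np.uint64), table_a.k)[0]
        if kmer in used:
            continue
        other_table = table_b if tag == "A" else table_a
        best_mate, best_cnt = None, -1
        for mate in _hamming1_neighbors(kmer):
            if mate in used:
                continue
            c = other_table.get(mate)
            if c >= min_high and c > best_cnt:
                best_mate, best_cnt = mate, c
        if best_mate is None:
            continue
        a_kmer, b_kmer = (kmer, best_mate) if tag == "A" else (best_mate, kmer)
        used.update((kmer, best_mate))
        pairs.append(KmerPair(a_kmer, b_kmer,
                              locus=f"{locus_prefix}{len(pairs) + 1}"))
    return pairs


def pair_counts(pairs: list[KmerPair],
                sample_tables: dict[str, KmerCountTable]) -> pd.DataFrame:
    """Per-sample counts of both members of each pair (long format)."""
    rows = []
    for pair in pairs:
        for sample, table in sample_tables.items():
            rows.append((pair.locus, sample, pair.allele_a_kmer,
                         pair.allele_b_kmer, table.get(pair.allele_a_kmer),
                         table.get(pair.allele_b_kmer)))
    df = pd.DataFrame(rows, columns=["locus", "sample", "kmer_A", "kmer_B",
                                     "count_A", "count_B"])
    for pair in pairs:
        pair.counts = df[df["locus"] == pair.locus].reset_index(drop=True)
    return df


def log2_ratio(count_a, count_b, pseudocount: float = 0.5):
    """Per-sample log2((B-allele + pc) / (A-allele + pc)).

    Samples where both members are zero are reported as NaN (omitted).
    Swapping the pair members negates the ratio exactly.
    """
    ca = np.asarray(count_a, dtype=float)
    cb = np.asarray(count_b, dtype=float)
    ratio = np.log2((cb + pseudocount) / (ca + pseudocount))
    ratio = np.where((ca == 0) & (cb == 0), np.nan, ratio)
    if np.isscalar(count_a):
        return float(ratio)
    return ratio


def parental_ratio_timecourse(counts: pd.DataFrame,
                              sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Pooled maternal:paternal count ratio per stage and cross direction.

    ``counts`` is the long-format pair-count table from
    :func:`pair_counts`; ``sample_meta`` is indexed by sample with
    columns ``stage``, ``cross`` and ``maternal_allele`` ('A' or 'B').
    The pooled ratio is the summed maternal count over the summed
    paternal count across pairs; zero paternal counts give ``inf``
    (maternal-only expression), not an error. Reciprocal crosses are
    reported separately.
    """
    df = counts.merge(sample_meta, left_on="sample", right_index=True)
    mat = np.where(df["maternal_allele"] == "A", df["count_A"], df["count_B"])
    pat = np.where(df["maternal_allele"] == "A", df["count_B"], df["count_A"])
    df = df.assign(maternal=mat, paternal=pat)
    rows = []
    for (cross, stage), sub in df.groupby(["cross", "stage"], sort=False):
        m, p = int(sub["maternal"].sum()), int(sub["paternal"].sum())
        ratio = float("inf") if p == 0 else m / p
        rows.append((cross, stage, m, p, ratio))
    return pd.DataFrame(rows, columns=["cross", "stage", "maternal_total",
                                       "paternal_total", "ratio"])
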
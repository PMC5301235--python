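"""Differential k-mer abundance between two genotypes.

High-abundance k-mers (HAKmers) are k-mers whose combined count across
the two compared libraries exceeds a threshold; they are enriched for
highly repetitive sequence, where shotgun counts are informative even at
modest depth. Each HAKmer is tested for association between counts and
genotype with a 1-df chi-square goodness-of-fit against the
library-size-proportional expectation, corrected by Benjamini-Hochberg
FDR, and called as a gain in one genotype when significant with at least
a two-fold normalized change. HAKmers nearly absent from one genotype
are flagged genotype-specific. K-mers are annotated against a repeat
library with a seed-and-extend matcher and located on a reference by
exact full-length matching.

HAKmer record tables are pandas DataFrames with columns
``kmer, count_A, count_B, chi2, p, p_adj, fold, call, annotation``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._encode import (
    canonical_codes,
    decode_kmers,
    encode_kmer,
    encode_seq,
    revcomp,
    window_codes,
)
from .kmers import KmerCountTable

__all__ = [
    "RepeatLibrary",
    "extract_hakmers",
    "chisq_differential",
    "call_differential",
    "classify_genotype_specific",
    "annotate_kmers",
    "map_kmers_to_reference",
    "class_abundance_summary",
    "scaled_min_total",
]

CALLS = ("A-gain", "B-gain", "A-specific", "B-specific", "nonsignificant")


@dataclass
class RepeatLibrary:
    """Named repeat sequences with class labels (satellite, rDNA, TE, ...)."""

    entries: list[tuple[str, str, str]]  # (name, class_label, sequence)

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("repeat library entry names must be unique")
        self.entries = [(n, c, s.upper()) for n, c, s in self.entries]

    @property
    def classes(self) -> list[str]:
        seen = []
        for _, c, _ in self.entries:
            if c not in seen:
                seen.append(c)
        return seen


def scaled_min_total(combined_depth: float, base: int = 20_000,
                     reference_depth: float = 92.0) -> int:
    """HAKmer total-count threshold rescaled to a different combined depth.

    The published threshold (20,000 combined counts at ~92x combined
    coverage) transfers to desk-scale simulations proportionally to the
    configured combined depth.
    """
    return max(1, int(round(base * combined_depth / reference_depth)))


def extract_hakmers(table_a: KmerCountTable, table_b: KmerCountTable,
                    min_total: int = 20_000) -> pd.DataFrame:
    """K-mers whose summed count across both genotypes reaches ``min_total``.

    Absent k-mers count as zero; the candidate set is the union of keys.
    """
    if table_a.k != table_b.k:
        raise ValueError("tables have different k")
    if min_total <= 0:
        raise ValueError("min_total must be positive")
    union = np.union1d(table_a.codes, table_b.codes)
    ca = table_a.get_many(union)
    cb = table_b.get_many(union)
    keep = (ca + cb) >= min_total
    return pd.DataFrame({
        "code": union[keep],
        "kmer": decode_kmers(union[keep], table_a.k),
        "count_A": ca[keep],
        "count_B": cb[keep],
    })


def chisq_differential(count_a, count_b, libsize_a: float, libsize_b: float):
    """1-df chi-square of (count_A, count_B) against the library-size split.

    Under the null of no genotype effect the total T = cA + cB splits in
    proportion to library sizes: eA = T*LA/(LA+LB), eB = T*LB/(LA+LB);
    chi2 = sum (obs - exp)^2 / exp with no continuity correction.
    Accepts scalars or aligned arrays; returns ``(chi2, p)``.
    """
    if libsize_a <= 0 or libsize_b <= 0:
        raise ValueError("library sizes must be positive")
    ca = np.asarray(count_a, dtype=float)
    cb = np.asarray(count_b, dtype=float)
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("counts must be non-negative")
    if np.any((ca == 0) & (cb == 0)):
        raise ValueError("counts must not both be zero")
    total = ca + cb
    pa = libsize_a / (libsize_a + libsize_b)
    ea, eb = total * pa, total * (1 - pa)
    chi2 = (ca - ea) ** 2 / ea + (cb - eb) ** 2 / eb
    p = stats.chi2.sf(chi2, df=1)
    if np.isscalar(count_a):
        return float(chi2), float(p)
    return chi2, p


def call_differential(records: pd.DataFrame, libsize_a: float, libsize_b: float,
                      fdr: float = 0.05, min_fold: float = 2.0) -> pd.DataFrame:
    """Test records and call A-gain / B-gain HAKmers.

    Adds ``chi2, p, p_adj`` (Benjamini-Hochberg over all tested HAKmers),
    normalized ``fold`` (zero counts floored at 1 raw count), and
    ``call``: a gain in the genotype with the larger normalized count iff
    ``p_adj < fdr`` and ``fold >= min_fold``.
    """
    rec = records.copy()
    if rec.empty:
        for col in ("chi2", "p", "p_adj", "fold"):
            rec[col] = pd.Series(dtype=float)
        rec["call"] = pd.Series(dtype=object)
        return rec
    chi2, p = chisq_differential(rec["count_A"].to_numpy(),
                                 rec["count_B"].to_numpy(),
                                 libsize_a, libsize_b)
    rec["chi2"], rec["p"] = chi2, p
    rec["p_adj"] = multipletests(p, method="fdr_bh")[1]
    na = rec["count_A"].to_numpy() / libsize_a
    nb = rec["count_B"].to_numpy() / libsize_b
    na_f = np.maximum(rec["count_A"].to_numpy(), 1) / libsize_a
    nb_f = np.maximum(rec["count_B"].to_numpy(), 1) / libsize_b
    hi = np.maximum(na, nb)
    lo = np.minimum(na_f, nb_f)
    rec["fold"] = hi / lo
    sig = (rec["p_adj"].to_numpy() < fdr) & (rec["fold"].to_numpy() >= min_fold)
    call = np.where(sig, np.where(na > nb, "A-gain", "B-gain"), "nonsignificant")
    rec["call"] = call
    return rec


def classify_genotype_specific(records: pd.DataFrame,
                               max_low: int = 10) -> pd.DataFrame:
    """Flag HAKmers nearly absent from one genotype as genotype-specific.

    A HAKmer with at most ``max_low`` counts in one genotype is specific
    to the other (its count there must exceed min_total - max_low by the
    extraction threshold). Specific labels supersede gain calls so that
    the five call labels stay mutually exclusive.
    """
    rec = records.copy()
    a_spec = rec["count_B"].to_numpy() <= max_low
    b_spec = rec["count_A"].to_numpy() <= max_low
    if "call" not in rec:
        rec["call"] = "nonsignificant"
    rec.loc[a_spec, "call"] = "A-specific"
    rec.loc[b_spec & ~a_spec, "call"] = "B-specific"
    return rec


# ---------------------------------------------------------------------------
# annotation


def _alignments(query: str, entry_seq: str, seed_index, entry_idx: int,
                min_seed: int, max_mismatch: int):
    """Yield (mismatches, seed_len, offset, strand) end-to-end alignments."""
    k = len(query)
    for strand, q in (("+", query), ("-", revcomp(query))):
        seen_offsets = set()
        for i in range(k - min_seed + 1):
            word = q[i : i + min_seed]
            for e_idx, pos in seed_index.get(word, ()):
                if e_idx != entry_idx:
                    continue
                off = pos - i
                if off < 0 or off + k > len(entry_seq) or off in seen_offsets:
                    continue
                seen_offsets.add(off)
                ref = entry_seq[off : off + k]
                mism = sum(a != b for a, b in zip(q, ref))
                if mism > max_mismatch:
                    continue
                # seed length = longest exact run of this alignment
                run = best = 0
                for a, b in zip(q, ref):
                    run = run + 1 if a == b else 0
                    best = max(best, run)
                if best >= min_seed:
                    yield mism, best, off, strand


def annotate_kmers(
    kmers: Sequence[str],
    library: RepeatLibrary,
    min_seed: int = 12,
    max_mismatch: int = 2,
) -> dict[str, str]:
    """Assign each k-mer the repeat class of its best library hit.

    A k-mer hits an entry when it aligns end-to-end within the entry (on
    either strand) with at most ``max_mismatch`` substitutions and the
    alignment contains an exact run of at least ``min_seed`` bases. The
    best hit has the fewest mismatches, ties broken by the longest exact
    run and then library order; k-mers with no hit map to "unannotated".
    """
    if not library.entries:
        raise ValueError("repeat library is empty")
    seed_index: dict[str, list[tuple[int, int]]] = {}
    for e_idx, (_, _, seq) in enumerate(library.entries):
        for pos in range(len(seq) - min_seed + 1):
            seed_index.setdefault(seq[pos : pos + min_seed], []).append(
                (e_idx, pos))
    out = {}
    for q in kmers:
        best = None  # (mismatches, -seed_len, entry_order)
        best_class = "unannotated"
        for e_idx, (_, cls, seq) in enumerate(library.entries):
            for mism, seed_len, _, _ in _alignments(
                    q, seq, seed_index, e_idx, min_seed, max_mismatch):
                key = (mism, -seed_len, e_idx)
                if best is None or key < best:
                    best, best_class = key, cls
        out[q] = best_class
    return out


# ---------------------------------------------------------------------------
# reference mapping


def map_kmers_to_reference(
    kmers: Sequence[str],
    reference: Mapping[str, str],
    bin_size: int = 100_000,
    min_bin_hits: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact full-length hits of k-mers on a reference, plus per-bin counts.

    Hits are reported on both strands with 1-based start coordinates; a
    palindromic k-mer yields one hit per position (identical coordinates
    from the two strands are not double-counted). Bins are half-open
    ``[i*bin_size, (i+1)*bin_size)`` on 0-based starts; only bins with at
    least ``min_bin_hits`` hits are reported (set to 0 to disable).
    """
    ks = {len(s) for s in kmers}
    if len(ks) > 1:
        raise ValueError("k-mers must share one length")
    if not kmers:
        return (pd.DataFrame(columns=["chrom", "start", "kmer", "strand"]),
                pd.DataFrame(columns=["chrom", "bin_start", "hits"]))
    k = ks.pop()
    canon_q = np.array([encode_kmer(min(s.upper(), revcomp(s))) for s in kmers],
                       dtype=np.uint64)
    given_q = np.array([encode_kmer(s.upper()) for s in kmers], dtype=np.uint64)
    order = np.argsort(canon_q)
    sorted_canon = canon_q[order]
    rows = []
    for chrom, seq in reference.items():
        codes = encode_seq(seq)
        fwd, valid = window_codes(codes, k)
        canon = canonical_codes(fwd, k)
        idx = np.searchsorted(sorted_canon, canon)
        idx_c = np.clip(idx, 0, sorted_canon.size - 1)
        hit = valid & (sorted_canon[idx_c] == canon)
        for pos in np.flatnonzero(hit):
            qi = int(order[idx_c[pos]])
            strand = "+" if fwd[pos] == given_q[qi] else "-"
            rows.append((chrom, int(pos) + 1, kmers[qi], strand))
    hits = pd.DataFrame(rows, columns=["chrom", "start", "kmer", "strand"])
    if hits.empty:
        bins = pd.DataFrame(columns=["chrom", "bin_start", "hits"])
    else:
        b = ((hits["start"] - 1) // bin_size) * bin_size
        bins = (hits.assign(bin_start=b)
                .groupby(["chrom", "bin_start"], as_index=False)
                .size().rename(columns={"size": "hits"}))
        bins = bins[bins["hits"] >= min_bin_hits].reset_index(drop=True)
    return hits, bins


def class_abundance_summary(
    records: pd.DataFrame,
    classes: Sequence[str],
    factor_a: float = 1.0,
    factor_b: float = 1.0,
) -> pd.DataFrame:
    """Normalized total count per repeat class per genotype and B/A ratio.

    ``factor_a``/``factor_b`` are the per-genotype normalization factors
    applied to raw counts. A class with zero normalized count in A but
    not in B gets ``ratio = inf`` (flagged, not an error).
    """
    known = set(classes) | {"unannotated"}
    bad = set(records["annotation"]) - known
    if bad:
        raise ValueError(f"unknown annotation classes: {sorted(bad)}")
    rows = []
    for cls in classes:
        sub = records[records["annotation"] == cls]
        ta = float(sub["count_A"].sum()) * factor_a
        tb = float(sub["count_B"].sum()) * factor_b
        if ta > 0:
            ratio = tb / ta
        elif tb > 0:
            ratio = float("inf")
        else:
            ratio = float("nan")
        rows.append((cls, ta, tb, ratio))
    return pd.DataFrame(rows, columns=["class", "norm_total_A",
                                       "norm_total_B", "ratio_B_over_A"])
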
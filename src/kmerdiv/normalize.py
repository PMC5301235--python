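"""Depth normalization via conserved single-copy k-mers; repeat copy numbers.

Across a panel of sequencing libraries, raw k-mer counts confound
genomic copy number with library size and organelle contamination. A
k-mer that is single-copy in (almost) every line should have counts
proportional to library size, so the candidate single-copy k-mers whose
per-line counts correlate best with library size are taken as
"conserved single-copy k-mers". The total count C_i of that set in line
i yields the multiplicative normalization factor

    f_i = mean_j(C_j) / C_i

which equalizes the conserved-set total across lines. Repeat-family
copy number is estimated as the median, over the family's conserved
k-mers, of count divided by the single-copy depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmers import KmerCountTable

__all__ = [
    "PanelCounts",
    "select_conserved_single_copy",
    "normalization_factors",
    "normalize_panel",
    "estimate_copy_number",
    "relative_copy_levels",
]


@dataclass
class PanelCounts:
    """Per-line counts of a query k-mer set across a panel.

    ``counts`` is a DataFrame with k-mers as the index and line labels
    as columns; ``library_sizes`` (same line order) is the per-line
    library size, in whatever unit is consistent across lines (total
    sequenced bases or total counted k-mer instances).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()]
            raise ValueError(f"library sizes missing for lines: {list(missing)}")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def lines(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tables(cls, tables: dict[str, KmerCountTable],
                    kmers: list[str]) -> "PanelCounts":
        """Restrict per-line count tables to a query k-mer set."""
        from ._encode import encode_kmer

        codes = np.array([encode_kmer(s) for s in kmers], dtype=np.uint64)
        data = {lid: t.get_many(codes) for lid, t in tables.items()}
        counts = pd.DataFrame(data, index=kmers)
        libs = pd.Series({lid: float(t.library_bases or t.total_instances)
                          for lid, t in tables.items()})
        return cls(counts, libs)


def select_conserved_single_copy(panel: PanelCounts,
                                 top_frac: float = 0.05) -> list[str]:
    """Top fraction of candidate k-mers by count-vs-library-size correlation.

    Candidates should be single-copy in the reference genotypes; the
    Pearson correlation of each k-mer's per-line counts with per-line
    library sizes ranks how faithfully it tracks depth, and the top
    ``top_frac`` (ceiling) are returned. Zero-variance k-mers are
    excluded before ranking.
    """
    if len(panel.lines) < 3:
        raise ValueError("need >= 3 lines for correlation ranking")
    X = panel.counts.to_numpy(dtype=float)
    lib = panel.library_sizes.to_numpy(dtype=float)
    sd = X.std(axis=1)
    ok = sd > 0
    Xc = X[ok] - X[ok].mean(axis=1, keepdims=True)
    libc = lib - lib.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1)) * np.sqrt((libc ** 2).sum())
    r = (Xc @ libc) / denom
    n_take = int(np.ceil(top_frac * len(panel.counts)))
    idx_ok = np.flatnonzero(ok)
    order = idx_ok[np.argsort(-r, kind="stable")][:n_take]
    return [panel.counts.index[i] for i in order]


def normalization_factors(totals: pd.Series) -> pd.DataFrame:
    """Per-line factors f_i = mean(C)/C_i from conserved-set totals C.

    Multiplying line i's raw counts by f_i equalizes the conserved
    single-copy total across lines at the panel mean (``reference_total``
    attribute of the returned frame).
    """
    totals = totals.astype(float)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"conserved-set total is zero for line(s): {list(zero)}")
    ref = totals.mean()
    out = pd.DataFrame({"C": totals, "factor": ref / totals})
    out.attrs["reference_total"] = float(ref)
    return out


def normalize_panel(panel: PanelCounts, factors: pd.DataFrame) -> pd.DataFrame:
    """Elementwise per-line scaling; non-integral values are expected."""
    missing = [l for l in panel.lines if l not in factors.index]
    if missing:
        raise ValueError(f"factors missing for lines: {missing}")
    f = factors.loc[panel.lines, "factor"].to_numpy(dtype=float)
    return panel.counts.astype(float) * f


def estimate_copy_number(family_kmers: list[str], counts,
                         single_copy_depth: float) -> float:
    """Median per-k-mer copy estimate (count / single-copy depth) of a family.

    ``counts`` may be a KmerCountTable, a mapping, or a Series over the
    family k-mers; family k-mers absent from the table contribute count
    zero. The family k-mer set must already exclude matches to other
    repeat classes and organelle sequence.
    """
    if not family_kmers:
        raise ValueError("empty family k-mer set")
    if single_copy_depth <= 0:
        raise ValueError("single_copy_depth must be positive")
    if isinstance(counts, KmerCountTable):
        vals = np.array([counts.get(s) for s in family_kmers], dtype=float)
    else:
        vals = np.array([float(counts.get(s, 0)) if hasattr(counts, "get")
                         else float(counts[s]) for s in family_kmers])
    return float(np.median(vals / single_copy_depth))


def relative_copy_levels(
    panel: PanelCounts,
    family_a_kmers: list[str],
    family_b_kmers: list[str],
    factors: pd.DataFrame,
    family_names: tuple[str, str] = ("45S", "5S"),
) -> tuple[pd.DataFrame, float | None]:
    """Per-line median normalized abundance of two families, plus their R^2.

    Mirrors comparing 45S and 5S rDNA copy-number levels across a panel;
    R^2 is the squared Pearson correlation of the two per-line median
    vectors, omitted (None) with fewer than 3 lines.
    """
    if not family_a_kmers or not family_b_kmers:
        raise ValueError("both family k-mer sets must be non-empty")
    norm = normalize_panel(panel, factors)
    in_a = [s for s in family_a_kmers if s in norm.index]
    in_b = [s for s in family_b_kmers if s in norm.index]
    if not in_a or not in_b:
        raise ValueError("family k-mers absent from the panel counts")
    med_a = norm.loc[in_a].median(axis=0)
    med_b = norm.loc[in_b].median(axis=0)
    levels = pd.DataFrame({family_names[0]: med_a, family_names[1]: med_b})
    r2 = None
    if len(panel.lines) >= 3 and med_a.std() > 0 and med_b.std() > 0:
        r2 = float(np.corrcoef(med_a, med_b)[0, 1] ** 2)
    return levels, r2
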
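"""Copy-number-variation QTL mapping of k-mer abundance traits.

Normalized k-mer abundance per DH line is treated as a quantitative
trait. For fully informative homozygous DH genotypes, single-marker
regression is the exact marker-level model: at each marker the LOD score
is

    LOD = (n/2) * log10(RSS0 / RSS1)

with RSS0 the squared deviations around the grand mean and RSS1 the
within-genotype-class squared deviations (normal likelihood-ratio with
MLE variances). Genome-wide significance is set by permuting the trait
across lines and taking the (1 - alpha) quantile of the permuted
genome-wide maximum LOD; peaks are declared above
max(permutation threshold, declare_min) with greedy suppression of
nearby markers on the same chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScanResult",
    "kmer_trait",
    "lod_scan",
    "batch_lod_scan",
    "permutation_threshold",
    "null_lod_threshold",
    "call_peaks",
    "map_hakmer_set",
]

LOD_CAP = 50.0  # reported ceiling for perfect genotype separation


@dataclass
class ScanResult:
    """Per-marker LOD profile with its threshold and called peaks."""

    scan: pd.DataFrame  # chrom, cM, marker_id, lod
    threshold: float | None = None
    peaks: pd.DataFrame | None = None
    capped: bool = field(default=False)


def kmer_trait(counts: pd.Series, factors: pd.DataFrame) -> pd.Series:
    """Normalized per-line abundance of one k-mer (count_i * f_i)."""
    f = factors.loc[counts.index, "factor"]
    trait = counts.astype(float) * f
    trait.attrs["constant"] = bool(np.ptp(trait.to_numpy()) == 0)
    return trait


def _class_stats(y: np.ndarray, genotypes: np.ndarray):
    """Per-marker sums needed for the two-group RSS decomposition.

    ``y`` is (n_traits, n_lines); ``genotypes`` is (n_lines, n_markers)
    with 0/1 codes and -1 for missing (pairwise deletion per marker).
    """
    A = ((genotypes == 0)).astype(float)
    B = ((genotypes == 1)).astype(float)
    nA, nB = A.sum(axis=0), B.sum(axis=0)
    sA, sB = y @ A, y @ B
    s2A, s2B = (y ** 2) @ A, (y ** 2) @ B
    return nA, nB, sA, sB, s2A, s2B


def batch_lod_scan(Y: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    """LOD scores for many traits at once: (n_traits, n_markers) matrix.

    Monomorphic markers (fewer than 2 lines in either class) get NaN;
    perfect separation is capped at ``LOD_CAP``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    nA, nB, sA, sB, s2A, s2B = _class_stats(Y, genotypes)
    valid = (nA >= 2) & (nB >= 2)
    n = nA + nB
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = (s2A + s2B) - (sA + sB) ** 2 / n
        rss1 = (s2A - sA ** 2 / nA) + (s2B - sB ** 2 / nB)
        rss0 = np.maximum(rss0, 0.0)
        rss1 = np.maximum(rss1, 0.0)
        lod = (n / 2.0) * np.log10(rss0 / rss1)
    # perfect separation (zero within-class RSS) reported at the ceiling;
    # finite scores are NOT clipped, so strong peaks still order correctly
    lod = np.where(rss1 <= 0, np.where(rss0 > 0, LOD_CAP, 0.0), lod)
    lod = np.maximum(lod, 0.0)
    lod[:, ~valid] = np.nan
    return lod


def lod_scan(trait, genotypes: np.ndarray,
             gmap: pd.DataFrame | None = None) -> pd.DataFrame | np.ndarray:
    """Single-marker LOD scan of one trait across all markers.

    ``trait`` is a per-line vector aligned with the rows of
    ``genotypes`` (lines x markers, 0=A, 1=B, -1 missing). Returns the
    per-marker LOD array, or a scan DataFrame when ``gmap`` is given.
    A constant trait yields an all-zero scan with a warning.
    """
    y = np.asarray(trait, dtype=float)
    if np.ptp(y[np.isfinite(y)]) == 0:
        warnings.warn("constant trait: LOD is zero everywhere")
        lod = np.zeros(genotypes.shape[1])
        lod[~(((genotypes == 0).sum(axis=0) >= 2)
              & ((genotypes == 1).sum(axis=0) >= 2))] = np.nan
    else:
        geno = genotypes.copy()
        geno[~np.isfinite(y), :] = -1  # drop lines with missing trait
        lod = batch_lod_scan(y[None, :], geno)[0]
    if gmap is None:
        return lod
    out = gmap[["chrom", "cM", "marker_id"]].copy()
    out["lod"] = lod
    return out


def permutation_threshold(trait, genotypes: np.ndarray, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int = 0) -> float:
    """Genome-wide LOD cutoff from trait permutations.

    The trait is shuffled across lines ``n_perm`` times; the cutoff is
    the empirical (1 - alpha) quantile (linear/type-7 interpolation) of
    the permuted genome-wide maximum LOD.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(trait, dtype=float)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    lods = batch_lod_scan(perms, genotypes)
    max_lod = np.nanmax(lods, axis=1)
    return float(np.quantile(max_lod, 1.0 - alpha))


def null_lod_threshold(gmap: pd.DataFrame, n_lines: int = 280,
                       n_traits: int = 1000, alpha: float = 0.05,
                       seed: int = 0) -> float:
    """Genome-wide LOD significance threshold under the null.

    Simulates a DH population on ``gmap`` (Haldane crossovers), draws
    ``n_traits`` independent standard-normal traits, scans each across
    all markers, and returns the empirical (1 - alpha) quantile of the
    genome-wide maximum LOD. Equivalent in law to permuting a null
    trait, and the reference point for the published 5% cutoffs.
    """
    from .simulate import simulate_dh_genotypes

    rng = np.random.default_rng(seed)
    geno = simulate_dh_genotypes(gmap, n_lines,
                                 seed=int(rng.integers(0, 2**31)))
    Y = rng.standard_normal((n_traits, n_lines))
    lods = batch_lod_scan(Y, geno)
    max_lod = np.nanmax(lods, axis=1)
    return float(np.quantile(max_lod, 1.0 - alpha))


def call_peaks(scan: pd.DataFrame, threshold: float, declare_min: float = 4.0,
               min_peak_gap: float = 30.0, max_peaks: int = 4) -> pd.DataFrame:
    """Greedy peak calling on a LOD scan.

    Markers at or above ``max(threshold, declare_min)`` are visited in
    decreasing LOD order; a marker becomes a peak unless it lies within
    ``min_peak_gap`` cM of an already-chosen peak on the same
    chromosome, up to ``max_peaks`` peaks. An empty result means the
    trait could not be mapped.
    """
    cutoff = max(threshold, declare_min)
    cand = scan.dropna(subset=["lod"])
    cand = cand[cand["lod"] >= cutoff].sort_values("lod", ascending=False)
    peaks = []
    for _, row in cand.iterrows():
        if len(peaks) >= max_peaks:
            break
        if any(p["chrom"] == row["chrom"]
               and abs(p["cM"] - row["cM"]) < min_peak_gap for p in peaks):
            continue
        peaks.append({"chrom": row["chrom"], "cM": float(row["cM"]),
                      "lod": float(row["lod"]),
                      "marker_id": row["marker_id"]})
    out = pd.DataFrame(peaks, columns=["chrom", "cM", "lod", "marker_id"])
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def map_hakmer_set(
    records: pd.DataFrame,
    panel_counts: pd.DataFrame,
    genotypes: np.ndarray,
    factors: pd.DataFrame,
    gmap: pd.DataFrame,
    threshold: float | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    declare_min: float = 4.0,
    min_peak_gap: float = 30.0,
    max_peaks: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """cnvQTL-map every HAKmer record; summarize peaks by annotation class.

    ``panel_counts`` holds per-line counts (k-mers x lines) for the
    record k-mers. A shared permutation threshold is computed from the
    first non-constant trait unless ``threshold`` is given. Returns
    ``(peak_table, class_summary)``; constant-trait k-mers are skipped.
    """
    peak_rows = []
    ann = (records.set_index("kmer")["annotation"]
           if "annotation" in records else None)
    shared_thr = threshold
    for kmer in records["kmer"]:
        if kmer not in panel_counts.index:
            continue
        trait = kmer_trait(panel_counts.loc[kmer], factors)
        if trait.attrs.get("constant"):
            continue
        if shared_thr is None:
            shared_thr = permutation_threshold(
                trait.to_numpy(), genotypes, n_perm=n_perm, alpha=alpha,
                seed=seed)
        scan = lod_scan(trait.to_numpy(), genotypes, gmap)
        peaks = call_peaks(scan, shared_thr, declare_min, min_peak_gap,
                           max_peaks)
        for _, p in peaks.iterrows():
            peak_rows.append({
                "kmer": kmer,
                "class": ann.get(kmer, "unannotated") if ann is not None
                         else "unannotated",
                "chrom": p["chrom"], "cM": p["cM"], "lod": p["lod"],
                "marker_id": p["marker_id"], "rank": int(p["rank"]),
            })
    peak_table = pd.DataFrame(
        peak_rows, columns=["kmer", "class", "chrom", "cM", "lod",
                            "marker_id", "rank"])
    if peak_table.empty:
        summary = pd.DataFrame(columns=["class", "chrom", "n_peaks",
                                        "median_cM", "median_lod"])
    else:
        summary = (peak_table.groupby(["class", "chrom"], as_index=False)
                   .agg(n_peaks=("kmer", "size"), median_cM=("cM", "median"),
                        median_lod=("lod", "median")))
    return peak_table, summary
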
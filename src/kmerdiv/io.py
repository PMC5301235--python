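"""Readers and writers for the pipeline's on-disk formats.

Sequence input is FASTA/FASTQ, gzip-compressed or plain, with CRLF
tolerated and sequences uppercased on read. Tabular artifacts are TSV
with '#'-prefixed metadata header lines (``# key=value``); every writer
round-trips through its reader to an equal in-memory object. Genomic
coordinates in BED-like outputs are 0-based half-open; truth tables are
1-based inclusive (declared in their headers).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .kmers import KmerCountTable, KmerSpectrum

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_count_table",
    "read_count_table",
    "write_spectrum",
    "read_spectrum",
    "write_tsv",
    "read_tsv",
    "write_genotype_matrix",
    "read_genotype_matrix",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
    elif str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode, newline=None)


def read_fasta(path) -> dict[str, str]:
    """FASTA records as name -> uppercased sequence (gzip accepted)."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[tuple[str, str]]:
    """FASTQ records as (name, uppercased sequence) pairs.

    Accepts gzip and CRLF line endings; raises on a sequence/quality
    length mismatch, reporting the offending line number.
    """
    records = []
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            header = header.rstrip("\r\n")
            if not header.startswith("@"):
                raise ValueError(f"line {lineno}: FASTQ header must start with @")
            seq = fh.readline().rstrip("\r\n")
            plus = fh.readline().rstrip("\r\n")
            qual = fh.readline().rstrip("\r\n")
            if not qual and not plus:
                raise ValueError(f"line {lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise ValueError(f"line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ValueError(
                    f"line {lineno}: sequence and quality lengths differ "
                    f"({len(seq)} vs {len(qual)})")
            records.append((header[1:].split()[0], seq.upper()))
    return records


def write_fastq(path, records: Iterable[tuple[str, str]],
                quality_char: str = "I") -> None:
    """Write (name, sequence) records with a constant dummy quality."""
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# TSV with '#' metadata


def _write_meta(fh, meta: dict) -> None:
    for key, val in meta.items():
        fh.write(f"# {key}={val}\n")


def _read_meta(path):
    meta = {}
    with _open_text(path) as fh:
        n_skip = 0
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, n_skip


def write_tsv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    with _open_text(path, "wt") as fh:
        _write_meta(fh, meta or {})
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> tuple[pd.DataFrame, dict]:
    meta, n_skip = _read_meta(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_skip)
    return df, meta


def write_count_table(path, table: KmerCountTable) -> None:
    """Serialize a count table as sorted (kmer, count) TSV with metadata."""
    kmers = table.kmers()
    order = np.argsort(kmers)
    with _open_text(path, "wt") as fh:
        _write_meta(fh, {"k": table.k, "sample_id": table.sample_id,
                         "library_bases": table.library_bases})
        fh.write("kmer\tcount\n")
        for i in order:
            fh.write(f"{kmers[i]}\t{int(table.counts[i])}\n")


def read_count_table(path) -> KmerCountTable:
    df, meta = read_tsv(path)
    d = dict(zip(df["kmer"], df["count"].astype(int)))
    return KmerCountTable.from_dict(
        d, k=int(meta.get("k", 25)),
        library_bases=int(meta.get("library_bases", 0)),
        sample_id=meta.get("sample_id", ""))


def write_spectrum(path, spec: KmerSpectrum) -> None:
    df = pd.DataFrame(sorted(spec.histogram.items()),
                      columns=["abundance", "n_kmers"])
    write_tsv(path, df, {"k": spec.k, "sample_id": spec.sample_id})


def read_spectrum(path) -> KmerSpectrum:
    df, meta = read_tsv(path)
    hist = dict(zip(df["abundance"].astype(int), df["n_kmers"].astype(int)))
    return KmerSpectrum(hist, k=int(meta.get("k", 25)),
                        sample_id=meta.get("sample_id", ""))


def write_genotype_matrix(path, genotypes: np.ndarray, line_ids: list[str],
                          marker_ids: list[str]) -> None:
    """Lines x markers A/B genotype codes as TSV (first column = line)."""
    letters = np.array(["A", "B"])[genotypes]
    df = pd.DataFrame(letters, index=pd.Index(line_ids, name="line"),
                      columns=marker_ids)
    with _open_text(path, "wt") as fh:
        _write_meta(fh, {"codes": "A,B"})
        df.to_csv(fh, sep="\t")


def read_genotype_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    meta, n_skip = _read_meta(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_skip, index_col=0)
    bad = set(np.unique(df.to_numpy())) - {"A", "B"}
    if bad:
        raise ValueError(f"genotype codes must be A/B, found {sorted(bad)}")
    geno = (df.to_numpy() == "B").astype(np.int8)
    return geno, list(df.index), list(df.columns)
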
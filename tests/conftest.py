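"""Shared fixtures: small synthetic genomes, reads, and count tables."""

import numpy as np
import pytest

from kmerdiv import kmers, simulate as sim


@pytest.fixture(scope="session")
def centc_genomes():
    """Two genotypes with a 1.71x centromeric-satellite copy difference."""
    fams = [sim.centc_like({"A": 100, "B": 171}, placement=(0, 250_000))]
    return sim.simulate_repeat_genome(500_000, fams, snv_rate=0.001, seed=11), fams


@pytest.fixture(scope="session")
def centc_tables(centc_genomes):
    """Error-free 10x read tables for the two genotypes."""
    genomes, _ = centc_genomes
    tables = {}
    for i, g in enumerate(("A", "B")):
        reads = sim.simulate_reads(genomes[g], depth=10, read_len=100,
                                   error_rate=0.0, seed=20 + i, sample_id=g)
        tables[g] = kmers.count_kmers(reads, 25, sample_id=g)
    return tables


@pytest.fixture(scope="session")
def dense_map():
    """10 chromosomes x 140 cM, one marker per cM."""
    return sim.make_genetic_map(10, 140, 1.0)


def brute_force_count(seqs, k):
    """Exhaustive positional canonical k-mer enumeration (test oracle)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) - set("ACGT"):
                continue
            rc = "".join(comp[c] for c in reversed(w))
            canon = min(w, rc)
            counts[canon] = counts.get(canon, 0) + 1
    return counts
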
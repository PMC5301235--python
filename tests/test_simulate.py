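"""Synthetic genomes, reads, DH panels, grouped panels, allelic counts."""

import numpy as np
import pandas as pd
import pytest

from kmerdiv import simulate as sim
from kmerdiv.simulate import RepeatFamilySpec


class TestRepeatFamilySpec:
    def test_non_acgt_unit_rejected(self):
        with pytest.raises(ValueError, match="ACGT"):
            RepeatFamilySpec("bad", "ACGTN", {"A": 1})

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            RepeatFamilySpec("bad", "ACGT" * 20, {"A": -1})

    def test_substructure_must_tile_unit(self):
        with pytest.raises(ValueError, match="substructure"):
            RepeatFamilySpec("bad", "A" * 100, {"A": 1},
                             substructure=[("x", 1, 40), ("y", 50, 100)])

    def test_rdna_substructure_is_valid(self):
        fam = sim.rdna_like({"A": 2})
        assert fam.sub_span("gene26S") == (2561, 5960)
        assert len(fam.unit_seq) == 9000


class TestSimulateRepeatGenome:
    def test_copy_difference_length_bookkeeping(self):
        fam = RepeatFamilySpec("f", "ACGT" * 45, {"A": 0, "B": 5},
                               placement=(0, 5000))
        g = sim.simulate_repeat_genome(10_000, [fam], snv_rate=0.0, seed=1)
        assert g["B"].total_length - g["A"].total_length == 5 * 180

    def test_no_snvs_equal_copies_identical_genomes(self):
        fam = RepeatFamilySpec("f", "ACGT" * 45, {"A": 3, "B": 3},
                               placement=(0, 5000))
        g = sim.simulate_repeat_genome(10_000, [fam], snv_rate=0.0, seed=1,
                                       per_copy_divergence=0.0)
        assert g["A"].sequences == g["B"].sequences

    def test_central_kmer_count_ratio_matches_copy_ratio(self, centc_genomes):
        genomes, fams = centc_genomes
        unit = fams[0].unit_seq
        central = unit[len(unit) // 2 - 12 : len(unit) // 2 + 13]
        na = genomes["A"].sequences["chr1"].count(central)
        nb = genomes["B"].sequences["chr1"].count(central)
        # 0.5% per-copy divergence erodes a few copies on both sides
        assert nb / na == pytest.approx(1.71, rel=0.08)

    def test_placement_coordinates_recover_cluster(self):
        fam = RepeatFamilySpec("f", "ACGT" * 45, {"A": 2, "B": 1},
                               placement=(0, 3000))
        g = sim.simulate_repeat_genome(10_000, [fam], snv_rate=0.0, seed=3,
                                       per_copy_divergence=0.0)
        row = g["A"].placements.iloc[0]
        seq = g["A"].sequences[row["chrom"]][row["start"] - 1 : row["end"]]
        assert seq == fam.unit_seq * 2

    def test_backbone_conservation(self):
        fam = RepeatFamilySpec("f", "ACGT" * 45, {"A": 7}, placement=(0, 800))
        g = sim.simulate_repeat_genome(2_000, [fam], snv_rate=0.01, seed=4)
        assert g["A"].total_length == 2_000 + 7 * 180

    def test_unplaceable_cluster_rejected(self):
        fam = RepeatFamilySpec("f", "ACGT" * 45, {"A": 2},
                               placement=(0, 5000))
        with pytest.raises(ValueError, match="beyond"):
            sim.simulate_repeat_genome(2_000, [fam], snv_rate=0.0, seed=5)

    def test_seed_determinism(self):
        fam = RepeatFamilySpec("f", "ACGT" * 45, {"A": 2, "B": 4},
                               placement=(0, 900))
        g1 = sim.simulate_repeat_genome(2_000, [fam], snv_rate=0.01, seed=9)
        g2 = sim.simulate_repeat_genome(2_000, [fam], snv_rate=0.01, seed=9)
        assert g1["B"].sequences == g2["B"].sequences
        assert g1["A"].snv_positions == g2["A"].snv_positions


class TestSimulateReads:
    def test_total_bases_match_depth(self):
        g = sim.simulate_repeat_genome(100_000, [], snv_rate=0, seed=1)["A"]
        reads = sim.simulate_reads(g, depth=30, read_len=100, seed=2)
        assert reads.total_bases == pytest.approx(30 * 100_000, abs=100)

    def test_error_free_reads_are_genome_substrings(self):
        g = sim.simulate_repeat_genome(5_000, [], snv_rate=0, seed=1)["A"]
        reads = sim.simulate_reads(g, depth=2, read_len=60, seed=3)
        from kmerdiv._encode import revcomp

        chrom = g.sequences["chr1"]
        for seq in reads.sequences:
            assert seq in chrom or revcomp(seq) in chrom

    def test_error_rate_matches_binomial_expectation(self):
        g = sim.simulate_repeat_genome(200_000, [], snv_rate=0, seed=1)["A"]
        clean = sim.simulate_reads(g, depth=6.25, read_len=125, seed=7,
                                   error_rate=0.0)
        noisy = sim.simulate_reads(g, depth=6.25, read_len=125, seed=7,
                                   error_rate=0.01)
        n = min(len(clean.sequences), 10_000)
        mism = [sum(a != b for a, b in zip(c, e)) for c, e in
                zip(clean.sequences[:n], noisy.sequences[:n])]
        mean = np.mean(mism)
        se = np.sqrt(125 * 0.01 * 0.99 / n)
        assert abs(mean - 1.25) < 3 * se

    def test_read_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="read_len"):
            sim.simulate_reads({"chr1": "ACGT" * 10}, depth=1, read_len=100)

    def test_paired_mode_produces_mate_pairs(self):
        g = sim.simulate_repeat_genome(20_000, [], snv_rate=0, seed=1)["A"]
        reads = sim.simulate_reads(g, depth=2, read_len=50, paired=True,
                                   seed=4)
        assert reads.n_reads % 2 == 0
        assert reads.names[0].endswith("/1") and reads.names[1].endswith("/2")

    def test_single_copy_kmer_depth_property(self, centc_tables):
        # error-free depth D: single-copy 25-mer count ~ D*(L-24)/L
        table = centc_tables["A"]
        lam = 10 * (100 - 24) / 100
        from kmerdiv import kmers

        spec = kmers.spectrum(table)
        _, peak = kmers.find_peak_and_trough(spec)
        assert abs(peak - lam) <= 4 * np.sqrt(lam)


class TestDHPanel:
    def test_fewer_than_two_lines_rejected(self, dense_map):
        with pytest.raises(ValueError, match="n_lines"):
            sim.simulate_dh_genotypes(dense_map, 1)

    def test_zero_distance_markers_cosegregate(self):
        gmap = pd.DataFrame({"chrom": ["chr1"] * 3, "cM": [0.0, 0.0, 0.0],
                             "marker_id": ["m1", "m2", "m3"]})
        geno = sim.simulate_dh_genotypes(gmap, 100, seed=1)
        assert (geno[:, 0] == geno[:, 1]).all()
        assert (geno[:, 0] == geno[:, 2]).all()

    def test_haldane_recombinant_fraction(self):
        gmap = pd.DataFrame({"chrom": ["chr1"] * 2, "cM": [0.0, 10.0],
                             "marker_id": ["m1", "m2"]})
        r_expect = 0.5 * (1 - np.exp(-0.2))
        rec = []
        for seed in range(5):
            geno = sim.simulate_dh_genotypes(gmap, 280, seed=seed)
            rec.append((geno[:, 0] != geno[:, 1]).mean())
        se = np.sqrt(r_expect * (1 - r_expect) / (280 * 5))
        assert abs(np.mean(rec) - r_expect) < 3 * se

    def test_genotype_frequency_near_half(self, dense_map):
        geno = sim.simulate_dh_genotypes(dense_map, 280, seed=3)
        freq = geno.mean(axis=0)
        se = np.sqrt(0.25 / 280)
        assert (np.abs(freq - 0.5) < 4 * se).mean() > 0.99

    def test_cluster_copy_number_follows_mosaic(self):
        fam = RepeatFamilySpec("f", "ACGT" * 45, {"A": 100, "B": 50},
                               placement=(0, 5000))
        genomes = sim.simulate_repeat_genome(10_000, [fam], snv_rate=0,
                                             seed=1)
        gmap = sim.make_genetic_map(1, 100, 1.0)
        panel = sim.simulate_dh_panel(genomes["A"], genomes["B"], gmap,
                                      n_lines=280, seed=2,
                                      cluster_positions={"f": ("chr1", 50.0)})
        j = (gmap["chrom"] == "chr1") & (gmap["cM"] == 50.0)
        col = panel.genotypes[:, int(np.flatnonzero(j)[0])]
        expect = np.where(col == 0, 100, 50)
        agree = (panel.line_truth["f"].to_numpy() == expect).mean()
        assert agree >= 0.95

    def test_mosaic_determinism(self, dense_map):
        g1 = sim.simulate_dh_genotypes(dense_map, 50, seed=8)
        g2 = sim.simulate_dh_genotypes(dense_map, 50, seed=8)
        assert (g1 == g2).all()


class TestSimulatePanel:
    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sim.simulate_panel({"teosinte": 0}, {"teosinte": {}},
                               (2, 4), (0, 0))

    def test_organelle_contamination_dilutes_nuclear_depth(self):
        fams = [sim.centc_like({}, placement=(0, 10_000))]
        profiles = {"g": {"CentC": (0, 0)}}
        kw = dict(families=fams, backbone_length=30_000, read_len=80,
                  organelle_length=20_000, snv_rate=0.0)
        clean = sim.simulate_panel({"g": 2}, profiles, (10, 10), (0.0, 0.0),
                                   seed=5, **kw)
        dirty = sim.simulate_panel({"g": 2}, profiles, (10, 10), (0.5, 0.5),
                                   seed=5, **kw)
        from kmerdiv import kmers

        med = []
        for p in (clean, dirty):
            t = kmers.count_kmers(p.read_sets[p.line_ids[0]], 25)
            med.append(np.median(t.counts))
        assert med[0] / med[1] == pytest.approx(2.0, rel=0.25)

    def test_decreasing_profile_gives_decreasing_counts(self):
        fams = [sim.centc_like({}, placement=(0, 15_000))]
        profiles = {"t": {"CentC": (100, 5)}, "l": {"CentC": (50, 4)},
                    "i": {"CentC": (25, 3)}}
        psim = sim.simulate_panel({"t": 3, "l": 3, "i": 3}, profiles,
                                  (4, 4), (0.0, 0.0), seed=6, families=fams,
                                  backbone_length=30_000, snv_rate=0.0)
        means = psim.truth.groupby("group")["copies"].mean()
        assert means["t"] > means["l"] > means["i"]

    def test_library_bases_independent_of_contamination(self):
        fams = [sim.centc_like({}, placement=(0, 10_000))]
        profiles = {"g": {"CentC": (0, 0)}}
        kw = dict(families=fams, backbone_length=30_000, read_len=80,
                  organelle_length=20_000, snv_rate=0.0)
        clean = sim.simulate_panel({"g": 2}, profiles, (10, 10), (0.0, 0.0),
                                   seed=5, **kw)
        dirty = sim.simulate_panel({"g": 2}, profiles, (10, 10), (0.5, 0.5),
                                   seed=5, **kw)
        b0 = clean.read_sets[clean.line_ids[0]].total_bases
        b1 = dirty.read_sets[dirty.line_ids[0]].total_bases
        assert b1 == pytest.approx(b0, rel=0.02)


class TestAllelicCounts:
    def test_both_dosages_zero_rejected(self):
        with pytest.raises(ValueError, match="dosage"):
            sim.simulate_allelic_counts(0, 0, 5000, 3)

    def test_paternal_dosage_zero_gives_zero_counts(self):
        df = sim.simulate_allelic_counts(2, 0, 5000, 10, seed=1)
        assert (df["paternal"] == 0).all()

    def test_balanced_dosage_log2_ratio_near_zero(self):
        df = sim.simulate_allelic_counts(1, 1, 5000, 20, seed=2)
        ratios = np.log2(df["paternal"] / df["maternal"])
        assert (np.abs(ratios) < 0.1).all()

    def test_triploid_pooled_ratio_near_two(self):
        df = sim.simulate_allelic_counts(2, 1, 5000, 3, seed=3)
        pooled = df["maternal"].sum() / df["paternal"].sum()
        assert pooled == pytest.approx(2.0, rel=0.05)
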
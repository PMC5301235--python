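"""HAKmer extraction, chi-square tests, calls, annotation, reference mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kmerdiv import differential as dd
from kmerdiv import kmers
from kmerdiv._encode import revcomp


def _table(d, **kw):
    return kmers.KmerCountTable.from_dict(d, **kw)


class TestExtractHakmers:
    def test_boundary_total_excluded_below_threshold(self):
        ta = _table({"AAAAC": 19_999})
        tb = _table({"AAAAG": 1})
        rec = dd.extract_hakmers(ta, tb, 20_000)
        assert rec.empty

    def test_threshold_met_by_combined_counts(self):
        ta = _table({"AAAAC": 10_000})
        tb = _table({"AAAAC": 10_000})
        rec = dd.extract_hakmers(ta, tb, 20_000)
        assert list(rec["kmer"]) == ["AAAAC"]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(3)
        kmer_pool = ["".join(rng.choice(list("ACGT"), size=11))
                     for _ in range(60)]
        kmer_pool = [min(s, revcomp(s)) for s in kmer_pool]
        da = {s: int(rng.integers(0, 300)) + 1 for s in kmer_pool[:40]}
        db = {s: int(rng.integers(0, 300)) + 1 for s in kmer_pool[20:]}
        rec = dd.extract_hakmers(_table(da), _table(db), 250)
        union = set(da) | set(db)
        expect = {s for s in union if da.get(s, 0) + db.get(s, 0) >= 250}
        assert set(rec["kmer"]) == expect
        for _, row in rec.iterrows():
            assert row["count_A"] == da.get(row["kmer"], 0)
            assert row["count_B"] == db.get(row["kmer"], 0)


class TestChisqDifferential:
    def test_worked_example_equal_libraries(self):
        chi2, p = dd.chisq_differential(100, 50, 1e6, 1e6)
        assert chi2 == pytest.approx(16.667, abs=1e-3)
        assert p == pytest.approx(4.45e-5, rel=0.01)

    def test_null_case_zero_statistic(self):
        chi2, p = dd.chisq_differential(77, 77, 1e6, 1e6)
        assert chi2 == 0.0 and p == 1.0

    def test_counts_proportional_to_libraries(self):
        chi2, _ = dd.chisq_differential(150, 50, 3e6, 1e6)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_scipy_chisquare(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ca, cb = int(rng.integers(1, 500)), int(rng.integers(1, 500))
            la, lb = rng.uniform(1e5, 1e6, size=2)
            chi2, p = dd.chisq_differential(ca, cb, la, lb)
            t = ca + cb
            ref = stats.chisquare(
                [ca, cb], [t * la / (la + lb), t * lb / (la + lb)])
            assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_null_calibration_false_positive_rate(self):
        # two libraries from the same genome: ~5% of tests below p=0.05
        rng = np.random.default_rng(8)
        n = 2000
        lam = 500
        ca = rng.poisson(lam, size=n) + 1
        cb = rng.poisson(lam, size=n) + 1
        _, p = dd.chisq_differential(ca, cb, 1e6, 1e6)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < 3 * se


class TestCallDifferential:
    def test_single_record_bh_identity(self):
        rec = pd.DataFrame({"kmer": ["AAAAC"], "count_A": [100],
                            "count_B": [50]})
        out = dd.call_differential(rec, 1e6, 1e6)
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_bh_adjustment_matches_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.04])
        # brute-force BH: p_adj[i] = min over j>=i of p(j)*m/j (sorted)
        expect = np.array([0.03, 0.03, 0.04])
        assert np.allclose(multipletests(p, method="fdr_bh")[1], expect)

    def test_low_fold_change_stays_nonsignificant(self):
        rec = pd.DataFrame({"kmer": ["AAAAC"], "count_A": [180_000],
                            "count_B": [100_000]})
        out = dd.call_differential(rec, 1e6, 1e6)
        assert out["p_adj"].iloc[0] < 0.001
        assert out["fold"].iloc[0] == pytest.approx(1.8)
        assert out["call"].iloc[0] == "nonsignificant"

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        rec = pd.DataFrame({
            "kmer": [f"K{i}" for i in range(50)],
            "count_A": rng.integers(1, 2000, size=50),
            "count_B": rng.integers(1, 2000, size=50)})
        out = dd.call_differential(rec, 2e6, 1e6)
        swapped = rec.rename(columns={"count_A": "count_B",
                                      "count_B": "count_A"})
        out_sw = dd.call_differential(swapped, 1e6, 2e6)
        trans = {"A-gain": "B-gain", "B-gain": "A-gain",
                 "nonsignificant": "nonsignificant"}
        assert [trans[c] for c in out["call"]] == list(out_sw["call"])

    def test_power_on_planted_difference(self):
        # a clearly super-2-fold planting is called in the right direction;
        # at exactly 2-fold the observed fold straddles the threshold, so
        # only the direction of the calls that fire is asserted
        rng = np.random.default_rng(5)
        n = 200
        rec = pd.DataFrame({
            "kmer": [f"K{i}" for i in range(n)],
            "count_A": rng.poisson(500, size=n),
            "count_B": rng.poisson(200, size=n)})
        out = dd.call_differential(rec, 1e6, 1e6)
        assert (out["call"] == "A-gain").mean() >= 0.95
        rec2 = rec.assign(count_A=rng.poisson(400, size=n))
        out2 = dd.call_differential(rec2, 1e6, 1e6)
        called = out2[out2["call"] != "nonsignificant"]
        assert len(called) and (called["call"] == "A-gain").all()


class TestGenotypeSpecific:
    def test_low_genotype_bound_from_thresholds(self):
        ta = _table({"AAAAC": 19_991})
        tb = _table({"AAAAC": 9})
        rec = dd.extract_hakmers(ta, tb, 20_000)
        out = dd.classify_genotype_specific(rec, max_low=10)
        assert out["call"].iloc[0] == "A-specific"

    def test_balanced_counts_not_specific(self):
        rec = pd.DataFrame({"kmer": ["AAAAC"], "count_A": [10_000],
                            "count_B": [10_000], "call": ["nonsignificant"]})
        out = dd.classify_genotype_specific(rec, max_low=10)
        assert out["call"].iloc[0] == "nonsignificant"

    def test_exact_double_boundary(self):
        # (10, 19,990): total 20,000 qualifies and count_A = 10 <= 10
        ta = _table({"AAAAC": 10})
        tb = _table({"AAAAC": 19_990})
        rec = dd.extract_hakmers(ta, tb, 20_000)
        out = dd.classify_genotype_specific(rec, max_low=10)
        assert out["call"].iloc[0] == "B-specific"

    def test_scaled_min_total_tracks_depth(self):
        assert dd.scaled_min_total(92.0) == 20_000
        assert dd.scaled_min_total(46.0) == 10_000


def _toy_library():
    rng = np.random.default_rng(11)
    centc = "".join(rng.choice(list("ACGT"), size=120))
    knob = "".join(rng.choice(list("ACGT"), size=150))
    return dd.RepeatLibrary([("CentC-1", "CentC", centc),
                             ("knob-1", "knob", knob)])


def _oracle_annotate(q, library, min_seed=12, max_mismatch=2):
    """Exhaustive alignment over every entry, offset, and strand."""
    best = None
    best_class = "unannotated"
    for e_idx, (_, cls, seq) in enumerate(library.entries):
        for strand_q in (q, revcomp(q)):
            for off in range(len(seq) - len(q) + 1):
                ref = seq[off : off + len(q)]
                mism = sum(a != b for a, b in zip(strand_q, ref))
                if mism > max_mismatch:
                    continue
                run = bst = 0
                for a, b in zip(strand_q, ref):
                    run = run + 1 if a == b else 0
                    bst = max(bst, run)
                if bst < min_seed:
                    continue
                key = (mism, -bst, e_idx)
                if best is None or key < best:
                    best, best_class = key, cls
    return best_class


class TestAnnotation:
    def test_exact_slice_hits_its_class(self):
        lib = _toy_library()
        q = lib.entries[0][2][40:65]
        assert dd.annotate_kmers([q], lib)[q] == "CentC"

    def test_reverse_complement_slice_hits(self):
        lib = _toy_library()
        q = revcomp(lib.entries[1][2][10:35])
        assert dd.annotate_kmers([q], lib)[q] == "knob"

    def test_fewest_mismatches_wins(self):
        lib = _toy_library()
        q = list(lib.entries[1][2][50:75])
        q[12] = "A" if q[12] != "A" else "C"  # one substitution vs knob
        q = "".join(q)
        result = dd.annotate_kmers([q], lib)[q]
        assert result == _oracle_annotate(q, lib) == "knob"

    def test_random_kmers_match_exhaustive_oracle(self):
        lib = _toy_library()
        rng = np.random.default_rng(12)
        queries = []
        for _ in range(30):
            src = lib.entries[rng.integers(0, 2)][2]
            off = int(rng.integers(0, len(src) - 25))
            q = list(src[off : off + 25])
            for _ in range(int(rng.integers(0, 4))):
                q[int(rng.integers(0, 25))] = "ACGT"[int(rng.integers(0, 4))]
            queries.append("".join(q))
        queries += ["".join(rng.choice(list("ACGT"), size=25))
                    for _ in range(10)]
        got = dd.annotate_kmers(queries, lib)
        for q in queries:
            assert got[q] == _oracle_annotate(q, lib)

    def test_unrelated_kmer_unannotated(self):
        lib = _toy_library()
        q = "AC" * 12 + "G"
        assert dd.annotate_kmers([q], lib)[q] == _oracle_annotate(q, lib)


class TestReferenceMapping:
    def test_single_forward_occurrence(self):
        ref = {"chr1": "TTTTTACGTACGTACGTACGTACGTACTTTTT"}
        q = "ACGTACGTACG"
        hits, _ = dd.map_kmers_to_reference([q], ref, min_bin_hits=0)
        assert (hits["kmer"] == q).sum() >= 1

    def test_palindrome_reported_once_per_position(self):
        q = "ACGCGT"  # its own reverse complement
        ref = {"chr1": "TTTTT" + q + "TTTTT"}
        hits, _ = dd.map_kmers_to_reference([q], ref, min_bin_hits=0)
        assert len(hits) == 1 and hits["start"].iloc[0] == 6

    def test_planted_repeat_matches_brute_force_scan(self):
        rng = np.random.default_rng(13)
        unit = "".join(rng.choice(list("ACGT"), size=25))
        ref = {}
        planted = 0
        for c in range(3):
            parts = []
            for _ in range(rng.integers(10, 20)):
                parts.append("".join(rng.choice(list("ACGT"), size=200)))
                parts.append(unit)
                planted += 1
            ref[f"chr{c + 1}"] = "".join(parts)
        hits, bins = dd.map_kmers_to_reference([unit], ref, bin_size=1000,
                                               min_bin_hits=0)
        # brute-force scan both strands
        expect = 0
        for seq in ref.values():
            expect += seq.count(unit) + seq.count(revcomp(unit))
        assert len(hits) == expect == planted
        brute_bins = {}
        for chrom, seq in ref.items():
            i = seq.find(unit)
            while i != -1:
                key = (chrom, (i // 1000) * 1000)
                brute_bins[key] = brute_bins.get(key, 0) + 1
                i = seq.find(unit, i + 1)
        got = {(r["chrom"], r["bin_start"]): r["hits"]
               for _, r in bins.iterrows()}
        assert got == brute_bins


class TestClassAbundanceSummary:
    def _records(self):
        return pd.DataFrame({
            "kmer": ["K1", "K2", "K3"],
            "count_A": [100, 0, 50],
            "count_B": [171, 80, 50],
            "annotation": ["CentC", "knob", "telomere"]})

    def test_equal_normalized_counts_unit_ratio(self):
        out = dd.class_abundance_summary(self._records(),
                                         ["CentC", "knob", "telomere"])
        row = out.set_index("class").loc["telomere"]
        assert row["ratio_B_over_A"] == 1.0

    def test_zero_a_count_flagged_infinite(self):
        out = dd.class_abundance_summary(self._records(),
                                         ["CentC", "knob", "telomere"])
        row = out.set_index("class").loc["knob"]
        assert np.isinf(row["ratio_B_over_A"])

    def test_record_outside_vocabulary_rejected(self):
        rec = self._records()
        rec.loc[0, "annotation"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            dd.class_abundance_summary(rec, ["CentC", "knob", "telomere"])

    def test_planted_copy_ratio_recovered(self, centc_genomes, centc_tables):
        genomes, fams = centc_genomes
        ta, tb = centc_tables["A"], centc_tables["B"]
        rec = dd.extract_hakmers(ta, tb, 200)
        lib = dd.RepeatLibrary([("CentC-1", "CentC", fams[0].unit_seq)])
        ann = dd.annotate_kmers(list(rec["kmer"]), lib)
        rec["annotation"] = rec["kmer"].map(ann)
        out = dd.class_abundance_summary(
            rec, ["CentC"], 1.0 / ta.total_instances,
            1.0 / tb.total_instances)
        assert out["ratio_B_over_A"].iloc[0] == pytest.approx(1.71, rel=0.05)
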
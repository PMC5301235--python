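"""Desk-scale end-to-end synthetic pipeline.

``run_demo`` exercises every stage on simulated data: two parental
genotypes differing in repeat copy number and SNVs; shotgun reads;
canonical k-mer counting and spectra; HAKmer extraction, chi-square
differential calls, genotype-specific classification, and repeat-class
annotation; a DH panel with conserved single-copy normalization and
cnvQTL mapping; a grouped multi-line panel with highly-variable
filtering, ANOVA, mixture clustering, and PCA; and paired polymorphic
k-mer allelic expression. All artifacts are written as TSV/FASTA/FASTQ
under the output directory with a JSON manifest of parameters, seeds,
and output hashes; identical seeds reproduce identical bytes.

Problem sizes are chosen for a single CPU at desk scale (a few hundred
kilobases of genome, a few-fold read depth); thresholds that the
published analysis states for ~46x whole-genome data (HAKmer total
20,000; >1000/<10 variable filter) are rescaled through the config to
the simulated depth, as the spec of each stage allows.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import cnvqtl as cnvqtl_mod
from . import differential as diff_mod
from . import io as kio
from . import kmers as kmers_mod
from . import normalize as norm_mod
from . import simulate as sim
from . import trends as trends_mod
from .config import PipelineConfig

__all__ = ["run_demo"]


def _demo_families(backbone: int):
    rdna_a = sim.rdna_like({"A": 6, "B": 0}, placement=(0, backbone // 3),
                           name="rDNA45S_A")
    # genotype B carries the same unit with a single substitution in the
    # 26S gene span: the planted allelic SNV
    s, _ = rdna_a.sub_span("gene26S")
    pos = s + 1700 - 1
    unit_b = rdna_a.unit_seq
    alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[unit_b[pos]]
    unit_b = unit_b[:pos] + alt + unit_b[pos + 1:]
    rdna_b = sim.RepeatFamilySpec("rDNA45S_B", unit_b, {"A": 0, "B": 4},
                                  placement=(0, backbone // 3 + 60_000),
                                  substructure=rdna_a.substructure)
    return [
        sim.telomere_like({"A": 60, "B": 45}, placement=(0, 1_000)),
        sim.centc_like({"A": 100, "B": 171}, placement=(0, backbone // 2)),
        sim.knob_like({"A": 90, "B": 45}, placement=(0, 2 * backbone // 3)),
        rdna_a,
        rdna_b,
    ]


def _write(outdir: Path, name: str, writer, *args) -> Path:
    path = outdir / name
    writer(path, *args)
    return path


def run_demo(outdir, seed: int = 7, config: PipelineConfig | None = None,
             backbone: int = 300_000, depth: float = 8.0,
             read_len: int = 100) -> dict:
    """Run the full synthetic pipeline; returns a summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig(
        seed=seed, hakmer_min_total=200, scale_min_total_to_depth=False,
        hv_high=100.0, hv_low=10.0, n_perm=200, min_count_filter=2)
    summary: dict = {"seed": seed, "params": cfg.to_dict()}

    # --- two genotypes, reads, counting -----------------------------------
    families = _demo_families(backbone)
    genomes = sim.simulate_repeat_genome(backbone, families, snv_rate=0.002,
                                         seed=cfg.seed_for("genome"))
    tables, spectra = {}, {}
    for g in ("A", "B"):
        kio.write_fasta(outdir / f"genome_{g}.fasta", genomes[g].sequences)
        reads = sim.simulate_reads(genomes[g], depth, read_len,
                                   error_rate=0.002,
                                   seed=cfg.seed_for(f"reads{g}"),
                                   sample_id=g)
        reads.write_fastq(outdir / f"reads_{g}.fastq")
        tables[g] = kmers_mod.count_kmers(reads, cfg.k,
                                          min_count_filter=cfg.min_count_filter,
                                          sample_id=g)
        kio.write_count_table(outdir / f"counts_{g}.tsv", tables[g])
        spec = kmers_mod.spectrum(tables[g])
        kmers_mod.find_peak_and_trough(spec)
        kmers_mod.estimate_genome_size(spec)
        kmers_mod.single_copy_band(spec, cfg.band_lo_frac, cfg.band_hi_frac,
                                   override=cfg.band_override())
        kio.write_spectrum(outdir / f"spectrum_{g}.tsv", spec)
        spectra[g] = spec
    sharing = kmers_mod.sharing_summary(
        tables["A"], tables["B"], spectra["A"].single_copy_band,
        spectra["B"].single_copy_band)
    summary["genome_size_estimates"] = {
        g: spectra[g].genome_size_estimate for g in spectra}
    summary["sharing"] = sharing

    # --- differential HAKmers ---------------------------------------------
    min_total = cfg.effective_min_total()
    records = diff_mod.extract_hakmers(tables["A"], tables["B"], min_total)
    lib_a = tables["A"].total_instances
    lib_b = tables["B"].total_instances
    records = diff_mod.call_differential(records, lib_a, lib_b,
                                         fdr=cfg.fdr, min_fold=cfg.min_fold)
    records = diff_mod.classify_genotype_specific(records,
                                                  cfg.specific_max_low)
    library = diff_mod.RepeatLibrary(
        [(f.name, f.name.split("_")[0], f.unit_seq) for f in families])
    ann = diff_mod.annotate_kmers(list(records["kmer"]), library)
    records["annotation"] = records["kmer"].map(ann)
    kio.write_tsv(outdir / "hakmers.tsv", records.drop(columns=["code"]),
                  {"min_total": min_total, "fdr": cfg.fdr,
                   "min_fold": cfg.min_fold})
    class_summary = diff_mod.class_abundance_summary(
        records, library.classes, 1.0 / lib_a, 1.0 / lib_b)
    kio.write_tsv(outdir / "class_abundance.tsv", class_summary)
    summary["n_hakmers"] = int(len(records))
    summary["calls"] = records["call"].value_counts().to_dict()
    summary["class_ratios"] = dict(zip(class_summary["class"],
                                       class_summary["ratio_B_over_A"]))

    # --- DH panel + cnvQTL -------------------------------------------------
    gmap = sim.make_genetic_map(n_chrom=3, length_cm=100, spacing_cm=2.0)
    cluster_pos = {"CentC": ("chr1", 50.0), "knob180": ("chr2", 30.0)}
    panel = sim.simulate_dh_panel(genomes["A"], genomes["B"], gmap,
                                  n_lines=80, seed=cfg.seed_for("dh"),
                                  cluster_positions=cluster_pos)
    kio.write_tsv(outdir / "genetic_map.tsv", gmap)
    kio.write_genotype_matrix(outdir / "dh_genotypes.tsv", panel.genotypes,
                              panel.line_ids, list(gmap["marker_id"]))
    # per-line read sets from mosaic-determined family copy numbers
    fam_by_name = {f.name: f for f in families}
    line_tables = {}
    rng = np.random.default_rng(cfg.seed_for("dh_reads"))
    for li, lid in enumerate(panel.line_ids):
        copies = {f.name: f.copies_per_genotype["A"] for f in families}
        copies.update({fam: int(panel.line_truth.loc[lid, fam])
                       for fam in cluster_pos})
        gt = sim._build_genotype(
            [np.random.default_rng(cfg.seed_for("genome")).integers(
                0, 4, size=backbone).astype(np.uint8)],
            families, copies, [(np.empty(0, np.int64), np.empty(0, np.uint8))],
            apply_alt=False, divergence=0.005,
            rng=np.random.default_rng(int(rng.integers(0, 2**31))),
            genotype=lid,
            dispersed_offsets={f.name: np.zeros(0, np.int64) for f in families})
        reads = sim.simulate_reads(gt, 2.0, read_len,
                                   seed=int(rng.integers(0, 2**31)),
                                   sample_id=lid)
        line_tables[lid] = kmers_mod.count_kmers(reads, cfg.k, sample_id=lid)

    band_a = spectra["A"].single_copy_band
    sc_codes = kmers_mod.select_single_copy(tables["A"], band_a)
    from ._encode import decode_kmers

    cand = decode_kmers(sc_codes[:2000], cfg.k)
    sc_panel = norm_mod.PanelCounts.from_tables(line_tables, cand)
    conserved = norm_mod.select_conserved_single_copy(sc_panel, cfg.top_frac)
    totals = sc_panel.counts.loc[conserved].sum(axis=0)
    factors = norm_mod.normalization_factors(totals)
    kio.write_tsv(outdir / "normalization_factors.tsv",
                  factors.reset_index(names="line"))

    mapped = records[records["call"] != "nonsignificant"]
    chosen = (mapped[mapped["annotation"].isin(["CentC", "knob180"])]
              .groupby("annotation").head(5))
    hak_panel = norm_mod.PanelCounts.from_tables(line_tables,
                                                 list(chosen["kmer"]))
    peak_table, peak_summary = cnvqtl_mod.map_hakmer_set(
        chosen, hak_panel.counts, panel.genotypes, factors, gmap,
        n_perm=cfg.n_perm, alpha=cfg.alpha, declare_min=cfg.declare_min,
        min_peak_gap=cfg.min_peak_gap, max_peaks=cfg.max_peaks,
        seed=cfg.seed_for("perm"))
    kio.write_tsv(outdir / "cnvqtl_peaks.tsv", peak_table)
    kio.write_tsv(outdir / "cnvqtl_summary.tsv", peak_summary)
    summary["cnvqtl_peaks"] = int(len(peak_table))

    # --- grouped panel trends ---------------------------------------------
    trend_fams = [sim.centc_like({}, placement=(0, 30_000)),
                  sim.RepeatFamilySpec("CRM", sim._random_unit(300, 1004),
                                       {}, placement=(0, 60_000)),
                  sim.knob_like({}, placement=(0, 45_000))]
    profiles = {
        "teosinte": {"CentC": (100, 10), "CRM": (20, 5), "knob180": (100, 10)},
        "landrace": {"CentC": (50, 8), "CRM": (45, 8), "knob180": (2, 1)},
        "improved": {"CentC": (25, 5), "CRM": (80, 10), "knob180": (0, 0)},
    }
    psim = sim.simulate_panel(
        {"teosinte": 5, "landrace": 5, "improved": 5}, profiles,
        depth_range=(2.0, 6.0), organelle_fraction_range=(0.0, 0.3),
        seed=cfg.seed_for("panel"), families=trend_fams,
        backbone_length=80_000, read_len=read_len)
    ptables = {lid: kmers_mod.count_kmers(rs, cfg.k, sample_id=lid)
               for lid, rs in psim.read_sets.items()}
    # candidate single-copy k-mers from the panel backbone
    t0 = ptables[psim.line_ids[0]]
    spec0 = kmers_mod.spectrum(t0)
    band0 = kmers_mod.single_copy_band(spec0)
    cand0 = decode_kmers(kmers_mod.select_single_copy(t0, band0)[:1500], cfg.k)
    sc_p = norm_mod.PanelCounts.from_tables(ptables, cand0)
    cons = norm_mod.select_conserved_single_copy(sc_p, cfg.top_frac)
    pfactors = norm_mod.normalization_factors(
        sc_p.counts.loc[cons].sum(axis=0))
    fam_kmers = []
    for f in trend_fams:
        tab = kmers_mod.count_kmers([f.unit_seq + f.unit_seq[:cfg.k - 1]],
                                    cfg.k)
        fam_kmers.extend(tab.kmers()[:40])
    fam_panel = norm_mod.PanelCounts.from_tables(ptables, fam_kmers)
    norm_counts = norm_mod.normalize_panel(fam_panel, pfactors)
    hv = trends_mod.highly_variable_filter(norm_counts, cfg.hv_high,
                                           cfg.hv_n_high, cfg.hv_low,
                                           cfg.hv_n_low)
    groups = pd.Series(psim.groups)
    gpanel = trends_mod.GroupedPanel(norm_counts, groups,
                                     ["teosinte", "landrace", "improved"])
    anova_rows = [(km, *trends_mod.group_anova(norm_counts.loc[km], groups))
                  for km in norm_counts.index]
    anova = pd.DataFrame(anova_rows, columns=["kmer", "F", "p"])
    anova["significant"] = trends_mod.bonferroni(anova["p"], cfg.alpha)
    kio.write_tsv(outdir / "trend_anova.tsv", anova)
    sig = anova.loc[anova["significant"], "kmer"]
    if len(sig) >= 4:
        scaled = trends_mod.scale_profiles(norm_counts.loc[sig])
        model = trends_mod.gmm_cluster(scaled, G_range=range(1, 5),
                                       n_init=4, seed=cfg.seed_for("gmm"))
        fam_ann = pd.Series(
            diff_mod.annotate_kmers(
                list(sig), diff_mod.RepeatLibrary(
                    [(f.name, f.name, f.unit_seq) for f in trend_fams])))
        trend_tab = trends_mod.group_trend_table(model, gpanel, fam_ann)
        kio.write_tsv(outdir / "trend_clusters.tsv",
                      trend_tab.reset_index())
        summary["trend_table"] = {c: trend_tab[c].to_dict()
                                  for c in trend_tab.columns}
    coords, varexp = trends_mod.pca_lines(norm_counts)
    kio.write_tsv(outdir / "pca_lines.tsv", coords.reset_index(names="line"),
                  {"var_explained_PC1": round(float(varexp[0]), 6),
                   "var_explained_PC2": round(float(varexp[1]), 6)})
    summary["n_highly_variable"] = len(hv)
    summary["pca_var_explained_12"] = float(varexp[:2].sum())

    # --- allelic expression -----------------------------------------------
    pairs = ase_mod.find_snv_pairs(tables["A"], tables["B"], min_high=20,
                                   max_other=2)
    summary["n_snv_pairs"] = len(pairs)
    stages = [("0DAP", 2, 0.0), ("3DAP", 2, 0.3), ("7DAP", 2, 1.0),
              ("10DAP", 2, 1.0)]
    meta_rows, count_rows = [], []
    rng_ase = np.random.default_rng(cfg.seed_for("ase"))
    for stage, mat_dose, pat_expr in stages:
        sample = f"BxM_{stage}"
        meta_rows.append((sample, stage, "BxM", "A"))
        for i, pair in enumerate(pairs[:3] or
                                 [ase_mod.KmerPair("A" * 24 + "C",
                                                   "A" * 24 + "G")]):
            m = rng_ase.poisson(mat_dose * 5000)
            p = rng_ase.poisson(1 * 5000 * pat_expr)
            count_rows.append((pair.locus or f"pair{i}", sample,
                               pair.allele_a_kmer, pair.allele_b_kmer, m, p))
    counts = pd.DataFrame(count_rows, columns=["locus", "sample", "kmer_A",
                                               "kmer_B", "count_A", "count_B"])
    meta = pd.DataFrame(meta_rows, columns=["sample", "stage", "cross",
                                            "maternal_allele"]).set_index("sample")
    ratios = ase_mod.parental_ratio_timecourse(counts, meta)
    kio.write_tsv(outdir / "ase_ratios.tsv", ratios)
    summary["ase_ratios"] = {
        f"{r.cross}_{r.stage}": (r.ratio if np.isfinite(r.ratio) else "inf")
        for r in ratios.itertuples()}

    # --- manifest -----------------------------------------------------------
    outputs = sorted(p.name for p in outdir.iterdir()
                     if p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "params": cfg.to_dict(),
        "outputs": {name: hashlib.sha256(
            (outdir / name).read_bytes()).hexdigest() for name in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    summary["manifest"] = manifest["outputs"]
    return summary
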
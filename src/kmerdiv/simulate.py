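"""Synthetic genomes, populations, shotgun reads, and allelic transcript counts.

This module generates data with the statistical structure the k-mer
analyses assume: two parental genotypes sharing a random backbone but
differing in copy number of clustered tandem-repeat families (a
centromeric-satellite-like family, knob-like families, a 45S-rDNA-like
unit with IGS/ITS/gene substructure, a telomere motif) and in single-copy
SNVs; uniform shotgun reads with i.i.d. substitution errors; a doubled
haploid (DH) population whose lines are mosaics of the two parental
genomes, segregating the repeat clusters on a supplied genetic map; a
multi-line panel in labeled evolutionary groups with varying library
sizes and organelle contamination; and Poisson-distributed allelic
transcript counts for a triploid endosperm-like tissue.

Coordinates in truth records are 1-based inclusive. Identical seeds
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._encode import _CODE_BASE, encode_seq

__all__ = [
    "RepeatFamilySpec",
    "GenomeTruth",
    "ReadSet",
    "DHPanel",
    "PanelSim",
    "centc_like",
    "knob_like",
    "telomere_like",
    "rdna_like",
    "organelle_sequence",
    "make_genetic_map",
    "simulate_repeat_genome",
    "simulate_reads",
    "simulate_dh_genotypes",
    "simulate_dh_panel",
    "simulate_panel",
    "simulate_allelic_counts",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RepeatFamilySpec:
    """One tandem-repeat family and its per-genotype copy numbers.

    ``placement`` is either ``(chrom_index, offset)`` for a clustered
    family inserted head-to-tail at one backbone locus, or the string
    ``"dispersed"`` for copies scattered individually. ``substructure``
    optionally names sub-spans of the unit (1-based inclusive) that must
    tile the unit without overlap, e.g. the IGS/ITS/gene anatomy of an
    rDNA unit.
    """

    name: str
    unit_seq: str
    copies_per_genotype: dict[str, int]
    placement: tuple[int, int] | str = "dispersed"
    substructure: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        u = self.unit_seq.upper()
        if not u or set(u) - set("ACGT"):
            raise ValueError(f"family {self.name}: unit_seq must be non-empty ACGT")
        self.unit_seq = u
        for g, c in self.copies_per_genotype.items():
            if c < 0:
                raise ValueError(f"family {self.name}: copies for {g} negative")
        if self.substructure is not None:
            spans = sorted(self.substructure, key=lambda s: s[1])
            cursor = 1
            for nm, start, end in spans:
                if start != cursor or end < start:
                    raise ValueError(
                        f"family {self.name}: substructure spans must tile the "
                        f"unit without overlap (bad span {nm} [{start},{end}])"
                    )
                cursor = end + 1
            if cursor != len(u) + 1:
                raise ValueError(
                    f"family {self.name}: substructure does not cover the unit"
                )

    def sub_span(self, name: str) -> tuple[int, int]:
        for nm, s, e in self.substructure or []:
            if nm == name:
                return s, e
        raise KeyError(name)


@dataclass
class GenomeTruth:
    """A simulated genotype: sequences plus a record of what was planted."""

    genotype: str
    sequences: dict[str, str]
    family_copy_number: dict[str, int]
    snv_positions: list[tuple[str, int, str, str]]
    placements: pd.DataFrame  # family, chrom, start, end, copies (1-based)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class ReadSet:
    """Simulated shotgun reads (uniform start positions, both strands)."""

    names: list[str]
    sequences: list[str]
    sample_id: str = ""

    @property
    def n_reads(self) -> int:
        return len(self.sequences)

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.sequences)

    def write_fastq(self, path) -> None:
        from .io import write_fastq

        write_fastq(path, zip(self.names, self.sequences))


@dataclass
class DHPanel:
    """A doubled-haploid population: map, genotype mosaic, per-line truth.

    ``genotypes`` is lines x markers with 0 = parent-A allele and
    1 = parent-B allele (DH lines are fully homozygous, so one code per
    marker suffices). ``line_truth`` carries the per-line copy number of
    each segregating repeat family.
    """

    gmap: pd.DataFrame  # chrom, cM, marker_id
    genotypes: np.ndarray  # int8 (n_lines, n_markers), 0=A 1=B
    line_ids: list[str]
    line_truth: pd.DataFrame | None = None

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    def genotypes_df(self) -> pd.DataFrame:
        """Genotype matrix with A/B letter codes (lines x marker_id)."""
        letters = np.array(["A", "B"])[self.genotypes]
        return pd.DataFrame(letters, index=self.line_ids,
                            columns=self.gmap["marker_id"].tolist())


@dataclass
class PanelSim:
    """A simulated multi-line panel in labeled evolutionary groups."""

    line_ids: list[str]
    groups: dict[str, str]  # line -> group label
    read_sets: dict[str, ReadSet]
    truth: pd.DataFrame  # line, family, copies
    depths: dict[str, float]
    organelle_fractions: dict[str, float]
    genomes: dict[str, GenomeTruth] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stock repeat families


def _random_unit(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return _CODE_BASE[rng.integers(0, 4, size=length)].tobytes().decode()


def centc_like(copies: dict[str, int], placement=(0, 500_000),
               name: str = "CentC") -> RepeatFamilySpec:
    """156-bp centromeric-satellite-like tandem unit."""
    return RepeatFamilySpec(name, _random_unit(156, 1001), dict(copies), placement)


def knob_like(copies: dict[str, int], placement=(0, 1_200_000),
              name: str = "knob180") -> RepeatFamilySpec:
    """180-bp knob-like tandem unit."""
    return RepeatFamilySpec(name, _random_unit(180, 1002), dict(copies), placement)


def telomere_like(copies: dict[str, int], placement=(0, 0),
                  name: str = "telomere") -> RepeatFamilySpec:
    """Telomere motif TTTAGGG repeated to a 70-bp unit."""
    return RepeatFamilySpec(name, "TTTAGGG" * 10, dict(copies), placement)


def rdna_like(copies: dict[str, int], placement=(0, 300_000),
              name: str = "rDNA45S") -> RepeatFamilySpec:
    """9-kb 45S-rDNA-like unit with 18S/ITS1/5.8S/ITS2/26S/IGS sub-spans.

    The named substructure lets callers plant genotype-specific IGS
    variants or a single SNV inside the 26S gene span.
    """
    return RepeatFamilySpec(
        name,
        _random_unit(9000, 1003),
        dict(copies),
        placement,
        substructure=[
            ("gene18S", 1, 1800),
            ("ITS1", 1801, 2100),
            ("gene5.8S", 2101, 2260),
            ("ITS2", 2261, 2560),
            ("gene26S", 2561, 5960),
            ("IGS", 5961, 9000),
        ],
    )


def organelle_sequence(length: int = 150_000, seed: int = 909) -> str:
    """A plasmid-like circular organelle stand-in (fixed random sequence)."""
    return _random_unit(length, seed)


def make_genetic_map(n_chrom: int = 10, length_cm: float = 140.0,
                     spacing_cm: float = 1.0) -> pd.DataFrame:
    """Evenly spaced marker map: columns chrom, cM, marker_id."""
    rows = []
    for c in range(1, n_chrom + 1):
        pos = np.arange(0.0, length_cm + 1e-9, spacing_cm)
        for p in pos:
            rows.append((f"chr{c}", float(p), f"m{c}_{p:g}"))
    return pd.DataFrame(rows, columns=["chrom", "cM", "marker_id"])


# ---------------------------------------------------------------------------
# genome construction


def _diverged_copies(unit_codes: np.ndarray, n: int, rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Concatenate n tandem copies, each with i.i.d. substitutions at `rate`."""
    tiled = np.tile(unit_codes, n)
    if rate > 0 and n > 0:
        mask = rng.random(tiled.size) < rate
        shift = rng.integers(1, 4, size=int(mask.sum()))
        tiled[mask] = (tiled[mask] + shift) % 4
    return tiled


def _build_genotype(
    backbones: list[np.ndarray],
    families: Sequence[RepeatFamilySpec],
    copies: Mapping[str, int],
    snv_tables: list[tuple[np.ndarray, np.ndarray]],
    apply_alt: bool,
    divergence: float,
    rng: np.random.Generator,
    genotype: str,
    dispersed_offsets: Mapping[str, np.ndarray],
) -> GenomeTruth:
    chrom_codes = [b.copy() for b in backbones]
    snv_records: list[tuple[str, int, str, str]] = []
    # apply SNVs on backbone coordinates first; cluster insertion shifts later
    for ci, (pos, alt) in enumerate(snv_tables):
        ref = backbones[ci][pos]
        if apply_alt:
            chrom_codes[ci][pos] = alt
        for p, r, a in zip(pos, ref, alt):
            snv_records.append((f"chr{ci + 1}", int(p) + 1,
                                _CODE_BASE[r:r + 1].tobytes().decode(),
                                _CODE_BASE[a:a + 1].tobytes().decode()))

    # collect insertions per chromosome: (offset_in_backbone, family, block)
    inserts: dict[int, list[tuple[int, str, np.ndarray]]] = {}
    for fam in families:
        n = int(copies.get(fam.name, fam.copies_per_genotype.get(genotype, 0)))
        unit_codes = encode_seq(fam.unit_seq)
        if fam.placement == "dispersed":
            offs = dispersed_offsets[fam.name][:n]
            for off in offs:
                block = _diverged_copies(unit_codes, 1, divergence, rng)
                ci = int(off) >> 32
                inserts.setdefault(ci, []).append((int(off) & 0xFFFFFFFF,
                                                   fam.name, block))
        else:
            ci, off = fam.placement
            if off > backbones[ci].size:
                raise ValueError(
                    f"family {fam.name}: offset {off} beyond backbone")
            block = _diverged_copies(unit_codes, n, divergence, rng)
            if n > 0:
                inserts.setdefault(ci, []).append((int(off), fam.name, block))

    sequences: dict[str, str] = {}
    placements = []
    fam_copy = {f.name: int(copies.get(f.name,
                f.copies_per_genotype.get(genotype, 0))) for f in families}
    for ci, codes in enumerate(chrom_codes):
        chrom = f"chr{ci + 1}"
        ins = sorted(inserts.get(ci, []), key=lambda t: t[0])
        pieces, cursor, shift = [], 0, 0
        for off, fam_name, block in ins:
            pieces.append(codes[cursor:off])
            start = off + shift + 1  # 1-based
            pieces.append(block)
            placements.append((fam_name, chrom, start, start + block.size - 1,
                               fam_copy[fam_name]))
            shift += block.size
            cursor = off
        pieces.append(codes[cursor:])
        final = np.concatenate(pieces) if pieces else codes
        sequences[chrom] = _CODE_BASE[final].tobytes().decode()

    # shift SNV coordinates by insertions upstream of each SNV
    shifted_snvs = []
    for chrom, pos1, ref, alt in snv_records:
        ci = int(chrom[3:]) - 1
        shift = sum(b.size for off, _, b in sorted(inserts.get(ci, []),
                    key=lambda t: t[0]) if off < pos1)
        shifted_snvs.append((chrom, pos1 + shift, ref, alt))

    pl = pd.DataFrame(placements,
                      columns=["family", "chrom", "start", "end", "copies"])
    return GenomeTruth(genotype, sequences, fam_copy, shifted_snvs, pl)


def simulate_repeat_genome(
    backbone_length: int,
    families: Sequence[RepeatFamilySpec],
    snv_rate: float,
    seed: int,
    genotypes: tuple[str, str] = ("A", "B"),
    n_chrom: int = 1,
    per_copy_divergence: float = 0.005,
) -> dict[str, GenomeTruth]:
    """Build one genome per genotype from a shared random backbone.

    Both genotypes share the backbone; they differ at SNV positions
    (drawn at ``snv_rate`` per backbone base; the first genotype carries
    the reference allele) and in the copy number of each repeat family.
    Clustered families are inserted as head-to-tail tandem arrays whose
    copies carry ``per_copy_divergence`` i.i.d. substitutions.
    """
    longest = max(len(f.unit_seq) for f in families) if families else 1
    if backbone_length < 10 * longest:
        raise ValueError("backbone_length must be >= 10 x longest unit")
    rng = np.random.default_rng(seed)
    backbones = [rng.integers(0, 4, size=backbone_length).astype(np.uint8)
                 for _ in range(n_chrom)]
    snv_tables = []
    for b in backbones:
        pos = np.flatnonzero(rng.random(b.size) < snv_rate)
        alt = ((b[pos] + rng.integers(1, 4, size=pos.size)) % 4).astype(np.uint8)
        snv_tables.append((pos, alt))
    dispersed: dict[str, np.ndarray] = {}
    for fam in families:
        if fam.placement == "dispersed":
            nmax = max(fam.copies_per_genotype.values())
            ci = rng.integers(0, n_chrom, size=nmax).astype(np.int64)
            off = rng.integers(0, backbone_length, size=nmax).astype(np.int64)
            dispersed[fam.name] = (ci << 32) | off
    out = {}
    for gi, g in enumerate(genotypes):
        grng = np.random.default_rng(seed * 1_000_003 + 17 * gi + 1)
        out[g] = _build_genotype(
            backbones, families,
            {f.name: f.copies_per_genotype.get(g, 0) for f in families},
            snv_tables, apply_alt=(gi > 0), divergence=per_copy_divergence,
            rng=grng, genotype=g, dispersed_offsets=dispersed)
    return out


# ---------------------------------------------------------------------------
# reads


def _sequences_from_matrix(mat: np.ndarray) -> list[str]:
    flat = _CODE_BASE[mat].tobytes().decode("ascii")
    L = mat.shape[1]
    return [flat[i * L:(i + 1) * L] for i in range(mat.shape[0])]


def simulate_reads(
    genome: GenomeTruth | Mapping[str, str] | str,
    depth: float,
    read_len: int = 125,
    error_rate: float = 0.0,
    paired: bool = False,
    seed: int = 0,
    sample_id: str = "",
    insert_len: int | None = None,
) -> ReadSet:
    """Uniform shotgun reads from both strands with i.i.d. substitution errors.

    Total sequenced bases are ``round(depth * genome_length / read_len)``
    reads of ``read_len`` bases (within one read of ``depth x length``).
    With ``paired`` the reads are drawn as R1/R2 ends of fragments of
    ``insert_len`` (default 3 x read_len).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if isinstance(genome, GenomeTruth):
        seqs = genome.sequences
    elif isinstance(genome, str):
        seqs = {"chr1": genome}
    else:
        seqs = dict(genome)
    chroms = list(seqs)
    arrays = [encode_seq(seqs[c]) for c in chroms]
    lengths = np.array([a.size for a in arrays])
    total_len = int(lengths.sum())
    if read_len > lengths.min():
        raise ValueError("read_len exceeds a chromosome length")
    rng = np.random.default_rng(seed)

    frag_len = read_len
    if paired:
        frag_len = insert_len or 3 * read_len
        frag_len = min(frag_len, int(lengths.min()))
    n_frag = max(1, round(depth * total_len / read_len / (2 if paired else 1)))

    n_starts = lengths - frag_len + 1
    chrom_idx = rng.choice(len(chroms), size=n_frag, p=n_starts / n_starts.sum())
    starts = (rng.random(n_frag) * n_starts[chrom_idx]).astype(np.int64)
    offsets = np.concatenate(([0], np.cumsum(lengths)))[:-1]
    big = np.concatenate(arrays)
    flip = rng.random(n_frag) < 0.5

    def _extract(start_abs: np.ndarray) -> np.ndarray:
        return big[start_abs[:, None] + np.arange(read_len)]

    abs_start = offsets[chrom_idx] + starts
    if paired:
        r1 = _extract(abs_start)
        r2 = _extract(abs_start + frag_len - read_len)
        r2 = 3 - r2[:, ::-1]  # mate on opposite strand
        # fragment orientation: flip swaps which end is forward
        r1[flip] = 3 - r1[flip][:, ::-1]
        r2[flip] = 3 - r2[flip][:, ::-1]
        mat = np.empty((2 * n_frag, read_len), dtype=np.uint8)
        mat[0::2], mat[1::2] = r1, r2
        names = [f"{sample_id or 'read'}_{i}/{j}" for i in range(n_frag)
                 for j in (1, 2)]
    else:
        mat = _extract(abs_start)
        mat[flip] = 3 - mat[flip][:, ::-1]
        names = [f"{sample_id or 'read'}_{i}" for i in range(n_frag)]

    if error_rate > 0:
        mask = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=int(mask.sum()))
        mat[mask] = (mat[mask] + shift) % 4
    return ReadSet(names, _sequences_from_matrix(mat), sample_id=sample_id)


# ---------------------------------------------------------------------------
# populations


def haldane_r(d_cm: float) -> float:
    """Haldane map function: recombination fraction for d centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def simulate_dh_genotypes(gmap: pd.DataFrame, n_lines: int,
                          seed: int = 0) -> np.ndarray:
    """DH genotype mosaic (0=A, 1=B) under Haldane crossovers, no interference.

    Each line starts each chromosome in either parental phase with
    probability 1/2 and switches phase between adjacent markers with the
    Haldane recombination fraction of their cM distance.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    rng = np.random.default_rng(seed)
    cols = []
    for _, sub in gmap.groupby("chrom", sort=False):
        cm = sub["cM"].to_numpy()
        if np.any(np.diff(cm) < 0):
            raise ValueError("cM positions must be non-decreasing per chromosome")
        g = (rng.random(n_lines) < 0.5).astype(np.int8)
        cols.append(g.copy())
        for d in np.diff(cm):
            switch = rng.random(n_lines) < haldane_r(float(d))
            g = g ^ switch.astype(np.int8)
            cols.append(g.copy())
    return np.column_stack(cols)


def simulate_dh_panel(
    parent_a: GenomeTruth,
    parent_b: GenomeTruth,
    gmap: pd.DataFrame,
    n_lines: int,
    seed: int = 0,
    cluster_positions: Mapping[str, tuple[str, float]] | None = None,
) -> DHPanel:
    """A DH population segregating the parents' repeat clusters.

    ``cluster_positions`` maps family name -> (chrom, cM) locus on the
    genetic map; a line's copy number for a clustered family is that of
    the parent whose mosaic block covers the locus (genotype at the
    nearest marker).
    """
    genotypes = simulate_dh_genotypes(gmap, n_lines, seed)
    line_ids = [f"DH{i + 1:03d}" for i in range(n_lines)]
    line_truth = None
    if cluster_positions:
        data = {}
        for fam, (chrom, cm) in cluster_positions.items():
            sub = gmap.index[gmap["chrom"] == chrom]
            if len(sub) == 0:
                raise ValueError(f"cluster chromosome {chrom} not on the map")
            j = sub[np.argmin(np.abs(gmap.loc[sub, "cM"].to_numpy() - cm))]
            col = genotypes[:, gmap.index.get_loc(j)]
            ca = parent_a.family_copy_number.get(fam, 0)
            cb = parent_b.family_copy_number.get(fam, 0)
            data[fam] = np.where(col == 0, ca, cb)
        line_truth = pd.DataFrame(data, index=line_ids)
    return DHPanel(gmap.reset_index(drop=True), genotypes, line_ids, line_truth)


def simulate_panel(
    groups: Mapping[str, int],
    family_abundance_profiles: Mapping[str, Mapping[str, tuple[float, float]]],
    depth_range: tuple[float, float],
    organelle_fraction_range: tuple[float, float],
    seed: int = 0,
    families: Sequence[RepeatFamilySpec] | None = None,
    backbone_length: int = 100_000,
    read_len: int = 100,
    snv_rate: float = 0.0005,
    per_copy_divergence: float = 0.005,
    organelle_length: int = 150_000,
    keep_genomes: bool = False,
) -> PanelSim:
    """Multi-line panel in labeled groups with per-line nuisance variation.

    Each line's genome is the shared backbone plus repeat families whose
    copy numbers are drawn from its group's ``(mean, sd)`` profile
    (rounded normal, truncated at zero); reads are drawn at a depth
    uniform in ``depth_range`` and a fraction uniform in
    ``organelle_fraction_range`` of its reads comes from a separate
    circular organelle-like sequence.
    """
    for g, n in groups.items():
        if n <= 0:
            raise ValueError(f"group {g!r} is empty")
    if families is None:
        families = [centc_like({}, placement=(0, backbone_length // 2))]
    rng = np.random.default_rng(seed)
    backbone = rng.integers(0, 4, size=backbone_length).astype(np.uint8)
    organelle = organelle_sequence(organelle_length,
                                   seed=int(rng.integers(0, 2**31)))

    line_ids, line_group = [], {}
    for g, n in groups.items():
        for i in range(n):
            lid = f"{g}_{i + 1:02d}"
            line_ids.append(lid)
            line_group[lid] = g

    read_sets, depths, org_fracs, genomes = {}, {}, {}, {}
    truth_rows = []
    for lid in line_ids:
        grp = line_group[lid]
        copies = {}
        for fam in families:
            mean, sd = family_abundance_profiles[grp].get(fam.name, (0.0, 0.0))
            copies[fam.name] = max(0, int(round(rng.normal(mean, sd))))
            truth_rows.append((lid, grp, fam.name, copies[fam.name]))
        snv_pos = np.flatnonzero(rng.random(backbone_length) < snv_rate)
        snv_alt = ((backbone[snv_pos] +
                    rng.integers(1, 4, size=snv_pos.size)) % 4).astype(np.uint8)
        gt = _build_genotype(
            [backbone], families, copies, [(snv_pos, snv_alt)],
            apply_alt=True, divergence=per_copy_divergence,
            rng=np.random.default_rng(int(rng.integers(0, 2**31))),
            genotype=lid, dispersed_offsets={
                f.name: np.zeros(0, dtype=np.int64) for f in families},
        )
        depth = float(rng.uniform(*depth_range))
        frac = float(rng.uniform(*organelle_fraction_range))
        nuclear = simulate_reads(gt, depth * (1 - frac), read_len,
                                 seed=int(rng.integers(0, 2**31)),
                                 sample_id=lid)
        reads = nuclear
        if frac > 0:
            # organelle reads proportional to the contaminated share of the
            # library; doubled sequence emulates circularity
            org_depth = depth * frac * gt.total_length / (2 * organelle_length)
            org = simulate_reads(organelle + organelle, max(org_depth, 1e-9),
                                 read_len, seed=int(rng.integers(0, 2**31)),
                                 sample_id=f"{lid}_org")
            reads = ReadSet(nuclear.names + org.names,
                            nuclear.sequences + org.sequences, sample_id=lid)
        read_sets[lid] = reads
        depths[lid], org_fracs[lid] = depth, frac
        if keep_genomes:
            genomes[lid] = gt

    truth = pd.DataFrame(truth_rows, columns=["line", "group", "family", "copies"])
    return PanelSim(line_ids, line_group, read_sets, truth, depths,
                    org_fracs, genomes)


# ---------------------------------------------------------------------------
# allelic transcript counts


def simulate_allelic_counts(
    maternal_dosage: int,
    paternal_dosage: int,
    per_copy_rate: float,
    n_pairs: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson allelic counts for paired polymorphic k-mers.

    Maternal and paternal counts are independent
    ``Poisson(dosage x per_copy_rate)`` per pair, emulating a triploid
    endosperm-like tissue (2 maternal : 1 paternal genome dosage) with
    equal per-copy transcription.
    """
    if maternal_dosage < 0 or paternal_dosage < 0:
        raise ValueError("dosages must be >= 0")
    if maternal_dosage == 0 and paternal_dosage == 0:
        raise ValueError("at least one dosage must be positive")
    if per_copy_rate <= 0:
        raise ValueError("per_copy_rate must be positive")
    rng = np.random.default_rng(seed)
    m = rng.poisson(maternal_dosage * per_copy_rate, size=n_pairs)
    p = rng.poisson(paternal_dosage * per_copy_rate, size=n_pairs)
    return pd.DataFrame({
        "pair": [f"pair{i + 1}" for i in range(n_pairs)],
        "maternal": m.astype(np.int64),
        "paternal": p.astype(np.int64),
    })
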
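"""Synthetic fixtures with known truth: a small genome carrying inverted
Alu-like repeat pairs, site catalogs, heterozygous SNPs, RNA/WGS reads with
programmed per-site editing levels, base-call errors, and hyper-edited
reads emitted as unmapped records.

The generator emulates the structure that makes A-to-I detection hard on
real data — editing concentrated in inverted repeats, SNPs masquerading as
edits, sequencing noise, and heavily edited reads that defeat a normal
aligner — at a scale where every expected value can be recounted exactly.
Reads are uniform over the genome (no transcript structure, no splicing,
no coverage bias), so tests exercise the calling and quantification
machinery, not alignment realism.

Defaults pin the study conditions used throughout the test suite: 200×
RNA depth, uniform programmed level 0.15 at catalog sites (Beta(1,9)
per-site levels for the Alu-region AEI checks), 30× WGS depth,
heterozygous alt probability 0.5 in both RNA and WGS, base error rate
1e-3, 100 bp reads at phred 40, and hyper reads edited at ≥60% of their
adenosines. Everything is deterministic under the mandatory seed; each
stage draws from its own spawned substream so adding a stage never
perturbs earlier ones.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from edikit.formats_io import (
    GenomeRef,
    RegionSet,
    SiteCatalog,
    SiteCatalogEntry,
    SnpSet,
)
from edikit.hyper_editing import revcomp

_BASES = "ACGT"


@dataclass
class SimConfig:
    seed: int  # mandatory; there is no default on purpose
    genome_length: int = 50_000
    chrom: str = "chrS"
    n_alu_pairs: int = 2
    alu_length: int = 300
    alu_divergence: float = 0.05  # per-copy substitution rate vs the consensus
    n_editing_sites: int = 30
    edit_all_alu_adenosines: bool = False  # AEI mode: every repeat A is a site
    level_dist: tuple = ("fixed", 0.15)  # or ("beta", a, b)
    n_recoding_sites: int = 5
    recoding_level: float = 0.4
    n_het_snps: int = 10
    read_length: int = 100
    depth: float = 200.0
    wgs_depth: float = 30.0
    base_error_rate: float = 1e-3
    low_qual_fraction: float = 0.0
    n_hyper_reads: int = 20
    hyper_fraction: float = 0.6
    n_multimap_reads: int = 0  # extra low-confidence reads at the first site

    def __post_init__(self) -> None:
        for rate in (self.base_error_rate, self.low_qual_fraction, self.hyper_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")


@dataclass
class TruthSite:
    chrom: str
    pos: int  # 0-based
    strand: str
    level: float
    kind: str  # alu | recoding
    gene: Optional[str] = None
    aa_change: Optional[str] = None


@dataclass
class TruthSnp:
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class SimRead:
    name: str
    chrom: str
    pos: int
    seq: str
    quals: list[int]
    is_reverse: bool
    mapq: int = 60
    n_hits: int = 1
    unmapped: bool = False


@dataclass
class SimTruth:
    config: SimConfig
    sites: list[TruthSite] = field(default_factory=list)
    snps: list[TruthSnp] = field(default_factory=list)
    repeat_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    rna_reads: list[SimRead] = field(default_factory=list)
    wgs_reads: list[SimRead] = field(default_factory=list)
    hyper_reads: list[SimRead] = field(default_factory=list)
    hyper_truth: dict[str, tuple[str, int, str, tuple[int, ...]]] = field(default_factory=dict)
    # site tallies from the final emitted sequences: (edited, informative)
    site_tallies: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)

    def catalog(self, include_recoding: bool = True) -> SiteCatalog:
        entries = [
            SiteCatalogEntry(
                s.chrom, s.pos, s.strand,
                recoding=(s.kind == "recoding"),
                aa_change=s.aa_change, gene=s.gene,
            )
            for s in self.sites
            if include_recoding or s.kind != "recoding"
        ]
        return SiteCatalog(entries)

    def snp_set(self) -> SnpSet:
        return SnpSet({(s.chrom, s.pos) for s in self.snps})

    def regions(self) -> RegionSet:
        return RegionSet(self.repeat_intervals)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_genome(cfg: SimConfig) -> tuple[GenomeRef, SimTruth]:
    """Build the genome, repeat annotation, site catalog and SNP truth.

    Repeats are placed as inverted pairs (forward copy + reverse complement)
    with editing sites at adenosines of the repeat in its transcribed sense:
    '+' sites (reference A) in forward copies, '−' sites (reference T) in
    inverted copies. Recoding sites sit outside the repeats on '+'. SNP
    positions are disjoint from all catalog sites.
    """
    rng_genome, rng_sites, rng_snp = _rngs(cfg.seed, 3)
    L = cfg.genome_length
    n_repeats = 2 * cfg.n_alu_pairs
    span_needed = n_repeats * (cfg.alu_length + 200) + 400
    if span_needed > L:
        raise ValueError(f"genome length {L} too small for {n_repeats} repeats")
    seq = list(rng_genome.choice(list(_BASES), size=L))
    # evenly spaced repeat slots; alternate forward / inverted copies
    intervals: list[tuple[str, int, int, str]] = []
    slot = L // n_repeats
    repeat_seq = "".join(rng_genome.choice(list(_BASES), size=cfg.alu_length))
    for i in range(n_repeats):
        start = i * slot + (slot - cfg.alu_length) // 2
        body = list(repeat_seq if i % 2 == 0 else revcomp(repeat_seq))
        # copies diverge from the consensus so each has a unique address
        n_div = int(round(cfg.alu_divergence * cfg.alu_length))
        for p in rng_genome.choice(cfg.alu_length, size=n_div, replace=False):
            body[p] = str(rng_genome.choice([b for b in _BASES if b != body[p]]))
        seq[start:start + cfg.alu_length] = body
        intervals.append((cfg.chrom, start, start + cfg.alu_length, "+" if i % 2 == 0 else "-"))
    genome_seq = "".join(seq)

    truth = SimTruth(config=cfg)
    truth.repeat_intervals = intervals

    # editable adenosines inside repeats, in the repeat's transcribed sense
    candidates: list[tuple[int, str]] = []
    for chrom, start, end, strand in intervals:
        target = "A" if strand == "+" else "T"
        for p in range(start, end):
            if genome_seq[p] == target:
                candidates.append((p, strand))
    if cfg.edit_all_alu_adenosines:
        chosen = np.arange(len(candidates))
    else:
        if cfg.n_editing_sites > len(candidates):
            raise ValueError(
                f"cannot place {cfg.n_editing_sites} editing sites: only "
                f"{len(candidates)} editable positions in repeats"
            )
        chosen = rng_sites.choice(len(candidates), size=cfg.n_editing_sites, replace=False)
    for i in sorted(chosen):
        pos, strand = candidates[i]
        if cfg.level_dist[0] == "fixed":
            level = float(cfg.level_dist[1])
        elif cfg.level_dist[0] == "beta":
            level = float(rng_sites.beta(cfg.level_dist[1], cfg.level_dist[2]))
        else:
            raise ValueError(f"unknown level distribution {cfg.level_dist[0]!r}")
        truth.sites.append(TruthSite(cfg.chrom, pos, strand, level, "alu"))

    taken = {s.pos for s in truth.sites}
    in_repeat = {p for _, st, en, _ in intervals for p in range(st, en)}
    outside_a = [
        p for p in range(L)
        if genome_seq[p] == "A" and p not in in_repeat and p not in taken
    ]
    rec_idx = rng_sites.choice(len(outside_a), size=cfg.n_recoding_sites, replace=False)
    for j, i in enumerate(sorted(rec_idx)):
        pos = outside_a[i]
        taken.add(pos)
        truth.sites.append(
            TruthSite(
                cfg.chrom, pos, "+", cfg.recoding_level, "recoding",
                gene=f"GENE{j + 1}", aa_change=f"K{j + 10}R",
            )
        )

    free = [p for p in range(L) if p not in taken]
    snp_idx = rng_snp.choice(len(free), size=cfg.n_het_snps, replace=False)
    for i in sorted(snp_idx):
        pos = free[i]
        ref = genome_seq[pos]
        alt = str(rng_snp.choice([b for b in _BASES if b != ref]))
        truth.snps.append(TruthSnp(cfg.chrom, pos, ref, alt))

    return GenomeRef({cfg.chrom: genome_seq}), truth


def _apply_edits(
    seq: list[str],
    start: int,
    truth: SimTruth,
    rng: np.random.Generator,
    with_editing: bool,
) -> None:
    end = start + len(seq)
    if with_editing:
        for site in truth.sites:
            if start <= site.pos < end:
                if rng.random() < site.level:
                    seq[site.pos - start] = "G" if site.strand == "+" else "C"
    for snp in truth.snps:
        if start <= snp.pos < end and rng.random() < 0.5:
            seq[snp.pos - start] = snp.alt


def _apply_errors(seq: list[str], rng: np.random.Generator, rate: float) -> None:
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        seq[i] = str(rng.choice([b for b in _BASES if b != seq[i]]))


def simulate_reads(genome: GenomeRef, truth: SimTruth, cfg: Optional[SimConfig] = None) -> SimTruth:
    """Populate ``truth`` with RNA, WGS and hyper reads.

    RNA reads carry programmed editing (G with probability equal to the
    site level, in genome space) and het SNP alleles (probability 0.5); WGS
    reads carry SNPs but never editing; hyper reads are taken from repeat
    intervals, edited at ≥ ``hyper_fraction`` of their sense adenosines and
    flagged unmapped. Per-site tallies of the final emitted bases are
    recorded for truth verification.
    """
    if cfg is None:
        cfg = truth.config
    rng_rna, rng_wgs, rng_hyper, rng_multi = _rngs(cfg.seed + 1_000_003, 4)
    L = genome.lengths[cfg.chrom]
    rl = cfg.read_length
    gseq = genome.sequences[cfg.chrom]

    def make_batch(rng, n_reads, prefix, with_editing):
        reads = []
        starts = np.sort(rng.integers(0, L - rl + 1, size=n_reads))
        for i, start in enumerate(starts):
            seq = list(gseq[start:start + rl])
            _apply_edits(seq, int(start), truth, rng, with_editing)
            _apply_errors(seq, rng, cfg.base_error_rate)
            low_qual = rng.random() < cfg.low_qual_fraction
            quals = [20 if low_qual else 40] * rl
            reads.append(
                SimRead(
                    name=f"{prefix}{i:06d}",
                    chrom=cfg.chrom,
                    pos=int(start),
                    seq="".join(seq),
                    quals=quals,
                    is_reverse=bool(rng.random() < 0.5),
                )
            )
        return reads

    n_rna = int(round(cfg.depth * L / rl))
    n_wgs = int(round(cfg.wgs_depth * L / rl))
    truth.rna_reads = make_batch(rng_rna, n_rna, "rna", with_editing=True)
    truth.wgs_reads = make_batch(rng_wgs, n_wgs, "wgs", with_editing=False)

    # low-confidence (multi-mapping) reads piled on the first catalog site,
    # carrying the variant so they would found a call without stage E
    if cfg.n_multimap_reads and truth.sites:
        site = truth.sites[0]
        lo = max(0, min(site.pos - rl // 2, L - rl))
        for i in range(cfg.n_multimap_reads):
            seq = list(gseq[lo:lo + rl])
            seq[site.pos - lo] = "G" if site.strand == "+" else "C"
            truth.rna_reads.append(
                SimRead(
                    name=f"multi{i:04d}",
                    chrom=cfg.chrom,
                    pos=lo,
                    seq="".join(seq),
                    quals=[40] * rl,
                    is_reverse=False,
                    mapq=30,  # above the pileup floor; flagged only via NH>1
                    n_hits=3,
                )
            )
        truth.rna_reads.sort(key=lambda r: r.pos)

    # hyper reads: dense editing within one repeat copy, emitted unmapped
    intervals = truth.repeat_intervals
    for i in range(cfg.n_hyper_reads):
        chrom, start, end, strand = intervals[i % len(intervals)]
        lo = int(rng_hyper.integers(start, max(start + 1, end - rl + 1)))
        lo = min(lo, L - rl)
        seq = list(gseq[lo:lo + rl])
        target, edited_to = ("A", "G") if strand == "+" else ("T", "C")
        a_pos = [j for j, b in enumerate(seq) if b == target]
        n_edit = max(4, math.ceil(cfg.hyper_fraction * len(a_pos)))
        n_edit = min(n_edit, len(a_pos))
        picked = rng_hyper.choice(len(a_pos), size=n_edit, replace=False)
        edited = tuple(sorted(lo + a_pos[j] for j in picked))
        for j in picked:
            seq[a_pos[j]] = edited_to
        emit_seq = "".join(seq)
        flip = bool(rng_hyper.random() < 0.5)
        if flip:
            emit_seq = revcomp(emit_seq)
        name = f"hyper{i:04d}"
        truth.hyper_reads.append(
            SimRead(
                name=name, chrom=chrom, pos=lo, seq=emit_seq,
                quals=[40] * rl, is_reverse=flip, mapq=0, unmapped=True,
            )
        )
        truth.hyper_truth[name] = (chrom, lo, strand, edited)

    # truth-side tallies of the final emitted RNA bases at catalog sites
    tallies: dict[tuple[str, int], list[int]] = {
        (s.chrom, s.pos): [0, 0] for s in truth.sites
    }
    for read in truth.rna_reads:
        for site in truth.sites:
            if read.pos <= site.pos < read.pos + rl:
                base = read.seq[site.pos - read.pos]
                edited_b = "G" if site.strand == "+" else "C"
                ref_b = "A" if site.strand == "+" else "T"
                if base == edited_b:
                    t = tallies[(site.chrom, site.pos)]
                    t[0] += 1
                    t[1] += 1
                elif base == ref_b:
                    tallies[(site.chrom, site.pos)][1] += 1
    truth.site_tallies = {k: (v[0], v[1]) for k, v in tallies.items()}
    return truth


def simulate_differential_cohort(
    seed: int,
    n_null: int = 100,
    n_shifted: int = 10,
    shift: float = 0.3,
    n_per_group: int = 12,
    mean_coverage: float = 100.0,
) -> tuple[dict, dict, list[tuple[str, int]]]:
    """Per-sample editing levels for a two-group differential comparison.

    Null sites draw levels from Beta(2, 8) (mean 0.2) in both groups;
    shifted sites keep that in group 1 and draw group 2 from a beta with
    the same concentration and mean raised by ``shift``. Coverage is
    Poisson(``mean_coverage``). Returns (group1, group2, shifted site
    keys) in the SampleLevels layout of
    :mod:`edikit.differential_editing`.
    """
    rng = np.random.default_rng(seed)
    conc = 10.0
    base_mean = 0.2
    sites = [("chrD", i) for i in range(n_null + n_shifted)]
    shifted = set(sites[n_null:])

    def draw(mean: float) -> float:
        return float(rng.beta(mean * conc, (1 - mean) * conc))

    group1 = {}
    group2 = {}
    for g, levels_by_sample, raised in ((1, group1, False), (2, group2, True)):
        for s in range(n_per_group):
            levels = {}
            for site in sites:
                mean = base_mean + (shift if raised and site in shifted else 0.0)
                cov = max(1, int(rng.poisson(mean_coverage)))
                levels[site] = (draw(mean), cov)
            levels_by_sample[f"g{g}s{s}"] = levels
    return group1, group2, sorted(shifted)


def as_aligned(reads: list[SimRead]) -> list:
    """View simulated reads as AlignedRead records (in-memory pipeline entry)."""
    from edikit.formats_io import AlignedRead

    out = []
    for r in sorted(reads, key=lambda r: (r.chrom, r.pos, r.name)):
        out.append(
            AlignedRead(
                name=r.name,
                chrom=None if r.unmapped else r.chrom,
                pos=-1 if r.unmapped else r.pos,
                cigar=[] if r.unmapped else [("M", len(r.seq))],
                seq=r.seq,
                quals=list(r.quals),
                mapq=r.mapq,
                is_reverse=r.is_reverse,
                is_unmapped=r.unmapped,
                n_hits=r.n_hits,
            )
        )
    return out


# ---------------------------------------------------------------------------
# file emission (plain text: FASTA / SAM / FASTQ / BED / TSV)

def _qual_str(quals: list[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def write_fasta(genome: GenomeRef, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.sequences):
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_sam(
    reads: list[SimRead],
    genome: GenomeRef,
    path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name in sorted(genome.sequences):
            fh.write(f"@SQ\tSN:{name}\tLN:{len(genome.sequences[name])}\n")
        for r in sorted(reads, key=lambda r: (r.unmapped, r.chrom, r.pos, r.name)):
            if r.unmapped:
                flag, rname, pos, mapq, cigar = 4, "*", 0, 0, "*"
            else:
                flag = 16 if r.is_reverse else 0
                rname, pos, mapq, cigar = r.chrom, r.pos + 1, r.mapq, f"{len(r.seq)}M"
            fh.write(
                f"{r.name}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
                f"{r.seq}\t{_qual_str(r.quals)}\tNH:i:{r.n_hits}\n"
            )


def write_fastq(reads: list[SimRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{_qual_str(r.quals)}\n")


def write_bed(intervals: list[tuple[str, int, int, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end, strand) in enumerate(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\trepeat{i}\t0\t{strand}\n")


def write_catalog_tsv(truth: SimTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrand\trecoding\taa_change\tgene\n")
        for s in truth.sites:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t"
                f"{'yes' if s.kind == 'recoding' else 'no'}\t"
                f"{s.aa_change or ''}\t{s.gene or ''}\n"
            )


def write_snp_tsv(truth: SimTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in truth.snps:
            fh.write(f"{s.chrom}\t{s.pos + 1}\n")


def emit_all(genome: GenomeRef, truth: SimTruth, outdir: str | os.PathLike) -> dict[str, str]:
    """Write every fixture file; returns a name → path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "rna_sam": os.path.join(outdir, "rna.sam"),
        "wgs_sam": os.path.join(outdir, "wgs.sam"),
        "hyper_sam": os.path.join(outdir, "hyper.sam"),
        "hyper_fastq": os.path.join(outdir, "hyper.fastq"),
        "repeats_bed": os.path.join(outdir, "repeats.bed"),
        "catalog_tsv": os.path.join(outdir, "catalog.tsv"),
        "snps_tsv": os.path.join(outdir, "snps.tsv"),
    }
    write_fasta(genome, paths["genome"])
    write_sam(truth.rna_reads, genome, paths["rna_sam"])
    write_sam(truth.wgs_reads, genome, paths["wgs_sam"])
    write_sam(truth.hyper_reads, genome, paths["hyper_sam"])
    write_fastq(truth.hyper_reads, paths["hyper_fastq"])
    write_bed(truth.repeat_intervals, paths["repeats_bed"])
    write_catalog_tsv(truth, paths["catalog_tsv"])
    write_snp_tsv(truth, paths["snps_tsv"])
    return paths


@dataclass
class TruthReport:
    consistent: bool
    n_reads_checked: int
    first_discrepancy: Optional[str] = None


def verify_truth(sam_path: str | os.PathLike, genome: GenomeRef, truth: SimTruth) -> TruthReport:
    """Independent recount of an emitted RNA SAM against the truth bookkeeping.

    Reconstructs nothing from the generator's internals: reads the file
    back, re-tallies edited/informative reads at every catalog site, and
    compares with the tallies recorded at emission time. Also re-checks
    that every record's sequence matches the recorded simulated read.
    """
    from edikit.formats_io import read_alignments

    by_name = {r.name: r for r in truth.rna_reads}
    tallies: dict[tuple[str, int], list[int]] = {
        (s.chrom, s.pos): [0, 0] for s in truth.sites
    }
    n = 0
    for read in read_alignments(sam_path):
        n += 1
        sim = by_name.get(read.name)
        if sim is None:
            return TruthReport(False, n, f"unexpected read {read.name}")
        if read.seq != sim.seq or read.pos != sim.pos:
            return TruthReport(False, n, f"read {read.name} differs from truth record")
        for site in truth.sites:
            if read.pos <= site.pos < read.reference_end():
                base = read.seq[site.pos - read.pos]
                edited_b = "G" if site.strand == "+" else "C"
                ref_b = "A" if site.strand == "+" else "T"
                key = (site.chrom, site.pos)
                if base == edited_b:
                    tallies[key][0] += 1
                    tallies[key][1] += 1
                elif base == ref_b:
                    tallies[key][1] += 1
    for key, (e, t) in tallies.items():
        if truth.site_tallies.get(key) != (e, t):
            return TruthReport(
                False, n,
                f"site {key}: recount {(e, t)} != truth {truth.site_tallies.get(key)}",
            )
    return TruthReport(True, n)
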
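"""Candidate-site calling: the five-stage filter cascade, mismatch spectrum
and spectrum-based false-discovery-rate estimate.

The cascade refines raw pileup mismatches into putative A-to-I sites:

A. every position whose quality-filtered counts contain a non-reference base;
B. genomic support — WGS coverage at least ``min_wgs_cov``, WGS non-reference
   fraction below the homozygosity threshold, and not a known SNP;
C. RNA coverage at least ``min_rna_cov`` and outside reference homopolymer
   runs longer than ``max_homopolymer`` (read-end trimming is already applied
   per-base in the pileup);
D. editing frequency at least ``min_freq``;
E. mapping confidence — not near a splice junction and not supported mostly
   by multi-mapping or low-MAPQ reads. The fraction test is a proxy for a
   Blat-style realignment check; an external per-read concordance annotation
   can be plugged in instead.

Because inosine pairs like guanosine, true editing inflates only the A→G
class (T→C for antisense reads of unstranded libraries); the residual rate
of the ten other substitution classes therefore estimates the false
discovery rate of the A→G/T→C calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from edikit.formats_io import AlignedRead, GenomeRef, RegionSet, SnpSet
from edikit.pileup_engine import BaseCount, BaseFilterConfig, pileup

SUBSTITUTION_CLASSES = [
    "AC", "AG", "AT", "CA", "CG", "CT",
    "GA", "GC", "GT", "TA", "TC", "TG",
]

STAGES = "ABCDE"


@dataclass
class CascadeConfig:
    min_wgs_cov: int = 10
    min_rna_cov: int = 10
    max_homopolymer: int = 5
    min_freq: float = 0.1
    splice_window: int = 4
    max_lowmapq_frac: float = 0.1
    wgs_max_nonref_frac: float = 0.1  # homozygosity test on genomic reads
    enabled_stages: frozenset[str] = frozenset(STAGES)

    def __post_init__(self) -> None:
        if min(
            self.min_wgs_cov, self.min_rna_cov, self.max_homopolymer,
            self.min_freq, self.splice_window, self.max_lowmapq_frac,
        ) < 0:
            raise ValueError("cascade thresholds must be >= 0")


@dataclass
class SiteCall:
    """A candidate editing position with its spectrum and filter history."""

    chrom: str
    pos: int  # 0-based
    ref: str
    strand: str = "?"
    counts: dict[str, int] = field(default_factory=dict)
    coverage: int = 0
    variant: Optional[str] = None
    frequency: float = 0.0
    stage_flags: set[str] = field(default_factory=set)
    sub_class: Optional[str] = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class SpectrumSummary:
    class_counts: dict[str, int]
    AG_TC_fraction: Optional[float]
    fdr_estimate: Optional[float]

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


def _infer_strand(ref: str, variant: str) -> str:
    if ref == "A" and variant == "G":
        return "+"
    if ref == "T" and variant == "C":
        return "-"
    return "?"


def call_stage_A(counts: Iterable[BaseCount], genome: GenomeRef) -> list[SiteCall]:
    """One call per position whose surviving counts hold a non-reference base.

    The variant base is the most frequent alternative (ties broken
    alphabetically); frequency is variant/(ref+variant).
    """
    calls: list[SiteCall] = []
    for bc in counts:
        merged = bc.counts
        alts = {b: n for b, n in merged.items() if b != bc.ref and n > 0}
        if not alts or bc.ref not in "ACGT":
            continue
        variant = max(sorted(alts), key=lambda b: alts[b])
        ref_n = merged.get(bc.ref, 0)
        freq = alts[variant] / (ref_n + alts[variant])
        calls.append(
            SiteCall(
                chrom=bc.chrom,
                pos=bc.pos,
                ref=bc.ref,
                strand=_infer_strand(bc.ref, variant),
                counts=merged,
                coverage=bc.total_reads,
                variant=variant,
                frequency=freq,
                stage_flags={"A"},
                sub_class=bc.ref + variant,
            )
        )
    return calls


def apply_stage_B(
    calls: list[SiteCall],
    wgs_counts: Optional[dict[tuple[str, int], BaseCount]],
    snps: SnpSet,
    cfg: CascadeConfig,
) -> list[SiteCall]:
    """Keep calls with homozygous-reference genomic support outside known SNPs.

    ``wgs_counts`` is a position-indexed pileup of the matched WGS sample,
    built with the same per-base filters (e.g. via
    :func:`edikit.pileup_engine.count_at_sites`).
    """
    if "B" not in cfg.enabled_stages:
        return calls
    if wgs_counts is None:
        raise ValueError("stage B enabled but no WGS counts supplied (disable the stage "
                         "or provide matched genomic reads)")
    kept = []
    for call in calls:
        if call.key in snps:
            continue
        wgs = wgs_counts.get(call.key)
        if wgs is None:
            continue
        cov = wgs.total_reads
        if cov < cfg.min_wgs_cov:
            continue
        nonref = cov - wgs.counts.get(call.ref, 0)
        if nonref / cov >= cfg.wgs_max_nonref_frac:
            continue
        call.stage_flags.add("B")
        kept.append(call)
    return kept


def homopolymer_run(genome: GenomeRef, chrom: str, pos: int) -> int:
    """Length of the maximal run of identical reference bases containing pos."""
    seq = genome.sequences[chrom]
    b = seq[pos]
    left = pos
    while left > 0 and seq[left - 1] == b:
        left -= 1
    right = pos
    while right + 1 < len(seq) and seq[right + 1] == b:
        right += 1
    return right - left + 1


def apply_stage_C(calls: list[SiteCall], genome: GenomeRef, cfg: CascadeConfig) -> list[SiteCall]:
    """Keep calls with RNA coverage >= min_rna_cov outside long homopolymers."""
    if "C" not in cfg.enabled_stages:
        return calls
    kept = []
    for call in calls:
        if call.coverage < cfg.min_rna_cov:
            continue
        if homopolymer_run(genome, call.chrom, call.pos) > cfg.max_homopolymer:
            continue
        call.stage_flags.add("C")
        kept.append(call)
    return kept


def apply_stage_D(calls: list[SiteCall], cfg: CascadeConfig) -> list[SiteCall]:
    """Keep calls with editing frequency >= min_freq."""
    if "D" not in cfg.enabled_stages:
        return calls
    kept = []
    for call in calls:
        if call.frequency >= cfg.min_freq:
            call.stage_flags.add("D")
            kept.append(call)
    return kept


def apply_stage_E(
    calls: list[SiteCall],
    reads: Iterable[AlignedRead],
    junctions: Optional[RegionSet],
    cfg: CascadeConfig,
    concordance: Optional[Callable[[AlignedRead], bool]] = None,
) -> list[SiteCall]:
    """Drop calls near splice junctions or supported by poorly mapped reads.

    A read is low-confidence when it is multi-mapped (``n_hits > 1``) or has
    MAPQ below the pileup threshold; a call is dropped when the
    low-confidence fraction of its covering reads exceeds
    ``max_lowmapq_frac``. ``concordance`` optionally supplies an external
    per-read realignment verdict (True = concordant) replacing the built-in
    proxy.
    """
    if "E" not in cfg.enabled_stages:
        return calls
    positions = {c.key for c in calls}
    total: dict[tuple[str, int], int] = {p: 0 for p in positions}
    bad: dict[tuple[str, int], int] = {p: 0 for p in positions}
    base_cfg = BaseFilterConfig()
    for read in reads:
        if read.is_unmapped:
            continue
        if concordance is not None:
            low_conf = not concordance(read)
        else:
            low_conf = read.n_hits > 1 or read.mapq < base_cfg.min_mapq
        for p in range(read.pos, read.reference_end()):
            key = (read.chrom, p)
            if key in total:
                total[key] += 1
                if low_conf:
                    bad[key] += 1
    kept = []
    for call in calls:
        if junctions is not None and len(junctions):
            w = cfg.splice_window
            if junctions.overlapping(call.chrom, call.pos - w, call.pos + w + 1):
                continue
        n = total[call.key]
        if n and bad[call.key] / n > cfg.max_lowmapq_frac:
            continue
        call.stage_flags.add("E")
        kept.append(call)
    return kept


def run_cascade(
    rna_reads: list[AlignedRead],
    genome: GenomeRef,
    cfg: Optional[CascadeConfig] = None,
    base_cfg: Optional[BaseFilterConfig] = None,
    wgs_counts: Optional[dict[tuple[str, int], BaseCount]] = None,
    snps: Optional[SnpSet] = None,
    junctions: Optional[RegionSet] = None,
) -> tuple[list[SiteCall], dict[str, int]]:
    """Run stages A–E and return (surviving calls, per-stage survivor counts)."""
    if cfg is None:
        cfg = CascadeConfig()
    if base_cfg is None:
        base_cfg = BaseFilterConfig()
    if snps is None:
        snps = SnpSet()
    counts = pileup(rna_reads, genome, cfg=base_cfg)
    calls = call_stage_A(counts, genome)
    survivors = {"A": len(calls)}
    if "B" in cfg.enabled_stages:
        calls = apply_stage_B(calls, wgs_counts, snps, cfg)
    survivors["B"] = len(calls)
    calls = apply_stage_C(calls, genome, cfg)
    survivors["C"] = len(calls)
    calls = apply_stage_D(calls, cfg)
    survivors["D"] = len(calls)
    calls = apply_stage_E(calls, rna_reads, junctions, cfg)
    survivors["E"] = len(calls)
    return calls, survivors


_MISSING = float("nan")


def spectrum(calls: Iterable[SiteCall]) -> SpectrumSummary:
    """Summarise the 12-class substitution spectrum of a call set.

    ``AG_TC_fraction`` is (AG+TC)/total. The FDR estimate treats the ten
    classes other than A→G/T→C as pure noise: it is the mean count of those
    classes divided by the A→G/T→C count (0 when the latter carries all the
    signal; missing when there is no signal at all).
    """
    class_counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    for call in calls:
        if call.sub_class in class_counts:
            class_counts[call.sub_class] += 1
    total = sum(class_counts.values())
    signal = class_counts["AG"] + class_counts["TC"]
    if total == 0:
        return SpectrumSummary(class_counts, None, None)
    frac = signal / total
    if signal == 0:
        return SpectrumSummary(class_counts, frac, None)
    noise_classes = [c for c in SUBSTITUTION_CLASSES if c not in ("AG", "TC")]
    mean_noise = sum(class_counts[c] for c in noise_classes) / len(noise_classes)
    return SpectrumSummary(class_counts, frac, mean_noise / signal)
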
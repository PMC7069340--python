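"""Hyper-editing rescue: recover heavily edited reads that fail normal
alignment by re-aligning base-transformed reads to a base-transformed
genome, then call A→G mismatch clusters and merge them with the standard
caller's sites.

ADARs can deaminate dense clusters of adenosines on one molecule; such
reads carry too many mismatches for a conventional aligner. Collapsing the
edited base pair away — replacing every A with G in both read and genome
(and T with C for the antisense signal of unstranded libraries) — makes a
hyper-edited read match its true locus exactly, after which the original
read is compared to the original genome to enumerate the A→G changes.

The rescue aligner is an adapter: the built-in :class:`ToyAligner` does
seed-and-extend with exact or 1-mismatch seeds, sufficient for small
genomes; a shell-out adapter can replace it for real-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from edikit.formats_io import AlignedRead, GenomeRef
from edikit.variant_calling import SiteCall

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def transform(seq: str, from_base: str, to_base: str) -> str:
    """Replace every ``from_base`` with ``to_base``; length preserved."""
    return seq.replace(from_base, to_base)


@dataclass
class HyperConfig:
    min_AG_per_read: int = 4
    min_AG_purity: float = 0.6  # A→G fraction of all mismatches
    max_other_mismatch_frac: float = 0.1  # of read length
    passes: str = "both"  # AG | TC | both
    max_align_mismatch_frac: float = 0.1  # tolerated in transformed space

    def __post_init__(self) -> None:
        if not 0 <= self.min_AG_purity <= 1 or not 0 <= self.max_other_mismatch_frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.passes not in ("AG", "TC", "both"):
            raise ValueError(f"unknown pass selection {self.passes!r}")


@dataclass
class Placement:
    chrom: str
    pos: int  # 0-based start on the original genome
    strand: str  # '+' read as given, '-' reverse-complemented
    transform_pass: str  # AG or TC


@dataclass
class HyperCluster:
    read_name: str
    chrom: str
    start: int
    end: int
    ag_positions: list[int]  # genome-space, 0-based, back-transformed
    n_other_mismatch: int
    passed: bool
    strand: str = "+"

    @property
    def n_AG(self) -> int:
        return len(self.ag_positions)


class ToyAligner:
    """Seed-and-extend aligner for transformed-space rescue on small genomes.

    Seeds of ``seed_len`` bases are taken from several offsets of the read;
    each exact seed hit is extended over the full read and accepted when the
    mismatch fraction stays within the configured tolerance. Both the read
    and its reverse complement are tried.
    """

    def __init__(self, genome: GenomeRef, from_base: str, to_base: str,
                 seed_len: int = 20, max_mismatch_frac: float = 0.1):
        self.from_base = from_base
        self.to_base = to_base
        self.seed_len = seed_len
        self.max_mismatch_frac = max_mismatch_frac
        self.t_genome = {
            name: transform(seq, from_base, to_base)
            for name, seq in genome.sequences.items()
        }

    def _find_exact(self, chrom_seq: str, seed: str) -> Iterable[int]:
        i = chrom_seq.find(seed)
        while i != -1:
            yield i
            i = chrom_seq.find(seed, i + 1)

    def _try_orientation(self, t_read: str) -> Optional[tuple[str, int, int]]:
        L = len(t_read)
        k = min(self.seed_len, L)
        max_mm = int(self.max_align_budget(L))
        offsets = [0, max(0, (L - k) // 2), max(0, L - k)]
        best: Optional[tuple[int, str, int]] = None  # (mm, chrom, pos)
        for chrom, seq in sorted(self.t_genome.items()):
            for off in offsets:
                seed = t_read[off:off + k]
                for hit in self._find_exact(seq, seed):
                    start = hit - off
                    if start < 0 or start + L > len(seq):
                        continue
                    window = seq[start:start + L]
                    mm = sum(a != b for a, b in zip(t_read, window))
                    if mm <= max_mm and (best is None or mm < best[0]):
                        best = (mm, chrom, start)
        if best is None:
            return None
        return best[1], best[2], best[0]

    def max_align_budget(self, read_len: int) -> float:
        return self.max_mismatch_frac * read_len

    def align(self, seq: str) -> Optional[tuple[str, int, str, int]]:
        """Best placement (chrom, pos, strand, n_mismatch) in transformed
        space over both orientations, or None."""
        best: Optional[tuple[str, int, str, int]] = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            t_read = transform(oriented, self.from_base, self.to_base)
            hit = self._try_orientation(t_read)
            if hit is not None and (best is None or hit[2] < best[3]):
                best = (hit[0], hit[1], strand, hit[2])
        return best


def rescue_align(
    unmapped_reads: Iterable[AlignedRead],
    genome: GenomeRef,
    cfg: Optional[HyperConfig] = None,
    aligner_factory: Optional[Callable[[GenomeRef, str, str], object]] = None,
) -> list[tuple[AlignedRead, Placement]]:
    """Place unmapped reads on the base-transformed genome.

    Runs an A→G pass and, for ``passes='both'``, a T→C pass (the antisense
    signature in unstranded data); each read keeps its first successful
    placement (A→G pass preferred). Placements are in original-genome
    coordinates, since the transform preserves length. Reads no pass can
    place are silently unrescued.
    """
    if cfg is None:
        cfg = HyperConfig()
    passes = {"AG": [("A", "G")], "TC": [("T", "C")], "both": [("A", "G"), ("T", "C")]}[
        cfg.passes
    ]
    aligners = []
    for from_b, to_b in passes:
        if aligner_factory is not None:
            aligner = aligner_factory(genome, from_b, to_b)
        else:
            aligner = ToyAligner(
                genome, from_b, to_b, max_mismatch_frac=cfg.max_align_mismatch_frac
            )
        aligners.append((from_b + to_b, aligner))
    placed: list[tuple[AlignedRead, Placement]] = []
    for read in unmapped_reads:
        best = None  # (mm, Placement); ties go to the earlier pass
        for label, aligner in aligners:
            hit = aligner.align(read.seq)
            if hit is None:
                continue
            chrom, pos, strand, mm = hit
            if best is None or mm < best[0]:
                best = (mm, Placement(chrom, pos, strand, label))
        if best is not None:
            placed.append((read, best[1]))
    return placed


def detect_clusters(
    placements: Iterable[tuple[AlignedRead, Placement]],
    genome: GenomeRef,
    cfg: Optional[HyperConfig] = None,
) -> list[HyperCluster]:
    """Compare each rescued read against the original genome and classify.

    Editing is counted in transcript sense: genome-A → read-G for '+'
    placements of the A→G pass, genome-T → read-C where the transcript runs
    antisense to the reference. A cluster passes when it has at least
    ``min_AG_per_read`` edits, edit purity ≥ ``min_AG_purity`` of all
    mismatches, and other mismatches ≤ ``max_other_mismatch_frac`` of the
    read length.
    """
    if cfg is None:
        cfg = HyperConfig()
    clusters: list[HyperCluster] = []
    for read, pl in placements:
        seq = read.seq if pl.strand == "+" else revcomp(read.seq)
        L = len(seq)
        ref = genome.fetch(pl.chrom, pl.pos, pl.pos + L)
        # The aligner collapses from→to on the oriented read, so in genome
        # space the edited pair is A→G for the AG pass ('+'-strand
        # transcript) and T→C for the TC pass (antisense transcript),
        # regardless of which read orientation was placed.
        sense_forward = pl.transform_pass == "AG"
        edit_from, edit_to = ("A", "G") if sense_forward else ("T", "C")
        ag_positions: list[int] = []
        n_other = 0
        for i, (g, r) in enumerate(zip(ref, seq)):
            if g == r:
                continue
            if g == edit_from and r == edit_to:
                ag_positions.append(pl.pos + i)
            else:
                n_other += 1
        n_ag = len(ag_positions)
        n_mm = n_ag + n_other
        passed = (
            n_ag >= cfg.min_AG_per_read
            and (n_mm > 0 and n_ag / n_mm >= cfg.min_AG_purity)
            and n_other <= cfg.max_other_mismatch_frac * L
        )
        clusters.append(
            HyperCluster(
                read_name=read.name,
                chrom=pl.chrom,
                start=pl.pos,
                end=pl.pos + L,
                ag_positions=ag_positions,
                n_other_mismatch=n_other,
                passed=passed,
                strand="+" if sense_forward else "-",
            )
        )
    return clusters


@dataclass
class MergedSites:
    """Union of standard-caller and hyper-editing site positions."""

    sites: dict[tuple[str, int], str] = field(default_factory=dict)  # key -> source

    @property
    def n_standard_only(self) -> int:
        return sum(1 for s in self.sites.values() if s == "standard")

    @property
    def n_hyper_only(self) -> int:
        return sum(1 for s in self.sites.values() if s == "hyper")

    @property
    def n_both(self) -> int:
        return sum(1 for s in self.sites.values() if s == "both")


def merge_calls(standard: Iterable[SiteCall], clusters: Iterable[HyperCluster]) -> MergedSites:
    """Union standard-caller positions with passing hyper-cluster positions,
    labelling each site standard/hyper/both."""
    std = {c.key for c in standard}
    hyp: set[tuple[str, int]] = set()
    for cl in clusters:
        if cl.passed:
            hyp.update((cl.chrom, p) for p in cl.ag_positions)
    merged = MergedSites()
    for key in std | hyp:
        if key in std and key in hyp:
            merged.sites[key] = "both"
        elif key in std:
            merged.sites[key] = "standard"
        else:
            merged.sites[key] = "hyper"
    return merged
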
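"""Strand-aware pileup with the per-base filters applied at counting time.

A base contributes to a position's tally only if its phred quality reaches
``min_base_qual`` (default 30) and its 1-based query offset lies more than
``read_end_trim`` bases from both read ends (default 6, so offsets 1–6 and
the last six are excluded). The end distance is measured on the query
sequence, so soft-clipped bases count toward it. Reads below ``min_mapq``
are tallied separately and contribute no bases; deletions, reference skips
and insertions contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from edikit.formats_io import AlignedRead, GenomeRef, SiteCatalog


@dataclass
class BaseFilterConfig:
    min_base_qual: int = 30
    read_end_trim: int = 6
    min_mapq: int = 20

    def __post_init__(self) -> None:
        if min(self.min_base_qual, self.read_end_trim, self.min_mapq) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class BaseCount:
    """Per-position nucleotide tallies split by read orientation."""

    chrom: str
    pos: int  # 0-based
    ref: str
    counts_fwd: dict[str, int] = field(default_factory=dict)
    counts_rev: dict[str, int] = field(default_factory=dict)
    qual_sum: float = 0.0
    low_mapq_reads: int = 0
    excluded_bases: int = 0  # aligned bases dropped by quality/trim filters

    @property
    def counts(self) -> dict[str, int]:
        merged = dict(self.counts_fwd)
        for b, n in self.counts_rev.items():
            merged[b] = merged.get(b, 0) + n
        return merged

    @property
    def total_reads(self) -> int:
        return sum(self.counts_fwd.values()) + sum(self.counts_rev.values())

    @property
    def mean_qual(self) -> float:
        n = self.total_reads
        return self.qual_sum / n if n else 0.0

    def _add(self, base: str, qual: int, is_reverse: bool) -> None:
        target = self.counts_rev if is_reverse else self.counts_fwd
        target[base] = target.get(base, 0) + 1
        self.qual_sum += qual


def _count_read(
    read: AlignedRead,
    counts: dict[int, BaseCount],
    chrom: str,
    genome: GenomeRef,
    cfg: BaseFilterConfig,
    positions: Optional[set[int]] = None,
) -> None:
    qlen = len(read.seq)
    low_mapq = read.mapq < cfg.min_mapq
    for qoff, rpos in read.aligned_pairs():
        if positions is not None and rpos not in positions:
            continue
        bc = counts.get(rpos)
        if bc is None:
            bc = BaseCount(chrom, rpos, genome.base(chrom, rpos))
            counts[rpos] = bc
        # 1-based query offset must exceed the trim from both ends
        off1 = qoff + 1
        in_body = off1 > cfg.read_end_trim and (qlen - off1 + 1) > cfg.read_end_trim
        base = read.seq[qoff]
        if low_mapq or not in_body or read.quals[qoff] < cfg.min_base_qual or base == "N":
            bc.excluded_bases += 1
            continue
        bc._add(base, read.quals[qoff], read.is_reverse)


def pileup(
    reads: Iterable[AlignedRead],
    genome: GenomeRef,
    region: Optional[tuple[str, int, int]] = None,
    cfg: Optional[BaseFilterConfig] = None,
) -> Iterator[BaseCount]:
    """Tally filtered base counts per reference position, in coordinate order.

    ``reads`` must be coordinate-sorted (verified; violation raises). Yields
    one :class:`BaseCount` per position touched by at least one read; the
    low-MAPQ read tally is maintained even where no base survives.
    """
    if cfg is None:
        cfg = BaseFilterConfig()
    counts: dict[int, BaseCount] = {}
    lowmapq_spans: list[tuple[int, int]] = []
    cur_chrom: Optional[str] = None
    last_pos = -1
    per_chrom: list[tuple[str, dict[int, BaseCount]]] = []

    def flush() -> None:
        nonlocal counts, lowmapq_spans
        if cur_chrom is not None:
            for start, end in lowmapq_spans:
                for p in range(start, end):
                    if p in counts:
                        counts[p].low_mapq_reads += 1
            per_chrom.append((cur_chrom, counts))
        counts = {}
        lowmapq_spans = []

    for read in reads:
        if read.is_unmapped:
            continue
        if region is not None:
            rchrom, rstart, rend = region
            if read.chrom != rchrom or read.reference_end() <= rstart or read.pos >= rend:
                continue
        if read.chrom != cur_chrom:
            if any(c == read.chrom for c, _ in per_chrom):
                raise ValueError(f"input not coordinate-sorted: {read.chrom} seen twice")
            flush()
            cur_chrom = read.chrom
            last_pos = -1
        if read.pos < last_pos:
            raise ValueError(
                f"input not coordinate-sorted: {read.name} at {read.chrom}:{read.pos} "
                f"after position {last_pos}"
            )
        last_pos = read.pos
        if read.mapq < cfg.min_mapq:
            lowmapq_spans.append((read.pos, read.reference_end()))
        _count_read(read, counts, read.chrom, genome, cfg)
    flush()

    for chrom, chrom_counts in per_chrom:
        for pos in sorted(chrom_counts):
            bc = chrom_counts[pos]
            if region is not None and not (region[1] <= pos < region[2]):
                continue
            if bc.total_reads > 0 or bc.low_mapq_reads > 0 or bc.excluded_bases > 0:
                yield bc


def count_at_sites(
    reads: Iterable[AlignedRead],
    genome: GenomeRef,
    catalog: SiteCatalog,
    cfg: Optional[BaseFilterConfig] = None,
) -> dict[tuple[str, int], BaseCount]:
    """Base counts at catalog positions only; zero-coverage sites included.

    Counting rules are identical to :func:`pileup`. Catalog chromosomes
    missing from the genome are an error listing the offenders.
    """
    if cfg is None:
        cfg = BaseFilterConfig()
    missing = sorted({e.chrom for e in catalog} - set(genome.sequences))
    if missing:
        raise ValueError(f"catalog chromosomes absent from genome: {', '.join(missing)}")
    by_chrom: dict[str, set[int]] = {}
    for e in catalog:
        by_chrom.setdefault(e.chrom, set()).add(e.pos)
    out: dict[tuple[str, int], BaseCount] = {
        (e.chrom, e.pos): BaseCount(e.chrom, e.pos, genome.base(e.chrom, e.pos))
        for e in catalog
    }
    for read in reads:
        if read.is_unmapped or read.chrom not in by_chrom:
            continue
        wanted = by_chrom[read.chrom]
        local: dict[int, BaseCount] = {
            p: out[(read.chrom, p)] for p in wanted if read.pos <= p < read.reference_end()
        }
        if not local:
            continue
        if read.mapq < cfg.min_mapq:
            for bc in local.values():
                bc.low_mapq_reads += 1
        _count_read(read, local, read.chrom, genome, cfg, positions=set(local))
    return out
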
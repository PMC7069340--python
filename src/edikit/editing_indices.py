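"""Global editing metrics: overall editing index, Alu editing index (AEI),
recoding editing index (REI), and the catalog-subsampling robustness check.

All three indices are coverage-weighted averages reported as percentages.
The overall index sums edited-read counts over a catalog of known sites
with no per-site coverage cutoff, so lowly covered sites contribute their
reads rather than an unstable per-site frequency. The AEI does the same
over every adenosine inside annotated Alu(-like) intervals — numerator
A→G read observations, denominator A+G — and the REI restricts the
overall index to recoding (nonsynonymous) sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import pearsonr

from edikit.formats_io import AlignedRead, GenomeRef, RegionSet, SiteCatalog
from edikit.pileup_engine import BaseCount, BaseFilterConfig, count_at_sites, pileup


@dataclass
class IndexResult:
    kind: str  # overall | AEI | REI
    numerator: int
    denominator: int
    n_sites_or_positions: int

    @property
    def value(self) -> Optional[float]:
        """Percentage 100·num/den, or None when no informative reads exist."""
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator


@dataclass
class SubsampleReport:
    """Per subsample size: the sampled size, per-sample index values per
    replicate, and the Pearson r of each replicate against the full-catalog
    per-sample indices."""

    sizes: list[int]
    per_size_values: dict[int, list[list[float]]]  # size -> [rep][sample]
    per_size_r: dict[int, list[Optional[float]]]
    full_values: list[float]


def _informative(counts: dict[str, int], strand: str) -> tuple[int, int]:
    """(edited, edited+unedited) read counts in genome space for one site."""
    if strand == "+":
        return counts.get("G", 0), counts.get("A", 0) + counts.get("G", 0)
    return counts.get("C", 0), counts.get("T", 0) + counts.get("C", 0)


def site_level(count: BaseCount, strand: str) -> Optional[float]:
    """Editing level at one site: G/(A+G) on '+', C/(T+C) on '−'.

    Other bases are ignored; None when no informative reads cover the site.
    """
    num, den = _informative(count.counts, strand)
    if den == 0:
        return None
    return num / den


def overall_index(
    counts: dict[tuple[str, int], BaseCount],
    catalog: SiteCatalog,
    kind: str = "overall",
) -> IndexResult:
    """Overall editing: Σ edited reads / Σ informative reads over the catalog.

    No coverage cutoff is imposed; zero-coverage sites contribute nothing.
    """
    num = den = 0
    for entry in catalog:
        bc = counts.get((entry.chrom, entry.pos))
        if bc is None:
            continue
        n, d = _informative(bc.counts, entry.strand)
        num += n
        den += d
    return IndexResult(kind, num, den, len(catalog))


def recoding_index(
    counts: dict[tuple[str, int], BaseCount], catalog: SiteCatalog
) -> IndexResult:
    """REI: the overall index restricted to recoding (nonsynonymous) sites."""
    return overall_index(counts, catalog.recoding_subset(), kind="REI")


def alu_index(
    reads: Iterable[AlignedRead],
    genome: GenomeRef,
    regions: RegionSet,
    cfg: Optional[BaseFilterConfig] = None,
    unique_only: bool = True,
) -> IndexResult:
    """AEI over every adenosine inside the stranded repeat intervals.

    On '+' intervals each reference-A position adds G reads to the numerator
    and A+G to the denominator; '−' intervals mirror with T/C. Only uniquely
    mapped reads contribute by default. The repeat strand comes from the
    annotation, not read orientation, so unstranded libraries are handled.
    """
    if unique_only:
        reads = [r for r in reads if r.n_hits == 1]
    else:
        reads = list(reads)
    num = den = n_pos = 0
    counts = {(bc.chrom, bc.pos): bc for bc in pileup(reads, genome, cfg=cfg)}
    seen: set[tuple[str, int]] = set()
    for chrom, start, end, strand in regions.intervals:
        target = "A" if strand == "+" else "T"
        seq = genome.fetch(chrom, start, end)
        for off, base in enumerate(seq):
            pos = start + off
            if base != target or (chrom, pos) in seen:
                continue
            seen.add((chrom, pos))
            bc = counts.get((chrom, pos))
            if bc is None:
                continue
            n, d = _informative(bc.counts, strand)
            if d:
                n_pos += 1
            num += n
            den += d
    return IndexResult("AEI", num, den, n_pos)


def subsample_robustness(
    per_sample_counts: dict[str, dict[tuple[str, int], BaseCount]],
    catalog: SiteCatalog,
    sizes: Sequence[int],
    n_reps: int = 10,
    seed: int = 0,
) -> SubsampleReport:
    """Robustness of the overall index to the number of catalog positions.

    For each size, draw ``n_reps`` random position subsets (without
    replacement), recompute the per-sample overall index on each subset and
    correlate it (Pearson) with the full-catalog per-sample indices.
    Requires at least 3 samples; zero-variance replicates report a missing r.
    """
    samples = sorted(per_sample_counts)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    if max(sizes) > len(catalog):
        raise ValueError(f"subsample size {max(sizes)} exceeds catalog size {len(catalog)}")
    rng = np.random.default_rng(seed)
    entries = list(catalog)

    def values_for(cat: SiteCatalog) -> list[float]:
        out = []
        for s in samples:
            v = overall_index(per_sample_counts[s], cat).value
            out.append(v if v is not None else math.nan)
        return out

    full = values_for(catalog)
    per_size_values: dict[int, list[list[float]]] = {}
    per_size_r: dict[int, list[Optional[float]]] = {}
    for size in sizes:
        reps_vals: list[list[float]] = []
        reps_r: list[Optional[float]] = []
        for _ in range(n_reps):
            idx = rng.choice(len(entries), size=size, replace=False)
            sub = SiteCatalog([entries[i] for i in sorted(idx)])
            vals = values_for(sub)
            reps_vals.append(vals)
            pairs = [(a, b) for a, b in zip(vals, full) if not (math.isnan(a) or math.isnan(b))]
            if len(pairs) < 3:
                reps_r.append(None)
                continue
            x = np.array([p[0] for p in pairs])
            y = np.array([p[1] for p in pairs])
            if np.std(x) == 0 or np.std(y) == 0:
                reps_r.append(None)  # undefined, not 0
            else:
                reps_r.append(float(pearsonr(x, y).statistic))
        per_size_values[int(size)] = reps_vals
        per_size_r[int(size)] = reps_r
    return SubsampleReport(list(int(s) for s in sizes), per_size_values, per_size_r, full)
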
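"""Differential editing between two sample groups.

Per-site editing levels are ratios of small counts and are far from
normal (empirically closer to a beta distribution), so group comparison
uses the two-tailed Mann–Whitney U test on per-sample levels, with
Benjamini–Hochberg control of the false discovery rate over the eligible
sites. A site is eligible when enough samples in each group reach the
coverage floor (default: coverage ≥ 10 in ≥ 50% of the samples per group);
missing levels are dropped, never imputed.

Sign convention: Δ editing = mean(group2) − mean(group1), with groups in
call order. Comparing (artery, cerebellum) therefore prints artery-high
sites with negative Δ.

The coverage-ranked Wilcoxon variant ranks sites by total read coverage
and tests only those where at least ``min_samples`` per group reach the
depth requirement, using the same U-test/BH machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

Level = tuple[Optional[float], int]  # (editing level or None, coverage)
SampleLevels = dict[str, dict[tuple[str, int], Level]]  # sample -> site -> Level


@dataclass
class DiffSite:
    site: tuple[str, int]
    mean1: float
    mean2: float
    delta: float  # mean2 - mean1
    u_stat: float
    p_value: float
    p_adj: float = math.nan
    direction: str = "ns"
    total_coverage: int = 0
    n1: int = 0
    n2: int = 0


def _site_union(groups: Sequence[SampleLevels]) -> set[tuple[str, int]]:
    sites: set[tuple[str, int]] = set()
    for g in groups:
        for levels in g.values():
            sites.update(levels)
    return sites


def eligible_sites(
    group1: SampleLevels,
    group2: SampleLevels,
    min_cov: int = 10,
    min_frac: float = 0.5,
) -> list[tuple[str, int]]:
    """Sites where each group has coverage ≥ min_cov in ≥ ceil(min_frac·n) samples."""
    if not group1 or not group2:
        raise ValueError("both groups must be non-empty")
    out = []
    for site in sorted(_site_union((group1, group2))):
        ok = True
        for group in (group1, group2):
            need = math.ceil(min_frac * len(group))
            have = sum(
                1
                for levels in group.values()
                if site in levels and levels[site][1] >= min_cov
            )
            if have < need:
                ok = False
                break
        if ok:
            out.append(site)
    return out


def _exact_two_sided_p(x: Sequence[float], y: Sequence[float], u_obs: float) -> float:
    """Enumerate all C(n1+n2, n1) group assignments of the pooled values and
    return 2·min(P(U ≤ u), P(U ≥ u)), capped at 1."""
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)
    us = []
    for idx in combinations(range(n), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in set(idx)]
        us.append(_u_statistic(xs, ys))
    total = len(us)
    le = sum(1 for u in us if u <= u_obs + 1e-12)
    ge = sum(1 for u in us if u >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(le, ge) / total)


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for group x: #{(i,j): x_i > y_j} + ½·ties (rank-sum definition)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mw_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U test.

    Returns (U for group x, two-sided p). The p-value is exact (full
    enumeration) when n1+n2 ≤ 12 and the pooled values are tie-free;
    otherwise the normal approximation with tie and continuity corrections
    is used.
    """
    x = [v for v in x if v is not None and not math.isnan(v)]
    y = [v for v in y if v is not None and not math.isnan(v)]
    if not x or not y:
        raise ValueError("each group needs at least one observation")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = x + y
    has_ties = len(set(pooled)) < len(pooled)
    if n1 + n2 <= 12 and not has_ties:
        return u, _exact_two_sided_p(x, y, u)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = sum(t**3 - t for t in tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    z = max(0.0, abs(u - mu) - 0.5) / math.sqrt(var)
    p = math.erfc(z / math.sqrt(2.0))
    return u, min(1.0, p)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    adj_(k) = min over j ≥ k of p_(j)·m/j along the ascending sort, capped
    at 1.
    """
    p = list(p_values)
    m = len(p)
    if m == 0:
        return []
    for v in p:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"p-value {v} outside [0, 1]")
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def _group_levels(group: SampleLevels, site: tuple[str, int]) -> list[float]:
    out = []
    for levels in group.values():
        lv = levels.get(site)
        if lv is not None and lv[0] is not None:
            out.append(lv[0])
    return out


def diff_table(
    group1: SampleLevels,
    group2: SampleLevels,
    alpha: float = 0.05,
    min_cov: int = 10,
    min_frac: float = 0.5,
    min_samples: Optional[int] = None,
) -> list[DiffSite]:
    """Differential-editing table over the eligible sites.

    Eligibility uses the per-group fraction rule by default, or an absolute
    per-group sample count when ``min_samples`` is given. Δ editing is
    mean(group2) − mean(group1); BH correction runs over the tested sites
    (m = number tested); direction is up/down by Δ sign at p_adj < alpha.
    Sorted by adjusted p.
    """
    if min_samples is not None:
        sites = [
            s
            for s in sorted(_site_union((group1, group2)))
            if all(
                sum(
                    1
                    for levels in g.values()
                    if s in levels and levels[s][1] >= min_cov
                )
                >= min_samples
                for g in (group1, group2)
            )
        ]
    else:
        sites = eligible_sites(group1, group2, min_cov, min_frac)
    rows: list[DiffSite] = []
    for site in sites:
        x = _group_levels(group1, site)
        y = _group_levels(group2, site)
        if not x or not y:
            continue  # a group is all-missing at this site
        u, p = mw_test(x, y)
        cov = sum(
            g[s][site][1]
            for g in (group1, group2)
            for s in g
            if site in g[s]
        )
        rows.append(
            DiffSite(
                site=site,
                mean1=float(np.mean(x)),
                mean2=float(np.mean(y)),
                delta=float(np.mean(y) - np.mean(x)),
                u_stat=u,
                p_value=p,
                total_coverage=cov,
                n1=len(x),
                n2=len(y),
            )
        )
    adj = bh_adjust([r.p_value for r in rows])
    for r, a in zip(rows, adj):
        r.p_adj = a
        if a < alpha:
            r.direction = "up" if r.delta > 0 else "down"
        else:
            r.direction = "ns"
    rows.sort(key=lambda r: (r.p_adj, r.p_value, r.site))
    return rows


def ranked_wilcoxon_procedure(
    group1: SampleLevels,
    group2: SampleLevels,
    alpha: float = 0.05,
    min_cov: int = 10,
    min_samples: int = 5,
) -> list[DiffSite]:
    """Coverage-ranked variant: sites ordered by total read coverage
    (descending); the rank-sum test is applied only where at least
    ``min_samples`` samples per group reach ``min_cov``."""
    rows = diff_table(
        group1, group2, alpha=alpha, min_cov=min_cov, min_samples=min_samples
    )
    rows.sort(key=lambda r: (-r.total_coverage, r.site))
    return rows
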
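"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, quadratic scans, direct
arithmetic) and shares no code with the package paths it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.stats import binom


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of fixed-margin tables."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def bh_bruteforce(p_values) -> np.ndarray:
    """Quadratic-time BH step-up: q_(i) = min_{j>=i} p_(j)*m/j, input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_i, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def binomial_deviance(test_counts, ctrl_counts) -> float:
    """−2·(ll_null − ll_full) via scipy binomial logpmf at fitted proportions."""
    tm = sum(m for m, _ in test_counts)
    tn = sum(m + u for m, u in test_counts)
    cm = sum(m for m, _ in ctrl_counts)
    cn = sum(m + u for m, u in ctrl_counts)
    pt, pc = tm / tn, cm / cn
    p0 = (tm + cm) / (tn + cn)

    def ll(k, n, p):
        p = min(max(p, 1e-300), 1 - 1e-16)
        return float(binom.logpmf(k, n, p))

    ll_full = ll(tm, tn, pt) + ll(cm, cn, pc)
    ll_null = ll(tm, tn, p0) + ll(cm, cn, p0)
    return -2.0 * (ll_null - ll_full)


def gene_categories_direct(gene, chrom: str, start: int, end: int
                           ) -> set[str]:
    """Flank categories of one query interval, by direct window arithmetic."""
    cats: set[str] = set()
    if gene.chrom != chrom:
        return cats

    def hits(lo: int, hi: int) -> bool:
        lo = max(lo, 0)
        return lo < hi and start < hi and lo < end

    if gene.strand == "+":
        tss, tes = gene.tx_start, gene.tx_end
        windows = {
            "promoter": (tss - 1000, tss + 500),
            "upstream": (tss - 5000, tss - 1000),
            "tes": (tes - 500, tes + 1000),
            "downstream": (tes + 1000, tes + 5000),
        }
    else:
        tss, tes = gene.tx_end, gene.tx_start
        windows = {
            "promoter": (tss - 500, tss + 1000),
            "upstream": (tss + 1000, tss + 5000),
            "tes": (tes - 1000, tes + 500),
            "downstream": (tes - 5000, tes - 1000),
        }
    for cat, (lo, hi) in windows.items():
        if hits(lo, hi):
            cats.add(cat)
    for s, e in zip(gene.exon_starts, gene.exon_ends):
        if hits(s, e):
            cats.add("exon")
    for e_prev, s_next in zip(gene.exon_ends[:-1], gene.exon_starts[1:]):
        if hits(e_prev, s_next):
            cats.add("intron")
    return cats


PRIORITY_ORDER = ["promoter", "upstream", "tes", "downstream", "exon",
                  "intron", "intergenic"]


def assign_location_allpairs(genes, chrom: str, start: int, end: int) -> str:
    """Priority-resolved location by an all-pairs scan over genes."""
    cats: set[str] = set()
    for gene in genes:
        cats |= gene_categories_direct(gene, chrom, start, end)
    for cat in PRIORITY_ORDER:
        if cat in cats:
            return cat
    return "intergenic"


def tile_members_interval_scan(sites, tile_width: int):
    """Map tile (chrom, start, end) -> member sites by scanning windows."""
    out = {}
    max_pos = {}
    for s in sites:
        max_pos[s.chrom] = max(max_pos.get(s.chrom, 0), s.pos)
    for chrom, hi in max_pos.items():
        for start in range(0, hi + tile_width, tile_width):
            end = start + tile_width
            members = [s for s in sites
                       if s.chrom == chrom and start < s.pos <= end]
            if members:
                out[(chrom, start, end)] = sorted(members)
    return out
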
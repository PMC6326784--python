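"""Genomic location assignment, ICR overlap/summary, and ICR refinement.

Each site or tile is assigned one location relative to nearby genes using
the fixed priority promoter > upstream > TES > downstream > exon > intron
> intergenic. Flank windows are strand-oriented distances from the TSS/TES
(promoter −1 kb..+0.5 kb, upstream −5 kb..−1 kb, TES −0.5 kb..+1 kb,
downstream +1 kb..+5 kb, all half-open, clipped at position 0); categories
from all overlapping genes are pooled before priority resolution, so gene
order never matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .dml import Comparison, DMRecord, STATUS_HYPO, counts_frame
from .io_formats import AnalysisConfig, GeneModel, Region, SiteKey

log = logging.getLogger(__name__)

PRIORITY = ("promoter", "upstream", "tes", "downstream", "exon", "intron",
            "intergenic")
_RANK = {cat: i for i, cat in enumerate(PRIORITY)}


@dataclass
class FlankSet:
    """Derived intervals of one gene, 0-based half-open genome coordinates."""

    gene: str
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def _clip(start: int, end: int) -> tuple[int, int] | None:
    start = max(start, 0)
    return (start, end) if start < end else None


def build_flanks(gene: GeneModel, config: AnalysisConfig | None = None
                 ) -> FlankSet:
    """Promoter/upstream/TES/downstream windows plus exons and introns.

    On the + strand TSS = tx_start and TES = tx_end; on the − strand the
    roles swap and every window mirrors through its anchor.
    """
    cfg = config or AnalysisConfig()
    out: dict[str, list[tuple[int, int]]] = {}

    def add(cat: str, iv: tuple[int, int] | None) -> None:
        if iv is not None:
            out.setdefault(cat, []).append(iv)

    def window(anchor: int, rel: tuple[int, int], strand: str
               ) -> tuple[int, int] | None:
        lo, hi = rel
        if strand == "+":
            return _clip(anchor + lo, anchor + hi)
        return _clip(anchor - hi, anchor - lo)

    if gene.strand == "+":
        tss, tes = gene.tx_start, gene.tx_end
    else:
        tss, tes = gene.tx_end, gene.tx_start
    add("promoter", window(tss, cfg.flank_promoter, gene.strand))
    add("upstream", window(tss, cfg.flank_upstream, gene.strand))
    add("tes", window(tes, cfg.flank_tes, gene.strand))
    add("downstream", window(tes, cfg.flank_downstream, gene.strand))
    for s, e in zip(gene.exon_starts, gene.exon_ends):
        add("exon", (s, e))
    for prev_end, next_start in zip(gene.exon_ends[:-1], gene.exon_starts[1:]):
        add("intron", _clip(prev_end, next_start))
    return FlankSet(gene=gene.name, intervals=out)


class GeneIndex:
    """Interval index of flank categories for fast location queries."""

    def __init__(self, genes: Iterable[GeneModel],
                 config: AnalysisConfig | None = None) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes:
            flanks = build_flanks(gene, config)
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for cat, ivs in flanks.intervals.items():
                for s, e in ivs:
                    tree.addi(s, e, cat)

    def categories(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def assign_location(chrom: str, start: int, end: int,
                    index: GeneIndex) -> str:
    """Highest-priority category overlapped by [start, end); else intergenic.

    A CpG site is the width-1 query [pos-1, pos); a tile matches on
    any-base overlap.
    """
    cats = index.categories(chrom, start, end)
    if not cats:
        return "intergenic"
    return min(cats, key=_RANK.__getitem__)


def assign_site_location(site: SiteKey, index: GeneIndex) -> str:
    return assign_location(site.chrom, site.pos - 1, site.pos, index)


def overlap_icr(units: Sequence[tuple[str, str, int, int]],
                icrs: Sequence[Region]) -> dict[str, str | None]:
    """Map unit id → ICR name by any-base overlap (0-based half-open units).

    ``units`` are (unit_id, chrom, start, end). When several ICRs overlap a
    unit, the first by coordinate wins.
    """
    trees: dict[str, IntervalTree] = {}
    for icr in icrs:
        trees.setdefault(icr.chrom, IntervalTree()).addi(
            icr.start, icr.end, icr)
    out: dict[str, str | None] = {}
    for unit_id, chrom, start, end in units:
        tree = trees.get(chrom)
        hits = sorted(tree.overlap(start, end),
                      key=lambda iv: (iv.begin, iv.end)) if tree else []
        out[unit_id] = hits[0].data.name if hits else None
    return out


def annotate_records(records: Sequence[DMRecord], genes: Sequence[GeneModel],
                     icrs: Sequence[Region],
                     config: AnalysisConfig | None = None) -> list[DMRecord]:
    """Fill ``location`` and ``icr`` on DM records in place; returns them."""
    index = GeneIndex(genes, config)
    units = [(r.unit, r.chrom, r.start, r.end) for r in records]
    icr_map = overlap_icr(units, icrs)
    for r in records:
        r.location = assign_location(r.chrom, r.start, r.end, index)
        r.icr = icr_map[r.unit]
    return list(records)


def icr_methylation_summary(comparison: Comparison, icrs: Sequence[Region],
                            config: AnalysisConfig | None = None
                            ) -> pd.DataFrame:
    """Pooled methylation percentage of qualified CpGs per ICR and group.

    Rows are ICR names plus an ``ALL_ICRS`` pooled row; columns are the two
    group labels ("test", "ctrl") keyed by genotype where unambiguous. ICRs
    without any qualified site are reported as NaN, not 0 — absence of
    evidence is not hypomethylation.
    """
    cfg = config or AnalysisConfig()
    frame = counts_frame(comparison.samples)
    cov = frame.T.groupby(level=0).sum().T
    qualified = (cov >= cfg.min_site_cov).all(axis=1).to_numpy()

    groups = {
        "test": [s.sample_id for s in comparison.test_group],
        "ctrl": [s.sample_id for s in comparison.control_group],
    }
    chroms = frame.index.get_level_values("chrom").to_numpy()
    poss = frame.index.get_level_values("pos").to_numpy()

    rows = {}
    totals = {g: [0, 0] for g in groups}  # [meth, cov]
    for icr in sorted(icrs, key=lambda r: (r.chrom, r.start)):
        # 1-based site pos p overlaps [start,end) iff start < p <= end
        mask = ((chroms == icr.chrom) & (poss > icr.start)
                & (poss <= icr.end) & qualified)
        row = {}
        for gname, sids in groups.items():
            m = sum(int(frame.loc[mask, (sid, "m")].sum()) for sid in sids)
            u = sum(int(frame.loc[mask, (sid, "u")].sum()) for sid in sids)
            row[gname] = 100.0 * m / (m + u) if m + u else float("nan")
            totals[gname][0] += m
            totals[gname][1] += m + u
        row["n_qualified_cpgs"] = int(mask.sum())
        rows[icr.name] = row
    rows["ALL_ICRS"] = {
        g: (100.0 * totals[g][0] / totals[g][1] if totals[g][1]
            else float("nan"))
        for g in groups}
    rows["ALL_ICRS"]["n_qualified_cpgs"] = sum(
        r["n_qualified_cpgs"] for name, r in rows.items() if name != "ALL_ICRS")
    return pd.DataFrame.from_dict(rows, orient="index")


def _name_stem(name: str) -> str:
    """ICR name without a trailing part suffix (ZAC1_1, ZAC1_2 → ZAC1)."""
    for sep in ("_", "-", "."):
        head, _, tail = name.rpartition(sep)
        if head and tail.isdigit():
            return head
    return name


def refine_icrs(icrs: Sequence[Region], hypo_sites: Iterable[SiteKey],
                config: AnalysisConfig | None = None
                ) -> tuple[list[Region], list[str]]:
    """Data-driven ICR boundary refinement; returns (regions, change log).

    Two edits, applied to a fixed point so the operation is idempotent:

    * merge: two same-stem ICRs separated by <= ``icr_merge_max_gap`` bp
      become one continuous region when at least one DM-called
      hypomethylated CpG lies in the gap;
    * extend: a boundary moves outward to the farthest hypomethylated CpG
      within ``icr_extend_max`` bp of it.
    """
    cfg = config or AnalysisConfig()
    hypo = sorted(set(hypo_sites))
    by_chrom: dict[str, list[int]] = {}
    for s in hypo:
        by_chrom.setdefault(s.chrom, []).append(s.pos)

    regions = list(icrs)
    changes: list[str] = []
    for _ in range(100):  # fixed-point iteration; bounded for safety
        changed = False

        # merge pass
        regions.sort(key=lambda r: (r.chrom, r.start))
        merged: list[Region] = []
        i = 0
        while i < len(regions):
            cur = regions[i]
            if i + 1 < len(regions):
                nxt = regions[i + 1]
                gap = nxt.start - cur.end
                if (cur.chrom == nxt.chrom
                        and _name_stem(cur.name) == _name_stem(nxt.name)
                        and 0 <= gap <= cfg.icr_merge_max_gap):
                    in_gap = [p for p in by_chrom.get(cur.chrom, [])
                              if cur.end < p <= nxt.start]
                    if in_gap:
                        merged.append(Region(_name_stem(cur.name), cur.chrom,
                                             cur.start, max(cur.end, nxt.end)))
                        changes.append(
                            f"merge {cur.name}+{nxt.name} -> "
                            f"{_name_stem(cur.name)} (gap {gap} bp, "
                            f"{len(in_gap)} hypo CpGs in gap)")
                        changed = True
                        i += 2
                        continue
            merged.append(cur)
            i += 1
        regions = merged

        # extend pass
        extended: list[Region] = []
        for r in regions:
            positions = by_chrom.get(r.chrom, [])
            # downstream of end: 0-based site start in (end-1, end+extend)
            past_end = [p for p in positions
                        if r.end < p <= r.end + cfg.icr_extend_max]
            # upstream of start: 1-based pos in [start-extend+1, start]
            before_start = [p for p in positions
                            if r.start - cfg.icr_extend_max < p <= r.start]
            new_start, new_end = r.start, r.end
            if past_end:
                new_end = max(past_end)
                changes.append(f"extend {r.name} end {r.end} -> {new_end} "
                               f"(+{new_end - r.end} bp, {len(past_end)} "
                               f"hypo CpGs 1-{max(p - r.end for p in past_end)}"
                               " bp downstream)")
                changed = True
            if before_start:
                new_start = min(before_start) - 1
                changes.append(f"extend {r.name} start {r.start} -> "
                               f"{new_start} (-{r.start - new_start} bp, "
                               f"{len(before_start)} hypo CpGs upstream)")
                changed = True
            extended.append(Region(r.name, r.chrom, new_start, new_end))
        regions = extended
        if not changed:
            break
    return regions, changes


def hypo_sites_of(records: Sequence[DMRecord]) -> list[SiteKey]:
    """SiteKeys of DM-called hypomethylated site records."""
    return [SiteKey(r.chrom, r.end) for r in records
            if r.status == STATUS_HYPO and r.end - r.start == 1]
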
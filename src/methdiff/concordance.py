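"""Cross-genotype concordance of differential-methylation calls.

From one comparison (typically KO vs WT) two tile groups are extracted:

* Group A — hypomethylated tiles: difference <= −25 points, q <= 0.01
  (inclusive, the standard call);
* Group B — stringently unchanged tiles: |difference| < 5 points and
  q > 0.1 (strict), which excludes tiles with intermediate 5–25 point
  losses from the "true unchanged" set.

Those units are then restricted to the ones testable in every other
comparison and scored for the same behaviour there, yielding the
"X of N (~P%)" concordance fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .dml import DMRecord, STATUS_HYPO, STATUS_UNQUALIFIED
from .io_formats import AnalysisConfig
from .reporting import round_half_up

GROUP_A = "A"
GROUP_B = "B"


@dataclass
class GroupExtract:
    """Unit ids of one extracted group plus its provenance."""

    group: str
    unit_ids: list[str]
    source_label: str


@dataclass
class ConcordanceResult:
    """Concordance of one extracted group in one other comparison."""

    group: str
    other_label: str
    n_common: int
    n_called: int
    fraction_exact: float
    fraction_reported: float
    n_not_significant: int  # units merely lacking a call in the other
    per_unit_diff: dict[str, float] = field(default_factory=dict)


def is_group_a(record: DMRecord, config: AnalysisConfig) -> bool:
    if record.q is None:
        return False
    return record.diff <= -config.dm_min_diff and record.q <= config.dm_max_q


def is_group_b(record: DMRecord, config: AnalysisConfig) -> bool:
    if record.q is None:
        return False
    return (abs(record.diff) < config.unchanged_max_diff
            and record.q > config.unchanged_min_q)


def extract_group(records: Sequence[DMRecord], group: str,
                  config: AnalysisConfig, source_label: str = ""
                  ) -> GroupExtract:
    """Extract Group A (hypomethylated) or B (unchanged) unit ids."""
    if group == GROUP_A:
        pred = is_group_a
    elif group == GROUP_B:
        pred = is_group_b
    else:
        raise ValueError(f"unknown group {group!r}")
    ids = [r.unit for r in records if pred(r, config)]
    return GroupExtract(group=group, unit_ids=ids, source_label=source_label)


def _tile_width_of(unit_id: str) -> int | None:
    chrom, _, span = unit_id.rpartition(":")
    if chrom and "-" in span:
        start, _, end = span.partition("-")
        return int(end) - int(start)
    return None  # site unit


def common_units(extract: GroupExtract,
                 other_comparisons: Mapping[str, Sequence[DMRecord]]
                 ) -> list[str]:
    """Extract units qualified (testable) in every other comparison.

    All comparisons must share one tiling scheme; a tile-width mismatch
    would silently intersect to nothing, so it is an error instead.
    """
    widths = {w for u in extract.unit_ids
              if (w := _tile_width_of(u)) is not None}
    keep = list(extract.unit_ids)
    for label, records in other_comparisons.items():
        other_widths = {w for r in records if r.status != STATUS_UNQUALIFIED
                        and (w := _tile_width_of(r.unit)) is not None}
        if widths and other_widths and widths != other_widths:
            raise ValueError(f"{label}: tile width mismatch "
                             f"({sorted(widths)} vs {sorted(other_widths)})")
        testable = {r.unit for r in records
                    if r.status != STATUS_UNQUALIFIED}
        keep = [u for u in keep if u in testable]
    return keep


def concordance_fraction(common: Sequence[str],
                         other_records: Sequence[DMRecord],
                         group: str, config: AnalysisConfig,
                         other_label: str = "") -> ConcordanceResult:
    """Fraction of common units showing the group's behaviour elsewhere.

    Group A counts standard hypomethylation calls in the other comparison;
    Group B counts units meeting the full unchanged criteria there (the
    looser "merely not significant" count is reported alongside).
    """
    if not common:
        raise ValueError("concordance_fraction: no common units")
    by_unit = {r.unit: r for r in other_records}
    missing = [u for u in common if u not in by_unit]
    if missing:
        raise ValueError(f"other comparison lacks records for "
                         f"{len(missing)} common units (e.g. {missing[0]})")
    n_called = 0
    n_not_significant = 0
    diffs = {}
    for unit in common:
        rec = by_unit[unit]
        diffs[unit] = rec.diff
        if group == GROUP_A:
            if rec.status == STATUS_HYPO:
                n_called += 1
        else:
            if is_group_b(rec, config):
                n_called += 1
        if rec.status not in (STATUS_HYPO, "hyper"):
            n_not_significant += 1
    exact = 100.0 * n_called / len(common)
    return ConcordanceResult(
        group=group, other_label=other_label, n_common=len(common),
        n_called=n_called, fraction_exact=exact,
        fraction_reported=round_half_up(exact, 0),
        n_not_significant=n_not_significant, per_unit_diff=diffs)


def common_hypo_sites(dm_a: Sequence[DMRecord], dm_b: Sequence[DMRecord],
                      config: AnalysisConfig
                      ) -> tuple[set[str], set[str], set[str]]:
    """Partition the union of hypomethylated sites of two comparisons.

    A union member counts as *common* when its q-value is <= the call
    threshold in both comparisons; the rest split by origin.
    """
    hypo_a = {r.unit for r in dm_a if r.status == STATUS_HYPO}
    hypo_b = {r.unit for r in dm_b if r.status == STATUS_HYPO}
    q_a = {r.unit: r.q for r in dm_a if r.q is not None}
    q_b = {r.unit: r.q for r in dm_b if r.q is not None}
    union = hypo_a | hypo_b
    common = {u for u in union
              if q_a.get(u, 1.0) <= config.dm_max_q
              and q_b.get(u, 1.0) <= config.dm_max_q}
    a_only = hypo_a - common
    b_only = hypo_b - common
    return common, a_only, b_only


def write_concordance_tsv(results: Sequence[ConcordanceResult],
                          path) -> None:
    """Plain-TSV export (one row per group x other comparison)."""
    with open(path, "w") as fh:
        fh.write("group\tother\tn_common\tn_called\tfraction_exact\t"
                 "fraction_reported\tn_not_significant\n")
        for r in results:
            fh.write(f"{r.group}\t{r.other_label}\t{r.n_common}\t"
                     f"{r.n_called}\t{r.fraction_exact:.6f}\t"
                     f"{r.fraction_reported:.0f}\t{r.n_not_significant}\n")


def write_diff_distribution_tsv(results: Sequence[ConcordanceResult],
                                path) -> None:
    """Per-unit diffs for violin-style plotting downstream."""
    with open(path, "w") as fh:
        fh.write("group\tother\tunit\tdiff\n")
        for r in results:
            for unit, diff in sorted(r.per_unit_diff.items()):
                fh.write(f"{r.group}\t{r.other_label}\t{unit}\t{diff:.6f}\n")
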
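"""Fixed 500-bp tiling of CpG calls and tile-level differential methylation.

Tiles are ungapped, non-overlapping windows anchored at 0-based multiples
of the tile width from each chromosome origin; a 1-based CpG position
belongs to tile ``floor((pos-1)/width)``. A tile qualifies when at least
``tile_min_cpgs`` of its member CpGs have coverage >= ``tile_min_cov`` in
every sample of both groups (per-site-in-all-samples reading, which keeps
tiles comparable across samples). Tested counts are per-sample sums over
member sites; thresholds for calling are identical to the site level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dml import (Comparison, DMRecord, STATUS_UNQUALIFIED, adjust_bh,
                  call_dm, counts_frame, logistic_lrt_arrays,
                  test_unit_fisher)
from .io_formats import AnalysisConfig, MethCallSet, SiteKey

log = logging.getLogger(__name__)


@dataclass
class Tile:
    """One window with its member CpGs and per-sample aggregated counts."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    member_sites: list[SiteKey] = field(default_factory=list)
    per_sample_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def tile_index(pos: int, tile_width: int) -> int:
    """Window index of a 1-based site position."""
    return (pos - 1) // tile_width


def tile_id_of_site(site: SiteKey, tile_width: int) -> str:
    k = tile_index(site.pos, tile_width)
    return f"{site.chrom}:{k * tile_width}-{(k + 1) * tile_width}"


def assign_tiles(call_sets: Sequence[MethCallSet],
                 tile_width: int) -> list[Tile]:
    """Materialize every tile containing at least one observed site."""
    if tile_width <= 0:
        raise ValueError("tile_width must be positive")
    members: dict[tuple[str, int], list[SiteKey]] = {}
    all_sites: set[SiteKey] = set()
    for cs in call_sets:
        all_sites.update(cs.calls)
    for site in sorted(all_sites):
        k = tile_index(site.pos, tile_width)
        members.setdefault((site.chrom, k), []).append(site)
    tiles = []
    for (chrom, k), sites in sorted(members.items()):
        tile = Tile(chrom=chrom, start=k * tile_width,
                    end=(k + 1) * tile_width, member_sites=sites)
        tile.per_sample_counts = aggregate_tile_counts(tile, call_sets)
        tiles.append(tile)
    return tiles


def aggregate_tile_counts(tile: Tile, call_sets: Sequence[MethCallSet]
                          ) -> dict[str, tuple[int, int]]:
    """Per-sample (n_meth, n_unmeth) sums over the tile's member sites."""
    out = {}
    for cs in call_sets:
        m = u = 0
        for site in tile.member_sites:
            cm, cu = cs.counts(site)
            m += cm
            u += cu
        out[cs.sample_id] = (m, u)
    return out


def qualify_tiles(tiles: Sequence[Tile], comparison: Comparison,
                  config: AnalysisConfig) -> set[str]:
    """Tile ids with >= ``tile_min_cpgs`` member CpGs at >= ``tile_min_cov``
    coverage in every sample of both groups."""
    samples = comparison.samples
    qualified = set()
    for tile in tiles:
        n_good = 0
        for site in tile.member_sites:
            if all(cs.coverage(site) >= config.tile_min_cov for cs in samples):
                n_good += 1
                if n_good >= config.tile_min_cpgs:
                    break
        if n_good >= config.tile_min_cpgs:
            qualified.add(tile.id)
    return qualified


def run_tile_dml(comparison: Comparison, config: AnalysisConfig
                 ) -> list[DMRecord]:
    """Tile-level pass: assign → qualify → aggregate → test → BH → call."""
    frame = counts_frame(comparison.samples)
    if frame.empty:
        return []
    w = config.tile_width
    chroms = frame.index.get_level_values("chrom").to_numpy()
    poss = frame.index.get_level_values("pos").to_numpy()
    tile_k = (poss - 1) // w

    sample_ids = [s.sample_id for s in comparison.samples]
    cov = frame.T.groupby(level=0).sum().T  # per-sample coverage per site
    site_good = (cov[sample_ids] >= config.tile_min_cov).all(axis=1).to_numpy()

    key = pd.MultiIndex.from_arrays([chroms, tile_k], names=["chrom", "k"])
    grouped = frame.groupby(key).sum()
    n_cpgs = pd.Series(1, index=key).groupby(level=[0, 1]).sum()
    n_good = pd.Series(site_good.astype(np.int64), index=key).groupby(
        level=[0, 1]).sum()
    qualified = (n_good >= config.tile_min_cpgs).to_numpy()

    test_ids = [s.sample_id for s in comparison.test_group]
    ctrl_ids = [s.sample_id for s in comparison.control_group]
    tm = sum(grouped[(sid, "m")].to_numpy() for sid in test_ids)
    tu = sum(grouped[(sid, "u")].to_numpy() for sid in test_ids)
    cm = sum(grouped[(sid, "m")].to_numpy() for sid in ctrl_ids)
    cu = sum(grouped[(sid, "u")].to_numpy() for sid in ctrl_ids)
    meth_test = 100.0 * tm / np.maximum(tm + tu, 1)
    meth_ctrl = 100.0 * cm / np.maximum(cm + cu, 1)

    use_logistic = comparison.has_replicates
    log.info("%s tiles: %d observed, %d qualified (>=%d CpGs at >=%dx); "
             "test = %s", comparison.label, len(grouped),
             int(qualified.sum()), config.tile_min_cpgs, config.tile_min_cov,
             "logistic" if use_logistic else "fisher")

    n = len(grouped)
    p = np.full(n, np.nan)
    if qualified.any():
        qi = np.flatnonzero(qualified)
        if use_logistic:
            p[qi], _ = logistic_lrt_arrays(tm[qi], tu[qi], cm[qi], cu[qi])
        else:
            p[qi] = [test_unit_fisher((int(tm[i]), int(tu[i])),
                                      (int(cm[i]), int(cu[i]))) for i in qi]
    q = np.full(n, np.nan)
    if qualified.any():
        q[qualified] = adjust_bh(p[qualified])

    records = []
    for i, (chrom, k) in enumerate(grouped.index):
        start, end = int(k) * w, (int(k) + 1) * w
        diff = float(meth_test[i] - meth_ctrl[i])
        if qualified[i]:
            status = call_dm(diff, float(q[i]), config)
            rec = DMRecord(unit=f"{chrom}:{start}-{end}", chrom=chrom,
                           start=start, end=end,
                           meth_test=float(meth_test[i]),
                           meth_ctrl=float(meth_ctrl[i]), diff=diff,
                           p=float(p[i]), q=float(q[i]), status=status,
                           n_cpgs=int(n_cpgs.iloc[i]))
        else:
            rec = DMRecord(unit=f"{chrom}:{start}-{end}", chrom=chrom,
                           start=start, end=end,
                           meth_test=float(meth_test[i]),
                           meth_ctrl=float(meth_ctrl[i]), diff=diff,
                           p=None, q=None, status=STATUS_UNQUALIFIED,
                           n_cpgs=int(n_cpgs.iloc[i]))
        records.append(rec)
    return records
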
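"""Site-level differential methylation: qualification, testing, calling.

The statistical model mirrors the replicate-aware path of count-based DM
testing: per unit (CpG site or tile), methylated read counts are modelled
as binomial with a logit-linear group effect, and significance comes from
the likelihood-ratio statistic against an intercept-only null (chi-square,
1 df). With a single binary covariate the binomial-logistic MLE is
available in closed form — the fitted proportion of each group is its
coverage-pooled methylation fraction — so no iterative fit is needed and
the whole genome is tested in one vectorized pass. For 1-vs-1 comparisons
(no replicates) Fisher's exact test on the pooled 2x2 table is used
instead.

Multiple testing uses Benjamini–Hochberg step-up over qualified units
only; calls require |difference| >= 25 percentage points at q <= 0.01
(both boundaries inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnalysisConfig, MethCallSet, SiteKey

log = logging.getLogger(__name__)

STATUS_HYPO = "hypo"
STATUS_HYPER = "hyper"
STATUS_NS = "ns"
STATUS_UNQUALIFIED = "unqualified"

STATE_UNMETHYLATED = "unmethylated"
STATE_PARTIAL = "partial"
STATE_HIGH = "high"


@dataclass
class Comparison:
    """A test-vs-control contrast, e.g. KO_vs_WT (diff sign = test − control)."""

    test_group: list[MethCallSet]
    control_group: list[MethCallSet]
    label: str

    def __post_init__(self) -> None:
        if not self.test_group or not self.control_group:
            raise ValueError(f"{self.label}: both groups must be non-empty")
        ids = [s.sample_id for s in self.test_group + self.control_group]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.label}: duplicate sample_ids across groups")

    @property
    def samples(self) -> list[MethCallSet]:
        return self.test_group + self.control_group

    @property
    def has_replicates(self) -> bool:
        return len(self.test_group) >= 2 or len(self.control_group) >= 2


@dataclass
class DMRecord:
    """Per-unit DM result. ``unit`` is "chrom:pos" for a site or
    "chrom:start-end" for a tile; ``start``/``end`` are 0-based half-open."""

    unit: str
    chrom: str
    start: int
    end: int
    meth_test: float
    meth_ctrl: float
    diff: float
    p: float | None
    q: float | None
    status: str
    location: str | None = None
    icr: str | None = None
    n_cpgs: int | None = None

    def __post_init__(self) -> None:
        if abs(self.diff - (self.meth_test - self.meth_ctrl)) > 1e-9:
            raise ValueError(f"{self.unit}: diff must equal meth_test - meth_ctrl")


def site_unit(site: SiteKey) -> str:
    return f"{site.chrom}:{site.pos}"


def counts_frame(samples: Sequence[MethCallSet]) -> pd.DataFrame:
    """Union of all sites x samples as a wide frame.

    Index: (chrom, pos). Columns: MultiIndex (sample_id, {m,u}); sites a
    sample did not observe carry zeros. Order-independent by construction
    (sorted index).
    """
    pieces = {}
    for s in samples:
        if s.calls:
            idx = pd.MultiIndex.from_tuples(list(s.calls),
                                            names=["chrom", "pos"])
            data = np.array([[c.n_meth, c.n_unmeth] for c in s.calls.values()],
                            dtype=np.int64)
        else:
            idx = pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"])
            data = np.empty((0, 2), dtype=np.int64)
        pieces[s.sample_id] = pd.DataFrame(data, index=idx, columns=["m", "u"])
    out = pd.concat(pieces, axis=1, join="outer").fillna(0).astype(np.int64)
    return out.sort_index()


def qualify_sites(comparison: Comparison, min_site_cov: int) -> set[SiteKey]:
    """Sites with coverage >= ``min_site_cov`` in every sample of both groups."""
    frame = counts_frame(comparison.samples)
    if frame.empty:
        return set()
    cov = frame.T.groupby(level=0).sum().T  # coverage per sample
    ok = (cov >= min_site_cov).all(axis=1)
    return {SiteKey(c, int(p)) for c, p in frame.index[ok]}


def group_percent(calls: Iterable[tuple[int, int]]) -> float:
    """Coverage-pooled methylation percentage: 100·Σm / Σ(m+u)."""
    m = u = 0
    for n_meth, n_unmeth in calls:
        m += n_meth
        u += n_unmeth
    if m + u == 0:
        raise ValueError("group_percent: zero total coverage")
    return 100.0 * m / (m + u)


def test_unit_fisher(test_counts: tuple[int, int],
                     ctrl_counts: tuple[int, int]) -> float:
    """Two-sided Fisher exact p for the pooled 2x2 (meth,unmeth)x(test,ctrl).

    Two-sided in the hypergeometric-tail sense: the sum of probabilities of
    all tables with fixed margins no more likely than the observed one.
    Any zero margin makes the table untestable; p = 1 with a warning.
    """
    tm, tu = test_counts
    cm, cu = ctrl_counts
    table = np.array([[tm, tu], [cm, cu]], dtype=np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.warning("fisher: zero margin in table %s; p = 1", table.tolist())
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _binom_ll(m: np.ndarray, u: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel m·ln p + u·ln(1−p) with 0·ln 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term_m = np.where(m > 0, m * np.log(p), 0.0)
        term_u = np.where(u > 0, u * np.log1p(-p), 0.0)
    return term_m + term_u


def logistic_lrt_arrays(tm: np.ndarray, tu: np.ndarray,
                        cm: np.ndarray, cu: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized binomial-logistic LRT of group effect; returns (p, G).

    Because replicates within a group share one fitted proportion, their
    log-likelihood contributions sum to the pooled-count contribution, so
    pooled per-group counts are sufficient. Degenerate units (zero total
    coverage in a group) get p = 1.
    """
    tm, tu, cm, cu = (np.asarray(a, dtype=np.float64) for a in (tm, tu, cm, cu))
    nt, nc = tm + tu, cm + cu
    with np.errstate(divide="ignore", invalid="ignore"):
        pt = np.where(nt > 0, tm / np.maximum(nt, 1), 0.0)
        pc = np.where(nc > 0, cm / np.maximum(nc, 1), 0.0)
        p0 = (tm + cm) / np.maximum(nt + nc, 1)
    ll_full = _binom_ll(tm, tu, pt) + _binom_ll(cm, cu, pc)
    ll_null = _binom_ll(tm + cm, tu + cu, p0)
    g = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pvals = stats.chi2.sf(g, df=1)
    degenerate = (nt == 0) | (nc == 0)
    pvals = np.where(degenerate, 1.0, pvals)
    return pvals, g


def test_unit_logistic(test_group_counts: Sequence[tuple[int, int]],
                       ctrl_group_counts: Sequence[tuple[int, int]]) -> float:
    """Replicate-aware binomial-logistic likelihood-ratio p for one unit."""
    if not test_group_counts or not ctrl_group_counts:
        raise ValueError("both groups need at least one replicate")
    tm = sum(m for m, _ in test_group_counts)
    tu = sum(u for _, u in test_group_counts)
    cm = sum(m for m, _ in ctrl_group_counts)
    cu = sum(u for _, u in ctrl_group_counts)
    if tm + tu == 0 or cm + cu == 0:
        raise ValueError("each group needs positive total coverage")
    p, _ = logistic_lrt_arrays(np.array([tm]), np.array([tu]),
                               np.array([cm]), np.array([cu]))
    return float(p[0])


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j)·m/j, capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_dm(diff: float, q: float, config: AnalysisConfig) -> str:
    """Call hypo/hyper/ns from difference and q, boundaries inclusive."""
    if q <= config.dm_max_q:
        if diff <= -config.dm_min_diff:
            return STATUS_HYPO
        if diff >= config.dm_min_diff:
            return STATUS_HYPER
    return STATUS_NS


def classify_state(percent: float, config: AnalysisConfig) -> str:
    """Three-way methylation state: <20 unmethylated, 20–80 partial, >=80 high."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent out of range: {percent}")
    if percent < config.state_low:
        return STATE_UNMETHYLATED
    if percent >= config.state_high:
        return STATE_HIGH
    return STATE_PARTIAL


def _group_sums(frame: pd.DataFrame, sample_ids: Sequence[str]
                ) -> tuple[np.ndarray, np.ndarray]:
    m = sum(frame[(sid, "m")].to_numpy() for sid in sample_ids)
    u = sum(frame[(sid, "u")].to_numpy() for sid in sample_ids)
    return np.asarray(m, dtype=np.int64), np.asarray(u, dtype=np.int64)


def run_site_dml(comparison: Comparison, config: AnalysisConfig
                 ) -> list[DMRecord]:
    """Full site-level pass: qualify → test → BH → call.

    Every observed site gets a record; sites failing the coverage filter
    carry status ``unqualified`` with no p/q. The logistic path is used
    whenever either group has >= 2 replicates, Fisher otherwise — the
    choice is logged per comparison.
    """
    frame = counts_frame(comparison.samples)
    if frame.empty:
        return []
    test_ids = [s.sample_id for s in comparison.test_group]
    ctrl_ids = [s.sample_id for s in comparison.control_group]

    cov = frame.T.groupby(level=0).sum().T
    qualified = (cov >= config.min_site_cov).all(axis=1).to_numpy()

    tm, tu = _group_sums(frame, test_ids)
    cm, cu = _group_sums(frame, ctrl_ids)
    with np.errstate(invalid="ignore"):
        meth_test = 100.0 * tm / np.maximum(tm + tu, 1)
        meth_ctrl = 100.0 * cm / np.maximum(cm + cu, 1)

    use_logistic = comparison.has_replicates
    log.info("%s: %d sites observed, %d qualified (>=%dx all samples); "
             "test = %s", comparison.label, len(frame), int(qualified.sum()),
             config.min_site_cov, "logistic" if use_logistic else "fisher")

    p = np.full(len(frame), np.nan)
    if qualified.any():
        qi = np.flatnonzero(qualified)
        if use_logistic:
            p[qi], _ = logistic_lrt_arrays(tm[qi], tu[qi], cm[qi], cu[qi])
        else:
            p[qi] = [test_unit_fisher((tm[i], tu[i]), (cm[i], cu[i]))
                     for i in qi]
    q = np.full(len(frame), np.nan)
    if qualified.any():
        q[qualified] = adjust_bh(p[qualified])

    records: list[DMRecord] = []
    for i, (chrom, pos) in enumerate(frame.index):
        pos = int(pos)
        if qualified[i]:
            diff = float(meth_test[i] - meth_ctrl[i])
            status = call_dm(diff, float(q[i]), config)
            rec = DMRecord(unit=f"{chrom}:{pos}", chrom=chrom,
                           start=pos - 1, end=pos,
                           meth_test=float(meth_test[i]),
                           meth_ctrl=float(meth_ctrl[i]), diff=diff,
                           p=float(p[i]), q=float(q[i]), status=status)
        else:
            diff = float(meth_test[i] - meth_ctrl[i])
            rec = DMRecord(unit=f"{chrom}:{pos}", chrom=chrom,
                           start=pos - 1, end=pos,
                           meth_test=float(meth_test[i]),
                           meth_ctrl=float(meth_ctrl[i]), diff=diff,
                           p=None, q=None, status=STATUS_UNQUALIFIED)
        records.append(rec)
    return records
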
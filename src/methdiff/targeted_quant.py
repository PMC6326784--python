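"""Targeted quantification: clone-based bisulfite summaries, conversion QC,
and protein half-life estimation from cycloheximide-chase densitometry."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

MISSING = "."


@dataclass
class CloneMatrix:
    """Clones x CpG calls for one PCR amplicon; NaN marks a missing call."""

    region: str
    calls: np.ndarray  # float array: 1 methylated, 0 unmethylated, NaN missing

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2 or self.calls.size == 0:
            raise ValueError("clone matrix needs >= 1 clone and >= 1 CpG")


def read_clone_matrix(path: str | Path, region: str | None = None
                      ) -> CloneMatrix:
    """Read a tiny TSV of clones (rows) x CpGs (columns), cells 1/0/'.'."""
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([math.nan if cell == MISSING else float(int(cell))
                         for cell in line.split("\t")])
    if not rows:
        raise ValueError(f"{path}: empty clone matrix")
    return CloneMatrix(region=region or Path(path).stem,
                       calls=np.array(rows, dtype=float))


def clone_region_percent(matrix: CloneMatrix) -> float:
    """Matrix-wide methylation percentage across all clones and CpGs.

    Pools every non-missing call (rather than averaging per-clone
    percentages), so clones with missing calls are weighted by what they
    actually report.
    """
    calls = matrix.calls
    n_obs = np.count_nonzero(~np.isnan(calls))
    if n_obs == 0:
        raise ValueError(f"{matrix.region}: all calls missing")
    return 100.0 * float(np.nansum(calls)) / n_obs


def conversion_rate(converted: int, unconverted: int) -> float:
    """Bisulfite conversion percentage from non-CpG cytosine calls.

    Non-CpG cytosines are essentially unmethylated in mESCs, so any
    retained C there is a conversion failure; adequate libraries exceed
    99%.
    """
    total = converted + unconverted
    if total == 0:
        raise ValueError("conversion_rate: zero total calls")
    if converted < 0 or unconverted < 0:
        raise ValueError("conversion_rate: negative counts")
    return 100.0 * converted / total


def conversion_passes_qc(rate: float, min_rate: float = 99.0) -> bool:
    return rate > min_rate


@dataclass
class HalfLifeResult:
    """Log-linear decay fit. ``half_life`` is NaN when no decay is seen."""

    half_life: float  # hours; NaN = "no decay"
    slope: float  # per hour, on ln(intensity)
    r_squared: float

    @property
    def no_decay(self) -> bool:
        return math.isnan(self.half_life)


def half_life(times: Sequence[float],
              intensities: Sequence[float]) -> HalfLifeResult:
    """Half-life from a cycloheximide chase by OLS of ln(intensity) on time.

    Densitometry noise is multiplicative, so the regression runs on logs;
    t1/2 = ln2 / (−slope). A non-negative slope means the protein did not
    measurably decay over the chase and is reported as the no-decay
    sentinel (NaN) rather than a negative half-life. Normalizing all
    intensities by a common loading-control factor leaves the slope, and
    hence the estimate, unchanged.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ValueError("need >= 3 matched time points")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must start at 0 and strictly increase")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")
    fit = stats.linregress(t, np.log(y))
    slope = float(fit.slope)
    r2 = float(fit.rvalue) ** 2
    if slope >= 0:
        return HalfLifeResult(half_life=math.nan, slope=slope, r_squared=r2)
    return HalfLifeResult(half_life=math.log(2) / -slope, slope=slope,
                          r_squared=r2)
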
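"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions (fixed across the package):

* Bismark coverage positions are 1-based inclusive; internal CpG site
  positions stay 1-based.
* BED and genePred/refFlat intervals are 0-based half-open; every internal
  interval (tiles, gene flanks, ICRs) is 0-based half-open.

Conversion happens exactly once, at the file boundary. All readers are
gzip-transparent (a ``.gz`` suffix triggers decompression).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence, TextIO

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class SiteKey(NamedTuple):
    """A single CpG cytosine: chromosome plus 1-based position."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class MethCall:
    """Methylated/unmethylated read counts at one CpG site."""

    site: SiteKey
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError(f"negative counts at {self.site}")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def percent(self) -> float:
        """Methylation percentage recomputed from counts (authoritative)."""
        return 100.0 * self.n_meth / self.coverage


@dataclass
class MethCallSet:
    """All CpG calls of one sample, keyed by site.

    ``genotype`` is a free-text group label (WT, KO, mKO, mzKO, ...).
    """

    sample_id: str
    genotype: str
    calls: dict[SiteKey, MethCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")

    def __len__(self) -> int:
        return len(self.calls)

    def sites(self) -> set[SiteKey]:
        return set(self.calls)

    def coverage(self, site: SiteKey) -> int:
        call = self.calls.get(site)
        return call.coverage if call is not None else 0

    def counts(self, site: SiteKey) -> tuple[int, int]:
        call = self.calls.get(site)
        return (call.n_meth, call.n_unmeth) if call is not None else (0, 0)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene structure, 0-based half-open coordinates."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.name}: strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.name}: tx_start must be < tx_end")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"{self.name}: exon list length mismatch")
        prev_end = self.tx_start
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.name}: exon [{s},{e}) outside transcript")
            if s < prev_end:
                raise ValueError(f"{self.name}: exons overlap or are unsorted")
            prev_end = e


@dataclass(frozen=True)
class Region:
    """A named genomic interval (e.g. an ICR), 0-based half-open."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.name}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnalysisConfig:
    """Every numeric threshold of the analysis in one place.

    Defaults reproduce the published qualification and calling rules:
    sites need >= 20x coverage in every sample, 500-bp tiles need at least
    three CpGs at >= 10x in every sample, and a differential call requires
    |difference| >= 25 percentage points at q <= 0.01.
    """

    min_site_cov: int = 20
    tile_width: int = 500
    tile_min_cpgs: int = 3
    tile_min_cov: int = 10
    dm_min_diff: float = 25.0
    dm_max_q: float = 0.01
    unchanged_max_diff: float = 5.0
    unchanged_min_q: float = 0.1
    state_low: float = 20.0
    state_high: float = 80.0
    # Strand-oriented distances from TSS/TES, transcription direction.
    flank_upstream: tuple[int, int] = (-5000, -1000)
    flank_promoter: tuple[int, int] = (-1000, 500)
    flank_tes: tuple[int, int] = (-500, 1000)
    flank_downstream: tuple[int, int] = (1000, 5000)
    icr_merge_max_gap: int = 500
    icr_extend_max: int = 600
    conversion_min_rate: float = 99.0
    destrand: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_site_cov", "tile_width", "tile_min_cpgs", "tile_min_cov",
                     "dm_min_diff", "unchanged_max_diff", "icr_merge_max_gap",
                     "icr_extend_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.state_low < self.state_high:
            raise ValueError("state_low must be < state_high")
        for name in ("flank_upstream", "flank_promoter", "flank_tes",
                     "flank_downstream"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} interval must be ordered")


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _iter_data_lines(handle: TextIO) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        yield lineno, line.split()


def read_bismark_coverage(path: str | Path, sample_id: str,
                          genotype: str) -> MethCallSet:
    """Load one sample's Bismark coverage file into a :class:`MethCallSet`.

    Expected columns: chrom, start (1-based), end, meth%, count-methylated,
    count-unmethylated. The percentage column is advisory only and is
    recomputed from the counts; zero-coverage lines are dropped with a
    warning.
    """
    calls: dict[SiteKey, MethCall] = {}
    with _open_text(path) as fh:
        for lineno, fields in _iter_data_lines(fh):
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                pos = int(fields[1])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field: {exc}") from exc
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: position must be >= 1")
            if n_meth + n_unmeth == 0:
                log.warning("%s:%d: zero-coverage site %s:%d dropped",
                            path, lineno, chrom, pos)
                continue
            key = SiteKey(chrom, pos)
            if key in calls:
                raise ParseError(f"{path}:{lineno}: duplicate site {chrom}:{pos}")
            calls[key] = MethCall(key, n_meth, n_unmeth)
    return MethCallSet(sample_id=sample_id, genotype=genotype, calls=calls)


def destrand(callset: MethCallSet) -> MethCallSet:
    """Merge the two strand calls of each CpG dyad (pos, pos+1) by summing.

    Off by default in the pipeline; the merged call keeps the lower
    position. Positions without a partner pass through unchanged.
    """
    merged: dict[SiteKey, MethCall] = {}
    consumed: set[SiteKey] = set()
    for key in sorted(callset.calls):
        if key in consumed:
            continue
        call = callset.calls[key]
        partner = SiteKey(key.chrom, key.pos + 1)
        other = callset.calls.get(partner)
        if other is not None:
            consumed.add(partner)
            call = MethCall(key, call.n_meth + other.n_meth,
                            call.n_unmeth + other.n_unmeth)
        merged[key] = call
    return MethCallSet(callset.sample_id, callset.genotype, merged)


def _parse_exon_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.strip(",").split(",") if x)


def read_genepred(path: str | Path) -> list[GeneModel]:
    """Load gene models from a genePred or refFlat table.

    Both dialects are accepted: refFlat prepends a geneName column, so the
    strand lands in column 3 instead of column 2. Trailing commas in the
    exon lists are tolerated; an exonCount that disagrees with the lists is
    an error.
    """
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, fields in _iter_data_lines(fh):
            if len(fields) >= 4 and fields[2] in {"+", "-"}:
                offset = 0  # genePred: name chrom strand txStart txEnd ...
            elif len(fields) >= 5 and fields[3] in {"+", "-"}:
                offset = 1  # refFlat: geneName name chrom strand ...
            else:
                raise ParseError(f"{path}:{lineno}: cannot locate strand column")
            try:
                name = fields[0]
                chrom = fields[offset + 1]
                strand = fields[offset + 2]
                tx_start = int(fields[offset + 3])
                tx_end = int(fields[offset + 4])
                exon_count = int(fields[offset + 7])
                exon_starts = _parse_exon_list(fields[offset + 8])
                exon_ends = _parse_exon_list(fields[offset + 9])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
                raise ParseError(
                    f"{path}:{lineno}: exonCount {exon_count} does not match "
                    f"exon lists ({len(exon_starts)}, {len(exon_ends)})")
            try:
                genes.append(GeneModel(name, chrom, strand, tx_start, tx_end,
                                       exon_starts, exon_ends))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_bed(path: str | Path) -> list[Region]:
    """Load BED3+ intervals; an optional 4th column names each region."""
    regions: list[Region] = []
    with _open_text(path) as fh:
        for lineno, fields in _iter_data_lines(fh):
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) >= 4 else f"region_{len(regions) + 1}"
            try:
                regions.append(Region(name, chrom, start, end))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# DM tables

_DM_COLUMNS = ("unit", "chrom", "start", "end", "meth_test", "meth_ctrl",
               "diff", "p", "q", "status", "location", "icr", "n_cpgs")


def _fmt(value, decimals: int = 6) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.{decimals}f}"
    return str(value)


def write_dm_table(records: Iterable, path: str | Path) -> None:
    """Write DM records as a deterministic, coordinate-sorted TSV.

    Numeric fields carry 6 decimals; missing p/q/location/icr are ``NA``.
    Writing the same records twice yields byte-identical files.
    """
    rows = sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.unit))
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_DM_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.unit, r.chrom, str(r.start), str(r.end),
                _fmt(r.meth_test), _fmt(r.meth_ctrl), _fmt(r.diff),
                _fmt(r.p, 9), _fmt(r.q, 9), r.status,
                r.location if r.location is not None else "NA",
                r.icr if r.icr is not None else "NA",
                str(r.n_cpgs) if r.n_cpgs is not None else "NA",
            ]) + "\n")


def read_dm_table(path: str | Path) -> list:
    """Read back a table written by :func:`write_dm_table`."""
    from .dml import DMRecord  # local import avoids a module cycle

    def _opt_float(text: str) -> float | None:
        return None if text == "NA" else float(text)

    records = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _DM_COLUMNS:
            raise ParseError(f"{path}: unexpected DM table header")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) != len(_DM_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected "
                                 f"{len(_DM_COLUMNS)} columns")
            records.append(DMRecord(
                unit=f[0], chrom=f[1], start=int(f[2]), end=int(f[3]),
                meth_test=float(f[4]), meth_ctrl=float(f[5]), diff=float(f[6]),
                p=_opt_float(f[7]), q=_opt_float(f[8]), status=f[9],
                location=None if f[10] == "NA" else f[10],
                icr=None if f[11] == "NA" else f[11],
                n_cpgs=None if f[12] == "NA" else int(f[12]),
            ))
    return records
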
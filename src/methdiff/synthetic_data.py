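"""Synthetic RRBS count data with known ground truth.

The generator emulates the post-alignment structure of an mESC RRBS study
of DNMT3L genotypes:

* bimodal CpG methylation — non-ICR levels come from a three-part mixture
  (defaults 0.35/0.15/0.50 of Beta(1,19), Uniform(0.2,0.8), Beta(19,1)),
  so most sites sit below 20% or above 80%; one level is drawn per
  ~750-bp block and shared by the CpGs inside it, mimicking the strong
  local autocorrelation of real methylomes (adjacent CpGs agree);
* imprinting control regions (ICRs) are monoallelic in WT — each site
  carries an allele pair (1, 0) and reads are sampled allele-first, so
  observed ICR methylation is genuinely binomial around 50%;
* DNMT3A-target tiles draw their WT site levels from the methylated
  Beta(19,1) component — a methylation loss can only be planted where
  methylation exists — and lose a fixed delta (default 0.30) in zygotic-KO
  genotypes;
* coverage is shifted negative binomial (mean 30, dispersion 5, min 1)
  per site and replicate, deep enough that many sites pass a 20x filter;
* bisulfite conversion failure (default 0.5%) adds spurious methylation to
  unmethylated cytosines, and a separate non-CpG cytosine file carries the
  same failure rate for conversion QC.

Genotype effects: mKO zeroes both ICR alleles and nothing else; KO
subtracts the target delta and leaves ICRs untouched; mzKO applies both.
Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Region, SiteKey, write_bed

log = logging.getLogger(__name__)

GENOTYPES = ("WT", "mKO", "KO", "mzKO")

EFFECT_NONE = "none"
EFFECT_ICR_LOSS = "icr_loss"
EFFECT_TARGET_LOSS = "target_loss"


@dataclass
class SyntheticGenomeSpec:
    """Shape of the simulated genome; defaults give ~23k CpGs over 2.5 Mb."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_000_000})
    cpg_spacing: float = 120.0  # mean bp between CpGs outside ICRs
    icr_cpg_spacing: float = 30.0  # ICRs are CpG-island-like, ~4x denser
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    n_icrs: int = 8
    icr_length_range: tuple[int, int] = (2_000, 4_000)
    target_tile_fraction: float = 0.05
    tile_width: int = 500
    level_block_bp: int = 750  # CpGs within a block share one level
    mixture_weights: tuple[float, float, float] = (0.35, 0.15, 0.50)
    beta_low: tuple[float, float] = (1.0, 19.0)
    beta_high: tuple[float, float] = (19.0, 1.0)
    mid_range: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not 0 <= self.target_tile_fraction < 1:
            raise ValueError("target_tile_fraction must be in [0, 1)")


@dataclass
class TruthTable:
    """Ground truth: per-site allele pairs per genotype plus region labels.

    ``sites`` columns: chrom, pos (1-based), icr (name or ""), target_tile
    (tile id or ""), and a1_<gt>/a2_<gt> allele levels per genotype; the
    expected observed level of a site is the allele average.
    """

    sites: pd.DataFrame
    icrs: list[Region]
    target_tiles: list[str]
    genes: list[GeneModel]
    spec: SyntheticGenomeSpec

    def genotypes(self) -> list[str]:
        return [c[3:] for c in self.sites.columns if c.startswith("a1_")]

    def level(self, genotype: str) -> np.ndarray:
        """Expected observed methylation level per site for a genotype."""
        s = self.sites
        return 0.5 * (s[f"a1_{genotype}"].to_numpy()
                      + s[f"a2_{genotype}"].to_numpy())

    def effect_label(self) -> pd.Series:
        s = self.sites
        out = pd.Series(EFFECT_NONE, index=s.index)
        out[s["target_tile"] != ""] = EFFECT_TARGET_LOSS
        out[s["icr"] != ""] = EFFECT_ICR_LOSS
        return out


def _place_regions(rng: np.random.Generator, chrom_lengths: dict[str, int],
                   n: int, length_range: tuple[int, int],
                   min_gap: int = 10_000) -> list[tuple[str, int, int]]:
    """Place n non-overlapping intervals, round-robin over chromosomes."""
    chroms = sorted(chrom_lengths)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out = []
    attempts = 0
    while len(out) < n and attempts < 10_000:
        attempts += 1
        chrom = chroms[len(out) % len(chroms)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        limit = chrom_lengths[chrom] - length - 1
        if limit <= 1:
            continue
        start = int(rng.integers(1, limit))
        end = start + length
        if any(not (end + min_gap <= s or e + min_gap <= start)
               for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        out.append((chrom, start, end))
    if len(out) < n:
        raise RuntimeError("could not place all regions; genome too small")
    return out


def _cpg_positions(rng: np.random.Generator, length: int,
                   spacing: float, icr_spans: list[tuple[int, int]],
                   icr_spacing: float) -> np.ndarray:
    """1-based CpG positions with denser spacing inside ICR spans."""
    positions = []
    pos = 1 + int(rng.exponential(spacing))
    while pos <= length:
        positions.append(pos)
        in_icr = any(s < pos <= e for s, e in icr_spans)
        step = rng.exponential(icr_spacing if in_icr else spacing)
        pos += max(2, int(step))  # CpGs cannot overlap
    return np.asarray(positions, dtype=np.int64)


def _make_genes(rng: np.random.Generator, chrom_lengths: dict[str, int],
                spec: SyntheticGenomeSpec) -> list[GeneModel]:
    spans = _place_regions(rng, chrom_lengths, spec.n_genes,
                           spec.gene_length_range, min_gap=2_000)
    genes = []
    for i, (chrom, start, end) in enumerate(spans):
        n_exons = int(rng.integers(2, 9))
        cuts = np.sort(rng.choice(np.arange(start + 1, end),
                                  size=2 * n_exons - 2, replace=False))
        bounds = np.concatenate([[start], cuts, [end]])
        exon_starts = tuple(int(b) for b in bounds[0::2])
        exon_ends = tuple(int(b) for b in bounds[1::2])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(name=f"gene{i + 1:03d}", chrom=chrom,
                               strand=strand, tx_start=start, tx_end=end,
                               exon_starts=exon_starts, exon_ends=exon_ends))
    return genes


def simulate_methylome(spec: SyntheticGenomeSpec,
                       seed: int) -> TruthTable:
    """Draw the WT methylome: CpG map, ICRs, genes, target tiles, levels."""
    rng = np.random.default_rng(seed)

    icr_spans = _place_regions(rng, spec.chrom_lengths, spec.n_icrs,
                               spec.icr_length_range, min_gap=20_000)
    icrs = [Region(f"ICR{i + 1:02d}", chrom, start, end)
            for i, (chrom, start, end) in enumerate(icr_spans)]
    genes = _make_genes(rng, spec.chrom_lengths, spec)

    frames = []
    for chrom in sorted(spec.chrom_lengths):
        spans = [(r.start, r.end) for r in icrs if r.chrom == chrom]
        pos = _cpg_positions(rng, spec.chrom_lengths[chrom],
                             spec.cpg_spacing, spans, spec.icr_cpg_spacing)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(frames, ignore_index=True)

    # annotate ICR membership (1-based pos in 0-based half-open region)
    icr_name = np.full(len(sites), "", dtype=object)
    for r in icrs:
        mask = ((sites["chrom"] == r.chrom) & (sites["pos"] > r.start)
                & (sites["pos"] <= r.end))
        icr_name[mask.to_numpy()] = r.name
    sites["icr"] = icr_name

    # choose DNMT3A-target tiles among non-ICR tiles that contain CpGs
    w = spec.tile_width
    tile_of_site = (sites["chrom"].astype(str) + ":"
                    + (((sites["pos"] - 1) // w) * w).astype(str) + "-"
                    + (((sites["pos"] - 1) // w) * w + w).astype(str))
    non_icr_tiles = sorted(set(tile_of_site[sites["icr"] == ""])
                           - set(tile_of_site[sites["icr"] != ""]))
    n_target = int(round(spec.target_tile_fraction * len(non_icr_tiles)))
    target_tiles = sorted(rng.choice(non_icr_tiles, size=n_target,
                                     replace=False).tolist())
    target_set = set(target_tiles)
    sites["target_tile"] = [t if t in target_set else ""
                            for t in tile_of_site]

    # WT levels: one mixture draw per level block, shared by its CpGs, so
    # nearby sites agree the way they do in real methylomes
    n = len(sites)
    a1 = np.empty(n)
    a2 = np.empty(n)
    block = (sites["chrom"].astype(str) + ":"
             + ((sites["pos"] - 1) // spec.level_block_bp).astype(str))
    blocks, block_of_site = np.unique(block.to_numpy(), return_inverse=True)
    nb = len(blocks)
    comp = rng.choice(3, size=nb, p=list(spec.mixture_weights))
    low = rng.beta(*spec.beta_low, size=nb)
    mid = rng.uniform(*spec.mid_range, size=nb)
    high = rng.beta(*spec.beta_high, size=nb)
    block_level = np.where(comp == 0, low, np.where(comp == 1, mid, high))
    level = block_level[block_of_site]
    # methylated component for target tiles (one draw per tile): a planted
    # loss is only observable where methylation exists
    target_mask = (sites["target_tile"] != "").to_numpy()
    tile_levels = {t: rng.beta(*spec.beta_high) for t in target_tiles}
    level[target_mask] = [tile_levels[t]
                          for t in sites.loc[target_mask, "target_tile"]]
    a1[:] = level
    a2[:] = level
    icr_mask = (sites["icr"] != "").to_numpy()
    a1[icr_mask] = 1.0  # methylated allele
    a2[icr_mask] = 0.0  # unmethylated allele
    sites["a1_WT"] = a1
    sites["a2_WT"] = a2

    truth = TruthTable(sites=sites, icrs=icrs, target_tiles=target_tiles,
                       genes=genes, spec=spec)
    return truth


def apply_genotype(truth: TruthTable, genotype: str,
                   effect_delta: float = 0.30) -> TruthTable:
    """Add a genotype's allele levels to the truth table and return it."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    s = truth.sites
    a1 = s["a1_WT"].to_numpy().copy()
    a2 = s["a2_WT"].to_numpy().copy()
    icr_mask = (s["icr"] != "").to_numpy()
    target_mask = (s["target_tile"] != "").to_numpy()
    if genotype in ("mKO", "mzKO"):
        a1[icr_mask] = 0.0
        a2[icr_mask] = 0.0
    if genotype in ("KO", "mzKO"):
        a1[target_mask] = np.maximum(a1[target_mask] - effect_delta, 0.0)
        a2[target_mask] = np.maximum(a2[target_mask] - effect_delta, 0.0)
    s[f"a1_{genotype}"] = a1
    s[f"a2_{genotype}"] = a2
    return truth


def _shifted_nb(rng: np.random.Generator, mean: float, dispersion: float,
                size: int) -> np.ndarray:
    """Coverage draw: 1 + NB with the given mean-1 and dispersion."""
    mu = max(mean - 1.0, 0.1)
    p = dispersion / (dispersion + mu)
    return 1 + rng.negative_binomial(dispersion, p, size=size)


def emit_counts(truth: TruthTable, genotype: str, out_dir: str | Path,
                n_replicates: int = 3, mean_cov: float = 30.0,
                conv_fail: float = 0.005, seed: int = 0,
                dispersion: float = 5.0, eps_overconv: float = 0.0,
                n_noncpg_sites: int = 2_000) -> list[Path]:
    """Write Bismark coverage files plus a non-CpG QC file per replicate.

    Reads are sampled allele-first: coverage splits Binomial(cov, 0.5)
    between the two alleles, then methylated counts are binomial at the
    conversion-adjusted allele level
    ``level·(1−eps_overconv) + (1−level)·conv_fail``. For biallelically
    identical sites this reduces to a plain binomial at the site level.
    """
    if mean_cov < 1:
        raise ValueError("mean_cov must be >= 1")
    if not 0 <= conv_fail < 0.05:
        raise ValueError("conv_fail must be in [0, 0.05)")
    if f"a1_{genotype}" not in truth.sites.columns:
        raise ValueError(f"genotype {genotype!r} not applied to truth table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    s = truth.sites
    n = len(s)
    a1 = s[f"a1_{genotype}"].to_numpy()
    a2 = s[f"a2_{genotype}"].to_numpy()

    def adj(level: np.ndarray) -> np.ndarray:
        return level * (1.0 - eps_overconv) + (1.0 - level) * conv_fail

    paths = []
    for rep in range(1, n_replicates + 1):
        cov = _shifted_nb(rng, mean_cov, dispersion, n)
        cov1 = rng.binomial(cov, 0.5)
        m = rng.binomial(cov1, adj(a1)) + rng.binomial(cov - cov1, adj(a2))
        u = cov - m
        sample = f"{genotype}_rep{rep}"
        path = out_dir / f"{sample}.cov"
        with open(path, "w") as fh:
            for chrom, pos, mi, ui in zip(s["chrom"], s["pos"], m, u):
                pct = 100.0 * mi / (mi + ui)
                fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:.6f}\t{mi}\t{ui}\n")
        paths.append(path)

        # non-CpG conversion QC: unmethylated cytosines outside CpG context
        qc_cov = _shifted_nb(rng, mean_cov, dispersion, n_noncpg_sites)
        unconv = rng.binomial(qc_cov, conv_fail)
        qc_path = out_dir / f"{sample}.noncpg.tsv"
        with open(qc_path, "w") as fh:
            fh.write("chrom\tpos\tn_converted\tn_unconverted\n")
            for i, (c, x) in enumerate(zip(qc_cov, unconv)):
                fh.write(f"chrQC\t{i + 1}\t{c - x}\t{x}\n")
    return paths


def read_noncpg_counts(path: str | Path) -> tuple[int, int]:
    """Total (converted, unconverted) counts from a non-CpG QC file."""
    frame = pd.read_csv(path, sep="\t")
    return int(frame["n_converted"].sum()), int(frame["n_unconverted"].sum())


@dataclass
class StudyConfig:
    """Full synthetic-study recipe: genome, replication, and noise model."""

    genome: SyntheticGenomeSpec = field(default_factory=SyntheticGenomeSpec)
    genotypes: tuple[str, ...] = GENOTYPES
    n_replicates: int = 3
    mean_cov: float = 30.0
    dispersion: float = 5.0
    conv_fail: float = 0.005
    effect_delta: float = 0.30


@dataclass
class Study:
    """A generated study: file paths plus the in-memory truth."""

    out_dir: Path
    truth: TruthTable
    samples: list[tuple[str, str, Path]]  # (sample_id, genotype, path)
    icr_bed: Path
    genepred: Path
    truth_tsv: Path
    samples_tsv: Path
    manifest: Path


def _write_genepred(genes: Sequence[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(x) for x in g.exon_starts) + ","
            ends = ",".join(str(x) for x in g.exon_ends) + ","
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t"
                     f"{g.tx_end}\t{g.tx_start}\t{g.tx_end}\t"
                     f"{len(g.exon_starts)}\t{starts}\t{ends}\n")


def make_study(config: StudyConfig, seed: int,
               out_dir: str | Path) -> Study:
    """Generate the full dataset: one genome spec, all genotypes, 3 reps.

    Writes coverage files, non-CpG QC files, the truth table, an ICR BED,
    a genePred gene table, a samples TSV (sample_id, genotype, path), and
    a JSON manifest with the seed and parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).generate_state(
        1 + len(config.genotypes)) % (2 ** 31)

    truth = simulate_methylome(config.genome, seed=int(seeds[0]))
    samples = []
    for gi, genotype in enumerate(config.genotypes):
        apply_genotype(truth, genotype, config.effect_delta)
        paths = emit_counts(truth, genotype, out_dir,
                            n_replicates=config.n_replicates,
                            mean_cov=config.mean_cov,
                            conv_fail=config.conv_fail,
                            seed=int(seeds[1 + gi]),
                            dispersion=config.dispersion)
        for rep, path in enumerate(paths, start=1):
            samples.append((f"{genotype}_rep{rep}", genotype, path))

    icr_bed = out_dir / "icrs.bed"
    write_bed(truth.icrs, icr_bed)
    genepred = out_dir / "genes.genepred"
    _write_genepred(truth.genes, genepred)

    truth_tsv = out_dir / "truth_sites.tsv"
    truth.sites.assign(effect=truth.effect_label()).to_csv(
        truth_tsv, sep="\t", index=False, float_format="%.6f")

    samples_tsv = out_dir / "samples.tsv"
    with open(samples_tsv, "w") as fh:
        fh.write("sample_id\tgenotype\tpath\n")
        for sid, gt, path in samples:
            fh.write(f"{sid}\t{gt}\t{path.name}\n")

    manifest = out_dir / "manifest.json"
    payload = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "n_sites": int(len(truth.sites)),
        "n_icrs": len(truth.icrs),
        "n_target_tiles": len(truth.target_tiles),
        "samples": [sid for sid, _, _ in samples],
    }
    with open(manifest, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("study written to %s: %d sites, %d samples", out_dir,
             len(truth.sites), len(samples))
    return Study(out_dir=out_dir, truth=truth, samples=samples,
                 icr_bed=icr_bed, genepred=genepred, truth_tsv=truth_tsv,
                 samples_tsv=samples_tsv, manifest=manifest)
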
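"""Shared fixtures: one synthetic study per session, plus derived DM runs."""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from methdiff.dml import Comparison, run_site_dml
from methdiff.io_formats import AnalysisConfig, read_bismark_coverage
from methdiff.synthetic_data import (StudyConfig, SyntheticGenomeSpec,
                                     TruthTable, apply_genotype, emit_counts,
                                     make_study, simulate_methylome)
from methdiff.tiling import run_tile_dml

SEED = 1234


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    return make_study(StudyConfig(), seed=SEED, out_dir=out)


@pytest.fixture(scope="session")
def call_sets(study):
    by_gt = {}
    for sid, gt, path in study.samples:
        by_gt.setdefault(gt, []).append(read_bismark_coverage(path, sid, gt))
    return by_gt


@pytest.fixture(scope="session")
def comparisons(call_sets):
    return {f"{t}_vs_WT": Comparison(call_sets[t], call_sets["WT"],
                                     f"{t}_vs_WT")
            for t in ("mKO", "KO", "mzKO")}


@pytest.fixture(scope="session")
def site_dml_runs(comparisons, config):
    return {label: run_site_dml(comp, config)
            for label, comp in comparisons.items()}


@pytest.fixture(scope="session")
def tile_dml_runs(comparisons, config):
    return {label: run_tile_dml(comp, config)
            for label, comp in comparisons.items()}


@pytest.fixture(scope="session")
def null_comparison(tmp_path_factory):
    """Two 3-replicate groups drawn from one WT methylome: no true effect."""
    spec = SyntheticGenomeSpec(chrom_lengths={"chr1": 500_000},
                               n_icrs=2, n_genes=5)
    truth = simulate_methylome(spec, seed=SEED + 1)
    apply_genotype(truth, "WT")
    out = tmp_path_factory.mktemp("null")
    paths = emit_counts(truth, "WT", out, n_replicates=6, seed=SEED + 2)
    sets = [read_bismark_coverage(p, f"WT_rep{i + 1}", "WT")
            for i, p in enumerate(paths)]
    return Comparison(sets[:3], sets[3:], "null_A_vs_B")


def make_truth(rows: list[tuple[str, int, float]],
               genotype_levels: dict[str, list[float]] | None = None
               ) -> TruthTable:
    """Hand-built truth table: rows = (chrom, pos, wt_level)."""
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "level"])
    frame["icr"] = ""
    frame["target_tile"] = ""
    frame["a1_WT"] = frame["level"]
    frame["a2_WT"] = frame["level"]
    frame = frame.drop(columns="level")
    truth = TruthTable(sites=frame, icrs=[], target_tiles=[], genes=[],
                       spec=SyntheticGenomeSpec())
    for gt, levels in (genotype_levels or {}).items():
        frame[f"a1_{gt}"] = levels
        frame[f"a2_{gt}"] = levels
    return truth
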
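"""Site-level qualification, testing, BH adjustment, calling, states."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methdiff.dml import (Comparison, STATUS_HYPER, STATUS_HYPO, STATUS_NS,
                          STATUS_UNQUALIFIED, adjust_bh, call_dm,
                          classify_state, group_percent, qualify_sites,
                          run_site_dml)
from methdiff.dml import test_unit_fisher as fisher_p
from methdiff.dml import test_unit_logistic as logistic_p
from methdiff.io_formats import AnalysisConfig, MethCall, MethCallSet, SiteKey

from oracles import bh_bruteforce, binomial_deviance, fisher_two_sided_enumeration


def callset(sample_id, genotype, rows):
    calls = {}
    for chrom, pos, m, u in rows:
        key = SiteKey(chrom, pos)
        calls[key] = MethCall(key, m, u)
    return MethCallSet(sample_id, genotype, calls)


class TestQualifySites:
    def test_boundary_coverage_is_inclusive(self):
        rows = lambda cov: [("chr1", 10, cov // 2, cov - cov // 2)]
        comp = Comparison(
            [callset("t1", "KO", rows(20)), callset("t2", "KO", rows(20))],
            [callset("c1", "WT", rows(20)), callset("c2", "WT", rows(20))],
            "KO_vs_WT")
        assert qualify_sites(comp, 20) == {SiteKey("chr1", 10)}

    def test_one_low_sample_excludes_site(self):
        comp = Comparison(
            [callset("t1", "KO", [("chr1", 10, 10, 10)])],
            [callset("c1", "WT", [("chr1", 10, 10, 9)])],  # 19x
            "KO_vs_WT")
        assert qualify_sites(comp, 20) == set()

    def test_matches_bruteforce_scan_on_toy_grid(self):
        rng = np.random.default_rng(0)
        sites = [("chr1", p) for p in (5, 10, 15, 20, 25)]
        samples = []
        for i in range(4):
            rows = [(c, p, int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                    for c, p in sites]
            samples.append(callset(f"s{i}", "KO" if i < 2 else "WT", rows))
        comp = Comparison(samples[:2], samples[2:], "KO_vs_WT")
        expected = {SiteKey(c, p) for c, p in sites
                    if all(s.coverage(SiteKey(c, p)) >= 20 for s in samples)}
        assert qualify_sites(comp, 20) == expected

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            Comparison([], [callset("c", "WT", [])], "bad")


class TestGroupPercent:
    @pytest.mark.parametrize("calls,expected", [
        ([(0, 10)], 0.0),
        ([(3, 7), (7, 3)], 50.0),  # pooled: 10 of 20
        ([(10, 0), (5, 0)], 100.0),
    ])
    def test_pooled_percentage(self, calls, expected):
        assert group_percent(calls) == pytest.approx(expected)

    def test_zero_total_coverage_is_error(self):
        with pytest.raises(ValueError):
            group_percent([(0, 0)])


class TestFisher:
    @pytest.mark.parametrize("table", [
        (18, 2, 2, 18), (5, 5, 5, 5), (10, 0, 0, 10), (3, 17, 9, 11),
        (1, 1, 1, 1), (30, 5, 12, 18),
    ])
    def test_matches_exhaustive_enumeration(self, table):
        a, b, c, d = table
        assert fisher_p((a, b), (c, d)) == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), rel=1e-9)

    def test_identical_rows_give_p_one(self):
        assert fisher_p((5, 5), (5, 5)) == 1.0

    def test_zero_margin_gives_p_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert fisher_p((0, 0), (5, 5)) == 1.0
        assert "zero margin" in caplog.text

    def test_symmetric_under_group_and_label_swaps(self):
        p = fisher_p((12, 4), (3, 11))
        assert fisher_p((3, 11), (12, 4)) == pytest.approx(p)
        assert fisher_p((4, 12), (11, 3)) == pytest.approx(p)


class TestLogistic:
    def test_equal_proportions_give_p_near_one(self):
        p = logistic_p([(10, 10), (5, 5)], [(20, 20)])
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_pooled_chisquare_one_vs_one(self):
        from scipy.stats import chi2_contingency
        table = [(30, 10), (18, 22)]
        p_lrt = logistic_p([table[0]], [table[1]])
        p_chi = chi2_contingency(np.array(table), correction=False)[1]
        assert p_lrt == pytest.approx(p_chi, rel=0.10)

    @pytest.mark.parametrize("test_counts,ctrl_counts", [
        ([(12, 8), (15, 5), (9, 11)], [(3, 17), (6, 14), (4, 16)]),
        ([(30, 1)], [(2, 28), (5, 25)]),
        ([(7, 7), (8, 6)], [(7, 7), (6, 8)]),
    ])
    def test_deviance_matches_closed_form_loglikelihood(self, test_counts,
                                                        ctrl_counts):
        from scipy.stats import chi2
        p = logistic_p(test_counts, ctrl_counts)
        g = binomial_deviance(test_counts, ctrl_counts)
        assert p == pytest.approx(float(chi2.sf(g, 1)), rel=1e-9, abs=1e-300)

    def test_requires_positive_group_coverage(self):
        with pytest.raises(ValueError):
            logistic_p([(0, 0)], [(5, 5)])


class TestBH:
    def test_hand_computed_stepup_minima(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.3]) == pytest.approx([0.3])

    def test_empty_input(self):
        assert adjust_bh([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=200))
    def test_matches_bruteforce_min_over_suffix(self, p_values):
        assert np.allclose(adjust_bh(p_values), bh_bruteforce(p_values),
                           rtol=1e-12, atol=1e-12)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(size=150)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adjust_bh(p), ref)

    def test_sorted_q_monotone_with_sorted_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=80)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCallDM:
    @pytest.mark.parametrize("diff,q,expected", [
        (-25.0, 0.01, STATUS_HYPO),   # both boundaries inclusive
        (-24.9, 0.001, STATUS_NS),
        (30.0, 0.001, STATUS_HYPER),
        (25.0, 0.01, STATUS_HYPER),
        (-60.0, 0.011, STATUS_NS),
        (0.0, 0.0001, STATUS_NS),
    ])
    def test_call_boundaries(self, diff, q, expected, config):
        assert call_dm(diff, q, config) == expected

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(min_value=-100, max_value=100),
           st.floats(min_value=0, max_value=1))
    def test_hypo_and_hyper_are_exclusive_and_signed(self, diff, q):
        cfg = AnalysisConfig()
        status = call_dm(diff, q, cfg)
        if status == STATUS_HYPO:
            assert diff < 0
        if status == STATUS_HYPER:
            assert diff > 0
        assert status in (STATUS_HYPO, STATUS_HYPER, STATUS_NS)


class TestClassifyState:
    @pytest.mark.parametrize("percent,expected", [
        (50.0, "partial"), (80.0, "high"), (19.999, "unmethylated"),
        (20.0, "partial"), (0.0, "unmethylated"), (100.0, "high"),
    ])
    def test_state_boundaries(self, percent, expected, config):
        assert classify_state(percent, config) == expected

    def test_out_of_range_rejected(self, config):
        with pytest.raises(ValueError):
            classify_state(101.0, config)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(min_value=0, max_value=100))
    def test_partitions_the_percent_range(self, percent):
        state = classify_state(percent, AnalysisConfig())
        assert state in ("unmethylated", "partial", "high")


class TestRunSiteDML:
    def test_identical_groups_give_zero_diffs_and_no_calls(self, config):
        rows = [("chr1", p, 10 + p % 5, 15) for p in range(10, 300, 13)]
        comp = Comparison(
            [callset("a1", "KO", rows), callset("a2", "KO", rows)],
            [callset("b1", "WT", rows), callset("b2", "WT", rows)],
            "self_vs_self")
        records = run_site_dml(comp, config)
        assert records
        for r in records:
            assert r.diff == pytest.approx(0.0, abs=1e-9)
            assert r.status in (STATUS_NS, STATUS_UNQUALIFIED)

    def test_unqualified_sites_have_no_p_or_q(self, config):
        rows_deep = [("chr1", 10, 15, 15)]
        rows_shallow = [("chr1", 10, 15, 15), ("chr1", 50, 2, 3)]
        comp = Comparison([callset("a", "KO", rows_shallow)],
                          [callset("b", "WT", rows_deep)], "KO_vs_WT")
        records = {r.unit: r for r in run_site_dml(comp, config)}
        assert records["chr1:50"].status == STATUS_UNQUALIFIED
        assert records["chr1:50"].p is None and records["chr1:50"].q is None
        assert records["chr1:10"].p is not None

    def test_planted_minus40_sites_recovered(self, config, tmp_path):
        # 3v3 at ~30x: sites dropping 80% -> 40% should nearly all be called
        from conftest import make_truth
        from methdiff.io_formats import read_bismark_coverage
        from methdiff.synthetic_data import emit_counts

        rows = [("chr1", 100 + 50 * i, 0.8) for i in range(400)]
        truth = make_truth(rows, {"KO": [0.4] * 400})
        wt_paths = emit_counts(truth, "WT", tmp_path, n_replicates=3, seed=11)
        ko_paths = emit_counts(truth, "KO", tmp_path, n_replicates=3, seed=12)
        comp = Comparison(
            [read_bismark_coverage(p, f"ko{i}", "KO")
             for i, p in enumerate(ko_paths)],
            [read_bismark_coverage(p, f"wt{i}", "WT")
             for i, p in enumerate(wt_paths)],
            "KO_vs_WT")
        records = run_site_dml(comp, config)
        qualified = [r for r in records if r.status != STATUS_UNQUALIFIED]
        hypo = sum(1 for r in qualified if r.status == STATUS_HYPO)
        assert len(qualified) > 50
        assert hypo / len(qualified) >= 0.90

    def test_null_comparison_false_call_rate_below_one_percent(
            self, null_comparison, config):
        records = run_site_dml(null_comparison, config)
        qualified = [r for r in records if r.status != STATUS_UNQUALIFIED]
        called = sum(1 for r in qualified
                     if r.status in (STATUS_HYPO, STATUS_HYPER))
        assert qualified
        assert called <= max(1, 0.01 * len(qualified))
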
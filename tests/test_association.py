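"""Odds-ratio engine: algebraic properties, intervals, and table building."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trialmeta.association import (
    ContingencyTable2x2,
    DegenerateTableError,
    build_table,
    class_or_report,
    odds_ratio,
    odds_ratio_ci,
)
from trialmeta.filters import compute_corpus_flags
from trialmeta.records import SponsorClass
from trialmeta.synthetic import GeneratorConfig, generate_records

from conftest import make_record

cells = st.integers(min_value=1, max_value=1000)


@st.composite
def tables(draw):
    return ContingencyTable2x2(draw(cells), draw(cells), draw(cells), draw(cells))


class TestOddsRatio:
    def test_hand_computed_cross_product(self):
        assert odds_ratio(ContingencyTable2x2(10, 5, 2, 8)) == 8.0

    def test_symmetric_table_is_one(self):
        assert odds_ratio(ContingencyTable2x2(25, 25, 25, 25)) == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(tables())
    def test_rowswap_inverts(self, table):
        assert odds_ratio(table.rowswap()) == pytest.approx(1 / odds_ratio(table))

    @settings(derandomize=True, max_examples=200)
    @given(tables())
    def test_transposition_invariance(self, table):
        assert odds_ratio(table.transpose()) == pytest.approx(odds_ratio(table))

    @settings(derandomize=True, max_examples=200)
    @given(tables())
    def test_counts_equal_probability_form(self, table):
        p = table.joint_probabilities()
        assert odds_ratio(table) == pytest.approx(
            p["p11"] * p["p00"] / (p["p10"] * p["p01"])
        )

    @settings(derandomize=True, max_examples=100)
    @given(tables(), st.integers(min_value=2, max_value=9))
    def test_cell_scaling_invariance(self, table, k):
        scaled = ContingencyTable2x2(
            k * table.n11, k * table.n10, k * table.n01, k * table.n00
        )
        assert odds_ratio(scaled) == pytest.approx(odds_ratio(table))

    def test_zero_cell_is_an_error_not_infinity(self):
        with pytest.raises(DegenerateTableError, match="zero cell"):
            odds_ratio(ContingencyTable2x2(10, 0, 2, 8))

    def test_haldane_correction_handles_zero_cell(self):
        value = odds_ratio(ContingencyTable2x2(10, 0, 2, 8), correction="haldane")
        assert value == pytest.approx((10.5 * 8.5) / (0.5 * 2.5))


class TestOddsRatioCI:
    @settings(derandomize=True, max_examples=100)
    @given(tables())
    def test_interval_brackets_estimate(self, table):
        result = odds_ratio_ci(table)
        assert result.ci_low <= result.or_value <= result.ci_high
        assert result.ci_low > 0

    def test_t_and_normal_converge_for_large_tables(self):
        table = ContingencyTable2x2(2500, 2500, 2500, 2500)
        t_ci = odds_ratio_ci(table, method="t")
        z_ci = odds_ratio_ci(table, method="normal")
        t_width = math.log(t_ci.ci_high) - math.log(t_ci.ci_low)
        z_width = math.log(z_ci.ci_high) - math.log(z_ci.ci_low)
        assert abs(t_width - z_width) / z_width < 1e-3

    def test_matches_statsmodels_woolf_interval(self):
        # independent implementation of the same log-odds interval
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        table = ContingencyTable2x2(120, 80, 60, 140)
        ours = odds_ratio_ci(table, method="normal")
        ref = sm.Table2x2(np.array([[120, 80], [60, 140]]))
        assert ours.or_value == pytest.approx(ref.oddsratio)
        low, high = ref.oddsratio_confint(alpha=0.05)
        assert ours.ci_low == pytest.approx(low)
        assert ours.ci_high == pytest.approx(high)

    def test_confidence_level_widens_interval(self):
        table = ContingencyTable2x2(30, 20, 15, 35)
        narrow = odds_ratio_ci(table, level=0.90)
        wide = odds_ratio_ci(table, level=0.99)
        assert wide.ci_high - wide.ci_low > narrow.ci_high - narrow.ci_low


class TestBuildTable:
    def test_toy_corpus_counts(self):
        corpus = [
            make_record("NCT00000001", lead_sponsor_name="A Inc."),
            make_record("NCT00000002", lead_sponsor_name="B Inc."),
            make_record("NCT00000003", lead_sponsor_name="C Inc.", has_results=False),
            make_record("NCT00000004", lead_sponsor_name="D University", has_results=False),
        ]
        assignments = {
            "NCT00000001": SponsorClass.COM,
            "NCT00000002": SponsorClass.COM,
            "NCT00000003": SponsorClass.COM,
            "NCT00000004": SponsorClass.EDU,
        }
        table = build_table(corpus, assignments, SponsorClass.COM)
        assert (table.n11, table.n10, table.n01, table.n00) == (2, 1, 0, 1)

    def test_excluded_class_absent_from_all_cells(self):
        corpus = [
            make_record("NCT00000001"),
            make_record("NCT00000002", has_results=False),
            make_record("NCT00000003"),
        ]
        assignments = {
            "NCT00000001": SponsorClass.COM,
            "NCT00000002": SponsorClass.EDU,
            "NCT00000003": SponsorClass.COL,
        }
        table = build_table(corpus, assignments, SponsorClass.COM)
        assert table.n == 2  # the col trial is gone from both margins

    def test_empty_restrained_pool_is_an_error(self):
        corpus = [make_record("NCT00000001", n_references=0)]
        assignments = {"NCT00000001": SponsorClass.COM}
        flags = compute_corpus_flags(corpus)
        with pytest.raises(DegenerateTableError, match="empty restrained pool"):
            build_table(corpus, assignments, SponsorClass.COM,
                        restrained=True, flags=flags)

    def test_single_class_corpus_has_zero_margin(self):
        corpus = [
            make_record("NCT00000001"),
            make_record("NCT00000002", has_results=False),
        ]
        assignments = {r.nct_id: SponsorClass.COM for r in corpus}
        with pytest.raises(DegenerateTableError, match="margin"):
            build_table(corpus, assignments, SponsorClass.COM)


class TestClassORReport:
    def _uniform_config(self, n, seed, com_multiplier=1.0):
        config = GeneratorConfig(n_trials=n, seed=seed)
        for cls in SponsorClass:
            config.unrestricted_results_prob[cls] = 0.10
            config.restrained_results_prob[cls] = 0.10
        config.unrestricted_results_prob[SponsorClass.COM] = 0.10 * com_multiplier
        config.restrained_results_prob[SponsorClass.COM] = 0.10 * com_multiplier
        return config

    def test_elevated_com_odds_detected(self):
        # com results odds 4x the rest: estimate lands near 4 at n=5,000
        config = self._uniform_config(5_000, 31)
        p_com = 4 * 0.10 / (1 + 3 * 0.10)  # odds(com)=4*odds(rest)
        config.unrestricted_results_prob[SponsorClass.COM] = p_com
        config.restrained_results_prob[SponsorClass.COM] = p_com
        corpus = generate_records(config)
        assignments = {t.nct_id: t.true_class for t in corpus.truth}
        flags = compute_corpus_flags(corpus.records)
        report = class_or_report(corpus.records, assignments, flags)
        com_or = report[
            (report["class"] == "com") & (report["indicator"] == "results")
        ]["odds_ratio"].iloc[0]
        assert 3.0 < com_or < 5.0

    def test_null_generator_cis_cover_one(self):
        # identical reporting probability everywhere: each class CI covers
        # OR=1 at roughly its nominal rate across seeded runs
        runs = 60
        covered = {cls.value: 0 for cls in
                   (SponsorClass.COM, SponsorClass.GOV, SponsorClass.HOS, SponsorClass.EDU)}
        for seed in range(runs):
            corpus = generate_records(self._uniform_config(800, 1000 + seed))
            assignments = {t.nct_id: t.true_class for t in corpus.truth}
            report = class_or_report(
                corpus.records, assignments, flags=None, restrained=False,
                indicators=("results",),
            )
            for _, row in report.iterrows():
                if row["ci_low"] <= 1.0 <= row["ci_high"]:
                    covered[row["class"]] += 1
        for cls, count in covered.items():
            assert count / runs >= 0.90, cls

    def test_or_estimate_converges_with_n(self):
        # absolute log-error of the com odds-ratio estimate shrinks as the
        # corpus grows (mean over seeds)
        p_com = 4 * 0.10 / (1 + 3 * 0.10)
        true_or = (p_com / (1 - p_com)) / (0.10 / 0.90)
        mean_errors = []
        for n in (400, 2_000, 10_000):
            errors = []
            for seed in range(10):
                config = self._uniform_config(n, 5000 + seed)
                config.unrestricted_results_prob[SponsorClass.COM] = p_com
                config.restrained_results_prob[SponsorClass.COM] = p_com
                corpus = generate_records(config)
                assignments = {t.nct_id: t.true_class for t in corpus.truth}
                report = class_or_report(
                    corpus.records, assignments, indicators=("results",),
                    classes=(SponsorClass.COM,),
                )
                errors.append(abs(math.log(report["odds_ratio"].iloc[0] / true_or)))
            mean_errors.append(float(np.mean(errors)))
        assert mean_errors[0] > mean_errors[1] > mean_errors[2]
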
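"""Summary tables: percentages, yearly cascade, per-class efficiency."""

import pytest

from trialmeta.filters import compute_corpus_flags
from trialmeta.records import PartialDate, SponsorClass
from trialmeta.reporting import (
    REQUIREMENT_COLUMNS,
    class_restrained_table,
    enrollment_table,
    format_percent,
    intervention_table,
    outcome_table,
    percent,
    phase_distribution,
    yearly_activity,
    yearly_requirement_table,
)
from trialmeta.synthetic import GeneratorConfig, generate_records

from conftest import make_record


class TestPercent:
    @pytest.mark.parametrize(
        "num, den, decimals, expected",
        [
            (168, 428, 2, 39.25),
            (75, 135, 2, 55.56),
            (220, 634, 1, 34.7),
            (0, 100, 2, 0.00),
            (1, 3, 2, 33.33),
        ],
    )
    def test_values(self, num, den, decimals, expected):
        assert percent(num, den, decimals) == expected

    def test_half_up_rounding(self):
        # 0.125% rounds up at two decimals, where bankers' rounding would not
        assert percent(1, 800, 2) == 0.13
        assert percent(1, 16, 1) == 6.3

    def test_zero_denominator_is_undefined(self):
        assert percent(0, 0) is None
        assert format_percent(None) == "n/a"

    def test_formatting_trims_trailing_zeros(self):
        assert format_percent(34.70) == "34.7"
        assert format_percent(39.25) == "39.25"
        assert format_percent(20.0) == "20"


def _small_corpus():
    """Six trials: four completed (three with results), two not completed."""
    return [
        make_record("NCT00000001", completion_date=PartialDate(2008, 6)),
        make_record("NCT00000002", completion_date=PartialDate(2008, 7), has_results=False),
        make_record("NCT00000003", completion_date=PartialDate(2010, 2)),
        make_record("NCT00000004", completion_date=PartialDate(1999, 5)),
        make_record("NCT00000005", overall_status="Recruiting", completion_date=None),
        make_record("NCT00000006", overall_status="Terminated",
                    completion_date=PartialDate(2009, 1)),
    ]


class TestYearlyRequirementTable:
    def test_only_completed_trials_enter(self):
        corpus = _small_corpus()
        flags = compute_corpus_flags(corpus)
        table = yearly_requirement_table(corpus, flags)
        assert table.loc["total", ("overall", "total")] == 4
        assert "2000 and before" in table.index

    def test_all_results_corpus_gives_100_percent(self):
        corpus = [r for r in _small_corpus() if r.nct_id != "NCT00000002"]
        flags = compute_corpus_flags(corpus)
        table = yearly_requirement_table(corpus, flags)
        completed_rows = table.drop(index="total")
        assert (completed_rows[("overall", "percent")] == 100.0).all()

    def test_no_completed_trials_gives_empty_total(self):
        corpus = [make_record(overall_status="Recruiting", completion_date=None)]
        flags = compute_corpus_flags(corpus)
        table = yearly_requirement_table(corpus, flags)
        assert table.loc["total", ("overall", "total")] == 0
        assert table.loc["total", ("overall", "percent")] is None

    def test_all_requirements_column_is_tightest(self):
        corpus = generate_records(GeneratorConfig(n_trials=3_000, seed=9)).records
        flags = compute_corpus_flags(corpus)
        table = yearly_requirement_table(corpus, flags)
        for column in REQUIREMENT_COLUMNS[:-1]:
            assert (
                table[("all_requirements", "total")] <= table[(column, "total")]
            ).all()

    def test_percent_recomputable_from_counts(self):
        corpus = generate_records(GeneratorConfig(n_trials=2_000, seed=10)).records
        flags = compute_corpus_flags(corpus)
        table = yearly_requirement_table(corpus, flags)
        for column in REQUIREMENT_COLUMNS:
            for label in table.index:
                expected = percent(
                    int(table.loc[label, (column, "with_results")]),
                    int(table.loc[label, (column, "total")]),
                )
                assert table.loc[label, (column, "percent")] == expected


class TestClassRestrainedTable:
    def test_one_trial_class_with_results_is_100(self):
        corpus = [make_record("NCT00000001", lead_sponsor_name="Aurora Hospital")]
        flags = compute_corpus_flags(corpus)
        assignments = {"NCT00000001": SponsorClass.HOS}
        with pytest.warns(UserWarning):  # other classes are empty
            table = class_restrained_table(corpus, assignments, flags)
        assert len(table) == 1
        assert table.iloc[0]["percent"] == 100.0

    def test_empty_class_row_omitted_with_warning(self):
        corpus = [make_record("NCT00000001")]
        flags = compute_corpus_flags(corpus)
        assignments = {"NCT00000001": SponsorClass.COM}
        with pytest.warns(UserWarning, match="hos"):
            table = class_restrained_table(corpus, assignments, flags)
        assert "hos" not in set(table["class"])

    def test_restrained_rates_recovered_when_all_trials_restrained(self):
        # Force every trial through the cascade so per-class deposition
        # rates are estimated on the full corpus.
        config = GeneratorConfig(
            n_trials=12_000,
            seed=21,
            completed_prob=1.0,
            fda_prob=1.0,
            s801_given_fda=1.0,
            pub_given_regulated_completed=1.0,
            interventional_given_unregulated=1.0,
        )
        corpus = generate_records(config)
        flags = compute_corpus_flags(corpus.records)
        truth = {t.nct_id: t for t in corpus.truth}
        assignments = {t.nct_id: t.true_class for t in corpus.truth}
        assert all(f.all_requirements for f in flags.values())
        table = class_restrained_table(corpus.records, assignments, flags)
        for _, row in table.iterrows():
            cls = SponsorClass(row["class"])
            expected = config.restrained_results_prob[cls] * 100
            assert abs(row["percent"] - expected) < 4.0


class TestOutcomeTable:
    def test_counting_rules(self):
        corpus = [
            make_record("NCT00000001", n_primary_outcomes=1, n_secondary_outcomes=0),
            make_record("NCT00000002", n_primary_outcomes=1, n_secondary_outcomes=1),
            make_record("NCT00000003", n_primary_outcomes=0, n_secondary_outcomes=0),
        ]
        assignments = {r.nct_id: SponsorClass.COM for r in corpus}
        table = outcome_table(corpus, assignments)
        com = table[table["class"] == "com"].iloc[0]
        assert com["n_at_least_one"] == 2
        assert com["n_more_than_one"] == 1
        assert com["pct_at_least_one"] == percent(2, 3)

    def test_nesting_invariant_on_synthetic(self):
        corpus = generate_records(GeneratorConfig(n_trials=3_000, seed=13))
        assignments = {t.nct_id: t.true_class for t in corpus.truth}
        table = outcome_table(corpus.records, assignments)
        assert (table["n_more_than_one"] <= table["n_at_least_one"]).all()
        assert (table["n_at_least_one"] <= table["class_total"]).all()


class TestInterventionTable:
    def test_multi_type_trial_counts_in_both_columns(self):
        corpus = [
            make_record("NCT00000001", intervention_types=frozenset({"Drug", "Device"})),
        ]
        assignments = {"NCT00000001": SponsorClass.COM}
        table = intervention_table(corpus, assignments)
        assert table.loc["com", ("Drug", "trials")] == 1
        assert table.loc["com", ("Device", "trials")] == 1

    def test_zero_trial_cell_has_undefined_efficiency(self):
        corpus = [make_record("NCT00000001", intervention_types=frozenset({"Drug"}))]
        assignments = {"NCT00000001": SponsorClass.GOV}
        table = intervention_table(corpus, assignments)
        assert table.loc["gov", ("Device", "efficiency_pct")] is None

    def test_efficiency_recovery(self):
        # a generator with com results probability 4.7% in and out of the
        # restrained pool must show ~4.7% com drug efficiency at n=10,000
        config = GeneratorConfig(n_trials=10_000, seed=17)
        config.unrestricted_results_prob[SponsorClass.COM] = 0.047
        config.restrained_results_prob[SponsorClass.COM] = 0.047
        corpus = generate_records(config)
        assignments = {t.nct_id: t.true_class for t in corpus.truth}
        table = intervention_table(corpus.records, assignments)
        assert abs(table.loc["com", ("Drug", "efficiency_pct")] - 4.7) < 1.5


class TestEnrollmentTable:
    def test_single_trial_statistics_coincide(self):
        corpus = [make_record("NCT00000001", enrollment=7)]
        assignments = {"NCT00000001": SponsorClass.HOS}
        table = enrollment_table(corpus, assignments)
        row = table[(table["class"] == "hos") & (table["stratum"] == "all")].iloc[0]
        assert row["n_trials"] == 1
        assert row["max_enrollment"] == row["total_participants"] == 7
        assert row["average_enrollment"] == 7

    def test_sentinel_enrollment_inflates_unrestricted_stratum(self):
        corpus = [
            make_record("NCT00000001", enrollment=100),
            make_record("NCT00000002", enrollment=99_999_999, has_results=False,
                        n_primary_outcomes=0, n_secondary_outcomes=0),
        ]
        assignments = {r.nct_id: SponsorClass.GOV for r in corpus}
        table = enrollment_table(corpus, assignments)
        all_row = table[(table["class"] == "gov") & (table["stratum"] == "all")].iloc[0]
        results_row = table[
            (table["class"] == "gov") & (table["stratum"] == "with_results")
        ].iloc[0]
        assert all_row["max_enrollment"] == 99_999_999
        assert results_row["max_enrollment"] == 100

    def test_missing_enrollment_excluded(self):
        corpus = [
            make_record("NCT00000001", enrollment=None, enrollment_type=None),
            make_record("NCT00000002", enrollment=50),
        ]
        assignments = {r.nct_id: SponsorClass.EDU for r in corpus}
        table = enrollment_table(corpus, assignments)
        row = table[(table["class"] == "edu") & (table["stratum"] == "all")].iloc[0]
        assert row["n_trials"] == 1

    def test_average_consistent_with_total(self):
        corpus = generate_records(GeneratorConfig(n_trials=3_000, seed=19))
        assignments = {t.nct_id: t.true_class for t in corpus.truth}
        table = enrollment_table(corpus.records, assignments)
        populated = table[table["n_trials"] > 0]
        for _, row in populated.iterrows():
            assert row["average_enrollment"] == pytest.approx(
                row["total_participants"] / row["n_trials"], abs=0.005
            )


class TestYearlyActivity:
    def test_single_start_year(self):
        corpus = [
            make_record("NCT00000001", start_date=PartialDate(2009, 1)),
            make_record("NCT00000002", start_date=PartialDate(2009, 8)),
        ]
        table = yearly_activity(corpus)
        started = dict(zip(table["year"], table["started"]))
        assert started[2009] == 2

    def test_missing_start_excluded(self):
        corpus = [make_record("NCT00000001", start_date=None)]
        table = yearly_activity(corpus)
        assert table["started"].sum() == 0
        assert table["completed"].sum() == 1

    def test_completions_can_exceed_starts_in_a_year(self):
        corpus = [
            make_record("NCT00000001", start_date=PartialDate(2009, 1),
                        completion_date=PartialDate(2011, 5)),
            make_record("NCT00000002", start_date=PartialDate(2008, 1),
                        completion_date=PartialDate(2011, 6)),
            make_record("NCT00000003", start_date=PartialDate(2011, 2),
                        completion_date=None),
        ]
        table = yearly_activity(corpus).set_index("year")
        assert table.loc[2011, "completed"] > table.loc[2011, "started"]


class TestPhaseDistribution:
    def test_multi_phase_trial_counts_twice(self):
        corpus = [make_record("NCT00000001", phase_raw="Phase 2/Phase 3")]
        assignments = {"NCT00000001": SponsorClass.COM}
        table = phase_distribution(corpus, assignments).set_index("class")
        assert table.loc["com", "phase_2"] == 1
        assert table.loc["com", "phase_3"] == 1

    def test_na_corpus_all_zero(self):
        corpus = [make_record("NCT00000001", phase_raw="N/A")]
        assignments = {"NCT00000001": SponsorClass.COM}
        table = phase_distribution(corpus, assignments)
        assert table[[f"phase_{p}" for p in (1, 2, 3, 4)]].to_numpy().sum() == 0

    def test_com_phase_mix_peaks_at_three(self):
        corpus = generate_records(GeneratorConfig(n_trials=5_000, seed=23))
        assignments = {t.nct_id: t.true_class for t in corpus.truth}
        table = phase_distribution(corpus.records, assignments).set_index("class")
        com = table.loc["com", [f"phase_{p}" for p in (1, 2, 3, 4)]]
        assert com.idxmax() == "phase_3"
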
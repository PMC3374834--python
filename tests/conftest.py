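import pytest

from trialmeta.records import PartialDate, TrialRecord


def make_record(nct_id="NCT00000001", **kwargs) -> TrialRecord:
    """A valid record with sensible defaults, overridable per test."""
    defaults = dict(
        nct_id=nct_id,
        lead_sponsor_name="Aurora Hospital",
        agency_class="Other",
        overall_status="Completed",
        start_date=PartialDate(2006, 3),
        completion_date=PartialDate(2008, 6),
        phase_raw="Phase 3",
        study_type="Interventional",
        intervention_types=frozenset({"Drug"}),
        is_fda_regulated=True,
        is_section_801=True,
        has_results=True,
        n_primary_outcomes=1,
        n_secondary_outcomes=0,
        n_references=1,
        enrollment=100,
        enrollment_type="Actual",
        number_of_arms=2,
    )
    defaults.update(kwargs)
    return TrialRecord(**defaults)


@pytest.fixture
def record_factory():
    return make_record
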
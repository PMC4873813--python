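import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pvsignal import (CaseReport, DrugExposure, Role, Sex, TermSet,
                      builtin_term_set)


@pytest.fixture(scope="session")
def dm_terms() -> TermSet:
    return builtin_term_set("dm_core")


def make_report(case_id, drugs=(), reactions=("nausea",), version=1, age=None,
                sex=Sex.UNKNOWN, indications=(), roles=None):
    """Terse report builder: ``drugs`` is a list of generic names (optionally
    (name, Role) pairs) that become already-normalized exposures."""
    exposures = []
    for item in drugs:
        if isinstance(item, tuple):
            name, role = item
        else:
            name, role = item, Role.UNKNOWN
        exposures.append(DrugExposure(raw_name=name, generic_name=name, role=role))
    return CaseReport(case_id=case_id, version=version, age_years=age, sex=sex,
                      drugs=tuple(exposures), reactions=frozenset(reactions),
                      indications=frozenset(indications))


@pytest.fixture
def six_reports(dm_terms):
    """2 exposed-with-event, 1 exposed-without, 1 unexposed-with,
    2 unexposed-without — the hand fixture for contingency counting."""
    return [
        make_report("c1", drugs=["quetiapine"], reactions=["diabetes mellitus"]),
        make_report("c2", drugs=["quetiapine", "lithium"], reactions=["diabetic coma"]),
        make_report("c3", drugs=["quetiapine"], reactions=["nausea"]),
        make_report("c4", drugs=["lithium"], reactions=["diabetes mellitus"]),
        make_report("c5", drugs=["lithium"], reactions=["rash"]),
        make_report("c6", drugs=[], reactions=["headache"]),
    ]
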
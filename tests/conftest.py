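import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famseg.annotation import build_variant_records
from famseg.cohort import CohortGenotypes, Family, VariantKey
from famseg.fixtures import build_shared_variant_fixture, build_table_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cohort(call_rows, samples):
    """Tiny in-memory cohort with auto-generated variant keys."""
    variants = [
        VariantKey.make("1", 1000 + i, "A", "T") for i in range(len(call_rows))
    ]
    return CohortGenotypes(
        variants=variants,
        samples=list(samples),
        calls=np.array(call_rows, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def table1():
    ann, fams, cohort = build_table_fixture("table1")
    records, _, _ = build_variant_records(ann, cohort)
    return ann, fams, cohort, records


@pytest.fixture(scope="session")
def table3():
    ann, fams, cohort = build_table_fixture("table3")
    records, _, _ = build_variant_records(ann, cohort)
    return ann, fams, cohort, records


@pytest.fixture(scope="session")
def shared_fixture():
    ann, fams, cohort = build_shared_variant_fixture()
    records, _, _ = build_variant_records(ann, cohort)
    return ann, fams, cohort, records


@pytest.fixture
def trio_family():
    return Family("F1", ("F1.1", "F1.2", "F1.3"), degree_span="1st")
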
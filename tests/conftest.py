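import io

import pytest

from smdmeta import SimulationConfig, make_fixture_table, simulate_ensemble
from smdmeta.ingest import write_comparisons


@pytest.fixture(scope="session")
def fixture_records():
    return make_fixture_table()


@pytest.fixture()
def fixture_csv(tmp_path, fixture_records):
    path = tmp_path / "fixture.csv"
    write_comparisons(fixture_records, path)
    return path


@pytest.fixture(scope="session")
def small_ensemble():
    """50 simulated comparisons with moderate heterogeneity."""
    records, params = simulate_ensemble(
        SimulationConfig(k=50, mu=0.33, tau2=0.1, seed=42)
    )
    return records, params


def records_to_csv_text(records) -> str:
    buf = io.StringIO()
    write_comparisons(records, buf)
    return buf.getvalue()
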
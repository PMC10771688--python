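import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from pssnet import pipeline, synth  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> synth.SimulationConfig:
    """A fast end-to-end configuration (150 prescribers, 600 clients)."""
    return synth.SimulationConfig(n_prescribers=150, n_clients=600, seed=7)


@pytest.fixture(scope="session")
def small_data(small_config) -> synth.SimulationData:
    return synth.simulate(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_data):
    """Cohort, classification and adoption derived from the small dataset."""
    return pipeline.run_analysis(small_data.tables, build_panels=False)


def make_dispensations(rows) -> pd.DataFrame:
    """Tiny dispensation table from (client, prescriber, date[, drug, class, text])."""
    full = []
    for i, r in enumerate(rows, start=1):
        client, prescriber, date = r[:3]
        drug = r[3] if len(r) > 3 else "RAMIPRIL"
        med = r[4] if len(r) > 4 else "other"
        text = r[5] if len(r) > 5 else "Take as directed"
        full.append((f"D{i:04d}", client, prescriber, date, drug, med, text))
    return pd.DataFrame(
        full,
        columns=["dispensation_id", "client_id", "prescriber_id", "date", "drug_code", "med_class", "directions"],
    )


EMPTY_VISITS = pd.DataFrame(columns=["client_id", "prescriber_id", "date", "diagnostic_code"])
EMPTY_ACUTE = pd.DataFrame(columns=["client_id", "date", "diagnostic_code"])
EMPTY_PERINATAL = pd.DataFrame(columns=["client_id", "date"])
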
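from __future__ import annotations

import pytest

from promiscuitrack.ingest import ActivityRecord
from promiscuitrack.synthetic_data import SyntheticConfig, generate_dataset, write_dataset


def make_record(
    compound_id: str = "C1",
    structure: str = "CCO",
    target_id: str = "P00001",
    target_family: str = "FAM01",
    relationship_type: str = "D",
    confidence_score: int = 9,
    measurement_type: str = "Ki",
    relation: str = "=",
    value: float = 50.0,
    units: str = "nM",
    year: int = 2005,
    value_nM: float | None = None,
) -> ActivityRecord:
    """An activity record with high-confidence defaults."""
    if value_nM is None and measurement_type in {"Ki", "IC50", "EC50", "Kd"}:
        value_nM = value * {"nM": 1.0, "uM": 1e3, "M": 1e9}[units]
    return ActivityRecord(
        compound_id=compound_id,
        structure=structure,
        target_id=target_id,
        target_family=target_family,
        relationship_type=relationship_type,
        confidence_score=confidence_score,
        measurement_type=measurement_type,
        relation=relation,
        value=value,
        units=units,
        year=year,
        value_nM=value_nM,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_drugs=60, n_decoy_compounds=15, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(activities, drugs, truth) frames for a small synthetic landscape."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_dataset_dir(small_config, tmp_path_factory):
    """The same small landscape written to disk."""
    out = tmp_path_factory.mktemp("synthetic")
    return write_dataset(small_config, out)
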
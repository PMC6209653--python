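from __future__ import annotations

import pytest

from genemeta.data_model_io import group_by_variant, write_records_tsv
from genemeta.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def sim_config():
    return SimulationConfig(
        variant_id="rs1000001",
        true_or=1.3,
        control_af=0.4,
        k_studies=6,
        n_cases_range=(300, 600),
        n_controls_range=(300, 600),
        seed=11,
    )


@pytest.fixture
def sim_records(sim_config):
    records, _ = simulate_dataset(sim_config)
    return records


@pytest.fixture
def sim_dataset(sim_records):
    return group_by_variant(sim_records)[0]


@pytest.fixture
def sim_tsv(tmp_path, sim_records):
    path = tmp_path / "input.tsv"
    write_records_tsv(sim_records, path)
    return path
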
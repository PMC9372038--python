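import pytest

from mastqtl import qtl_data
from mastqtl.consensus_map import build_consensus
from mastqtl.pipeline import RunConfig, run_pipeline
from mastqtl.synthetic_data import (
    SimulationScenario,
    simulate_omics,
    simulate_studies,
    write_inputs,
)


@pytest.fixture(scope="session")
def scenario():
    return SimulationScenario(seed=0)


@pytest.fixture(scope="session")
def study_data(scenario):
    return simulate_studies(scenario)


@pytest.fixture(scope="session")
def omics(scenario, study_data):
    return simulate_omics(scenario, study_data)


@pytest.fixture(scope="session")
def prepared_records(study_data):
    return qtl_data.prepare_records(study_data.qtls, study_data.study_maps)


@pytest.fixture(scope="session")
def cmap(study_data):
    return build_consensus([study_data.base_map, *study_data.study_maps.values()])


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, scenario, study_data, omics):
    d = tmp_path_factory.mktemp("sim")
    write_inputs(scenario, study_data, omics, d)
    return d


@pytest.fixture(scope="session")
def pipeline_run(sim_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    # LD window matched to the synthetic marker resolution: physical anchoring
    # can only resolve intervals to one marker spacing (~33 kb), so MTA
    # containment uses a 50 kb window.
    cfg = RunConfig.from_directory(str(sim_dir), outdir=str(out), seed=0, mta_window_bp=50_000)
    return run_pipeline(cfg)
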
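import pytest

from specuniq import PipelineConfig, SampleMeta, SimConfig, generate, run_pipeline

# Table-1-style cohort: 4 atrophic controls, 2 endometrioid, 2 serous
TABLE1 = [
    ("012", "atrophic", "none", 55, 19),
    ("015", "atrophic", "none", 65, 22),
    ("062", "atrophic", "none", 63, 26),
    ("069", "atrophic", "none", 57, 24),
    ("038", "cancer", "type1", 88, 24),
    ("075", "cancer", "type1", 74, 42),
    ("TA-01", "cancer", "type2", 61, 38),
    ("TA-02", "cancer", "type2", 61, 40),
]


@pytest.fixture(scope="session")
def table1_meta():
    return [SampleMeta(*row) for row in TABLE1]


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def sim_output():
    """Default synthetic cohort, fixed seed, shared across the session."""
    return generate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(sim_output, default_config):
    return run_pipeline(
        sim_output.psms,
        sim_output.fasta,
        sim_output.samples,
        sim_output.knowledge,
        sim_output.annotations,
        default_config,
    )
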
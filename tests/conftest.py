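import numpy as np
import pytest

from dupdiverge.pipeline import PipelineConfig, run_pipeline
from dupdiverge.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bundle50(tmp_path_factory):
    """A 50-pair synthetic study with a full all-vs-all hit table."""
    config = SimulationConfig(seed=11, n_pairs=50, alignment_scope="all_vs_all")
    out = tmp_path_factory.mktemp("bundle50")
    return simulate_study(config, out)


@pytest.fixture(scope="session")
def pipeline_run(bundle50, tmp_path_factory):
    """Outputs of a full pipeline run on the 50-pair bundle."""
    out_dir = tmp_path_factory.mktemp("pipeline50")
    config = PipelineConfig(
        proteins=str(bundle50.proteins_path),
        cds=str(bundle50.cds_path),
        gene_models=str(bundle50.gene_models_path),
        hits=str(bundle50.hits_path),
        expression=str(bundle50.expression_path),
        lineage=str(bundle50.lineage_path),
        out_dir=str(out_dir),
        structure_bin_size=10,
        expression_bin_size=5,
    )
    return config, run_pipeline(config)
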
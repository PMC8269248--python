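import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import termscape as ts

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SIM_SEED = 1  # seeded default study conditions shared across the suite


@pytest.fixture(scope="session")
def default_sim():
    """20 genes, 2 replicates, peak height 50, noise 0.02."""
    return ts.default_simulation(seed=SIM_SEED)


@pytest.fixture(scope="session")
def pipeline_result(default_sim):
    genome, genes, tss_set, truth, termseq, rnaseq = default_sim
    cfg = ts.PipelineConfig(cv_reps=200, rng_seed=SIM_SEED)
    return ts.run_pipeline(genome, genes, tss_set, termseq, rnaseq, cfg)


@pytest.fixture(scope="session")
def recovery(default_sim, pipeline_result):
    truth = default_sim[3]
    return ts.recovery_metrics(pipeline_result.teps, pipeline_result.tus, truth)


@pytest.fixture()
def flat_genome():
    """Unstructured 2-contig genome for coordinate arithmetic tests."""
    rng = np.random.default_rng(42)
    seqs = {
        "c1": "".join(rng.choice(list("ACGT"), size=5000)),
        "c2": "".join(rng.choice(list("ACGT"), size=3000)),
    }
    return ts.Genome(seqs)
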
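import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poolseqval as pv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# the triallelic warning fires for most simulated sites once sequencing
# error is on; keep the test output readable
logging.getLogger("poolseqval.poolfreq").setLevel(logging.ERROR)


STUDY_MODEL = pv.SequencingModel(
    coverage=("uniform", 55, 284), error_rate=0.01
)


@pytest.fixture(scope="session")
def study_run():
    """One emulated study: 3 pools x 20 diploids x 9 SNPs, 1% error,
    assay dropout at the emulated rate, fully piped to comparison
    records."""
    design = pv.PopulationDesign.random(np.random.default_rng(42))
    exp = pv.simulate_experiment(design, STUDY_MODEL, 22 / 540, seed=42)
    table = pv.call_snps(exp.sites)
    records = pv.pair_records(table, exp.observed_genotypes)
    return exp, table, records
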
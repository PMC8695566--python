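import logging

import pytest

from icimeth.labeling import assign_labels, compute_tgfb_score, compute_tmb
from icimeth.pathways import default_pathway
from icimeth.simulate import SimConfig, generate_cohort

logging.getLogger("icimeth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_types=4, cases_per_type=60, n_probes=600, n_informative=90,
        n_signature=60, n_genes=300, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    tmb = compute_tmb(small_cohort.mutations, small_cohort.case_ids)
    score = compute_tgfb_score(small_cohort.counts, default_pathway())
    return assign_labels(tmb, score)
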
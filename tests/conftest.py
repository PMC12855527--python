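import numpy as np
import pandas as pd
import pytest

from pgxmeta import SimConfig, corpus_from_frame, simulate_corpus


def make_corpus(smds, variances=None, studies=None, outcomes=None, phenotypes=None, n_totals=None):
    """Small hand-built corpus for toy tests."""
    k = len(smds)
    variances = variances if variances is not None else [0.04] * k
    studies = studies if studies is not None else [f"s{i}" for i in range(k)]
    outcomes = outcomes if outcomes is not None else ["proximal"] * k
    phenotypes = phenotypes if phenotypes is not None else ["poor"] * k
    n_totals = n_totals if n_totals is not None else [100] * k
    return corpus_from_frame(
        pd.DataFrame(
            {
                "effect_id": [f"e{i}" for i in range(k)],
                "study_id": studies,
                "smd": smds,
                "smd_variance": variances,
                "n_total": n_totals,
                "outcome_label": outcomes,
                "phenotype": phenotypes,
            }
        ),
        errors="raise",
    )


@pytest.fixture(scope="session")
def sim_corpus_small():
    """A 40-study corpus at the default (literature-shaped) configuration."""
    return simulate_corpus(SimConfig(n_studies=40, seed=42))


@pytest.fixture(scope="session")
def sim_corpus_signed():
    return simulate_corpus(SimConfig(n_studies=40, seed=43, signed=True))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
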
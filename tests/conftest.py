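import numpy as np
import pandas as pd
import pytest

from ionpanel import synth


@pytest.fixture(scope="session")
def small_proteome():
    return synth.generate_proteome(60, 0.15, synth.ProteomeConfig(seed=42))


@pytest.fixture(scope="session")
def small_experiment(small_proteome):
    """Three paired tumor/control maps from one platform."""
    cfg = synth.MapSimConfig(n_pairs_per_platform=3, noise_sd=0.2, seed=7)
    return synth.generate_platform_experiment(small_proteome, cfg), cfg


@pytest.fixture(scope="session")
def small_cohort():
    return synth.generate_serum_cohort(
        synth.CohortSimConfig(n_cases=60, n_controls=90, seed=5)
    )


@pytest.fixture()
def proteome_annotations(small_proteome):
    return pd.DataFrame(
        {
            "accession": [p.accession for p in small_proteome],
            "localization": [p.localization for p in small_proteome],
            "protein_class": "",
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
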
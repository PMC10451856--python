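import numpy as np
import pandas as pd
import pytest

from mvifusion.phantom import PhantomConfig, cohort_labels, generate_study


@pytest.fixture(scope="session")
def small_cohort():
    """Ten in-memory studies (48^3, calibrated defaults) shared across tests."""
    cfg = PhantomConfig(n_patients=20, volume_shape=(48, 48, 48), mvi_fraction=0.5, seed=11)
    labels = cohort_labels(cfg)
    studies = [generate_study(cfg, i, int(l)) for i, l in enumerate(labels)]
    return cfg, studies


@pytest.fixture(scope="session")
def small_roster(small_cohort):
    _, studies = small_cohort
    return pd.DataFrame(
        {"patient_id": [s.patient_id for s in studies], "mvi_label": [s.mvi_label for s in studies]}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
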
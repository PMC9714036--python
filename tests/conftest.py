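import numpy as np
import pytest

import tcaflux as tf


@pytest.fixture(scope="session")
def default_model():
    return tf.build_network()


@pytest.fixture(scope="session")
def glucose_infusion_tc():
    """Noiseless primed-infusion glucose time course at default parameters."""
    return tf.experiments.infusion_timecourse(
        "glucose_U13C6", times=(0.0, 5.0, 10.0, 14.0, 15.0, 16.0, 20.0, 25.0, 30.0, 60.0, 150.0)
    )


@pytest.fixture(scope="session")
def small_cohort():
    spec = tf.CohortSpec(
        n_genes=60,
        n_samples=200,
        planted_positive={"SLC7A7": 0.8},
        planted_negative={"SLC7A5": 0.8},
        seed=7,
    )
    return tf.generate_expression_cohort(spec)


def random_mid(rng: np.random.Generator, n_carbons: int, metabolite: str = "citrate"):
    frac = rng.dirichlet(np.ones(n_carbons + 1))
    return tf.MIDVector(metabolite, frac)
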
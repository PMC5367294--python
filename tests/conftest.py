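import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def noise_free_peck():
    """One noise-free simulated pigeon peck with its ground truth."""
    from peckkit import simulate

    sp = simulate.pigeon_params(marker_noise_sd=0.0)
    return simulate.simulate_peck(sp, rng_seed=7, trial_id="nf-0")


@pytest.fixture()
def two_trials():
    """Two small simulated trials (one per species), with noise."""
    from peckkit import simulate

    t1, _ = simulate.simulate_peck(simulate.pigeon_params(), rng_seed=1,
                                   trial_id="p-1", individual="p1")
    t2, _ = simulate.simulate_peck(simulate.crow_params(), rng_seed=2,
                                   trial_id="c-1", individual="c1")
    t2.species = "crow"
    return [t1, t2]
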
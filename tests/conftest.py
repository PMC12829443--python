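import numpy as np
import pytest

import fearcond as fc
from fearcond import models, synth

SEED = 123


@pytest.fixture(scope="session")
def schedule():
    return fc.build_schedule(seed=SEED)


@pytest.fixture(scope="session")
def cohort_1a(schedule):
    """Twenty subjects simulated from the base model with a decisive lapse,
    so learning rates are identifiable from the 60 trials."""
    spec = fc.get_model("1a")
    hyper = fc.GroupHyperparameters.reference()
    rng = np.random.default_rng(2024)
    truths = synth.draw_subject_parameters(hyper, 20, rng, spec)
    ratings = {
        f"S{i + 1:03d}": models.simulate_ratings(spec, p, schedule, rng)
        for i, p in enumerate(truths)
    }
    responses = models.responses_frame(schedule, ratings)
    return {"spec": spec, "hyper": hyper, "truths": truths, "responses": responses}


@pytest.fixture(scope="session")
def fit_1a(cohort_1a):
    """Base-model fit at the study's published sampler settings
    (4 chains, 500 warm-up, 500 sampling iterations)."""
    return fc.fit_model(
        cohort_1a["spec"],
        cohort_1a["responses"],
        fc.SamplerConfig(chains=4, warmup=500, samples=500, seed=11),
    )
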
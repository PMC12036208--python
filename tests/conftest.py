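import numpy as np
import pytest

import respcurve as rc


@pytest.fixture
def ll4_noiseless():
    recipe = rc.DRRecipe("LL.4", (2.0, 5.0, 95.0, 3.0), noise_sd=0.0, seed=1)
    return rc.simulate_dose_response(recipe), recipe


@pytest.fixture
def ll4_noisy():
    recipe = rc.DRRecipe("LL.4", (2.0, 5.0, 95.0, 3.0), noise_sd=5.0, seed=7)
    return rc.simulate_dose_response(recipe), recipe


@pytest.fixture
def bc5_dataset():
    recipe = rc.DRRecipe("BC.5", (2.0, 0.0, 100.0, 10.0, 5.0),
                         doses=rc.default_doses(8, 0.01, 300.0),
                         noise_sd=3.0, seed=11)
    return rc.simulate_dose_response(recipe), recipe


@pytest.fixture
def te_toy():
    """Non-overlapping intervals (0,2],(2,4],(4,6] with counts 20/30/10 of
    100; censored remainder 40 beyond t=6."""
    recs = [rc.TERecord(("a",), 1, 0.0, 2.0, 20),
            rc.TERecord(("a",), 1, 2.0, 4.0, 30),
            rc.TERecord(("a",), 1, 4.0, 6.0, 10)]
    ds = rc.TimeToEventDataset(recs, {(("a",), 1): 100})
    return ds.with_censored_remainder()


@pytest.fixture
def te_large():
    recipe = rc.TERecipe(model_id="TE_LL4",
                         params=dict(b=4.0, d=0.9, e=48.0),
                         inspection_times=np.arange(6.0, 169.0, 6.0),
                         n_individuals=5000, seed=3)
    return rc.simulate_time_to_event(recipe), recipe
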
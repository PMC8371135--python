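import numpy as np
import pytest

from t5rf import stimuli, synth


@pytest.fixture(scope="session")
def geometry():
    return stimuli.ScreenGeometry()


@pytest.fixture(scope="session")
def fixed_linear_population():
    """A dispersion-free linear-ROI population for exact-recovery tests."""
    return synth.RFPopulation(
        polarity="linear",
        x0_between_fly_sd=0.0,
        x0_within_fly_sd=0.0,
        log_w_between_fly_sd=0.0,
        log_w_within_fly_sd=0.0,
        log_A_between_fly_sd=0.0,
        log_A_within_fly_sd=0.0,
        surround_amp_ratio=0.0,  # pure-Gaussian receptive field
    )


@pytest.fixture(scope="session")
def single_linear_roi(fixed_linear_population):
    cohort = synth.make_cohort(1, 1, fixed_linear_population, seed=0)
    fly_id, roi_id, rf = next(cohort.all_rois())
    return cohort, rf
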
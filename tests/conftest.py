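import pytest

from teppipe import features as feat_mod
from teppipe import synthgen, workflow
from teppipe.montage import make_default_layout, make_roi_layout


@pytest.fixture(scope="session")
def default_layout():
    return make_default_layout()


@pytest.fixture(scope="session")
def roi_layout():
    return make_roi_layout()


@pytest.fixture(scope="session")
def micro_cohort():
    """4 subjects x 9 trials x 8 channels; runs through every stage in seconds."""
    return workflow.make_fixtures()


@pytest.fixture(scope="session")
def micro_table(micro_cohort):
    cohort, rois = micro_cohort
    pre = workflow.preprocess_cohort(cohort)
    return feat_mod.build_feature_table(pre, rois=rois)


@pytest.fixture(scope="session")
def ci_recovery_table():
    """Feature table of a 200-subject CI cohort at low noise.

    Generator amplitudes/latencies and the local-field-power calibration
    follow the reported right-frontal CI group statistics.  90 trials per
    subject give balanced 30/30/30 segments; the compact ROI montage is
    used because the right-frontal features under test are identical by
    construction (the topography is reference-neutral on any montage) and
    the full scalp would only add runtime.
    """
    params = synthgen.GenParams(n_trials=90, noise_sd=0.2, seed=1,
                                layout=make_roi_layout())
    return workflow.simulate_group_features("CI", 200, params)
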
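import numpy as np
import pytest

from dfcstates import features as feat
from dfcstates import prep
from dfcstates.synthetic import SyntheticCohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-scale two-group cohort: 4+4 subjects, 8 components, 120 volumes."""
    cfg = SyntheticCohortConfig(
        n_per_group=4,
        n_components=8,
        n_volumes=120,
        k_true=3,
        separation=0.9,
        mean_dwell_target=30,
        noise_sd=0.3,
        seed=11,
    )
    subjects, truth = simulate_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def small_feature_sets(small_cohort):
    _, subjects, _ = small_cohort
    sets = []
    for tc in subjects:
        clean = prep.preprocess(tc)
        swc = feat.sliding_window_correlations(clean)
        sets.append(feat.zscore_feature_blocks(feat.aswc_and_derivatives(swc)))
    return sets


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_tc(data, subject_id="S01", group="control", tr=2.0):
    return prep.ComponentTimecourses(subject_id=subject_id, group=group, data=data, tr_seconds=tr)
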
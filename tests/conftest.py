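import numpy as np
import pytest

from fmvpa import bold_sim, preprocess, roi

GRID = (16, 16, 8)
REGION_A_CENTER = (4, 8, 4)
REGION_B_CENTER = (12, 8, 4)
REGION_RADIUS = 2.5


@pytest.fixture(scope="session")
def region_a():
    return roi.sphere_mask(GRID, REGION_A_CENTER, REGION_RADIUS, "region_a")


@pytest.fixture(scope="session")
def region_b():
    return roi.sphere_mask(GRID, REGION_B_CENTER, REGION_RADIUS, "region_b")


@pytest.fixture(scope="session")
def signal_subject(region_a):
    """One synthetic subject with a strong memory signal confined to region A."""
    config = bold_sim.SimulationConfig(
        grid_shape=GRID,
        informative_regions={"region_a": region_a.data},
        effect_size=1.5,
        seed=3,
    )
    return bold_sim.simulate_subject("FM", config)


def preprocess_subject(subject: bold_sim.SubjectData, cb_seed: int = 1):
    sets = []
    for rd, vs, ev in zip(subject.design.runs, subject.runs, subject.events):
        base = preprocess.baseline_volume_indices(rd, tr=vs.tr)
        normed, _ = preprocess.detrend_and_zscore(vs, base)
        sets.append(preprocess.extract_trial_samples(normed, ev, subject.truth))
    return preprocess.counterbalance(preprocess.SampleSet.concatenate(sets), cb_seed)


@pytest.fixture(scope="session")
def signal_samples(signal_subject):
    return preprocess_subject(signal_subject)


def random_sample_set(rng: np.random.Generator, **kw) -> preprocess.SampleSet:
    """Pure-noise balanced sample set: Gaussian features, labels carry no signal."""
    from fmvpa.experiments import gaussian_null_samples

    return gaussian_null_samples(rng, **kw)
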
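"""Detrending, baseline z-scoring, peak-window extraction, counterbalancing."""

import numpy as np
import pytest

from fmvpa import bold_sim, paradigm, preprocess
from fmvpa.bold_sim import VolumeSeries
from fmvpa.paradigm import BASELINE


def make_series(data, tr=2.0, run_index=0):
    return VolumeSeries(
        data=np.asarray(data, float),
        tr=tr,
        affine=np.eye(4),
        run_index=run_index,
        subject_id="sub-01",
    )


@pytest.mark.parametrize(
    "onset,expected",
    [(12.0, [9, 10]), (0.0, [3, 4]), (13.0, [10])],  # odd onsets hit one volume
)
def test_window_volume_indices(onset, expected):
    assert preprocess.window_volume_indices(onset, tr=2.0) == expected


def test_baseline_indices_against_enumeration():
    design = paradigm.make_subject_design("FM", 3)
    run = design.runs[0]
    idx = preprocess.baseline_volume_indices(run, tr=2.0)
    # independent brute force: every volume time inside some baseline peak window
    n_vol = run.n_volumes(2.0)
    expected = []
    for i in range(n_vol):
        t = i * 2.0
        if t < run.lead_in:
            continue
        for ev in run.events:
            if ev.trial_type == BASELINE and ev.onset + 6 <= t <= ev.onset + 8:
                expected.append(i)
                break
    assert idx.tolist() == expected
    assert idx.min() >= 6  # 12 s lead-in at TR=2
    assert idx.max() < n_vol
    assert len(idx) >= 10  # every baseline trial contributes at least one volume


def test_zscore_identity_on_baseline_volumes():
    rng = np.random.default_rng(0)
    vs = make_series(rng.normal(5, 3, size=(3, 3, 2, 40)))
    base = np.arange(10, 20)
    out, flagged = preprocess.detrend_and_zscore(vs, base, detrend=False)
    base_vals = out.data[..., base]
    assert np.allclose(base_vals.mean(axis=3), 0.0, atol=1e-10)
    assert np.allclose(base_vals.std(axis=3), 1.0, atol=1e-10)
    assert not flagged.any()


def test_zscore_idempotent_on_baseline_statistics():
    rng = np.random.default_rng(1)
    vs = make_series(rng.normal(size=(2, 2, 2, 30)))
    base = np.arange(5, 15)
    once, _ = preprocess.detrend_and_zscore(vs, base, detrend=False)
    twice, _ = preprocess.detrend_and_zscore(once, base, detrend=False)
    assert np.allclose(once.data[..., base], twice.data[..., base], atol=1e-8)


def test_constant_voxel_zeroed_and_flagged():
    vs = make_series(np.full((2, 2, 1, 20), 7.0))
    out, flagged = preprocess.detrend_and_zscore(vs, np.arange(5, 10), detrend=False)
    assert np.all(out.data == 0.0)
    assert flagged.all()


def test_detrend_removes_known_slope():
    t = np.arange(50, dtype=float)
    data = np.zeros((2, 2, 1, 50)) + 0.7 * t + np.random.default_rng(2).normal(
        0, 0.01, (2, 2, 1, 50)
    )
    vs = make_series(data)
    out, _ = preprocess.detrend_and_zscore(vs, np.arange(10, 20))
    series = out.data[0, 0, 0]
    slope = np.polyfit(t, series, 1)[0]
    assert abs(slope) < 1e-8


def test_too_few_baseline_volumes_rejected():
    vs = make_series(np.zeros((2, 2, 1, 20)))
    with pytest.raises(ValueError, match="baseline"):
        preprocess.detrend_and_zscore(vs, np.array([3]))


def test_extraction_averages_peak_window_volumes():
    import pandas as pd

    data = np.zeros((2, 2, 1, 20))
    data[..., 9] = 2.0
    data[..., 10] = 4.0
    vs = make_series(data)
    events = pd.DataFrame(
        {
            "onset": [12.0],
            "duration": [9.0],
            "trial_type": ["novel_target"],
            "stimulus_id": ["novel_001"],
        }
    )
    labels = pd.DataFrame({"stimulus_id": ["novel_001"], "label": ["remembered"]})
    ss = preprocess.extract_trial_samples(vs, events, labels)
    assert ss.n_samples == 1 and ss.n_features == 4
    assert np.allclose(ss.X, 3.0)  # mean of volumes 9 and 10
    assert ss.y[0]
    cc = preprocess.extract_trial_samples(vs, events, labels, aggregation="concatenate")
    assert cc.n_samples == 2
    assert np.allclose(cc.X[0], 2.0) and np.allclose(cc.X[1], 4.0)


def test_window_past_run_end_drops_trial():
    import pandas as pd

    vs = make_series(np.zeros((2, 2, 1, 8)))
    events = pd.DataFrame(
        {
            "onset": [12.0],
            "duration": [9.0],
            "trial_type": ["novel_target"],
            "stimulus_id": ["novel_001"],
        }
    )
    labels = pd.DataFrame({"stimulus_id": ["novel_001"], "label": ["forgotten"]})
    with pytest.warns(UserWarning, match="dropped"):
        ss = preprocess.extract_trial_samples(vs, events, labels)
    assert ss.n_samples == 0


def test_full_subject_extraction_yields_at_most_62_samples():
    cfg = bold_sim.SimulationConfig(grid_shape=(8, 8, 4), seed=2)
    sub = bold_sim.simulate_subject("FM", cfg)
    sets = []
    for rd, vs, ev in zip(sub.design.runs, sub.runs, sub.events):
        base = preprocess.baseline_volume_indices(rd)
        normed, _ = preprocess.detrend_and_zscore(vs, base)
        sets.append(preprocess.extract_trial_samples(normed, ev, sub.truth))
    ss = preprocess.SampleSet.concatenate(sets)
    assert ss.n_samples == 62  # no trial window exceeds a run here
    assert sorted(np.unique(ss.runs)) == [0, 1, 2]


def _toy_samples(n_pos, n_neg, run=0, rng=None):
    rng = rng or np.random.default_rng(0)
    n = n_pos + n_neg
    return preprocess.SampleSet(
        X=rng.standard_normal((n, 3)),
        y=np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)],
        runs=np.full(n, run),
        subjects=np.array(["s"] * n),
        stimulus_ids=np.array([f"t{run}_{i}" for i in range(n)]),
        voxel_index=np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]]),
        grid_shape=(3, 1, 1),
    )


def test_counterbalance_min_rule():
    ss = _toy_samples(10, 6)
    out = preprocess.counterbalance(ss, 0)
    assert int(out.y.sum()) == 6 and int((~out.y).sum()) == 6
    # outputs are a subset of inputs, never fabricated
    assert set(out.stimulus_ids) <= set(ss.stimulus_ids)


def test_counterbalance_balanced_run_unchanged():
    ss = _toy_samples(5, 5)
    out = preprocess.counterbalance(ss, 3)
    assert set(out.stimulus_ids) == set(ss.stimulus_ids)


def test_counterbalance_deterministic():
    ss = _toy_samples(12, 7)
    a = preprocess.counterbalance(ss, 9)
    b = preprocess.counterbalance(ss, 9)
    assert np.array_equal(a.stimulus_ids, b.stimulus_ids)


def test_counterbalance_drops_single_class_run():
    both = _toy_samples(4, 4, run=0)
    lone = _toy_samples(5, 0, run=1)
    ss = preprocess.SampleSet.concatenate([both, lone])
    with pytest.warns(UserWarning, match="one class"):
        out = preprocess.counterbalance(ss, 0)
    assert set(np.unique(out.runs)) == {0}


def test_sample_set_tsv_round_trip(tmp_path):
    ss = _toy_samples(4, 4)
    path = tmp_path / "samples.tsv"
    ss.to_tsv(path)
    back = preprocess.SampleSet.from_tsv(path)
    assert np.allclose(back.X, ss.X)
    assert np.array_equal(back.y, ss.y)
    assert np.array_equal(back.voxel_index, ss.voxel_index)
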
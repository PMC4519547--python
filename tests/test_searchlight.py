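"""Searchlight geometry, mapping, thresholding and peak reporting."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_sample_set
from fmvpa import decode, searchlight
from fmvpa.searchlight import AccuracyMap


def brute_force_count(radius: int) -> int:
    count = 0
    for i in range(-radius, radius + 1):
        for j in range(-radius, radius + 1):
            for k in range(-radius, radius + 1):
                if i * i + j * j + k * k <= radius * radius:
                    count += 1
    return count


@pytest.mark.parametrize("radius,expected", [(0, 1), (2, 33), (4, 257)])
def test_sphere_offsets_counts(radius, expected):
    assert len(searchlight.sphere_offsets(radius)) == expected


@pytest.mark.parametrize("radius", range(6))
def test_sphere_offsets_match_lattice_enumeration(radius):
    offs = searchlight.sphere_offsets(radius)
    assert len(offs) == brute_force_count(radius)
    assert (0, 0, 0) in {tuple(o) for o in offs}
    assert np.all(np.einsum("ij,ij->i", offs, offs) <= radius**2)
    # deterministic lexicographic order
    assert sorted(map(tuple, offs)) == list(map(tuple, offs))


def test_negative_radius_rejected():
    with pytest.raises(ValueError):
        searchlight.sphere_offsets(-1)


def test_mm_offsets_respect_anisotropic_voxels():
    # 3x3x5 mm voxels: a 6 mm ball reaches 2 voxels in-plane but only 1 in z
    offs = searchlight.sphere_offsets_mm(6.0, (3.0, 3.0, 5.0))
    assert (0, 0, 0) in {tuple(o) for o in offs}
    assert max(abs(o[0]) for o in offs) == 2
    assert max(abs(o[2]) for o in offs) == 1
    # with isotropic unit voxels the mm ball equals the index ball
    iso = searchlight.sphere_offsets_mm(4.0, (1.0, 1.0, 1.0))
    assert len(iso) == 257


def test_null_map_centered_at_chance():
    rng = np.random.default_rng(0)
    ss = random_sample_set(rng, n_voxels=256, grid_shape=(8, 8, 4))
    plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
    amap = searchlight.searchlight_map(ss, plan, radius=1)
    vals = amap.data[amap.defined()]
    assert len(vals) == 256
    assert np.mean(vals) == pytest.approx(0.5, abs=0.02)


def test_signal_localizes_near_source():
    """Accuracy peaks within the informative sphere dilated by the radius."""
    rng = np.random.default_rng(1)
    ss = random_sample_set(rng, n_voxels=256, grid_shape=(8, 8, 4))
    src = np.array([2, 2, 2])
    in_src = (np.linalg.norm(ss.voxel_index - src, axis=1) <= 1.5).nonzero()[0]
    ss.X[:, in_src] += 2.0 * np.where(ss.y, 1.0, -1.0)[:, None] * rng.standard_normal(
        len(in_src)
    )[None, :]
    plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
    radius = 2
    amap = searchlight.searchlight_map(ss, plan, radius=radius)
    peak = np.unravel_index(np.nanargmax(amap.data), amap.data.shape)
    assert np.linalg.norm(np.array(peak) - src) <= 1.5 + radius


def test_edge_centers_are_scored_not_skipped():
    rng = np.random.default_rng(2)
    ss = random_sample_set(rng, n_voxels=64, grid_shape=(4, 4, 4))
    plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
    amap = searchlight.searchlight_map(ss, plan, radius=1)
    assert not np.isnan(amap.data[0, 0, 0])  # corner neighborhood is clipped, not dropped


def test_map_invariant_to_sample_order():
    rng = np.random.default_rng(3)
    ss = random_sample_set(rng, n_voxels=64, grid_shape=(4, 4, 4))
    plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
    a = searchlight.searchlight_map(ss, plan, radius=1)
    perm = rng.permutation(ss.n_samples)
    ss_perm = ss.subset(perm)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    plan_perm = decode.FoldPlan(
        folds=[(np.sort(inv[tr]), np.sort(inv[te])) for tr, te in plan.folds],
        scheme=plan.scheme,
    )
    b = searchlight.searchlight_map(ss_perm, plan_perm, radius=1)
    assert np.array_equal(np.nan_to_num(a.data), np.nan_to_num(b.data))


def _flat_map(acc_value, shape=(4, 4, 2)):
    return AccuracyMap(
        data=np.full(shape, acc_value, dtype=float),
        n_test_samples=40,
        affine=np.eye(4),
    )


def test_threshold_chance_map_has_no_significant_voxels():
    out = searchlight.threshold_map(_flat_map(0.5), alpha=0.05)
    assert out.significant.sum() == 0


def test_threshold_perfect_accuracy_significant():
    out = searchlight.threshold_map(_flat_map(1.0), n_test_samples=40, alpha=0.05)
    assert out.significant.all()


def test_fdr_mode_is_more_conservative():
    rng = np.random.default_rng(4)
    amap = AccuracyMap(
        data=rng.uniform(0.4, 0.7, size=(6, 6, 3)), n_test_samples=40, affine=np.eye(4)
    )
    raw = searchlight.threshold_map(amap, alpha=0.05)
    fdr = searchlight.threshold_map(amap, alpha=0.05, fdr=True)
    assert fdr.significant.sum() <= raw.significant.sum()


def test_false_positive_rate_calibrated():
    """Binomial thresholding of chance maps keeps per-voxel FPR near alpha."""
    rng = np.random.default_rng(5)
    n = 40
    fp = []
    for _ in range(200):
        acc = rng.binomial(n, 0.5, size=(5, 5, 2)) / n
        amap = AccuracyMap(data=acc.astype(float), n_test_samples=n, affine=np.eye(4))
        out = searchlight.threshold_map(amap, alpha=0.05)
        fp.append(out.significant.mean())
    # exact binomial test is conservative at discrete n
    assert np.mean(fp) <= 0.05 + 0.03


def test_report_peaks_empty_and_clusters():
    amap = _flat_map(0.5)
    amap.significant = np.zeros(amap.data.shape, bool)
    assert len(searchlight.report_peaks(amap)) == 0

    data = np.full((6, 6, 2), 0.5)
    sig = np.zeros((6, 6, 2), bool)
    sig[0:2, 0, 0] = True  # cluster of 2
    data[0, 0, 0] = 0.8
    sig[4:6, 4:6, 1] = True  # cluster of 4, higher peak
    data[5, 5, 1] = 0.9
    amap = AccuracyMap(
        data=data, n_test_samples=40, affine=np.diag([3.0, 3.0, 5.0, 1.0])
    )
    amap.significant = sig
    peaks = searchlight.report_peaks(amap)
    assert len(peaks) == 2
    assert peaks.loc[0, "peak_accuracy"] == 0.9  # sorted descending
    assert peaks.loc[0, "size"] == 4
    assert (peaks.loc[0, "x_mm"], peaks.loc[0, "z_mm"]) == (15.0, 5.0)
    only_big = searchlight.report_peaks(amap, min_cluster_size=3)
    assert len(only_big) == 1


def test_unthresholded_map_cannot_report_peaks():
    with pytest.raises(ValueError, match="threshold"):
        searchlight.report_peaks(_flat_map(0.6))
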
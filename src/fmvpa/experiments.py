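"""Canned experiments over synthetic cohorts.

These drivers wire the simulator to the decoding stack for the standard
validation studies: null calibration of the whole pipeline, type-I error of
the permutation test, signal recovery / double dissociation across regions
with searchlight localization, and the feature-selection leakage contrast.
Problem sizes default to desk scale (16x16x8 grids, a dozen subjects); all
randomness descends from a single seed.
"""

from __future__ import annotations

import numpy as np

from . import decode, permute, roi, searchlight
from ._rng import substream
from .pipeline import RunConfig, preprocess_subject, simulate_cohort
from .preprocess import SampleSet

DEFAULT_GRID = (16, 16, 8)
REGION_A = {"kind": "sphere", "center": [4, 8, 4], "radius": 2.5}
REGION_B = {"kind": "sphere", "center": [12, 8, 4], "radius": 2.5}


def gaussian_null_samples(
    rng: np.random.Generator,
    n_per_run_class: int = 8,
    n_runs: int = 3,
    n_voxels: int = 64,
    grid_shape: tuple = (8, 8, 4),
) -> SampleSet:
    """Balanced pure-noise sample set: features carry no label information."""
    n = 2 * n_per_run_class * n_runs
    coords = np.column_stack(
        np.unravel_index(np.arange(n_voxels), grid_shape, order="F")
    )
    runs = np.repeat(np.arange(n_runs), 2 * n_per_run_class)
    y = np.tile(
        np.r_[np.ones(n_per_run_class, bool), np.zeros(n_per_run_class, bool)], n_runs
    )
    return SampleSet(
        X=rng.standard_normal((n, n_voxels)),
        y=y,
        runs=runs,
        subjects=np.array(["sub-01"] * n),
        stimulus_ids=np.array([f"s{i:03d}" for i in range(n)]),
        voxel_index=coords,
        grid_shape=grid_shape,
    )


def null_pipeline_accuracy(
    n_subjects: int = 12, grid_shape: tuple = DEFAULT_GRID, seed: int = 0
) -> dict:
    """Full pipeline on signal-free BOLD: within-subject accuracy should sit at 0.5."""
    config = RunConfig(
        n_subjects=n_subjects, grid_shape=grid_shape, effect_size=0.0, seed=seed
    )
    subjects = simulate_cohort(config)
    sample_sets = {s.subject_id: preprocess_subject(s, config) for s in subjects}
    per_subject, mean = decode.within_subject_decode(sample_sets, k=config.k)
    return {
        "mean_accuracy": mean,
        "per_subject": {s: r.mean_accuracy for s, r in per_subject.items()},
        "n_subjects": n_subjects,
    }


def permutation_type_one_error(
    n_repetitions: int = 100,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n_voxels: int = 64,
    k: int = 16,
) -> dict:
    """Rejection rate of the permutation test on label-free data."""
    rng = substream(seed, "type-one")
    rejections = 0
    p_values = []
    for rep in range(n_repetitions):
        ss = gaussian_null_samples(rng, n_voxels=n_voxels)
        plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
        null = permute.permutation_test(
            ss,
            plan,
            k=k,
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        p_values.append(null.p_value)
        rejections += null.p_value < alpha
    return {
        "rejection_rate": rejections / n_repetitions,
        "alpha": alpha,
        "n_repetitions": n_repetitions,
        "p_values": np.asarray(p_values),
    }


def _dissociation_config(n_subjects, effect_size, grid_shape, seed) -> RunConfig:
    return RunConfig(
        n_subjects=n_subjects,
        grid_shape=grid_shape,
        effect_size=effect_size,
        seed=seed,
        regions={"region_a": REGION_A, "region_b": REGION_B},
        signal_regions=["region_a"],
    )


def double_dissociation(
    n_subjects: int = 6,
    effect_size: float = 1.5,
    grid_shape: tuple = DEFAULT_GRID,
    seed: int = 0,
    radius: float = 2.0,
    alpha: float = 0.05,
    run_searchlight: bool = True,
) -> dict:
    """Signal confined to region A: regional decoding plus searchlight Dice.

    Region A should decode about as well as the whole brain, control region
    B should stay at chance, and the thresholded group searchlight map
    should overlap region A (Dice over the region mask).
    """
    config = _dissociation_config(n_subjects, effect_size, grid_shape, seed)
    subjects = simulate_cohort(config)
    sample_sets = {s.subject_id: preprocess_subject(s, config) for s in subjects}
    mask_a = roi.sphere_mask(
        grid_shape, tuple(REGION_A["center"]), REGION_A["radius"], "region_a"
    )
    mask_b = roi.sphere_mask(
        grid_shape, tuple(REGION_B["center"]), REGION_B["radius"], "region_b"
    )
    acc: dict[str, list[float]] = {"whole_brain": [], "region_a": [], "region_b": []}
    maps = []
    for samples in sample_sets.values():
        plan = decode.make_fold_plan(samples, decode.LEAVE_ONE_RUN_OUT)
        battery = roi.roi_battery(samples, [mask_a, mask_b], plan, k=config.k)
        for name, res in battery.items():
            acc[name].append(res.mean_accuracy)
        if run_searchlight:
            maps.append(searchlight.searchlight_map(samples, plan, radius=radius))
    out = {name: float(np.mean(v)) for name, v in acc.items()}
    result = {"accuracy": out, "per_subject": acc, "n_subjects": n_subjects}
    if run_searchlight:
        group = searchlight.AccuracyMap(
            data=np.mean(np.stack([m.data for m in maps]), axis=0),
            n_test_samples=sum(m.n_test_samples for m in maps),
            affine=maps[0].affine,
        )
        thresholded = searchlight.threshold_map(group, alpha=alpha, fdr=True)
        sig = thresholded.significant
        inter = np.logical_and(sig, mask_a.data).sum()
        dice = 2.0 * inter / (sig.sum() + mask_a.data.sum())
        result["searchlight"] = {
            "dice_region_a": float(dice),
            "n_significant": int(sig.sum()),
            "map": thresholded,
        }
    return result


def leakage_comparison(
    n_datasets: int = 30,
    n_voxels: int = 500,
    k: int = 50,
    seed: int = 0,
) -> dict:
    """Nested vs global (leaky) feature selection on label-free data.

    Selecting voxels on all data before cross-validation leaks test labels
    into training and inflates null accuracy; nested selection does not.
    """
    rng = substream(seed, "leakage")
    nested, leaky = [], []
    for _ in range(n_datasets):
        ss = gaussian_null_samples(rng, n_voxels=n_voxels, grid_shape=(10, 10, 8))
        plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
        nested.append(decode.cross_validate(ss, plan, k=k).mean_accuracy)
        leaky.append(
            decode.cross_validate(ss, plan, k=k, selection="global").mean_accuracy
        )
    nested = np.asarray(nested)
    leaky = np.asarray(leaky)
    se = float(nested.std(ddof=1) / np.sqrt(n_datasets))
    return {
        "nested_mean": float(nested.mean()),
        "global_mean": float(leaky.mean()),
        "nested_se": se,
        "n_datasets": n_datasets,
    }
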
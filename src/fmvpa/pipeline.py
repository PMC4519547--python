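"""End-to-end orchestration: simulate -> preprocess -> decode/roi/searchlight -> permute.

A single declarative RunConfig drives every stage; all randomness descends
from one master seed through named substreams, the config is serialized
into the output directory, and a run manifest logs each stage with its wall
time so any result can be traced to its inputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bold_sim, decode, permute, preprocess, roi, searchlight
from ._rng import substream


@dataclass
class RunConfig:
    out_dir: str = "fmvpa_run"
    condition: str = "FM"
    n_subjects: int = 4
    scheme: str = decode.LEAVE_ONE_RUN_OUT
    k: int = decode.DEFAULT_K
    svm_c: float = decode.DEFAULT_C
    radius: float = 4.0
    alpha: float = 0.05
    n_permutations: int = 200
    seed: int = 0
    aggregation_mode: str = "average"
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    effect_size: float = 1.0
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 0.5
    p_remember: float | None = None
    regions: dict[str, dict] = field(default_factory=dict)
    #: region names that carry simulated class signal (None = all regions)
    signal_regions: list[str] | None = None
    run_searchlight: bool = False
    run_permutation: bool = True

    def validate(self) -> None:
        if self.condition not in ("FM", "EE"):
            raise ValueError("condition must be FM or EE")
        if self.scheme not in (decode.LEAVE_ONE_RUN_OUT, decode.LEAVE_ONE_SUBJECT_OUT):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.aggregation_mode not in ("average", "concatenate"):
            raise ValueError("aggregation_mode must be average or concatenate")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _region_masks(config: RunConfig) -> dict[str, np.ndarray]:
    masks = {}
    for name, spec in config.regions.items():
        kind = spec.get("kind", "sphere")
        if kind == "sphere":
            m = roi.sphere_mask(config.grid_shape, tuple(spec["center"]), spec["radius"], name)
        elif kind == "box":
            m = roi.box_mask(config.grid_shape, tuple(spec["lo"]), tuple(spec["hi"]), name)
        else:
            raise ValueError(f"unknown region kind {kind!r}")
        masks[name] = m.data
    return masks


def simulate_cohort(config: RunConfig) -> list[bold_sim.SubjectData]:
    """One synthetic subject per seed substream, identical acquisition.

    Class patterns are drawn once per cohort and shared by every subject,
    emulating spatially normalized data in which the same multivoxel code
    distinguishes later-remembered trials across people — the premise of the
    cross-subject validation scheme.
    """
    subjects = []
    cohort_patterns = None
    all_masks = _region_masks(config)
    if config.signal_regions is None:
        informative = all_masks
    else:
        missing = set(config.signal_regions) - set(all_masks)
        if missing:
            raise ValueError(f"signal_regions not defined as regions: {sorted(missing)}")
        informative = {n: all_masks[n] for n in config.signal_regions}
    for i in range(config.n_subjects):
        sub_seed = int(substream(config.seed, f"subject-{i}").integers(2**31))
        sim = bold_sim.SimulationConfig(
            grid_shape=config.grid_shape,
            informative_regions=informative,
            effect_size=config.effect_size,
            noise_sd=config.noise_sd,
            ar1_coef=config.ar1_coef,
            drift_amplitude=config.drift_amplitude,
            p_remember=config.p_remember,
            seed=sub_seed,
        )
        if cohort_patterns is None:
            cohort_patterns = bold_sim.draw_patterns(
                sim, substream(config.seed, "cohort-patterns")
            )
        subjects.append(
            bold_sim.simulate_subject(
                config.condition,
                sim,
                subject_id=f"sub-{i + 1:02d}",
                patterns=cohort_patterns,
            )
        )
    return subjects


def preprocess_subject(
    subject: bold_sim.SubjectData, config: RunConfig
) -> preprocess.SampleSet:
    """Detrend + baseline z-score each run, extract and counterbalance trials."""
    per_run = []
    for rd, vs, ev in zip(subject.design.runs, subject.runs, subject.events):
        base_idx = preprocess.baseline_volume_indices(rd, tr=vs.tr)
        normed, _ = preprocess.detrend_and_zscore(vs, base_idx)
        per_run.append(
            preprocess.extract_trial_samples(
                normed, ev, subject.truth, aggregation=config.aggregation_mode
            )
        )
    samples = preprocess.SampleSet.concatenate(per_run)
    cb_seed = int(substream(config.seed, f"counterbalance-{subject.subject_id}").integers(2**31))
    return preprocess.counterbalance(samples, cb_seed)


def run_experiment(config: RunConfig) -> dict:
    """Execute the configured pipeline; write TSV/JSON outputs and a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: list[dict] = []

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest.append(
                {"stage": name, "seconds": round(time.perf_counter() - t0, 3)}
            )

        return done

    end = stage("simulate")
    subjects = simulate_cohort(config)
    end()

    end = stage("preprocess")
    sample_sets = {s.subject_id: preprocess_subject(s, config) for s in subjects}
    end()

    end = stage("decode")
    if config.scheme == decode.LEAVE_ONE_RUN_OUT:
        per_subject, group_mean = decode.within_subject_decode(
            sample_sets, k=config.k, C=config.svm_c
        )
        rows = [
            {"scheme": config.scheme, "subject": sub, "fold": i, "accuracy": acc}
            for sub, res in per_subject.items()
            for i, acc in enumerate(res.fold_accuracies)
        ]
        pooled_cm = decode.ConfusionMatrix()
        for res in per_subject.values():
            pooled_cm = pooled_cm + res.confusion
        first_plan_samples = next(iter(sample_sets.values()))
        plan = decode.make_fold_plan(first_plan_samples, config.scheme)
        perm_target = (first_plan_samples, plan)
    else:
        pooled = preprocess.SampleSet.concatenate(list(sample_sets.values()))
        plan = decode.make_fold_plan(pooled, config.scheme)
        result = decode.cross_validate(pooled, plan, k=config.k, C=config.svm_c)
        group_mean = result.mean_accuracy
        pooled_cm = result.confusion
        rows = [
            {"scheme": config.scheme, "subject": "all", "fold": i, "accuracy": acc}
            for i, acc in enumerate(result.fold_accuracies)
        ]
        perm_target = (pooled, plan)
    pd.DataFrame(rows).to_csv(out / "decoding_results.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "tp": pooled_cm.tp,
                "fp": pooled_cm.fp,
                "fn": pooled_cm.fn,
                "tn": pooled_cm.tn,
                "precision": decode.precision(pooled_cm) if pooled_cm.tp + pooled_cm.fp else float("nan"),
                "f_score": decode.f_score(pooled_cm),
                "accuracy": pooled_cm.accuracy,
            }
        ]
    ).to_csv(out / "confusion.tsv", sep="\t", index=False)
    end()

    summary = {"scheme": config.scheme, "mean_accuracy": group_mean, "seed": config.seed}

    if config.regions:
        end = stage("roi")
        masks = [
            roi.Mask(data=m, name=n, affine=bold_sim.DEFAULT_AFFINE)
            for n, m in _region_masks(config).items()
        ]
        battery_rows = []
        for sub, samples in sample_sets.items():
            sub_plan = decode.make_fold_plan(samples, decode.LEAVE_ONE_RUN_OUT)
            res = roi.roi_battery(samples, masks, sub_plan, k=config.k, C=config.svm_c)
            for region, r in res.items():
                battery_rows.append(
                    {"subject": sub, "region": region, "accuracy": r.mean_accuracy}
                )
        battery = pd.DataFrame(battery_rows)
        battery.to_csv(out / "roi_results.tsv", sep="\t", index=False)
        summary["roi_mean_accuracy"] = (
            battery.groupby("region")["accuracy"].mean().to_dict()
        )
        end()

    if config.run_permutation:
        end = stage("permute")
        samples, perm_plan = perm_target
        null = permute.permutation_test(
            samples,
            perm_plan,
            k=config.k,
            n_permutations=config.n_permutations,
            seed=int(substream(config.seed, "permutation").integers(2**31)),
            C=config.svm_c,
        )
        pd.DataFrame(
            {
                "permutation": np.arange(null.n_permutations),
                "accuracy": null.permuted_accuracies,
            }
        ).to_csv(out / "permutation.tsv", sep="\t", index=False)
        summary["permutation"] = {
            "observed": null.observed_accuracy,
            "p_value": null.p_value,
            "n_permutations": null.n_permutations,
        }
        end()

    if config.run_searchlight:
        end = stage("searchlight")
        maps = []
        for sub, samples in sample_sets.items():
            sub_plan = decode.make_fold_plan(samples, decode.LEAVE_ONE_RUN_OUT)
            maps.append(
                searchlight.searchlight_map(
                    samples, sub_plan, radius=config.radius, C=config.svm_c
                )
            )
        group = searchlight.AccuracyMap(
            data=np.nanmean(np.stack([m.data for m in maps]), axis=0),
            n_test_samples=sum(m.n_test_samples for m in maps),
            affine=maps[0].affine,
        )
        thresholded = searchlight.threshold_map(group, alpha=config.alpha, fdr=True)
        import nibabel as nib

        nib.save(thresholded.to_nifti(), out / "searchlight_accuracy.nii.gz")
        nib.save(thresholded.significance_nifti(), out / "searchlight_significant.nii.gz")
        peaks = searchlight.report_peaks(thresholded)
        peaks.to_csv(out / "searchlight_peaks.tsv", sep="\t", index=False)
        summary["searchlight_n_significant"] = int(thresholded.significant.sum())
        end()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
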
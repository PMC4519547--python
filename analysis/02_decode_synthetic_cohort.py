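"""Decode subsequent memory in a synthetic cohort, within and across subjects.

Simulates a small FM cohort with a moderate memory signal in one region,
runs the whole-brain pipeline under both validation schemes, and attaches a
permutation p-value to each observed accuracy. Outputs: per-fold accuracies,
the pooled confusion matrix with precision/F-score, and a JSON summary.
"""

import json
from pathlib import Path

import pandas as pd

from fmvpa import decode, permute
from fmvpa.pipeline import RunConfig, preprocess_subject, simulate_cohort
from fmvpa.preprocess import SampleSet

OUT = Path(__file__).resolve().parents[1] / "results"
N_PERMUTATIONS = 200  # desk-scale stand-in for the 10000/1000 defaults


def main() -> None:
    config = RunConfig(
        n_subjects=6,
        grid_shape=(16, 16, 8),
        effect_size=0.8,
        seed=42,
        regions={"signal": {"kind": "sphere", "center": [4, 8, 4], "radius": 2.5}},
        n_permutations=N_PERMUTATIONS,
    )
    subjects = simulate_cohort(config)
    sample_sets = {s.subject_id: preprocess_subject(s, config) for s in subjects}

    # within-subject: leave-one-run-out per subject, group mean over subjects
    per_subject, within_mean = decode.within_subject_decode(sample_sets, k=config.k)
    rows = [
        {"scheme": "within_subject", "subject": sub, "fold": i, "accuracy": acc}
        for sub, res in per_subject.items()
        for i, acc in enumerate(res.fold_accuracies)
    ]
    first = next(iter(sample_sets))
    within_null = permute.permutation_test(
        sample_sets[first],
        decode.make_fold_plan(sample_sets[first], decode.LEAVE_ONE_RUN_OUT),
        k=config.k,
        n_permutations=N_PERMUTATIONS,
        seed=config.seed,
        observed=per_subject[first],
    )

    # cross-subject: pool everyone, leave one subject out
    pooled = SampleSet.concatenate(list(sample_sets.values()))
    plan = decode.make_fold_plan(pooled, decode.LEAVE_ONE_SUBJECT_OUT)
    cross = decode.cross_validate(pooled, plan, k=config.k)
    rows += [
        {"scheme": "cross_subject", "subject": "all", "fold": i, "accuracy": acc}
        for i, acc in enumerate(cross.fold_accuracies)
    ]
    cross_null = permute.permutation_test(
        pooled, plan, k=config.k, n_permutations=N_PERMUTATIONS,
        seed=config.seed + 1, observed=cross,
    )

    pd.DataFrame(rows).to_csv(OUT / "decoding_accuracies.tsv", sep="\t", index=False)
    cm = cross.confusion
    pd.DataFrame(
        [
            {
                "scheme": "cross_subject",
                "tp": cm.tp,
                "fp": cm.fp,
                "fn": cm.fn,
                "tn": cm.tn,
                "precision": round(decode.precision(cm), 3),
                "f_score": round(decode.f_score(cm), 3),
                "accuracy": round(cm.accuracy, 3),
            }
        ]
    ).to_csv(OUT / "decoding_confusion.tsv", sep="\t", index=False)

    summary = {
        "within_subject_mean_accuracy": within_mean,
        "within_subject_first_subject_p": within_null.p_value,
        "cross_subject_mean_accuracy": cross.mean_accuracy,
        "cross_subject_p": cross_null.p_value,
        "n_subjects": config.n_subjects,
        "effect_size": config.effect_size,
        "n_permutations": N_PERMUTATIONS,
        "seed": config.seed,
    }
    (OUT / "decoding_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    print(
        f"within-subject decoding recovers the signal at "
        f"{within_mean:.3f} (chance 0.5); cross-subject pooling reaches "
        f"{cross.mean_accuracy:.3f} with permutation p = {cross_null.p_value:.4g}."
    )


if __name__ == "__main__":
    main()
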
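"""Scoring of the out-of-scanner 4AFC recognition tests.

Memory for each novel picture–label association is probed twice with a
four-alternative forced choice (chance = 1/4). Items the participant reports
as pre-experimentally familiar are excluded from scoring. A participant is
retained for decoding only when performance is above chance on both a
test-1 binomial criterion and a two-test consistency criterion; the
consistency null takes the probability of guessing the same item correctly
twice as (1/4)^2. Labels for the decoding analysis come from the first test:
remembered iff test-1 correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

N_ALTERNATIVES = 4

RECORD_COLUMNS = ["stimulus_id", "test1_correct", "test2_correct", "reported_familiar"]


@dataclass
class RecognitionScore:
    n: int
    n_correct1: int
    prop1: float
    n_correct_both: int
    prop_both: float
    n_familiar_excluded: int


def _usable(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"recognition table lacks columns {missing}")
    return records[~records["reported_familiar"].astype(bool)]


def score_recognition(records: pd.DataFrame) -> RecognitionScore:
    """Proportions correct on test 1 and on both tests, familiar items excluded."""
    if len(records) == 0:
        raise ValueError("no recognition records")
    kept = _usable(records)
    n = len(kept)
    if n == 0:
        raise ValueError("all items reported familiar; nothing to score")
    k1 = int(kept["test1_correct"].astype(bool).sum())
    kb = int((kept["test1_correct"].astype(bool) & kept["test2_correct"].astype(bool)).sum())
    return RecognitionScore(
        n=n,
        n_correct1=k1,
        prop1=k1 / n,
        n_correct_both=kb,
        prop_both=kb / n,
        n_familiar_excluded=len(records) - n,
    )


def inclusion_test(
    records: pd.DataFrame,
    alpha: float = 0.05,
    consistency_null: str = "both_correct",
) -> dict:
    """Above-chance inclusion criterion over both recognition tests.

    ``p1`` is the upper-tail binomial p-value for the test-1 correct count
    against chance 1/4. The two-test consistency criterion defaults to the
    both-tests-correct count against chance (1/4)^2; the alternative
    ``consistency_null='test2'`` scores the test-2 marginal against 1/4.
    Inclusion requires both p-values below ``alpha``.
    """
    score = score_recognition(records)
    chance = 1.0 / N_ALTERNATIVES
    p1 = stats.binomtest(score.n_correct1, score.n, chance, alternative="greater").pvalue
    if consistency_null == "both_correct":
        p_both = stats.binomtest(
            score.n_correct_both, score.n, chance**2, alternative="greater"
        ).pvalue
    elif consistency_null == "test2":
        kept = _usable(records)
        k2 = int(kept["test2_correct"].astype(bool).sum())
        p_both = stats.binomtest(k2, score.n, chance, alternative="greater").pvalue
    else:
        raise ValueError(f"unknown consistency null {consistency_null!r}")
    return {
        "include": bool(p1 < alpha and p_both < alpha),
        "p1": float(p1),
        "p_both": float(p_both),
    }


def labels_from_behavior(records: pd.DataFrame, which_test: str = "test1") -> pd.DataFrame:
    """Subsequent-memory labels: remembered iff correct on the chosen test.

    Familiar-flagged items are dropped; the decoding pipeline never sees them.
    """
    kept = _usable(records)
    col = {"test1": "test1_correct", "test2": "test2_correct"}.get(which_test)
    if col is None:
        raise ValueError(f"which_test must be 'test1' or 'test2', got {which_test!r}")
    label = kept[col].astype(bool).map({True: "remembered", False: "forgotten"})
    return pd.DataFrame(
        {"stimulus_id": kept["stimulus_id"].to_numpy(), "label": label.to_numpy()}
    )
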
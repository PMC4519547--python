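"""Trial schedule generation for the fast-mapping / explicit-encoding design.

The experiment presents three trial types — novel-association targets (the
trials later sorted by subsequent memory), familiar targets, and perceptual
baseline trials — in pseudorandomized sequences of 8 (composition 4/2/2) or
4 (composition 2/1/1). A subject receives 124 events over 3 runs: two runs
of 5 eight-event sequences (40 events, 482 s) and a final run with an extra
four-event sequence (44 events, 532 s).

Each event is built from four fixed sub-stages — question (3 s), picture
(2 s), response (1.5 s), feedback (0.5 s) — followed by a fixation cross of
2 s in half of a run's events and 6 s in the other half, so events last 9 or
13 s with a mean of 11 s. Runs open with a 12 s lead-in (equilibration
volumes, excluded from analysis) and a 6 s blank screen follows each
sequence. At TR = 2 s the runs span 241, 241 and 266 volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream

NOVEL = "novel_target"
FAMILIAR = "familiar_target"
BASELINE = "baseline"
TRIAL_TYPES = (NOVEL, FAMILIAR, BASELINE)

QUESTION_DUR = 3.0
PICTURE_DUR = 2.0
RESPONSE_DUR = 1.5
FEEDBACK_DUR = 0.5
FIXATION_SHORT = 2.0
FIXATION_LONG = 6.0

LEAD_IN = 12.0
INTER_SEQUENCE_BLANK = 6.0
DEFAULT_TR = 2.0

#: trial-type composition of a full and a half sequence
SEQ8_COMPOSITION = {NOVEL: 4, FAMILIAR: 2, BASELINE: 2}
SEQ4_COMPOSITION = {NOVEL: 2, FAMILIAR: 1, BASELINE: 1}

#: number of 8-event sequences per run; run 2 gets one extra 4-event sequence
RUN_SEQUENCES = ((8,) * 5, (8,) * 5, (8,) * 5 + (4,))


@dataclass
class EventSpec:
    """One trial with its sub-stage timings."""

    trial_type: str
    onset: float
    fixation_dur: float
    stimulus_id: str
    sequence_index: int
    run_index: int
    question_dur: float = QUESTION_DUR
    picture_dur: float = PICTURE_DUR
    response_dur: float = RESPONSE_DUR
    feedback_dur: float = FEEDBACK_DUR

    @property
    def duration(self) -> float:
        """Total event duration (9 or 13 s)."""
        return (
            self.question_dur
            + self.picture_dur
            + self.response_dur
            + self.feedback_dur
            + self.fixation_dur
        )

    @property
    def stimulus_onset(self) -> float:
        """Onset of the picture stage, the assumed neural event."""
        return self.onset + self.question_dur


@dataclass
class RunDesign:
    run_index: int
    events: list[EventSpec]
    lead_in: float = LEAD_IN
    inter_sequence_blank: float = INTER_SEQUENCE_BLANK

    @property
    def n_sequences(self) -> int:
        return max(e.sequence_index for e in self.events) + 1

    @property
    def total_duration(self) -> float:
        return (
            self.lead_in
            + sum(e.duration for e in self.events)
            + self.n_sequences * self.inter_sequence_blank
        )

    def n_volumes(self, tr: float = DEFAULT_TR) -> int:
        n = self.total_duration / tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"run duration {self.total_duration} s is not a multiple of TR={tr}"
            )
        return int(round(n))


@dataclass
class SubjectDesign:
    condition: str
    seed: int
    runs: list[RunDesign] = field(default_factory=list)

    @property
    def events(self) -> list[EventSpec]:
        return [e for run in self.runs for e in run.events]

    def count(self, trial_type: str) -> int:
        return sum(e.trial_type == trial_type for e in self.events)


def make_sequence(
    n_events: int,
    rng_seed: int | np.random.Generator,
    fixation_durs: list[float] | None = None,
) -> list[EventSpec]:
    """Pseudorandomize one sequence of trials.

    Composition is 4 novel / 2 familiar / 2 baseline for ``n_events=8`` and
    2/1/1 for ``n_events=4``. Fixation durations may be supplied by the
    caller (run-level balancing); when omitted, the sequence itself is
    balanced half 2 s / half 6 s. Onsets and stimulus ids are placeholders
    until the sequence is packed into a run.
    """
    if n_events == 8:
        composition = SEQ8_COMPOSITION
    elif n_events == 4:
        composition = SEQ4_COMPOSITION
    else:
        raise ValueError(f"sequence length must be 8 or 4, got {n_events}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    types = [t for t, n in composition.items() for _ in range(n)]
    order = rng.permutation(len(types))
    types = [types[i] for i in order]
    if fixation_durs is None:
        fixation_durs = [FIXATION_SHORT] * (n_events // 2) + [FIXATION_LONG] * (
            n_events // 2
        )
        fixation_durs = [fixation_durs[i] for i in rng.permutation(n_events)]
    if len(fixation_durs) != n_events:
        raise ValueError("one fixation duration required per event")
    return [
        EventSpec(
            trial_type=t,
            onset=float("nan"),
            fixation_dur=f,
            stimulus_id="",
            sequence_index=-1,
            run_index=-1,
        )
        for t, f in zip(types, fixation_durs)
    ]


def _make_run(run_index: int, rng: np.random.Generator) -> RunDesign:
    seq_lengths = RUN_SEQUENCES[run_index]
    n_events = sum(seq_lengths)
    # run-level fixation balance: exactly half short, half long
    fixations = [FIXATION_SHORT] * (n_events // 2) + [FIXATION_LONG] * (n_events // 2)
    fixations = [fixations[i] for i in rng.permutation(n_events)]
    events: list[EventSpec] = []
    t = LEAD_IN
    pos = 0
    for seq_idx, n in enumerate(seq_lengths):
        seq = make_sequence(n, rng, fixation_durs=fixations[pos : pos + n])
        pos += n
        for ev in seq:
            ev.onset = t
            ev.sequence_index = seq_idx
            ev.run_index = run_index
            t += ev.duration
            events.append(ev)
        t += INTER_SEQUENCE_BLANK
    return RunDesign(run_index=run_index, events=events)


def make_subject_design(condition: str, seed: int) -> SubjectDesign:
    """Generate the full 3-run, 124-event schedule for one subject."""
    if condition not in ("FM", "EE"):
        raise ValueError(f"condition must be 'FM' or 'EE', got {condition!r}")
    rng = substream(seed, f"design-{condition}")
    runs = [_make_run(i, rng) for i in range(3)]
    # assign stable stimulus ids in presentation order
    counters = dict.fromkeys(TRIAL_TYPES, 0)
    prefix = {NOVEL: "novel", FAMILIAR: "familiar", BASELINE: "baseline"}
    for run in runs:
        for ev in run.events:
            counters[ev.trial_type] += 1
            ev.stimulus_id = f"{prefix[ev.trial_type]}_{counters[ev.trial_type]:03d}"
    design = SubjectDesign(condition=condition, seed=seed, runs=runs)
    _validate(design)
    return design


def _validate(design: SubjectDesign) -> None:
    if len(design.events) != 124:
        raise AssertionError("subject must have 124 events")
    if design.count(NOVEL) != 62 or design.count(FAMILIAR) != 31:
        raise AssertionError("trial-type composition violated")
    for run in design.runs:
        fix = [e.fixation_dur for e in run.events]
        if fix.count(FIXATION_SHORT) != fix.count(FIXATION_LONG):
            raise AssertionError("fixation durations must split half/half per run")
        onsets = [e.onset for e in run.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise AssertionError("onsets must be strictly increasing")


def design_to_events_table(design: SubjectDesign) -> list[pd.DataFrame]:
    """Render the design as one BIDS-style events table per run."""
    tables = []
    for run in design.runs:
        tables.append(
            pd.DataFrame(
                {
                    "onset": [e.onset for e in run.events],
                    "duration": [e.duration for e in run.events],
                    "trial_type": [e.trial_type for e in run.events],
                    "stimulus_id": [e.stimulus_id for e in run.events],
                    "sequence": [e.sequence_index for e in run.events],
                }
            )
        )
    return tables


def write_events_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_events_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
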
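"""From volumes to labeled trial samples.

In-scope preprocessing: per-voxel linear detrending, run-wise z-scoring
referenced to the baseline-trial volumes (mean and SD are computed only over
volumes acquired during the peak hemodynamic window of baseline trials),
extraction of one feature vector per novel trial from the 6-8 s post-onset
peak window, and per-run class counterbalancing by random down-sampling of
the majority class. Spatial realignment/normalization is assumed done
upstream (or unnecessary, for synthetic data).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bold_sim import FORGOTTEN, REMEMBERED, VolumeSeries
from .paradigm import BASELINE, DEFAULT_TR, NOVEL, RunDesign

PEAK_WINDOW = (6.0, 8.0)  # seconds post trial onset


@dataclass
class SampleSet:
    """Labeled trial feature vectors with run/subject provenance.

    ``X`` is (n_samples, n_features); column j measures the voxel at grid
    coordinate ``voxel_index[j]`` (x-fastest scan order of the originating
    mask). ``y`` is True for remembered trials.
    """

    X: np.ndarray
    y: np.ndarray  # bool, True = remembered
    runs: np.ndarray
    subjects: np.ndarray
    stimulus_ids: np.ndarray
    voxel_index: np.ndarray  # (n_features, 3) int grid coordinates
    grid_shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows and labels disagree")
        if self.X.shape[1] != len(self.voxel_index):
            raise ValueError("X columns and voxel_index disagree")
        coords = {tuple(c) for c in np.asarray(self.voxel_index)}
        if len(coords) != len(self.voxel_index):
            raise ValueError("voxel_index contains duplicates")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def labels(self) -> np.ndarray:
        return np.where(self.y, REMEMBERED, FORGOTTEN)

    def subset(self, rows: np.ndarray) -> "SampleSet":
        rows = np.asarray(rows)
        return SampleSet(
            X=self.X[rows],
            y=self.y[rows],
            runs=self.runs[rows],
            subjects=self.subjects[rows],
            stimulus_ids=self.stimulus_ids[rows],
            voxel_index=self.voxel_index,
            grid_shape=self.grid_shape,
            affine=self.affine,
        )

    def restrict_features(self, cols: np.ndarray) -> "SampleSet":
        cols = np.asarray(cols)
        return SampleSet(
            X=self.X[:, cols],
            y=self.y,
            runs=self.runs,
            subjects=self.subjects,
            stimulus_ids=self.stimulus_ids,
            voxel_index=self.voxel_index[cols],
            grid_shape=self.grid_shape,
            affine=self.affine,
        )

    @staticmethod
    def concatenate(sets: list["SampleSet"]) -> "SampleSet":
        """Pool subjects sharing a common voxel space (cross-subject analysis)."""
        first = sets[0]
        for s in sets[1:]:
            if s.grid_shape != first.grid_shape or not np.array_equal(
                s.voxel_index, first.voxel_index
            ):
                raise ValueError("sample sets do not share a voxel space")
        return SampleSet(
            X=np.vstack([s.X for s in sets]),
            y=np.concatenate([s.y for s in sets]),
            runs=np.concatenate([s.runs for s in sets]),
            subjects=np.concatenate([s.subjects for s in sets]),
            stimulus_ids=np.concatenate([s.stimulus_ids for s in sets]),
            voxel_index=first.voxel_index,
            grid_shape=first.grid_shape,
            affine=first.affine,
        )

    def to_tsv(self, path: str | Path) -> None:
        """One row per trial: subject, run, label, then features; JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.X, columns=[f"v{i}" for i in range(self.n_features)])
        df.insert(0, "stimulus_id", self.stimulus_ids)
        df.insert(0, "label", self.labels())
        df.insert(0, "run", self.runs)
        df.insert(0, "subject", self.subjects)
        df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "voxel_index": np.asarray(self.voxel_index).tolist(),
            "grid_shape": list(self.grid_shape),
            "affine": np.asarray(self.affine).tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        feat_cols = [c for c in df.columns if c.startswith("v")]
        return cls(
            X=df[feat_cols].to_numpy(dtype=float),
            y=(df["label"] == REMEMBERED).to_numpy(),
            runs=df["run"].to_numpy(),
            subjects=df["subject"].to_numpy(),
            stimulus_ids=df["stimulus_id"].to_numpy(),
            voxel_index=np.asarray(sidecar["voxel_index"], dtype=int),
            grid_shape=tuple(sidecar["grid_shape"]),
            affine=np.asarray(sidecar["affine"]),
        )


def window_volume_indices(
    onset: float, tr: float, window: tuple[float, float] = PEAK_WINDOW
) -> list[int]:
    """Volumes acquired within [onset+lo, onset+hi], endpoints inclusive.

    Volume i is acquired at time i*TR from run start (volume 0 at t=0).
    """
    lo, hi = window
    first = int(np.ceil((onset + lo) / tr - 1e-9))
    last = int(np.floor((onset + hi) / tr + 1e-9))
    return list(range(first, last + 1))


def baseline_volume_indices(
    run_design: RunDesign,
    tr: float = DEFAULT_TR,
    window: tuple[float, float] = PEAK_WINDOW,
) -> np.ndarray:
    """Volumes in the peak window of baseline trials, excluding the lead-in."""
    n_vol = run_design.n_volumes(tr)
    lead_in_vols = int(np.ceil(run_design.lead_in / tr - 1e-9))
    idx: set[int] = set()
    for ev in run_design.events:
        if ev.trial_type != BASELINE:
            continue
        for i in window_volume_indices(ev.onset, tr, window):
            if lead_in_vols <= i < n_vol:
                idx.add(i)
    return np.array(sorted(idx), dtype=int)


def detrend_and_zscore(
    vs: VolumeSeries,
    baseline_indices: np.ndarray,
    detrend: bool = True,
) -> tuple[VolumeSeries, np.ndarray]:
    """Linear detrend, then z-score each voxel against baseline-volume statistics.

    Returns the transformed series plus a boolean grid flagging voxels whose
    baseline SD was zero (their series is set to 0).
    """
    baseline_indices = np.asarray(baseline_indices, dtype=int)
    if len(baseline_indices) < 2:
        raise ValueError("need at least 2 baseline volumes for z-scoring")
    data = np.asarray(vs.data, dtype=np.float64)
    n_t = data.shape[3]
    if detrend:
        t = np.arange(n_t, dtype=float)
        t_c = t - t.mean()
        slope = (data * t_c).sum(axis=3, keepdims=True) / (t_c**2).sum()
        data = data - slope * t_c  # remove linear trend, keep mean
    base = data[..., baseline_indices]
    mu = base.mean(axis=3, keepdims=True)
    sd = base.std(axis=3, ddof=0, keepdims=True)
    flagged = sd[..., 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (data - mu) / sd_safe
    out[flagged, :] = 0.0
    return (
        VolumeSeries(
            data=out,
            tr=vs.tr,
            affine=vs.affine,
            run_index=vs.run_index,
            subject_id=vs.subject_id,
        ),
        flagged,
    )


def _grid_voxel_index(
    grid_shape: tuple[int, int, int], mask: np.ndarray | None
) -> np.ndarray:
    nx, ny, nz = grid_shape
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    flat = np.flatnonzero(mask.ravel(order="F"))
    x, y, z = np.unravel_index(flat, grid_shape, order="F")
    return np.column_stack([x, y, z]).astype(int)


def extract_trial_samples(
    vs: VolumeSeries,
    events: pd.DataFrame,
    labels: pd.DataFrame,
    window: tuple[float, float] = PEAK_WINDOW,
    mask: np.ndarray | None = None,
    aggregation: str = "average",
) -> SampleSet:
    """One feature vector per labeled novel trial from its peak-window volumes.

    ``aggregation='average'`` averages the window's volumes into a single
    sample per trial (default). ``'concatenate'`` stacks them as separate
    rows sharing the trial's label and stimulus id.
    """
    if aggregation not in ("average", "concatenate"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    label_of = dict(zip(labels["stimulus_id"], labels.iloc[:, 1]))
    voxel_index = _grid_voxel_index(vs.grid_shape, mask)
    if mask is None:
        flat_cols = np.arange(int(np.prod(vs.grid_shape)))
    else:
        flat_cols = np.flatnonzero(mask.ravel(order="F"))
    # (n_vox, n_t) in x-fastest order
    flat = np.transpose(vs.data, (2, 1, 0, 3)).reshape(-1, vs.n_volumes)[flat_cols]

    rows, ys, stims = [], [], []
    novel = events[events["trial_type"] == NOVEL]
    for _, ev in novel.iterrows():
        stim = ev["stimulus_id"]
        if stim not in label_of:
            continue
        idx = window_volume_indices(float(ev["onset"]), vs.tr, window)
        if idx[-1] >= vs.n_volumes:
            warnings.warn(
                f"trial {stim}: peak window exceeds run end, trial dropped",
                stacklevel=2,
            )
            continue
        vols = flat[:, idx]
        lab = label_of[stim] == REMEMBERED
        if aggregation == "average":
            rows.append(vols.mean(axis=1))
            ys.append(lab)
            stims.append(stim)
        else:
            for j in range(vols.shape[1]):
                rows.append(vols[:, j])
                ys.append(lab)
                stims.append(stim)
    n = len(rows)
    return SampleSet(
        X=np.asarray(rows, dtype=np.float64).reshape(n, len(voxel_index)),
        y=np.asarray(ys, dtype=bool),
        runs=np.full(n, vs.run_index, dtype=int),
        subjects=np.array([vs.subject_id] * n),
        stimulus_ids=np.asarray(stims),
        voxel_index=voxel_index,
        grid_shape=vs.grid_shape,
        affine=vs.affine,
    )


def counterbalance(samples: SampleSet, rng_seed: int) -> SampleSet:
    """Equalize class counts within each run by down-sampling the majority.

    Runs containing a single class cannot contribute balanced data and are
    excluded with a warning.
    """
    rng = np.random.default_rng(rng_seed)
    keep: list[int] = []
    for sub in np.unique(samples.subjects):
        for run in np.unique(samples.runs[samples.subjects == sub]):
            rows = np.flatnonzero((samples.runs == run) & (samples.subjects == sub))
            pos = rows[samples.y[rows]]
            neg = rows[~samples.y[rows]]
            if len(pos) == 0 or len(neg) == 0:
                warnings.warn(
                    f"subject {sub} run {run}: only one class present, run excluded",
                    stacklevel=2,
                )
                continue
            m = min(len(pos), len(neg))
            keep.extend(rng.choice(pos, size=m, replace=False))
            keep.extend(rng.choice(neg, size=m, replace=False))
    return samples.subset(np.sort(np.asarray(keep, dtype=int)))
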
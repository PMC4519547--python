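"""Synthetic 4D BOLD generation with class-dependent multivoxel patterns.

The simulator reproduces the statistical structure the decoding analysis
assumes rather than scanner physics: inside each designated informative
region, to-be-remembered and to-be-forgotten novel trials evoke two distinct
but trial-stable spatial activation patterns, convolved with a canonical
double-gamma hemodynamic response; everywhere, voxel time series carry
AR(1) noise, slow drift and a constant baseline. Default geometry follows
the emulated acquisition: TR = 2 s, 64x64x32 grid of 3x3x5 mm voxels, runs
of 241/241/266 volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal, stats

from . import paradigm
from ._rng import substream
from .paradigm import NOVEL, RunDesign, SubjectDesign

REMEMBERED = "remembered"
FORGOTTEN = "forgotten"
LABELS = (REMEMBERED, FORGOTTEN)

#: neural event: picture presentation through the response window
NEURAL_DUR = paradigm.PICTURE_DUR + paradigm.RESPONSE_DUR

#: voxel size of the emulated acquisition, mm
DEFAULT_AFFINE = np.diag([3.0, 3.0, 5.0, 1.0])

#: mean proportion of associations later recognized, per encoding condition
DEFAULT_P_REMEMBER = {"FM": 0.3528, "EE": 0.4367}


@dataclass
class VolumeSeries:
    """One run's 4D BOLD grid plus acquisition metadata."""

    data: np.ndarray  # (nx, ny, nz, nt)
    tr: float
    affine: np.ndarray
    run_index: int
    subject_id: str

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def frame_times(self) -> np.ndarray:
        """Acquisition time of each volume (volume 0 at t=0)."""
        return np.arange(self.n_volumes) * self.tr

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(
        cls, path: str | Path, tr: float, run_index: int = 0, subject_id: str = ""
    ) -> "VolumeSeries":
        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.get_fdata(), dtype=np.float64),
            tr=tr,
            affine=np.asarray(img.affine),
            run_index=run_index,
            subject_id=subject_id,
        )


@dataclass
class SimulationConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    tr: float = paradigm.DEFAULT_TR
    informative_regions: dict[str, np.ndarray] = field(default_factory=dict)
    effect_size: float = 1.0
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 0.5
    baseline_mean: float = 100.0
    p_remember: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.p_remember is not None and not 0 <= self.p_remember <= 1:
            raise ValueError("p_remember must lie in [0, 1]")
        for name, mask in self.informative_regions.items():
            if tuple(mask.shape) != tuple(self.grid_shape):
                raise ValueError(
                    f"region {name!r} mask shape {mask.shape} does not match "
                    f"grid {self.grid_shape}"
                )


@dataclass
class SubjectData:
    """Everything the simulator knows about one synthetic subject."""

    subject_id: str
    condition: str
    design: SubjectDesign
    runs: list[VolumeSeries]
    events: list[pd.DataFrame]
    truth: pd.DataFrame  # stimulus_id, true_label over the 62 novel trials
    config: SimulationConfig


_HRF_NORM: float | None = None


def _double_gamma(t: np.ndarray) -> np.ndarray:
    # canonical shape: peak gamma(6,1), undershoot gamma(16,1)/6
    return stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0


def hrf(t) -> np.ndarray | float:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    Peaks near 5 s after the neural event with a late undershoot; zero at
    onset and decaying to zero by ~30 s.
    """
    global _HRF_NORM
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("hrf is defined for t >= 0")
    if _HRF_NORM is None:
        grid = np.arange(0.0, 30.0, 0.001)
        _HRF_NORM = float(_double_gamma(grid).max())
    out = _double_gamma(t_arr) / _HRF_NORM
    return float(out) if np.isscalar(t) else out


_EVENT_RESPONSE_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _event_response(duration: float = NEURAL_DUR) -> tuple[np.ndarray, np.ndarray]:
    """Peak-normalized response to one boxcar neural event, on a fine grid."""
    if duration not in _EVENT_RESPONSE_CACHE:
        dt = 0.05
        t = np.arange(0.0, 40.0, dt)
        box = (t < duration).astype(float)
        resp = np.convolve(box, _double_gamma(t))[: len(t)] * dt
        resp /= resp.max()
        _EVENT_RESPONSE_CACHE[duration] = (t, resp)
    return _EVENT_RESPONSE_CACHE[duration]


def class_regressors(run_design: RunDesign, truth: pd.DataFrame, tr: float) -> dict:
    """Expected response time course of each label class over a run's volumes.

    Each novel-target trial contributes a unit-peak hemodynamic response
    starting at its picture onset; responses are summed per class and
    sampled at the volume acquisition times.
    """
    label_of = dict(zip(truth["stimulus_id"], truth["true_label"]))
    n_vol = run_design.n_volumes(tr)
    times = np.arange(n_vol) * tr
    grid_t, resp = _event_response()
    out = {lab: np.zeros(n_vol) for lab in LABELS}
    for ev in run_design.events:
        if ev.trial_type != NOVEL:
            continue
        lab = label_of[ev.stimulus_id]
        rel = times - ev.stimulus_onset
        valid = (rel >= 0) & (rel <= grid_t[-1])
        out[lab][valid] += np.interp(rel[valid], grid_t, resp)
    return out


def _ar1_noise(
    rng: np.random.Generator, n_vox: int, n_t: int, sd: float, coef: float
) -> np.ndarray:
    innov = rng.standard_normal((n_vox, n_t)) * sd
    if coef == 0:
        return innov
    # stationary start: y[-1] drawn from the marginal AR(1) distribution
    y_prev = rng.standard_normal(n_vox) * sd / np.sqrt(1.0 - coef**2)
    zi = (coef * y_prev)[:, None]
    out, _ = signal.lfilter([1.0], [1.0, -coef], innov, axis=1, zi=zi)
    return out


def _drift(
    rng: np.random.Generator, n_vox: int, n_t: int, amplitude: float
) -> np.ndarray:
    if amplitude == 0:
        return np.zeros((n_vox, n_t))
    t = np.linspace(-0.5, 0.5, n_t)
    lin = rng.uniform(-1, 1, n_vox)[:, None] * t[None, :]
    cos = rng.uniform(-1, 1, n_vox)[:, None] * np.cos(np.pi * (t + 0.5))[None, :]
    return amplitude * (lin + cos)


def draw_patterns(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[tuple[str, str], np.ndarray]:
    """One fixed spatial pattern per (region, class), standard-normal per voxel."""
    patterns = {}
    for name, mask in config.informative_regions.items():
        n = int(np.count_nonzero(mask))
        for lab in LABELS:
            patterns[(name, lab)] = rng.standard_normal(n)
    return patterns


def _flat_indices(mask: np.ndarray) -> np.ndarray:
    # x-fastest scan order, matching the voxel_index convention downstream
    return np.flatnonzero(mask.ravel(order="F"))


def simulate_run(
    run_design: RunDesign,
    truth: pd.DataFrame,
    config: SimulationConfig,
    patterns: dict[tuple[str, str], np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "sub-00",
) -> VolumeSeries:
    """Generate one run: class patterns in informative regions + AR(1) noise + drift."""
    nx, ny, nz = config.grid_shape
    n_vox = nx * ny * nz
    n_t = run_design.n_volumes(config.tr)
    if rng is None:
        rng = substream(config.seed, f"noise-run{run_design.run_index}")
    if patterns is None:
        patterns = draw_patterns(config, substream(config.seed, "patterns"))

    flat = _ar1_noise(rng, n_vox, n_t, config.noise_sd, config.ar1_coef)
    flat += _drift(rng, n_vox, n_t, config.drift_amplitude)
    flat += config.baseline_mean

    if config.effect_size > 0 and config.informative_regions:
        regressors = class_regressors(run_design, truth, config.tr)
        amp = config.effect_size * config.noise_sd
        for name, mask in config.informative_regions.items():
            idx = _flat_indices(mask)
            for lab in LABELS:
                flat[idx] += amp * np.outer(patterns[(name, lab)], regressors[lab])

    data = np.transpose(flat.reshape((nz, ny, nx, n_t)), (2, 1, 0, 3))
    return VolumeSeries(
        data=data.astype(np.float32),
        tr=config.tr,
        affine=DEFAULT_AFFINE.copy(),
        run_index=run_design.run_index,
        subject_id=subject_id,
    )


def draw_truth(
    design: SubjectDesign, p_remember: float, rng: np.random.Generator
) -> pd.DataFrame:
    """I.i.d. Bernoulli subsequent-memory outcome for every novel trial."""
    novel_ids = [e.stimulus_id for e in design.events if e.trial_type == NOVEL]
    remembered = rng.random(len(novel_ids)) < p_remember
    return pd.DataFrame(
        {
            "stimulus_id": novel_ids,
            "true_label": np.where(remembered, REMEMBERED, FORGOTTEN),
        }
    )


def simulate_subject(
    condition: str,
    config: SimulationConfig,
    subject_id: str = "sub-01",
    patterns: dict[tuple[str, str], np.ndarray] | None = None,
) -> SubjectData:
    """Design, memory outcomes, and 3 BOLD runs for one synthetic subject.

    ``patterns`` lets a cohort simulator share the class patterns across
    subjects (emulating a common normalized space, which cross-subject
    decoding requires); by default each subject draws its own.
    """
    design = paradigm.make_subject_design(condition, config.seed)
    p = config.p_remember
    if p is None:
        p = DEFAULT_P_REMEMBER[condition]
    truth = draw_truth(design, p, substream(config.seed, "labels"))
    if patterns is None:
        patterns = draw_patterns(config, substream(config.seed, "patterns"))
    runs = [
        simulate_run(
            rd,
            truth,
            config,
            patterns=patterns,
            rng=substream(config.seed, f"noise-run{rd.run_index}"),
            subject_id=subject_id,
        )
        for rd in design.runs
    ]
    return SubjectData(
        subject_id=subject_id,
        condition=condition,
        design=design,
        runs=runs,
        events=paradigm.design_to_events_table(design),
        truth=truth,
        config=config,
    )


def write_subject(subject: SubjectData, out_dir: str | Path) -> Path:
    """Write the BIDS-like layout: func/run-*_bold.nii.gz, events, truth, config."""
    import json

    sub_dir = Path(out_dir) / subject.subject_id
    func = sub_dir / "func"
    func.mkdir(parents=True, exist_ok=True)
    for vs, ev in zip(subject.runs, subject.events):
        nib.save(vs.to_nifti(), func / f"run-{vs.run_index + 1}_bold.nii.gz")
        paradigm.write_events_table(ev, func / f"run-{vs.run_index + 1}_events.tsv")
    subject.truth.to_csv(sub_dir / "truth.tsv", sep="\t", index=False)
    cfg = {
        "condition": subject.condition,
        "grid_shape": list(subject.config.grid_shape),
        "tr": subject.config.tr,
        "effect_size": subject.config.effect_size,
        "noise_sd": subject.config.noise_sd,
        "ar1_coef": subject.config.ar1_coef,
        "drift_amplitude": subject.config.drift_amplitude,
        "baseline_mean": subject.config.baseline_mean,
        "p_remember": subject.config.p_remember,
        "seed": subject.config.seed,
        "informative_regions": sorted(subject.config.informative_regions),
    }
    (sub_dir / "config.json").write_text(json.dumps(cfg, indent=2))
    return sub_dir
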
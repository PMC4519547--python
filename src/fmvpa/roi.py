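"""Region-restricted decoding.

The whole-brain pipeline is re-run on voxels inside a binary mask (e.g.
hippocampus, anterior temporal lobe, putamen analogues) using the same
folds, seed and feature-selection rule, so regional accuracies are directly
comparable. Masks come from NIfTI files or from the geometric helpers below
(synthetic brains have no anatomy). When a region holds fewer than k voxels
the selection is clamped to the region size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .decode import DEFAULT_C, DEFAULT_K, DecodingResult, FoldPlan, cross_validate
from .preprocess import SampleSet


@dataclass
class Mask:
    data: np.ndarray  # 3D bool
    name: str
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3D grid")
        if not self.data.any():
            raise ValueError(f"mask {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def from_nifti(cls, path: str | Path, name: str | None = None) -> "Mask":
        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.get_fdata()) != 0,
            name=name or Path(path).stem,
            affine=np.asarray(img.affine),
        )


def sphere_mask(
    grid_shape: tuple[int, int, int],
    center: tuple[int, int, int],
    radius: float,
    name: str = "sphere",
    affine: np.ndarray | None = None,
) -> Mask:
    """Ball of the given voxel-index radius around ``center``."""
    x, y, z = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return Mask(
        data=d2 <= radius**2,
        name=name,
        affine=np.eye(4) if affine is None else affine,
    )


def box_mask(
    grid_shape: tuple[int, int, int],
    lo: tuple[int, int, int],
    hi: tuple[int, int, int],
    name: str = "box",
    affine: np.ndarray | None = None,
) -> Mask:
    """Axis-aligned box with inclusive corners ``lo`` and ``hi``."""
    data = np.zeros(grid_shape, dtype=bool)
    data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    return Mask(data=data, name=name, affine=np.eye(4) if affine is None else affine)


def apply_mask(samples: SampleSet, mask: Mask) -> SampleSet:
    """Restrict a sample set to the voxels inside the mask, order preserved."""
    if tuple(mask.data.shape) != tuple(samples.grid_shape):
        raise ValueError(
            f"mask grid {mask.data.shape} does not match sample grid "
            f"{samples.grid_shape}"
        )
    vi = np.asarray(samples.voxel_index)
    inside = mask.data[vi[:, 0], vi[:, 1], vi[:, 2]]
    if not inside.any():
        raise ValueError(f"mask {mask.name!r} shares no voxels with the sample set")
    return samples.restrict_features(np.flatnonzero(inside))


def roi_battery(
    samples: SampleSet,
    masks: list[Mask],
    plan: FoldPlan,
    k: int | None = DEFAULT_K,
    C: float = DEFAULT_C,
    include_whole_brain: bool = True,
) -> dict[str, DecodingResult]:
    """Decode within each region (plus whole brain) under identical folds."""
    if not masks and not include_whole_brain:
        raise ValueError("no regions to analyse")
    results: dict[str, DecodingResult] = {}
    if include_whole_brain:
        results["whole_brain"] = cross_validate(samples, plan, k=k, C=C)
    for mask in masks:
        restricted = apply_mask(samples, mask)
        k_eff = None if k is None else min(k, restricted.n_features)
        results[mask.name] = cross_validate(restricted, plan, k=k_eff, C=C)
    return results


def battery_table(results: dict[str, DecodingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": list(results),
            "scheme": [r.scheme for r in results.values()],
            "mean_accuracy": [r.mean_accuracy for r in results.values()],
            "n_features_k": [r.feature_k for r in results.values()],
        }
    )
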
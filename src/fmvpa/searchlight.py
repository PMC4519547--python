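"""Spherical-searchlight information mapping.

A ball of integer-lattice offsets (radius in voxel-index units; radius 4
holds 257 voxels) is centered on every in-mask voxel, the sample features
are projected onto the (edge-clipped) neighborhood, and the same linear-SVM
cross-validation as the whole-brain analysis is run — without ANOVA top-k
selection, since the projection is the selection. Each center records its
mean cross-validated accuracy; centers are thresholded with a one-sided
binomial test of the pooled correct count against chance 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .decode import DEFAULT_C, FoldPlan, fit_linear_classifier
from .preprocess import SampleSet


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets with Euclidean norm <= radius, lexicographic order."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius))
    offsets = [
        (i, j, k)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        for k in range(-r, r + 1)
        if i * i + j * j + k * k <= radius * radius
    ]
    return np.array(offsets, dtype=int)


def sphere_offsets_mm(
    radius_mm: float, voxel_size_mm: tuple[float, float, float]
) -> np.ndarray:
    """Offsets within a physical-distance ball, for anisotropic voxels.

    Non-default alternative to :func:`sphere_offsets`: the neighborhood is a
    true sphere in millimetres rather than in voxel-index units.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    vs = np.asarray(voxel_size_mm, dtype=float)
    if np.any(vs <= 0):
        raise ValueError("voxel sizes must be positive")
    r = np.floor(radius_mm / vs).astype(int)
    offsets = [
        (i, j, k)
        for i in range(-r[0], r[0] + 1)
        for j in range(-r[1], r[1] + 1)
        for k in range(-r[2], r[2] + 1)
        if (i * vs[0]) ** 2 + (j * vs[1]) ** 2 + (k * vs[2]) ** 2 <= radius_mm**2
    ]
    return np.array(offsets, dtype=int)


@dataclass
class AccuracyMap:
    data: np.ndarray  # 3D float, NaN outside the analysis mask
    n_test_samples: int
    affine: np.ndarray
    threshold_alpha: float | None = None
    significant: np.ndarray | None = None  # 3D bool

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.data)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def significance_nifti(self) -> nib.Nifti1Image:
        if self.significant is None:
            raise ValueError("map has not been thresholded")
        return nib.Nifti1Image(self.significant.astype(np.uint8), self.affine)


def searchlight_map(
    samples: SampleSet,
    plan: FoldPlan,
    radius: float = 4.0,
    analysis_mask: np.ndarray | None = None,
    C: float = DEFAULT_C,
    voxel_size_mm: tuple[float, float, float] | None = None,
) -> AccuracyMap:
    """Mean cross-validated accuracy of the neighborhood classifier per center.

    The radius is in voxel-index units by default; pass ``voxel_size_mm`` to
    interpret it as a physical distance instead. Neighborhoods are clipped
    at the grid edge; a center is scored whenever at least 2 of its voxels
    carry data, and NaN otherwise. The result is independent of the order
    centers are visited.
    """
    if radius < 1:
        raise ValueError("searchlight radius must be >= 1")
    shape = samples.grid_shape
    if analysis_mask is None:
        analysis_mask = np.zeros(shape, dtype=bool)
        vi = samples.voxel_index
        analysis_mask[vi[:, 0], vi[:, 1], vi[:, 2]] = True
    if not analysis_mask.any():
        raise ValueError("analysis mask is empty")
    if tuple(analysis_mask.shape) != tuple(shape):
        raise ValueError("analysis mask does not match the sample grid")

    col_of = np.full(shape, -1, dtype=np.int64)
    vi = samples.voxel_index
    col_of[vi[:, 0], vi[:, 1], vi[:, 2]] = np.arange(samples.n_features)

    if voxel_size_mm is None:
        offsets = sphere_offsets(radius)
    else:
        offsets = sphere_offsets_mm(radius, voxel_size_mm)
    accuracy = np.full(shape, np.nan)
    n_test_total = 0
    # per-fold training labels fixed across centers; precompute index arrays
    folds = plan.folds
    X, y = samples.X, samples.y
    for center in np.argwhere(analysis_mask):
        pts = center[None, :] + offsets
        ok = np.all((pts >= 0) & (pts < np.array(shape)[None, :]), axis=1)
        cols = col_of[pts[ok, 0], pts[ok, 1], pts[ok, 2]]
        cols = cols[cols >= 0]
        if len(cols) < 2:
            continue
        fold_acc = []
        n_test = 0
        for train, test in folds:
            model = fit_linear_classifier(X[train], y[train], cols, C=C)
            pred = model.predict(X[test])
            fold_acc.append(float((pred == y[test]).mean()))
            n_test += len(test)
        accuracy[tuple(center)] = float(np.mean(fold_acc))
        n_test_total = n_test
    return AccuracyMap(
        data=accuracy, n_test_samples=n_test_total, affine=samples.affine
    )


def threshold_map(
    amap: AccuracyMap,
    n_test_samples: int | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> AccuracyMap:
    """Flag centers beating chance by a one-sided binomial test.

    Per center, the correct count (accuracy * n) is tested against
    Binomial(n, 0.5); ``fdr=True`` applies Benjamini-Hochberg control at
    ``alpha`` across the defined centers instead of the uncorrected cutoff.
    """
    n = amap.n_test_samples if n_test_samples is None else n_test_samples
    if n <= 0:
        raise ValueError("n_test_samples must be positive")
    defined = amap.defined()
    acc = amap.data[defined]
    correct = np.rint(acc * n).astype(int)
    p = stats.binom.sf(correct - 1, n, 0.5)  # P(X >= correct)
    if fdr:
        sig_flat = stats.false_discovery_control(p) < alpha
    else:
        sig_flat = p < alpha
    significant = np.zeros(amap.data.shape, dtype=bool)
    significant[defined] = sig_flat
    return AccuracyMap(
        data=amap.data,
        n_test_samples=n,
        affine=amap.affine,
        threshold_alpha=alpha,
        significant=significant,
    )


def report_peaks(amap: AccuracyMap, min_cluster_size: int = 1) -> pd.DataFrame:
    """Clusters (6-connectivity) of significant centers with world-space peaks.

    One row per cluster — size, peak accuracy, peak coordinates in mm via
    the affine — sorted by peak accuracy descending.
    """
    if amap.significant is None:
        raise ValueError("threshold the map before reporting peaks")
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    labeled, n_clusters = ndimage.label(amap.significant, structure=structure)
    rows = []
    for c in range(1, n_clusters + 1):
        in_cluster = labeled == c
        size = int(in_cluster.sum())
        if size < min_cluster_size:
            continue
        vals = np.where(in_cluster, amap.data, -np.inf)
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        world = amap.affine @ np.array([*peak, 1.0])
        rows.append(
            {
                "cluster": c,
                "size": size,
                "peak_accuracy": float(amap.data[peak]),
                "x_mm": float(world[0]),
                "y_mm": float(world[1]),
                "z_mm": float(world[2]),
            }
        )
    df = pd.DataFrame(
        rows, columns=["cluster", "size", "peak_accuracy", "x_mm", "y_mm", "z_mm"]
    )
    return df.sort_values("peak_accuracy", ascending=False).reset_index(drop=True)
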
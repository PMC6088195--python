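"""Collapse voxel time series within a region into one representative series.

The representative is a correlation-strength-weighted average: voxels that
correlate strongly with the rest of the region dominate, so the output
tracks the coherent regional signal rather than noisy outlying voxels.
Weights derive from the pairwise Pearson correlation matrix: each voxel's
strength is the sum of its correlations to the other voxels (self
excluded), floored at zero and normalized to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import WindowPlan

__all__ = ["VoxelBlock", "RoiWeights", "roi_representative",
           "roi_representative_windowed", "read_voxel_block_text",
           "read_voxel_block_hdf5", "write_voxel_block_hdf5"]


@dataclass
class VoxelBlock:
    """n_voxels x n_samples block of voxel series from one region."""

    data: np.ndarray
    fs: float
    roi_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 samples per voxel")
        if np.any(self.data.std(axis=1) == 0):
            raise ValueError("constant (zero-variance) voxel rows are not allowed: "
                             "correlation is undefined")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]


@dataclass
class RoiWeights:
    """Per-voxel aggregation weights and their provenance."""

    w: np.ndarray          # nonnegative, sums to 1
    strengths: np.ndarray  # raw correlation-sum per voxel (self excluded)
    corr: np.ndarray       # voxel x voxel Pearson correlation matrix


def _weights_from(data: np.ndarray) -> RoiWeights:
    nv = data.shape[0]
    if nv == 1:
        return RoiWeights(w=np.ones(1), strengths=np.ones(1), corr=np.ones((1, 1)))
    corr = np.corrcoef(data)
    strengths = corr.sum(axis=1) - 1.0  # exclude the self-correlation
    floored = strengths.copy()
    if (floored < 0).any():
        warnings.warn("negative voxel strengths floored at 0 before normalization")
        floored = np.clip(floored, 0.0, None)
    total = floored.sum()
    if total <= 0:
        raise ValueError("total voxel strength is non-positive; the region has "
                         "no coherent signal to weight toward")
    return RoiWeights(w=floored / total, strengths=strengths, corr=corr)


def roi_representative(
    block: VoxelBlock,
    normalize: str = "none",
) -> tuple[np.ndarray, RoiWeights]:
    """Weighted-average representative series for one region.

    ``normalize="variance"`` scales each voxel row to unit variance before
    the weighted sum (making the output invariant to a common positive
    rescaling of the rows); the default uses the raw rows, so a single
    voxel passes through unchanged.
    """
    if normalize not in ("none", "variance"):
        raise ValueError("normalize must be 'none' or 'variance'")
    weights = _weights_from(block.data)
    rows = block.data
    if normalize == "variance":
        rows = rows / rows.std(axis=1, keepdims=True)
    series = weights.w @ rows
    return series, weights


def roi_representative_windowed(
    block: VoxelBlock,
    plan: WindowPlan,
    normalize: str = "none",
) -> tuple[np.ndarray, np.ndarray]:
    """Recompute the representative independently within each window.

    Returns ``(segments, weights)`` with shapes (n_windows, width) and
    (n_windows, n_voxels).  Tracking the weights per window lets the
    representative follow a mid-recording change in which voxel dominates.
    """
    if plan.starts[-1] + plan.width > block.data.shape[1]:
        raise ValueError("window plan exceeds the block length")
    segs = np.empty((plan.n_windows, plan.width))
    ws = np.empty((plan.n_windows, block.n_voxels))
    for wi, start in enumerate(plan.starts):
        sub = VoxelBlock(block.data[:, start:start + plan.width], fs=block.fs,
                         roi_label=block.roi_label)
        series, weights = roi_representative(sub, normalize=normalize)
        segs[wi] = series
        ws[wi] = weights.w
    return segs, ws


# ---------------------------------------------------------------------------
# voxel block I/O
# ---------------------------------------------------------------------------

def read_voxel_block_text(path, fs: float, roi_label: str = "") -> VoxelBlock:
    """Delimited-text matrix (voxels x samples) -> :class:`VoxelBlock`."""
    data = np.loadtxt(path, delimiter="\t")
    return VoxelBlock(np.atleast_2d(data), fs=fs, roi_label=roi_label)


def _voxel_group(subject: int, roi_label: str) -> str:
    return f"sub-{subject:03d}/voxels/roi-{roi_label}"


def write_voxel_block_hdf5(path, block: VoxelBlock, subject: int) -> None:
    import h5py

    with h5py.File(path, "a") as f:
        name = _voxel_group(subject, block.roi_label)
        if name in f:
            del f[name]
        d = f.create_dataset(name, data=block.data, track_times=False)
        d.attrs["fs"] = block.fs


def read_voxel_block_hdf5(path, subject: int, roi_label: str) -> VoxelBlock:
    import h5py

    with h5py.File(path, "r") as f:
        d = f[_voxel_group(subject, roi_label)]
        return VoxelBlock(d[()], fs=float(d.attrs["fs"]), roi_label=roi_label)
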
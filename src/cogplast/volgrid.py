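"""Volumetric data model and shared primitives.

The pipeline operates on 3D scalar maps (centrality, diffusion indices,
percentage-change images) and 4D resting-state-like timeseries.  Volumes are
carried as :class:`VolumeGrid` / :class:`Timeseries4D` objects that wrap a
numpy array together with the voxel geometry; NIfTI-1 is the on-disk format
throughout, read and written with :mod:`nibabel`.

Missing voxels (e.g. a percentage change with a near-zero baseline) propagate
as NaN and are excluded from every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "Mask",
    "Timeseries4D",
    "ChangeMap",
    "DimensionalityError",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "percentage_change",
    "residualize",
    "extract_cluster_mean",
]


class VolumeFormatError(ValueError):
    """Raised when a file is not a readable NIfTI-1 volume."""


class DimensionalityError(ValueError):
    """Raised when an image has the wrong number of dimensions."""


def _default_affine(voxel_size: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        One scalar per voxel, in modality units.  NaN marks missing voxels.
    voxel_size : 3-sequence of float
        Edge lengths in mm, strictly positive.
    affine : ndarray (4, 4), optional
        Voxel-to-world transform.  Defaults to a diagonal scaling by
        ``voxel_size``.  Indexing is 0-based (x, y, z); no reorientation is
        ever applied.
    """

    values: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise DimensionalityError(
                f"VolumeGrid requires a 3D array, got {self.values.ndim}D"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class Mask:
    """Boolean voxel membership for an analysis region."""

    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.ndim != 3:
            raise DimensionalityError("Mask requires a 3D boolean array")
        if self.n_voxels < 1:
            raise ValueError("mask must contain at least one voxel")

    @property
    def shape(self) -> tuple:
        return self.membership.shape

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    def check_compatible(self, grid) -> None:
        if tuple(self.shape) != tuple(grid.shape)[:3]:
            raise ValueError(f"mask shape {self.shape} != volume shape {tuple(grid.shape)}")


@dataclass
class Timeseries4D:
    """A 4D (x, y, z, t) signal array, e.g. a resting-state BOLD run."""

    values: np.ndarray
    frame_interval: float = 1.0  # TR, seconds
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise DimensionalityError("Timeseries4D requires a 4D array")
        if self.values.shape[3] < 8:
            raise ValueError("temporal length must be >= 8 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval (TR) must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def zero_variance_voxels(self, mask: Mask) -> np.ndarray:
        """Indices (N, 3) of masked voxels whose series is constant."""
        mask.check_compatible(self)
        data = self.values[mask.membership]
        flat = np.flatnonzero(np.ptp(data, axis=1) == 0)
        coords = np.argwhere(mask.membership)
        return coords[flat]


@dataclass
class ChangeMap(VolumeGrid):
    """A pre-to-post change image (percentage or residualized change)."""

    kind: str = "percentage_change"
    source_modality: str = "EC"
    n_missing: int = 0

    _KINDS = ("percentage_change", "residualized_change")

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_nifti(path):
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    return img, data


def read_volume(path) -> VolumeGrid:
    """Read a 3D NIfTI-1 image into a :class:`VolumeGrid`."""
    img, data = _load_nifti(path)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise DimensionalityError(f"{path!r} is {data.ndim}D; expected a 3D volume")
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(values=data.astype(np.float64), voxel_size=zooms, affine=img.affine)


def write_volume(grid: VolumeGrid, path, dtype=np.float32) -> None:
    """Write a :class:`VolumeGrid` as NIfTI-1 (float32 by default)."""
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=dtype), grid.affine)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


def read_timeseries(path) -> Timeseries4D:
    """Read a 4D NIfTI-1 image into a :class:`Timeseries4D`."""
    img, data = _load_nifti(path)
    if data.ndim != 4:
        raise DimensionalityError(f"{path!r} is {data.ndim}D; expected a 4D timeseries")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Timeseries4D(values=data.astype(np.float64), frame_interval=tr,
                        voxel_size=zooms[:3], affine=img.affine)


def write_timeseries(ts: Timeseries4D, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(ts.values, dtype=dtype), ts.affine)
    img.header.set_zooms(tuple(ts.voxel_size) + (ts.frame_interval,))
    nib.save(img, str(path))


def read_mask(path) -> Mask:
    """Read a {0,1}-valued NIfTI into a :class:`Mask`."""
    grid = read_volume(path)
    vals = grid.values
    if not np.all(np.isin(vals[np.isfinite(vals)], (0.0, 1.0))):
        raise VolumeFormatError(f"{path!r} is not a binary mask")
    return Mask(membership=vals > 0.5)


def write_mask(mask: Mask, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    write_volume(VolumeGrid(mask.membership.astype(np.float64), voxel_size), path,
                 dtype=np.uint8)


# ---------------------------------------------------------------------------
# Change-map and residualization primitives
# ---------------------------------------------------------------------------

def percentage_change(pre: VolumeGrid, post: VolumeGrid, mask: Mask,
                      eps: float = 1e-6, source_modality: str = "EC") -> ChangeMap:
    """Voxel-wise percentage change image, 100 * (post - pre) / pre.

    Masked voxels whose baseline magnitude is <= ``eps`` are set to NaN
    (missing) and counted in ``n_missing``; voxels outside the mask are NaN.
    """
    if tuple(pre.shape) != tuple(post.shape):
        raise ValueError(f"pre shape {pre.shape} != post shape {post.shape}")
    mask.check_compatible(pre)
    m = mask.membership
    out = np.full(pre.shape, np.nan)
    valid = m & (np.abs(pre.values) > eps)
    degenerate = m & ~valid
    if not valid.any():
        raise ValueError("all masked voxels have baseline magnitude <= eps")
    out[valid] = 100.0 * (post.values[valid] - pre.values[valid]) / pre.values[valid]
    return ChangeMap(values=out, voxel_size=pre.voxel_size, affine=pre.affine,
                     kind="percentage_change", source_modality=source_modality,
                     n_missing=int(degenerate.sum()))


def residualize(y, covariates=None, add_intercept: bool = True) -> np.ndarray:
    """Least-squares residuals of ``y`` on ``[intercept | covariates]``.

    Used to produce residualized change scores: regressing a change score on
    its baseline removes baseline-associated variance before group inference
    or mediation.  With no covariates and an intercept this is centering.

    Raises if the design is rank deficient, naming the collinear columns.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    cols = []
    names = []
    if add_intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    if covariates is not None:
        X = np.asarray(covariates, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError(f"covariates have {X.shape[0]} rows, y has {n}")
        for j in range(X.shape[1]):
            cols.append(X[:, j])
            names.append(f"covariate_{j}")
    if not cols:
        return y.copy()
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[min(j, R.shape[0] - 1), j]) < 1e-10]
        raise ValueError(f"design is rank deficient (rank {rank} < {X.shape[1]}); "
                         f"collinear columns: {bad or names}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def extract_cluster_mean(grid: VolumeGrid, cluster: Mask) -> float:
    """Mean map value over a cluster, ignoring NaN (missing) voxels."""
    cluster.check_compatible(grid)
    vals = grid.values[cluster.membership]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("all cluster voxels are missing")
    return float(vals.mean())
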
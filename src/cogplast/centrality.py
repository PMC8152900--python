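"""Voxel-wise functional-connectivity centrality and seed-based correlation.

Eigenvector centrality (EC) ranks voxels by the dominant eigenvector of a
voxel-by-voxel similarity matrix built from the Pearson correlations of
their timeseries: a voxel is central when it correlates with many voxels
that are themselves central.  The similarity transform A = (r + 1) / 2 makes
the matrix strictly positive, so the dominant eigenvector is unique and
nonnegative (Perron-Frobenius), and power iteration converges without ever
materializing the N x N matrix: with Z the (N, T) row-standardized data,

    A v = ( Z (Z^T v) / (T - 1) + 1 * sum(v) ) / 2.

Degree centrality (DC) is the thresholded row sum of the correlation matrix,
computed blockwise to bound memory.  Seed-based correlation analysis (SBCA)
regresses each voxel on the mean seed timeseries and averages standardized
coefficient and Fisher-z maps across subjects; the group z map can then be
parcellated into clusters of voxels exceeding the within-mask mean by a
multiple of the within-mask SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volgrid import Mask, Timeseries4D, VolumeGrid

__all__ = [
    "CentralityMap",
    "SBCAResult",
    "eigenvector_centrality",
    "degree_centrality",
    "sbca",
    "parcellate_zmap",
    "Z_CAP",
]

Z_CAP = float(np.arctanh(1.0 - 1e-7))  # finite stand-in for r = +/-1


class ConvergenceError(RuntimeError):
    def __init__(self, iterations, delta, tol):
        super().__init__(
            f"power iteration did not converge in {iterations} iterations "
            f"(final delta {delta:.3e} > tol {tol:.3e})"
        )
        self.delta = delta


@dataclass
class CentralityMap(VolumeGrid):
    kind: str = "EC"
    iterations: int = 0
    final_delta: float = 0.0


@dataclass
class SBCAResult:
    beta_map: VolumeGrid      # mean standardized regression coefficients
    z_map: VolumeGrid         # mean Fisher-z correlation map
    capped_fraction: float    # fraction of voxel/subject r at the z cap


def _standardized_data(ts: Timeseries4D, mask: Mask) -> np.ndarray:
    """(N, T) row-standardized masked timeseries; errors on zero variance."""
    mask.check_compatible(ts)
    if mask.n_voxels < 2:
        raise ValueError("need at least 2 masked voxels")
    data = ts.values[mask.membership]  # (N, T)
    sd = data.std(axis=1, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        coords = np.argwhere(mask.membership)[bad]
        raise ValueError(f"zero-variance timeseries at masked voxels {coords.tolist()[:10]}"
                         + ("..." if bad.size > 10 else ""))
    return (data - data.mean(axis=1, keepdims=True)) / sd[:, None]


def eigenvector_centrality(ts: Timeseries4D, mask: Mask, tol: float = 1e-6,
                           max_iter: int = 100) -> CentralityMap:
    """Fast eigenvector centrality over the masked voxels.

    Power iteration on the implicit similarity matrix A = (R + 1)/2 with R
    the Pearson correlation matrix.  Starts from a uniform vector,
    renormalizes to unit 2-norm each step, and stops when consecutive
    iterates differ by less than ``tol`` in 2-norm.  The returned map has
    unit Euclidean norm over the mask and zeros (NaN) outside.
    """
    Z = _standardized_data(ts, mask)
    n, t = Z.shape
    v = np.full(n, 1.0 / np.sqrt(n))
    delta = np.inf
    for it in range(1, max_iter + 1):
        w = (Z @ (Z.T @ v) / (t - 1) + v.sum()) / 2.0
        w /= np.linalg.norm(w)
        delta = np.linalg.norm(w - v)
        v = w
        if delta < tol:
            break
    else:
        raise ConvergenceError(max_iter, delta, tol)
    out = np.full(mask.shape, np.nan)
    out[mask.membership] = v
    return CentralityMap(values=out, voxel_size=ts.voxel_size, affine=ts.affine,
                         kind="EC", iterations=it, final_delta=float(delta))


def degree_centrality(ts: Timeseries4D, mask: Mask, tau: float = 0.0,
                      block_size: int = 512) -> CentralityMap:
    """Weighted degree centrality: DC_i = sum_{j != i} r_ij [r_ij > tau].

    The default tau = 0 keeps positive correlations only; tau = -1 gives the
    plain (signed) row sum.  Correlations are computed in voxel blocks so
    only a (block, N) slab is ever held.
    """
    Z = _standardized_data(ts, mask)
    n, t = Z.shape
    dc = np.empty(n)
    for lo in range(0, n, block_size):
        hi = min(lo + block_size, n)
        r = Z[lo:hi] @ Z.T / (t - 1)          # (block, N)
        np.clip(r, -1.0, 1.0, out=r)
        keep = r > tau
        rows = np.arange(lo, hi)
        keep[np.arange(hi - lo), rows] = False  # exclude self-correlation
        dc[lo:hi] = np.where(keep, r, 0.0).sum(axis=1)
    out = np.full(mask.shape, np.nan)
    out[mask.membership] = dc
    return CentralityMap(values=out, voxel_size=ts.voxel_size, affine=ts.affine, kind="DC")


def sbca(subjects: Sequence[Timeseries4D], seed_mask: Mask, mask: Mask) -> SBCAResult:
    """Seed-based correlation analysis averaged across subjects.

    Per subject, the seed timeseries is the spatial mean over ``seed_mask``;
    each masked voxel's series is regressed on it after standardizing both,
    so the standardized coefficient equals the Pearson correlation r, and
    the z map is atanh(r) capped at atanh(1 - 1e-7) for |r| -> 1.
    """
    if len(subjects) < 1:
        raise ValueError("need at least one subject")
    beta_acc = None
    z_acc = None
    capped = 0
    total = 0
    for ts in subjects:
        seed_mask.check_compatible(ts)
        seed = ts.values[seed_mask.membership].mean(axis=0)
        if seed.std() == 0:
            raise ValueError("zero-variance seed timeseries")
        s = (seed - seed.mean()) / seed.std()
        Z = _standardized_data(ts, mask)
        r = Z @ s / len(s)
        np.clip(r, -1.0, 1.0, out=r)
        z = np.arctanh(np.clip(r, -(1.0 - 1e-7), 1.0 - 1e-7))
        capped += int(np.sum(np.abs(z) >= Z_CAP - 1e-12))
        total += r.size
        beta_acc = r if beta_acc is None else beta_acc + r
        z_acc = z if z_acc is None else z_acc + z
    k = len(subjects)
    beta_map = np.full(mask.shape, np.nan)
    z_map = np.full(mask.shape, np.nan)
    beta_map[mask.membership] = beta_acc / k
    z_map[mask.membership] = z_acc / k
    vs, aff = subjects[0].voxel_size, subjects[0].affine
    return SBCAResult(beta_map=VolumeGrid(beta_map, vs, aff),
                      z_map=VolumeGrid(z_map, vs, aff),
                      capped_fraction=capped / total)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D neighborhood structuring element for 6/18/26-connectivity."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def parcellate_zmap(zmap: VolumeGrid, mask: Mask, k_sd: float = 2.0,
                    connectivity: int = 26, min_size: int = 1) -> np.ndarray:
    """Cluster voxels exceeding the within-mask mean z by ``k_sd`` SDs.

    Returns an integer label volume: 0 is background, labels 1.. are
    connected components of the suprathreshold set ordered by descending
    size; components smaller than ``min_size`` are dropped.  An empty
    suprathreshold set yields an all-zero labeling.
    """
    mask.check_compatible(zmap)
    vals = zmap.values[mask.membership]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite masked values")
    thr = vals.mean() + k_sd * vals.std(ddof=0)
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask.membership] = False
    with np.errstate(invalid="ignore"):
        supra = mask.membership & (zmap.values > thr)
    labels, n = ndimage.label(supra, structure=connectivity_structure(connectivity))
    if n == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_size) + 1
    order = keep[np.argsort(sizes[keep - 1])[::-1]]
    out = np.zeros(mask.shape, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out
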
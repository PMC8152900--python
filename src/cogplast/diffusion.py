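"""Diffusion-tensor estimation and scalar index maps (FA, MD, radial
diffusivity).

The single-tensor model predicts the diffusion-weighted signal as
S = S0 * exp(-b g^T D g) for a unit gradient direction g and b-value b.
Taking logs turns tensor estimation into ordinary least squares over the six
unique tensor elements; the scalar indices follow from the eigenvalues
(Pierpaoli/Basser lineage):

    MD = (l1 + l2 + l3) / 3
    RD = (l2 + l3) / 2
    FA = sqrt(3/2) * sqrt(sum (li - MD)^2) / sqrt(sum li^2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DWIProtocol",
    "TensorEigenvalues",
    "fit_tensor",
    "forward_signal",
    "fa",
    "md",
    "rad_diff",
    "read_bvals_bvecs",
]


@dataclass
class DWIProtocol:
    """Gradient table: unit direction and b-value per acquired volume."""

    bvecs: np.ndarray  # (n, 3), unit norm where b > 0
    bvals: np.ndarray  # (n,), s/mm^2

    def __post_init__(self) -> None:
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        self.bvals = np.asarray(self.bvals, dtype=np.float64)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError("bvecs must be (n, 3)")
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ValueError("bvals and bvecs length mismatch")
        dwi = self.bvals > 0
        if dwi.sum() < 6:
            raise ValueError("need >= 6 diffusion-weighted directions")
        if (~dwi).sum() < 1:
            raise ValueError("need >= 1 b=0 volume")
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("b>0 gradient directions must be unit vectors")
        if np.linalg.matrix_rank(_design_matrix(self)[dwi]) < 6:
            raise ValueError("gradient directions are rank deficient for tensor fitting")


@dataclass
class TensorEigenvalues:
    """Sorted (descending) diffusion-tensor eigenvalues per voxel, mm^2/s."""

    values: np.ndarray            # (..., 3), l1 >= l2 >= l3
    negative_flag: np.ndarray     # boolean per voxel: any eigenvalue < 0

    @property
    def clamped(self) -> np.ndarray:
        """Copy with negative eigenvalues clamped to 0."""
        return np.clip(self.values, 0.0, None)


def _design_matrix(protocol: DWIProtocol) -> np.ndarray:
    g = protocol.bvecs
    b = protocol.bvals
    # order: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    return -b[:, None] * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def forward_signal(D: np.ndarray, protocol: DWIProtocol, s0: float = 1.0) -> np.ndarray:
    """Noise-free single-tensor signal for a 3x3 SPD tensor ``D``."""
    X = _design_matrix(protocol)
    d6 = np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
    return s0 * np.exp(X @ d6)


def fit_tensor(signals: np.ndarray, protocol: DWIProtocol) -> TensorEigenvalues:
    """OLS tensor fit per voxel from DWI signals.

    ``signals`` has shape (..., n_volumes).  S0 is the mean of the b=0
    volumes; the fit solves log(S/S0) = -b g^T D g in least squares.  Voxels
    with any nonpositive signal are flagged and returned as NaN eigenvalues.
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.shape[-1] != len(protocol.bvals):
        raise ValueError("signal count does not match protocol length")
    lead = signals.shape[:-1]
    flat = signals.reshape(-1, signals.shape[-1])
    dwi = protocol.bvals > 0
    X = _design_matrix(protocol)[dwi]

    ok = np.all(flat > 0, axis=1)
    evals = np.full((flat.shape[0], 3), np.nan)
    neg = np.zeros(flat.shape[0], dtype=bool)
    if ok.any():
        s0 = flat[ok][:, ~dwi].mean(axis=1)
        y = np.log(flat[ok][:, dwi] / s0[:, None])
        d6, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (6, n_ok)
        d6 = d6.T
        tensors = np.empty((d6.shape[0], 3, 3))
        tensors[:, 0, 0] = d6[:, 0]
        tensors[:, 1, 1] = d6[:, 1]
        tensors[:, 2, 2] = d6[:, 2]
        tensors[:, 0, 1] = tensors[:, 1, 0] = d6[:, 3]
        tensors[:, 0, 2] = tensors[:, 2, 0] = d6[:, 4]
        tensors[:, 1, 2] = tensors[:, 2, 1] = d6[:, 5]
        w = np.linalg.eigvalsh(tensors)[:, ::-1]  # descending
        evals[ok] = w
        neg[ok] = np.any(w < 0, axis=1)
    return TensorEigenvalues(values=evals.reshape(lead + (3,)),
                             negative_flag=neg.reshape(lead))


def md(e: TensorEigenvalues) -> np.ndarray:
    """Mean diffusivity, (l1 + l2 + l3) / 3."""
    return e.values.mean(axis=-1)


def rad_diff(e: TensorEigenvalues) -> np.ndarray:
    """Radial diffusivity, (l2 + l3) / 2."""
    return (e.values[..., 1] + e.values[..., 2]) / 2.0


def fa(e: TensorEigenvalues) -> np.ndarray:
    """Fractional anisotropy in [0, 1]; all-zero tensors yield 0."""
    lam = e.values
    m = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - m) ** 2).sum(axis=-1))
    den = np.sqrt((lam ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(1.5) * num / den
    zero = den == 0
    if np.any(zero):
        import warnings

        warnings.warn("all-zero tensor: FA undefined, reported as 0", RuntimeWarning)
        out = np.where(zero, 0.0, out)
    return out


def read_bvals_bvecs(bval_path, bvec_path) -> DWIProtocol:
    """Read FSL-style plain-text bval/bvec files (bvecs as 3 rows)."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DWIProtocol(bvecs=bvecs, bvals=bvals)
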
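"""Diffusion tensor estimation and scalar metrics.

Tensors are fitted per voxel by linear least squares on the
log-signal, using only volumes with b <= max_b (default 1000 s/mm²,
i.e. the b = 2000 shell is excluded from the fit) plus the b = 0
volumes. Diffusivities are expressed in μm²/s throughout, matching the
convention of normative bundle tables; FA is dimensionless in [0, 1]
with a per-mille report option at the table layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ReferenceSpace, ScalarVolume

logger = logging.getLogger(__name__)

__all__ = ["TensorVolume", "fit_tensor", "tensor_metrics", "design_matrix"]

#: μm²/s -> mm²/s, so that b [s/mm²] · D is dimensionless
_UM2S_TO_MM2S = 1e-6

# upper-triangle component order
_COMP = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor (Dxx,Dxy,Dxz,Dyy,Dyz,Dzz in μm²/s)."""

    data: np.ndarray  # (X, Y, Z, 6)
    space: ReferenceSpace
    mask: np.ndarray  # (X, Y, Z) bool

    def __post_init__(self) -> None:
        if self.data.shape != tuple(self.space.shape) + (6,):
            raise ValueError("tensor data must be (X, Y, Z, 6) on the space grid")
        if self.mask.shape != tuple(self.space.shape):
            raise ValueError("mask shape mismatch")

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 tensors, shape (X, Y, Z, 3, 3)."""
        d = self.data
        m = np.empty(d.shape[:-1] + (3, 3))
        m[..., 0, 0] = d[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = d[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = d[..., 2]
        m[..., 1, 1] = d[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = d[..., 4]
        m[..., 2, 2] = d[..., 5]
        return m

    @classmethod
    def from_matrices(cls, m: np.ndarray, space: ReferenceSpace,
                      mask: np.ndarray | None = None) -> "TensorVolume":
        d = np.stack([m[..., 0, 0], m[..., 0, 1], m[..., 0, 2],
                      m[..., 1, 1], m[..., 1, 2], m[..., 2, 2]], axis=-1)
        if mask is None:
            mask = np.ones(space.shape, dtype=bool)
        return cls(data=d, space=space, mask=mask)


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear DTI design matrix: ln S = X · [ln S0, Dxx..Dzz·1e-6]."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    X = np.empty((b.size, 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -2.0 * b * g[:, 0] * g[:, 1]
    X[:, 3] = -2.0 * b * g[:, 0] * g[:, 2]
    X[:, 4] = -b * g[:, 1] ** 2
    X[:, 5] = -2.0 * b * g[:, 1] * g[:, 2]
    X[:, 6] = -b * g[:, 2] ** 2
    return X


def fit_tensor(dwi: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray,
               space: ReferenceSpace, mask: np.ndarray | None = None,
               max_b: float = 1000.0, b0_threshold: float = 50.0,
               weighted: bool = False) -> TensorVolume:
    """Fit diffusion tensors per voxel from a 4-D DWI series.

    Only volumes with b <= ``max_b`` enter the fit; higher shells are
    sliced away before any computation so they cannot influence the
    estimate. Requires >= 6 unique diffusion-weighted directions within
    the kept shells and >= 1 b ~ 0 volume. Non-positive signals are
    clamped to machine epsilon (count logged). ``weighted`` switches from
    ordinary to signal-weighted least squares.
    """
    dwi = np.asarray(dwi, dtype=float)
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != bvals.size:
        raise ValueError("dwi must be 4-D with one volume per b-value")
    keep = bvals <= max_b
    b_kept = bvals[keep]
    g_kept = bvecs[keep]
    is_b0 = b_kept <= b0_threshold
    dirs = np.unique(np.round(np.abs(g_kept[~is_b0]), 6), axis=0)
    if not np.any(is_b0):
        raise ValueError("need at least one b=0 volume")
    if len(dirs) < 6:
        raise ValueError(
            f"need >= 6 unique directions with 0 < b <= {max_b}, got {len(dirs)}"
        )
    if mask is None:
        mask = np.ones(space.shape, dtype=bool)
    sig = dwi[..., keep][mask]  # (nvox, m)
    n_bad = int((sig <= 0).sum())
    if n_bad:
        logger.warning("fit_tensor: clamped %d non-positive signal values", n_bad)
        sig = np.maximum(sig, np.finfo(float).eps)
    X = design_matrix(b_kept, g_kept)
    Y = np.log(sig).T  # (m, nvox)
    if weighted:
        W = sig.T  # classic WLS weights ~ signal
        XtW = X.T[None] * W.T[:, None, :]  # (nvox, 7, m)
        A = XtW @ X
        rhs = np.einsum("vpm,mv->vp", XtW, Y)
        coef = np.linalg.solve(A, rhs[..., None])[..., 0].T  # (7, nvox)
    else:
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    D = coef[1:].T / _UM2S_TO_MM2S  # (nvox, 6) in μm²/s
    data = np.zeros(tuple(space.shape) + (6,))
    data[mask] = D
    return TensorVolume(data=data, space=space, mask=mask)


def _fa_from_eigs(ev: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues (last axis)."""
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt((np.square(ev - mean)).sum(axis=-1))
    den = np.sqrt(np.square(ev).sum(axis=-1))
    fa = np.zeros(ev.shape[:-1])
    np.divide(num, den, out=fa, where=den > 0)
    return np.sqrt(1.5) * fa


def tensor_metrics(t: TensorVolume, clamp_negative: bool = True
                   ) -> dict[str, ScalarVolume]:
    """FA and axial/radial/mean diffusivity maps from a tensor volume.

    Eigenvalues are sorted non-increasing (λ1 >= λ2 >= λ3): axial = λ1,
    radial = (λ2 + λ3)/2, mean = trace/3, FA = sqrt(3/2)·‖λ − λ̄‖/‖λ‖.
    Negative eigenvalues are clamped to zero for the FA computation and
    the affected voxel count is logged; ADCs keep the raw values.
    """
    m = t.as_matrices()
    ev = np.linalg.eigvalsh(m)[..., ::-1]  # descending
    ev = np.where(t.mask[..., None], ev, 0.0)
    n_neg = int(np.any(ev < 0, axis=-1)[t.mask].sum())
    if n_neg and clamp_negative:
        logger.warning("tensor_metrics: %d voxels with negative eigenvalues "
                       "(clamped for FA)", n_neg)
    ev_fa = np.maximum(ev, 0.0) if clamp_negative else ev
    sp = t.space
    return {
        "fa": ScalarVolume(_fa_from_eigs(ev_fa), sp, units=""),
        "axial": ScalarVolume(ev[..., 0], sp, units="um^2/s"),
        "radial": ScalarVolume(0.5 * (ev[..., 1] + ev[..., 2]), sp, units="um^2/s"),
        "mean": ScalarVolume(ev.mean(axis=-1), sp, units="um^2/s"),
    }
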
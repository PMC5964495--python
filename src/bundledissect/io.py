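"""Tractogram (TCK/TRK) and NIfTI volume I/O via nibabel.

TCK is the canonical on-disk format (streamlines are world-mm native);
TRK is supported with explicit header-driven conversion to world mm.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping

import nibabel as nib
import numpy as np
from nibabel.streamlines import TckFile, TrkFile
from nibabel.streamlines.tractogram import Tractogram as NibTractogram

from .core import LabelVolume, ReferenceSpace, ScalarVolume, Tractogram

logger = logging.getLogger(__name__)

__all__ = [
    "read_tractogram",
    "write_tractogram",
    "read_volume",
    "write_volume",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]


def read_tractogram(path: str | os.PathLike, space: ReferenceSpace | None = None) -> Tractogram:
    """Read a TCK or TRK file into world-mm streamlines.

    nibabel returns streamlines in RAS+ world mm for both formats (TRK is
    converted from its voxel-order frame using the stored header affine,
    never silently assumed). ``space`` declares the reference grid for
    downstream voxel operations; for TRK it defaults to the header grid.
    """
    path = os.fspath(path)
    try:
        tf = nib.streamlines.load(path)
    except Exception as exc:  # nibabel raises several format-specific errors
        raise IOError(f"cannot read tractogram {path!r}: {exc}") from exc
    sls = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    if space is None:
        if isinstance(tf, TrkFile):
            hdr = tf.header
            space = ReferenceSpace(
                affine=np.asarray(hdr["voxel_to_rasmm"], dtype=float),
                shape=tuple(int(d) for d in hdr["dimensions"]),
            )
        else:
            space = ReferenceSpace(affine=np.eye(4), shape=(1, 1, 1))
    return Tractogram(sls, space)


def write_tractogram(t: Tractogram, path: str | os.PathLike) -> None:
    """Write a tractogram as TCK or TRK (decided by extension)."""
    path = os.fspath(path)
    nt = NibTractogram([np.asarray(s, dtype=np.float32) for s in t.streamlines],
                       affine_to_rasmm=np.eye(4))
    ext = os.path.splitext(path)[1].lower()
    if ext == ".tck":
        TckFile(nt).save(path)
    elif ext == ".trk":
        header = TrkFile.create_empty_header()
        header["voxel_to_rasmm"] = t.space.affine.astype(np.float32)
        header["dimensions"] = np.array(t.space.shape, dtype=np.int16)
        header["voxel_sizes"] = np.linalg.norm(t.space.affine[:3, :3], axis=0).astype(
            np.float32
        )
        header["voxel_order"] = b"RAS"
        TrkFile(nt, header).save(path)
    else:
        raise IOError(f"unknown tractogram format for {path!r} (use .tck or .trk)")


def read_volume(
    path: str | os.PathLike,
    names: Mapping[int, str] | None = None,
    units: str = "",
) -> ScalarVolume | LabelVolume:
    """Read a 3-D NIfTI volume.

    Integer-typed data with a provided ``names`` map yields a LabelVolume,
    anything else a ScalarVolume. 4-D input raises.
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    space = ReferenceSpace(affine=np.asarray(img.affine, dtype=float), shape=data.shape)
    if names is not None:
        return LabelVolume(grid=np.asarray(data).astype(np.int32), space=space, names=dict(names))
    return ScalarVolume(grid=np.asarray(data, dtype=float), space=space, units=units)


def read_dwi(path: str | os.PathLike) -> tuple[np.ndarray, ReferenceSpace]:
    """Read a 4-D DWI series; returns (data[x,y,z,volume], space)."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path!r}: expected 4-D DWI, got shape {data.shape}")
    space = ReferenceSpace(affine=np.asarray(img.affine, dtype=float), shape=data.shape[:3])
    return np.asarray(data, dtype=float), space


def write_volume(vol: ScalarVolume | LabelVolume | np.ndarray, path: str | os.PathLike,
                 space: ReferenceSpace | None = None) -> None:
    """Write a volume (or bare grid + space) to NIfTI."""
    if isinstance(vol, np.ndarray):
        if space is None:
            raise ValueError("a bare array needs an explicit space")
        grid, affine = vol, space.affine
    else:
        grid, affine = vol.grid, vol.space.affine
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    nib.save(nib.Nifti1Image(grid, affine), os.fspath(path))


def read_bvals_bvecs(bval_path: str | os.PathLike, bvec_path: str | os.PathLike
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style b-tables: one row of b-values; three rows of unit vectors."""
    bvals = np.loadtxt(os.fspath(bval_path)).ravel()
    bvecs = np.loadtxt(os.fspath(bvec_path))
    if bvecs.shape[0] != 3:
        bvecs = bvecs.T
    if bvecs.shape != (3, bvals.size):
        raise ValueError(
            f"bvec shape {bvecs.shape} incompatible with {bvals.size} b-values"
        )
    return bvals, bvecs.T  # (n,), (n, 3)


def write_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray,
                      bval_path: str | os.PathLike, bvec_path: str | os.PathLike) -> None:
    np.savetxt(os.fspath(bval_path), np.asarray(bvals)[None, :], fmt="%.1f")
    np.savetxt(os.fspath(bvec_path), np.asarray(bvecs).T, fmt="%.6f")
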
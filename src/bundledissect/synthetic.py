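"""Synthetic phantom cohort with known ground truth.

The phantom emulates the statistical structure of a VTA-connectivity
study: a trunk-and-fan bundle family that passes a 3 mm sphere at
(±6, −12, −8), runs through a common trunk, and fans out to eight thin
prefrontal parcel slabs with configurable proportions; plus ~20%
distractor streamlines (temporally projecting, and a small
anterior-commissure-like set crossing the midline). Scalar maps (FA,
axial/radial/mean diffusivity, compartment fractions) are derived from
a tensor field built from the bundle geometry itself, so every
downstream stage — selection, decomposition, density maps, tensor fit,
FACT tracking — can be validated against the generator's ground truth.

Streamline centerlines are cubic splines through a basal start, the VTA
sphere, a trunk waypoint and a parcel-specific approach/terminal pair,
sampled at ~1 mm arc steps (control points are kept as exact vertices).
Jitter is Gaussian with per-point standard deviation ``jitter_sd`` but
correlated along the streamline (smoothed white noise), because real
streamlines are locally smooth; i.i.d. point noise would make segment
directions unphysically jagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import LabelVolume, ReferenceSpace, ScalarVolume, Tractogram, default_space
from .density import resample_polyline
from .tensor import TensorVolume, tensor_metrics

__all__ = [
    "PhantomSpec",
    "trunk_tractogram",
    "GroundTruth",
    "PhantomSubject",
    "make_phantom_parcellation",
    "make_bundle",
    "make_cohort",
    "make_synthetic_dwi",
    "default_gradients",
    "tensor_field_from_tractogram",
    "homogeneous_tensor_field",
    "quarter_circle_field",
    "DEFAULT_PARCEL_FRACTIONS",
]

SPHERE_RIGHT = np.array([6.0, -12.0, -8.0])
SPHERE_LEFT = np.array([-6.0, -12.0, -8.0])

#: intended proportions of prefrontal streamlines per parcel (sum to 1)
DEFAULT_PARCEL_FRACTIONS = {
    "superiorfrontal": 0.38,
    "rostralmiddlefrontal": 0.35,
    "lateralorbitofrontal": 0.24,
    "medialorbitofrontal": 0.006,
    "parstriangularis": 0.006,
    "parsopercularis": 0.006,
    "parsorbitalis": 0.006,
    "caudalmiddlefrontal": 0.006,
}

# Parcel boxes in right-hemisphere world mm (x0,x1, y0,y1, z0,z1); left mirrors x.
# Six parcels are 1-voxel-thin coronal tiles on the y=58 plane, the two
# orbitofrontal parcels are 1-voxel-thin axial tiles on the z=1 plane, so
# the distal-20 mm terminal test has to matter.
_PARCEL_BOXES = {
    "superiorfrontal": (2, 16, 56.5, 59.5, 26, 58),
    "rostralmiddlefrontal": (17, 31, 56.5, 59.5, 26, 58),
    "caudalmiddlefrontal": (32, 46, 56.5, 59.5, 26, 58),
    "parsorbitalis": (2, 16, 56.5, 59.5, 2, 25),
    "parstriangularis": (17, 31, 56.5, 59.5, 2, 25),
    "parsopercularis": (32, 46, 56.5, 59.5, 2, 25),
    "medialorbitofrontal": (2, 16, 26, 52, -0.5, 2.5),
    "lateralorbitofrontal": (20, 40, 26, 52, -0.5, 2.5),
}
_TEMPORAL_BOX = (38, 64, -43, -11, -24, -10)

#: normal axis of each parcel slab (the approach direction of terminals)
_PARCEL_NORMAL = {name: (np.array([0.0, 1.0, 0.0]) if box[2] == 56.5
                         else np.array([0.0, 0.0, -1.0]))
                  for name, box in _PARCEL_BOXES.items()}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the phantom cohort."""

    space: ReferenceSpace = field(default_factory=default_space)
    parcel_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARCEL_FRACTIONS))
    n_streamlines: int = 2000          # per subject, both hemispheres
    distractor_fraction: float = 0.20  # non-prefrontal share of the tractogram
    commissural_share: float = 0.15    # of the distractors; the rest is temporal
    jitter_sd: float = 0.3             # mm, per-point marginal SD
    jitter_smooth: float = 3.0         # correlation length of jitter, in points
    step: float = 1.0                  # mm, centerline sampling
    sphere_spread: float = 1.0         # mm, radius of passage spread in the VTA sphere
    axial_diffusivity: float = 935.0   # μm²/s inside a coherent bundle
    radial_diffusivity: float = 520.0  # μm²/s  (gives FA ~ 0.35)
    background_diffusivity: float = 700.0  # μm²/s isotropic outside the bundle
    mass_saturation: float = 350.0     # mm/voxel at which the *tracking* field saturates
    scalar_saturation: float = 20.0    # mm/voxel at which the *scalar maps* saturate
    intra_fraction: float = 0.43       # bundle-interior intra-axonal volume fraction
    extra_fraction: float = 0.38       # bundle-interior extra-axonal volume fraction
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.parcel_fractions
        if any(v < 0 for v in fr.values()):
            raise ValueError("parcel fractions must be non-negative")
        if sum(fr.values()) > 1 + 1e-9:
            raise ValueError("parcel fractions must sum to <= 1")
        if not 0 <= self.distractor_fraction < 1:
            raise ValueError("distractor fraction must be in [0, 1)")
        unknown = set(fr) - set(_PARCEL_BOXES)
        if unknown:
            raise ValueError(f"unknown parcels: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Intended class of every streamline, plus the intended proportions."""

    classes: list[str]  # 'rh-<parcel>', 'lh-<parcel>', '?h-temporal', 'commissural'
    proportions: dict[str, float]  # per parcel, within the prefrontal class
    #: per streamline, vertex index where the shared trunk ends (the
    #: waypoint vertex of prefrontal streamlines; None for distractors)
    trunk_end: list[int | None] = field(default_factory=list)


@dataclass
class PhantomSubject:
    subject_id: str
    tractogram: Tractogram
    labels: LabelVolume
    scalars: dict[str, ScalarVolume]
    tensor: TensorVolume
    wm_mask: np.ndarray
    ground_truth: GroundTruth


def _mirror_box(box: tuple, side: str) -> tuple:
    if side == "right":
        return box
    x0, x1, y0, y1, z0, z1 = box
    return (-x1, -x0, y0, y1, z0, z1)


def make_phantom_parcellation(spec: PhantomSpec | None = None) -> LabelVolume:
    """Thin prefrontal parcel slabs (all voxels y > 18) per hemisphere,
    plus a temporal territory (y < 0, z < −8) per hemisphere."""
    spec = spec or PhantomSpec()
    space = spec.space
    cx, cy, cz = space.voxel_centers()
    grid = np.zeros(space.shape, dtype=np.int32)
    names: dict[int, str] = {}
    parcel_order = list(_PARCEL_BOXES)
    for side, base_id, prefix in (("right", 1, "rh-"), ("left", 11, "lh-")):
        for i, parcel in enumerate(parcel_order):
            x0, x1, y0, y1, z0, z1 = _mirror_box(_PARCEL_BOXES[parcel], side)
            sel = ((cx >= x0) & (cx <= x1) & (cy >= y0) & (cy <= y1)
                   & (cz >= z0) & (cz <= z1))
            if not np.any(sel):
                raise ValueError(
                    f"grid too small to host parcel {parcel!r} ({side})")
            grid[sel] = base_id + i
            names[base_id + i] = prefix + parcel
        x0, x1, y0, y1, z0, z1 = _mirror_box(_TEMPORAL_BOX, side)
        sel = ((cx >= x0) & (cx <= x1) & (cy >= y0) & (cy <= y1)
               & (cz >= z0) & (cz <= z1))
        if not np.any(sel):
            raise ValueError(f"grid too small to host the temporal territory ({side})")
        tid = 21 if side == "right" else 22
        grid[sel] = tid
        names[tid] = prefix + "temporal"
    return LabelVolume(grid=grid, space=space, names=names)


def _smooth_noise(n: int, rng: np.random.Generator, sd: float, smooth: float) -> np.ndarray:
    """Gaussian noise with per-point marginal SD ``sd``, correlated along
    the first axis with Gaussian kernel width ``smooth`` points."""
    noise = rng.normal(size=(n, 3))
    if smooth <= 0 or sd == 0:
        return sd * noise
    sm = gaussian_filter1d(noise, smooth, axis=0, mode="nearest")
    imp = np.zeros(max(n, int(8 * smooth) + 1))
    imp[len(imp) // 2] = 1.0
    scale = np.linalg.norm(gaussian_filter1d(imp, smooth, mode="constant"))
    return sd * sm / scale


def _uniform_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    if radius == 0:
        return np.zeros(3)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.random() ** (1.0 / 3.0)


def _spline_through(controls: np.ndarray, step: float
                    ) -> tuple[np.ndarray, list[int]]:
    """Cubic spline through control points, sampled at ~``step`` mm arc
    length. Control points are kept as exact vertices; their vertex
    indices are returned alongside the sampled polyline."""
    chord = np.linalg.norm(np.diff(controls, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(chord)])
    cs = CubicSpline(s, controls, axis=0)
    pieces = []
    ctrl_idx = [0]
    n = 0
    for a, b in zip(s[:-1], s[1:]):
        dense = cs(np.linspace(a, b, 32))
        piece = resample_polyline(dense, step)[:-1]
        pieces.append(piece)
        n += len(piece)
        ctrl_idx.append(n)
    pieces.append(controls[-1:][:])
    return np.vstack(pieces), ctrl_idx


def _parcel_target(parcel: str, side: str, rng: np.random.Generator) -> np.ndarray:
    """Terminal point inside the parcel slab, with a 3 mm in-plane margin
    so jitter cannot push terminals into a neighbouring tile."""
    x0, x1, y0, y1, z0, z1 = _mirror_box(_PARCEL_BOXES[parcel], side)
    normal = _PARCEL_NORMAL[parcel]
    lo = np.array([x0, y0, z0], float)
    hi = np.array([x1, y1, z1], float)
    margin = np.where(np.abs(normal) > 0.5, 0.0, 3.0)
    p = lo + margin + rng.random(3) * (hi - lo - 2 * margin)
    # center in the slab's normal direction
    mid = 0.5 * (lo + hi)
    p = np.where(np.abs(normal) > 0.5, mid, p)
    return p


def make_bundle(kind: str, n: int, spec: PhantomSpec, side: str = "right",
                rng: np.random.Generator | None = None
                ) -> tuple[list[np.ndarray], list[str], list[int | None]]:
    """Generate ``n`` streamlines of one class.

    ``kind`` is a prefrontal parcel name, 'temporal' or 'commissural'.
    Prefrontal streamlines pass within the VTA sphere, terminate in their
    parcel slab and stay in one hemisphere; temporal streamlines visit the
    sphere but never reach frontal territory; commissural streamlines
    satisfy the sphere and frontal/basal rules but cross the midline.
    """
    if kind not in _PARCEL_BOXES and kind not in ("temporal", "commissural"):
        raise ValueError(f"unknown streamline class {kind!r}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    sgn = 1.0 if side == "right" else -1.0
    center = SPHERE_RIGHT if side == "right" else SPHERE_LEFT
    prefix = "rh-" if side == "right" else "lh-"
    streamlines: list[np.ndarray] = []
    classes: list[str] = []
    trunk_ends: list[int | None] = []
    for _ in range(n):
        basal = np.array([sgn * 7.0, -16.0, -22.0]) + rng.uniform(-2, 2, 3)
        sphere_pt = center + _uniform_ball(rng, spec.sphere_spread)
        if kind in _PARCEL_BOXES:
            waypoint = np.array([sgn * 14.0, 8.0, 14.0]) + rng.uniform(-3, 3, 3)
            terminal = _parcel_target(kind, side, rng)
            approach = terminal - 18.0 * _PARCEL_NORMAL[kind]
            controls = np.vstack([basal, sphere_pt, waypoint, approach, terminal])
            label = prefix + kind
            trunk_ctrl = 2  # the waypoint: where the shared trunk ends
        elif kind == "temporal":
            mid = np.array([sgn * 28.0, -6.0, -10.0]) + rng.uniform(-2, 2, 3)
            x0, x1, y0, y1, z0, z1 = _mirror_box(_TEMPORAL_BOX, side)
            terminal = (np.array([x0, y0, z0], float) + np.array([3.0, 3.0, 3.0])
                        + rng.random(3) * (np.array([x1, y1, z1]) - np.array([x0, y0, z0]) - 6.0))
            controls = np.vstack([basal, sphere_pt, mid, terminal])
            label = prefix + "temporal"
            trunk_ctrl = 2  # temporal distractors share the bottleneck too
        else:  # commissural: basal terminal on the opposite hemisphere
            basal = np.array([-sgn * 7.0, -16.0, -22.0]) + rng.uniform(-2, 2, 3)
            # corridor kept below z ~ -5 so the arc cannot graze the thin
            # orbitofrontal slabs on the z=1 voxel plane
            waypoint = np.array([sgn * 12.0, 6.0, -6.0]) + rng.uniform(-2, 2, 3)
            frontal = np.array([sgn * 9.0, 40.0, -6.0]) + rng.uniform(-1, 1, 3)
            controls = np.vstack([basal, sphere_pt, waypoint, frontal])
            label = "commissural"
            trunk_ctrl = None
        line, ctrl_idx = _spline_through(controls, spec.step)
        line = line + _smooth_noise(len(line), rng, spec.jitter_sd, spec.jitter_smooth)
        streamlines.append(line)
        classes.append(label)
        trunk_ends.append(ctrl_idx[trunk_ctrl] if trunk_ctrl is not None else None)
    return streamlines, classes, trunk_ends


def _class_probabilities(spec: PhantomSpec) -> tuple[list[str], np.ndarray]:
    """Per-hemisphere class probability table (parcels + distractors)."""
    pf = 1.0 - spec.distractor_fraction
    fr = spec.parcel_fractions
    total = sum(fr.values())
    kinds = list(fr)
    probs = [pf * fr[k] / total for k in kinds]
    kinds += ["temporal", "commissural"]
    probs += [spec.distractor_fraction * (1 - spec.commissural_share),
              spec.distractor_fraction * spec.commissural_share]
    return kinds, np.asarray(probs)


def make_subject(spec: PhantomSpec, subject_id: str = "sub-01",
                 seed: int | None = None) -> PhantomSubject:
    """One phantom subject: tractogram, parcellation, tensor field,
    scalar maps and ground truth."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = make_phantom_parcellation(spec)
    kinds, probs = _class_probabilities(spec)
    streamlines: list[np.ndarray] = []
    classes: list[str] = []
    trunk_ends: list[int | None] = []
    for side in ("right", "left"):
        n_side = spec.n_streamlines // 2 if side == "right" \
            else spec.n_streamlines - spec.n_streamlines // 2
        counts = rng.multinomial(n_side, probs)
        for kind, cnt in zip(kinds, counts):
            if cnt == 0:
                continue
            sls, cls, tks = make_bundle(kind, int(cnt), spec, side=side, rng=rng)
            streamlines.extend(sls)
            classes.extend(cls)
            trunk_ends.extend(tks)
    tractogram = Tractogram(streamlines, spec.space, tags=list(classes))
    tensor, wm_mask, mass = tensor_field_from_tractogram(
        tractogram, spec.space,
        axial=spec.axial_diffusivity, radial=spec.radial_diffusivity,
        background=spec.background_diffusivity, saturation=spec.mass_saturation)
    # Scalar maps use a much lower saturation than the tracking field: a
    # voxel a few streamlines deep already represents fully myelinated
    # tissue for microstructure purposes, whereas the tracking field keeps
    # the distal fan partial-volumed to emulate where local tracking fails.
    scalar_tensor, _, _ = tensor_field_from_tractogram(
        tractogram, spec.space,
        axial=spec.axial_diffusivity, radial=spec.radial_diffusivity,
        background=spec.background_diffusivity, saturation=spec.scalar_saturation)
    metrics = tensor_metrics(scalar_tensor)
    w = np.minimum(1.0, mass / spec.scalar_saturation)
    scalars: dict[str, ScalarVolume] = dict(metrics)
    for name, target in (("intra_axonal", spec.intra_fraction),
                         ("extra_axonal", spec.extra_fraction)):
        fgrid = gaussian_filter(target * w, sigma=0.6)
        scalars[name] = ScalarVolume(fgrid, spec.space, units="")
    gt = GroundTruth(classes=classes,
                     proportions={k: v / sum(spec.parcel_fractions.values())
                                  for k, v in spec.parcel_fractions.items()},
                     trunk_end=trunk_ends)
    return PhantomSubject(subject_id=subject_id, tractogram=tractogram,
                          labels=labels, scalars=scalars, tensor=tensor,
                          wm_mask=wm_mask, ground_truth=gt)


def trunk_tractogram(t: Tractogram, gt: GroundTruth, side: str = "right") -> Tractogram:
    """Ground-truth trunk: each sphere-visiting streamline of one
    hemisphere cut at its divergence vertex — the shared corridor from the
    basal terminals through the VTA bottleneck to where the prefrontal fan
    (or the temporal branch) begins. Midline-crossing streamlines are
    excluded."""
    prefix = "rh-" if side == "right" else "lh-"
    pieces = [np.asarray(s)[: k + 1]
              for s, c, k in zip(t.streamlines, gt.classes, gt.trunk_end)
              if k is not None and c.startswith(prefix)]
    return Tractogram(pieces, t.space)


def make_cohort(spec: PhantomSpec, n_subjects: int) -> list[PhantomSubject]:
    """Cohort of phantom subjects with subject-specific derived seeds."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_subjects)
    return [make_subject(spec, subject_id=f"sub-{i + 1:02d}", seed=int(s) % (2**31))
            for i, s in enumerate(seeds)]


def tensor_field_from_tractogram(t: Tractogram, space: ReferenceSpace,
                                 axial: float = 935.0, radial: float = 520.0,
                                 background: float = 700.0,
                                 saturation: float = 5.0
                                 ) -> tuple[TensorVolume, np.ndarray, np.ndarray]:
    """Voxel-wise diffusion tensor field implied by a streamline set.

    Per voxel, segment directions are accumulated into a length-weighted
    orientation tensor S (unit trace). The diffusion tensor is
    D = radial·I + (axial − radial)·w·S with w = min(1, mass/saturation):
    a coherent, well-filled voxel has eigenvalues (axial, radial, radial);
    crossing or sparsely traversed voxels are less anisotropic — the
    partial-volume behaviour a walker-based tracker actually faces.
    Voxels without streamline support get the isotropic ``background``
    diffusivity. Returns (tensor, wm_mask = traversed voxels, mass grid).
    """
    shape = np.array(space.shape)
    acc = np.zeros(tuple(space.shape) + (6,))
    mass = np.zeros(space.shape)
    for s in t.streamlines:
        p = np.asarray(s)
        seg = np.diff(p, axis=0)
        ln = np.linalg.norm(seg, axis=1)
        ok = ln > 0
        seg, ln = seg[ok], ln[ok]
        v = seg / ln[:, None]
        mids = 0.5 * (p[:-1] + p[1:])[ok]
        idx = np.rint(space.world_to_voxel(mids)).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        idx, v, ln = idx[inside], v[inside], ln[inside]
        comps = np.stack([v[:, 0] * v[:, 0], v[:, 0] * v[:, 1], v[:, 0] * v[:, 2],
                          v[:, 1] * v[:, 1], v[:, 1] * v[:, 2], v[:, 2] * v[:, 2]],
                         axis=1)
        np.add.at(acc, tuple(idx.T), comps * ln[:, None])
        np.add.at(mass, tuple(idx.T), ln)
    wm_mask = mass > 0
    data = np.zeros(tuple(space.shape) + (6,))
    iso = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 1.0])
    data[~wm_mask] = background * iso
    w = np.minimum(1.0, mass[wm_mask] / saturation)
    S = acc[wm_mask] / mass[wm_mask, None]
    data[wm_mask] = radial * iso + (axial - radial) * w[:, None] * S
    return (TensorVolume(data=data, space=space, mask=np.ones(space.shape, bool)),
            wm_mask, mass)


def homogeneous_tensor_field(space: ReferenceSpace, axis=(0.0, 1.0, 0.0),
                             axial: float = 935.0, radial: float = 520.0
                             ) -> TensorVolume:
    """Uniform anisotropic tensor field with principal axis ``axis``."""
    v = np.asarray(axis, float)
    v = v / np.linalg.norm(v)
    D = radial * np.eye(3) + (axial - radial) * np.outer(v, v)
    comps = np.array([D[0, 0], D[0, 1], D[0, 2], D[1, 1], D[1, 2], D[2, 2]])
    data = np.broadcast_to(comps, tuple(space.shape) + (6,)).copy()
    return TensorVolume(data=data, space=space, mask=np.ones(space.shape, bool))


def quarter_circle_field(radius: float = 20.0, band: float = 3.0,
                         voxel: float = 1.0, axial: float = 935.0,
                         radial: float = 520.0) -> tuple[TensorVolume, np.ndarray]:
    """Tensor field whose principal axis follows circles about the z axis,
    masked to the first-quadrant annulus of the given radius — an analytic
    test bed for arc-length accuracy of streamline propagation."""
    lo = np.array([-4.0, -4.0, -3.0])
    hi = np.array([radius + band + 4.0, radius + band + 4.0, 3.0])
    shape = tuple(int(np.floor((h - l) / voxel)) + 1 for l, h in zip(lo, hi))
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = lo
    space = ReferenceSpace(affine=affine, shape=shape)
    cx, cy, cz = space.voxel_centers()
    r = np.hypot(cx, cy)
    mask = (cx >= 0) & (cy >= 0) & (np.abs(cz) <= 2.0) \
        & (r >= radius - band) & (r <= radius + band)
    with np.errstate(invalid="ignore", divide="ignore"):
        tx = np.where(r > 0, -cy / r, 0.0)
        ty = np.where(r > 0, cx / r, 1.0)
    data = np.zeros(shape + (6,))
    data[..., 0] = radial + (axial - radial) * tx * tx
    data[..., 1] = (axial - radial) * tx * ty
    data[..., 3] = radial + (axial - radial) * ty * ty
    data[..., 5] = radial
    return TensorVolume(data=data, space=space, mask=np.ones(shape, bool)), mask


def default_gradients(n_dirs: int = 30, shells=(1000.0, 2000.0), n_b0: int = 2
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic multi-shell b-table: ``n_b0`` b=0 volumes plus a
    Fibonacci-hemisphere direction set repeated on each shell."""
    i = np.arange(n_dirs)
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * i / golden
    zc = 1 - (i + 0.5) / n_dirs  # upper hemisphere
    rho = np.sqrt(1 - zc ** 2)
    dirs = np.stack([rho * np.cos(theta), rho * np.sin(theta), zc], axis=1)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for b in shells:
        bvals.extend([b] * n_dirs)
        bvecs.extend(dirs)
    return np.asarray(bvals), np.asarray(bvecs)


def make_synthetic_dwi(tensor: TensorVolume, bvals: np.ndarray, bvecs: np.ndarray,
                       s0: float = 1000.0, snr: float = np.inf,
                       seed: int = 0) -> np.ndarray:
    """Single-tensor DWI signal S = S0·exp(−b·gᵀDg) with Rician noise.

    Diffusivities are in μm²/s and b in s/mm², so the exponent carries a
    1e-6 unit factor. ``snr`` is S0 over the Gaussian channel noise SD;
    infinite SNR means noise-free. Raises if the tensor is not positive
    definite anywhere (the offending voxel is named).
    """
    bvals = np.asarray(bvals, float).ravel()
    bvecs = np.asarray(bvecs, float)
    nz = bvals > 0
    norms = np.linalg.norm(bvecs[nz], axis=1)
    if np.any(np.abs(norms - 1) > 1e-6):
        raise ValueError("b-vectors of diffusion-weighted volumes must be unit norm")
    m = tensor.as_matrices()
    ev = np.linalg.eigvalsh(m)
    bad = np.argwhere(ev[..., 0] <= 0)
    if len(bad):
        raise ValueError("tensor not positive definite at voxel "
                         f"{tuple(int(i) for i in bad[0])}")
    # exponent: b [s/mm²] · gᵀDg [μm²/s] · 1e-6
    quad = np.einsum("...ij,nj,ni->...n", m, bvecs, bvecs)
    signal = s0 * np.exp(-1e-6 * bvals * quad)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        n1 = rng.normal(scale=sigma, size=signal.shape)
        n2 = rng.normal(scale=sigma, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
    return signal
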
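"""Digital head phantom: quantitative map sets with known ground truth.

The phantom is a set of nested, randomly perturbed superellipsoid shells —
a WM core inside a GM shell inside a CSF shell, optionally wrapped in a
fat-like skull/scalp shell — on a regular grid.  Each tissue carries
representative (T1, T2, PD) values; voxel-wise Gaussian jitter emulates
intra-tissue variability and a Gaussian blur of the parameter maps emulates
partial-volume mixing at boundaries.  The label volume stores the
pre-smoothing assignments, so label-conditional statistics recover the
nominal tissue values.  An optional neck extension adds non-brain labels
(muscle/bone/skin) in a zero-intensity region below the head for testing
the neck-synthesis augmentation.

A companion generator perturbs the phantom labels at region boundaries at a
controlled flip rate, producing label stacks with analytically predictable
disagreement statistics for exercising the consensus metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .metrics import LabelStack
from .synthesis import QuantitativeMapSet

__all__ = [
    "TISSUE_LABELS",
    "PhantomSpec",
    "generate_phantom",
    "generate_label_stack",
]

TISSUE_LABELS = {"WM": 1, "GM": 2, "CSF": 3, "SKULL": 4}
NECK_LABELS = {"MUSCLE": 10, "BONE": 11, "SKIN": 12}

# (T1 ms, T2 ms, PD): canonical 3T brain values; skull/scalp modeled as a
# fat-like shell (short T1, bright PD), neck tissues as muscle/bone/skin.
DEFAULT_TISSUE_PARAMS: dict[str, tuple[float, float, float]] = {
    "WM": (850.0, 40.0, 0.70),
    "GM": (1400.0, 70.0, 0.85),
    "CSF": (3000.0, 300.0, 1.00),
    "SKULL": (380.0, 110.0, 0.90),
}

# nominal radii of the shells as fractions of the half-extent
_SHELL_RADII = {"WM": 0.52, "GM": 0.72, "CSF": 0.86, "SKULL": 0.97}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of the digital phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_params: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PARAMS))
    jitter_frac: float = 0.03      # per-voxel Gaussian jitter, fraction of value
    smoothing_vox: float = 1.0     # boundary blur width (voxels)
    superellipse_power: float = 2.5
    perturb_amplitude: float = 0.06  # low-frequency radial perturbation
    skull: bool = True
    neck_extension: int = 0        # extra all-zero slices with non-brain labels

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape):
            raise GeometryError("grid must be at least 16 voxels per axis")
        if self.jitter_frac < 0 or self.smoothing_vox < 0:
            raise GeometryError("jitter and smoothing must be non-negative")


def _radial_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Normalized superellipsoid radius with a smooth random perturbation."""
    nx, ny, nz = spec.shape
    grids = [np.linspace(-1.0, 1.0, n) for n in (nx, ny, nz)]
    x, y, z = np.meshgrid(*grids, indexing="ij")
    p = spec.superellipse_power
    # mild anisotropy so the head is not a sphere
    r = (np.abs(x / 0.95) ** p + np.abs(y / 0.80) ** p
         + np.abs(z / 0.90) ** p) ** (1.0 / p)
    if spec.perturb_amplitude > 0:
        noise = rng.standard_normal(spec.shape)
        smooth = ndimage.gaussian_filter(noise, sigma=[n / 8 for n in spec.shape])
        smooth /= max(np.abs(smooth).max(), 1e-12)
        r = r * (1.0 + spec.perturb_amplitude * smooth)
    return r


def generate_phantom(spec: Optional[PhantomSpec] = None,
                     seed: int = 0) -> QuantitativeMapSet:
    """Build a quantitative map set with ground-truth labels.

    With zero jitter and zero smoothing, the maps are exactly piecewise
    constant at the nominal tissue values inside each label.
    """
    spec = spec if spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    head_shape = spec.shape
    r = _radial_field(spec, rng)

    labels = np.zeros(head_shape, dtype=np.int16)
    shells = ["SKULL", "CSF", "GM", "WM"] if spec.skull else ["CSF", "GM", "WM"]
    for name in shells:  # outermost first; inner assignments overwrite
        labels[r <= _SHELL_RADII[name]] = TISSUE_LABELS[name]
    for name in ("WM", "GM", "CSF"):
        if not np.any(labels == TISSUE_LABELS[name]):
            raise GeometryError(f"{name} shell not representable on this grid")

    t1 = np.zeros(head_shape)
    t2 = np.zeros(head_shape)
    pd_map = np.zeros(head_shape)
    for name in shells:
        mask = labels == TISSUE_LABELS[name]
        vt1, vt2, vpd = spec.tissue_params[name]
        n = int(mask.sum())
        jit = spec.jitter_frac
        t1[mask] = vt1 * (1.0 + jit * rng.standard_normal(n)) if jit else vt1
        t2[mask] = vt2 * (1.0 + jit * rng.standard_normal(n)) if jit else vt2
        pd_map[mask] = vpd * (1.0 + jit * rng.standard_normal(n)) if jit else vpd
    if spec.smoothing_vox > 0:
        t1 = ndimage.gaussian_filter(t1, spec.smoothing_vox)
        t2 = ndimage.gaussian_filter(t2, spec.smoothing_vox)
        pd_map = ndimage.gaussian_filter(pd_map, spec.smoothing_vox)
    t1, t2, pd_map = np.clip(t1, 0, None), np.clip(t2, 0, None), \
        np.clip(pd_map, 0, None)

    nonbrain = None
    if spec.neck_extension > 0:
        ext = spec.neck_extension
        full = (head_shape[0], head_shape[1], head_shape[2] + ext)

        def _extend(vol, dtype=None):
            out = np.zeros(full, dtype=vol.dtype if dtype is None else dtype)
            out[:, :, ext:] = vol
            return out

        t1, t2, pd_map = _extend(t1), _extend(t2), _extend(pd_map)
        labels = _extend(labels)
        nonbrain = np.zeros(full, dtype=np.int16)
        nx, ny = head_shape[:2]
        xs, ys = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
                             indexing="ij")
        rho = np.sqrt(xs**2 + ys**2)
        neck_slab = np.zeros(full, dtype=bool)
        neck_slab[:, :, :ext] = True
        nonbrain[neck_slab & (rho[:, :, None] < 0.35)] = NECK_LABELS["BONE"]
        nonbrain[neck_slab & (rho[:, :, None] >= 0.35)
                 & (rho[:, :, None] < 0.60)] = NECK_LABELS["MUSCLE"]
        nonbrain[neck_slab & (rho[:, :, None] >= 0.60)
                 & (rho[:, :, None] < 0.70)] = NECK_LABELS["SKIN"]

    affine = np.diag([*spec.spacing, 1.0])
    return QuantitativeMapSet(t1=t1, t2=t2, pd=pd_map, labels=labels,
                              nonbrain_labels=nonbrain,
                              spacing=spec.spacing, affine=affine)


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels with at least one 6-neighbour carrying a different label."""
    out = np.zeros(labels.shape, dtype=bool)
    for axis in range(labels.ndim):
        sl_a = [slice(None)] * labels.ndim
        sl_b = [slice(None)] * labels.ndim
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        diff = labels[tuple(sl_a)] != labels[tuple(sl_b)]
        out[tuple(sl_a)] |= diff
        out[tuple(sl_b)] |= diff
    return out


def _flip_targets(labels: np.ndarray, boundary: np.ndarray) -> np.ndarray:
    """For each boundary voxel, the label it flips to: the first differing
    6-neighbour label in axis order (deterministic)."""
    targets = labels.copy()
    assigned = np.zeros(labels.shape, dtype=bool)
    for axis in range(labels.ndim):
        for direction in (1, -1):
            shifted = np.roll(labels, direction, axis=axis)
            # roll wraps; mask out the wrapped border slice
            border = [slice(None)] * labels.ndim
            border[axis] = 0 if direction == 1 else -1
            valid = np.ones(labels.shape, dtype=bool)
            valid[tuple(border)] = False
            cand = boundary & ~assigned & valid & (shifted != labels)
            targets[cand] = shifted[cand]
            assigned |= cand
    return targets


def generate_label_stack(labels: np.ndarray, j: int, flip_rate: float = 0.1,
                         seed: int = 0,
                         voxel_volume: float = 1.0) -> LabelStack:
    """J perturbed copies of a label volume with boundary flips.

    Each copy independently flips every boundary voxel to its (fixed,
    deterministic) neighbouring label with probability ``flip_rate``;
    interior voxels are never touched, so the expected per-voxel
    disagreement follows the binomial law of J independent flips.
    """
    if j < 1:
        raise GeometryError("j must be >= 1")
    if not 0.0 <= flip_rate <= 1.0:
        raise GeometryError("flip_rate must be in [0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    boundary = boundary_mask(labels)
    targets = _flip_targets(labels, boundary)
    stack = np.repeat(labels[None], j, axis=0)
    for i in range(j):
        flips = boundary & (rng.random(labels.shape) < flip_rate)
        stack[i][flips] = targets[flips]
    return LabelStack(stack, voxel_volume)
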
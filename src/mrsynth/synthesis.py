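"""Rendering synthetic images onto an anatomy by dictionary lookup.

A quantitative map set (voxel-wise T1, T2 and proton density) carries the
anatomy; a contrast column carries the physics.  Each voxel's (T1, T2) pair
is snapped to the nearest tissue-grid node, the column's signed intensity is
read there, and the result is scaled by the voxel's proton density — so
PD = 0 voxels (air, background) render as 0.  Out-of-grid relaxation times
clamp to the grid extremes.  Percentile normalization (1st-99th) maps the
rendered intensities into [0, 1] for downstream consumers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ContractError
from .landscape import ContrastColumn, ContrastLandscape, synthesize_contrast

__all__ = [
    "QuantitativeMapSet",
    "SyntheticImage",
    "lookup_image",
    "normalize_percentile",
    "synthesize_batch",
]


@dataclass
class QuantitativeMapSet:
    """Co-registered voxel-wise T1/T2/PD maps plus optional B1 and labels.

    All volumes share one grid; ``spacing`` is the voxel size in mm and
    ``affine`` the voxel-to-world (RAS+) transform.
    """

    t1: np.ndarray
    t2: np.ndarray
    pd: np.ndarray
    b1: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    nonbrain_labels: Optional[np.ndarray] = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shape = self.t1.shape
        for name in ("t2", "pd", "b1", "labels", "nonbrain_labels"):
            vol = getattr(self, name)
            if vol is not None and vol.shape != shape:
                raise ContractError(f"{name} shape {vol.shape} != t1 shape {shape}")
        if np.any(self.t1 < 0) or np.any(self.t2 < 0):
            raise ContractError("T1/T2 maps must be non-negative")
        if np.any(self.pd < 0):
            raise ContractError("PD map must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1.shape

    _FILES = {"t1": "t1.nii.gz", "t2": "t2.nii.gz", "pd": "pd.nii.gz",
              "b1": "b1.nii.gz", "labels": "labels.nii.gz",
              "nonbrain_labels": "nonbrain_labels.nii.gz"}

    def to_nifti(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        for name, fname in self._FILES.items():
            vol = getattr(self, name)
            if vol is None:
                continue
            dtype = np.int16 if "labels" in name else np.float32
            nib.save(nib.Nifti1Image(vol.astype(dtype), self.affine),
                     os.path.join(directory, fname))

    @classmethod
    def from_nifti(cls, directory) -> "QuantitativeMapSet":
        vols = {}
        affine = None
        for name, fname in cls._FILES.items():
            path = os.path.join(directory, fname)
            if not os.path.exists(path):
                if name in ("t1", "t2", "pd"):
                    raise ContractError(f"missing required map {fname}")
                continue
            img = nib.load(path)
            data = np.asarray(img.dataobj)
            vols[name] = data.astype(int) if "labels" in name else \
                np.asarray(data, dtype=float)
            affine = img.affine
        spacing = tuple(float(s) for s in
                        np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
        return cls(affine=affine, spacing=spacing, **vols)


@dataclass
class SyntheticImage:
    """A rendered volume plus the provenance needed to regenerate it."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    labels: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), path)


def lookup_image(maps: QuantitativeMapSet, column: ContrastColumn,
                 interpolate: bool = False) -> SyntheticImage:
    """Render a contrast column onto an anatomy.

    Nearest-node lookup by default; ``interpolate=True`` switches to
    bilinear interpolation over the (T1, T2) grid.  The looked-up value is
    multiplied by the voxel's proton density.
    """
    axis = column.tissue_axis
    if interpolate:
        grid = column.values.reshape(axis.t1_values.size, axis.t2_values.size)
        i1 = np.interp(maps.t1.ravel(), axis.t1_values,
                       np.arange(axis.t1_values.size))
        i2 = np.interp(maps.t2.ravel(), axis.t2_values,
                       np.arange(axis.t2_values.size))
        vals = ndimage.map_coordinates(grid, np.vstack([i1, i2]), order=1,
                                       mode="nearest")
    else:
        rows = axis.nearest_row(maps.t1.ravel(), maps.t2.ravel())
        vals = column.values[rows]
    data = vals.reshape(maps.shape) * maps.pd
    return SyntheticImage(data, maps.spacing, maps.affine,
                          labels=None if maps.labels is None else maps.labels.copy())


def normalize_percentile(image, p_lo: float = 1.0, p_hi: float = 99.0):
    """Map the [P_lo, P_hi] intensity band linearly onto [0, 1] and clip.

    Percentiles use order statistics (lower for P_lo, higher for P_hi), which
    makes the operation exactly idempotent.  Constant images map to zeros.
    Accepts a SyntheticImage (returns a new one) or a bare array.
    """
    arr = image.data if isinstance(image, SyntheticImage) else np.asarray(image)
    lo = np.percentile(arr, p_lo, method="lower")
    hi = np.percentile(arr, p_hi, method="higher")
    if hi <= lo:
        out = np.zeros_like(arr, dtype=float)
    else:
        out = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    if isinstance(image, SyntheticImage):
        prov = dict(image.provenance)
        prov["normalized"] = {"p_lo": p_lo, "p_hi": p_hi,
                              "lo": float(lo), "hi": float(hi)}
        return SyntheticImage(out, image.spacing, image.affine,
                              labels=image.labels, provenance=prov)
    return out


def synthesize_batch(maps: QuantitativeMapSet, landscape: ContrastLandscape,
                     coefficients: np.ndarray,
                     augment_config=None, seed: int = 0,
                     normalize: bool = True) -> list[SyntheticImage]:
    """Render one image per coefficient vector, with optional augmentation.

    Pipeline per vector: synthesize the contrast column, look it up over the
    anatomy, apply the augmentation chain (if a config is given; requires
    ``maps.labels``), then percentile-normalize.  A SeedSequence spawned from
    ``seed`` gives every image an independent, reproducible stream; each
    image's provenance records its coefficients, child seed and augmentation
    draw log.
    """
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=float))
    if augment_config is not None and maps.labels is None:
        raise ContractError("augmentation requires a label volume in the map set")
    children = np.random.SeedSequence(seed).spawn(coefficients.shape[0])
    out: list[SyntheticImage] = []
    for i, c in enumerate(coefficients):
        column = synthesize_contrast(landscape, c)
        img = lookup_image(maps, column)
        img.provenance.update({"coefficients": c.tolist(), "batch_seed": seed,
                               "index": i})
        if augment_config is not None:
            from .augment import augment as _augment
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            data, labels, log = _augment(
                img.data, maps.labels, augment_config,
                np.random.default_rng(child_seed),
                nonbrain_labels=maps.nonbrain_labels)
            img = SyntheticImage(data, img.spacing, img.affine, labels=labels,
                                 provenance={**img.provenance,
                                             "augment_seed": child_seed,
                                             "augment_log": log})
        if normalize:
            img = normalize_percentile(img)
        out.append(img)
    return out
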
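"""Segmentation agreement and consistency metrics.

Operates on stacks of aligned integer label volumes (J raters or J repeated
segmentations over one grid):

* volume-weighted Dice — per-label Dice overlap averaged with weights
  proportional to each label's voxel share in the reference volume;
* majority vote — per-voxel modal label (ties resolved to the smallest id);
* PDM — percent disagreement from the majority vote, per voxel;
* label volumes and LVV — per-label volume in mm^3 and its mean absolute
  relative deviation across the stack, in percent;
* consensus pipeline — label condensation, majority voting, and the two
  auxiliary classes (in-mask unlabeled tissue, out-of-mask tissue);
* largest-component masking — connected-component post-processing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats

from .errors import ContractError

__all__ = [
    "LabelStack",
    "volume_weighted_dice",
    "majority_vote",
    "pdm",
    "pdm_summary",
    "label_volumes",
    "lvv",
    "consensus_pipeline",
    "largest_component_mask",
]

# 26-neighbourhood for connected components
_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)

UNLABELED_IN_MASK = 17   # nonzero-intensity, inside mask, unlabeled
OUTSIDE_MASK = 18        # nonzero-intensity outside the mask
NOISE_MINOR = 19         # reserved background-noise classes
NOISE_MAJOR = 20


@dataclass
class LabelStack:
    """J aligned integer label volumes over one grid."""

    volumes: np.ndarray  # shape (J, ...) integer labels
    voxel_volume: float = 1.0  # mm^3

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes)
        if self.volumes.ndim < 2:
            raise ContractError("stack must be (J, ...) with J >= 1")
        if self.voxel_volume <= 0:
            raise ContractError("voxel volume must be positive")

    @property
    def j(self) -> int:
        return self.volumes.shape[0]


def _as_stack(stack) -> LabelStack:
    return stack if isinstance(stack, LabelStack) else LabelStack(np.asarray(stack))


def volume_weighted_dice(x: np.ndarray, y: np.ndarray) -> float:
    """Volume-weighted Sorensen-Dice coefficient of two label volumes.

    sum_l (N_{X,l} / N_X) * 2 |X_l & Y_l| / (|X_l| + |Y_l|), with weights
    from the first (reference) argument — so the measure is asymmetric
    unless the two volumes have identical label shares.
    """
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise ContractError("label volumes must share one grid")
    labels = np.union1d(np.unique(x), np.unique(y))
    labels = labels[labels != 0]
    n_x = int(np.count_nonzero(x))
    if n_x == 0:
        return 0.0
    total = 0.0
    for label in labels:
        xl, yl = x == label, y == label
        nxl, nyl = int(xl.sum()), int(yl.sum())
        if nxl == 0:
            continue  # zero weight
        inter = int(np.count_nonzero(xl & yl))
        total += (nxl / n_x) * (2.0 * inter / (nxl + nyl))
    return float(total)


def majority_vote(stack) -> np.ndarray:
    """Per-voxel modal label; ties resolve to the smallest label id."""
    s = _as_stack(stack)
    if s.j == 1:
        return s.volumes[0].copy()
    mode, _ = sstats.mode(s.volumes, axis=0, keepdims=False)
    return np.asarray(mode)


def pdm(stack) -> np.ndarray:
    """Percent disagreement from the majority vote, per voxel (0..100)."""
    s = _as_stack(stack)
    if s.j == 1:
        warnings.warn("PDM of a single segmentation is identically zero",
                      stacklevel=2)
        return np.zeros(s.volumes.shape[1:])
    mv = majority_vote(s)
    agree = (s.volumes == mv[None]).sum(axis=0)
    return (s.j - agree) / s.j * 100.0


def pdm_summary(stack, background: int = 0,
                exclude: Sequence[int] = (NOISE_MINOR, NOISE_MAJOR)):
    """Mean +/- sd of voxel-wise PDM over non-background majority voxels."""
    s = _as_stack(stack)
    values = pdm(s)
    mv = majority_vote(s)
    mask = (mv != background) & ~np.isin(mv, exclude)
    vox = values[mask]
    if vox.size == 0:
        return {"mean": 0.0, "sd": 0.0, "n_voxels": 0}
    return {"mean": float(vox.mean()), "sd": float(vox.std()),
            "n_voxels": int(vox.size)}


def label_volumes(volume: np.ndarray, voxel_volume: float = 1.0,
                  labels: Optional[Sequence[int]] = None) -> pd.Series:
    """Per-label volume in mm^3 (voxel count times voxel volume)."""
    volume = np.asarray(volume)
    if labels is None:
        labels = [int(l) for l in np.unique(volume) if l != 0]
    counts = {int(l): int(np.count_nonzero(volume == l)) for l in labels}
    return pd.Series({l: c * voxel_volume for l, c in counts.items()},
                     name="volume_mm3", dtype=float)


def lvv(volumes) -> pd.Series:
    """Label Volume Variation: mean absolute relative deviation, percent.

    ``volumes`` is a per-label table of volumes across images — a DataFrame
    (rows: labels, columns: images), a mapping label -> sequence, or a 2-D
    array.  Labels with zero mean volume are undefined and reported as NaN.
    """
    if isinstance(volumes, pd.DataFrame):
        table = volumes
    elif isinstance(volumes, Mapping):
        table = pd.DataFrame({l: pd.Series(v) for l, v in volumes.items()}).T
    else:
        table = pd.DataFrame(np.atleast_2d(np.asarray(volumes, dtype=float)))
    mean = table.mean(axis=1)
    out = (table.sub(mean, axis=0).abs().div(mean, axis=0)).mean(axis=1) * 100.0
    out[mean == 0] = np.nan
    out.name = "lvv_percent"
    return out


def consensus_pipeline(stack, condensation: Mapping[int, int],
                       intensity: Optional[np.ndarray] = None,
                       brain_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Condense fine labels, majority-vote, and add auxiliary classes.

    Every fine label appearing in the stack must be present in
    ``condensation`` (background 0 maps to 0 implicitly).  When an intensity
    image and a mask are given, unlabeled nonzero voxels inside the mask get
    label 17 and nonzero voxels outside the mask get label 18; zero-intensity
    voxels are never relabeled.  Ids 19/20 are reserved for background-noise
    classes and never assigned here.
    """
    s = _as_stack(stack)
    present = np.unique(s.volumes)
    mapping = dict(condensation)
    mapping.setdefault(0, 0)
    missing = [int(l) for l in present if int(l) not in mapping]
    if missing:
        raise ContractError(f"condensation map lacks entries for labels {missing}")
    lut = np.zeros(int(present.max()) + 1, dtype=int)
    for fine, coarse in mapping.items():
        if fine <= present.max():
            lut[fine] = coarse
    condensed = lut[s.volumes]
    consensus = majority_vote(LabelStack(condensed, s.voxel_volume))
    if intensity is not None and brain_mask is not None:
        if intensity.shape != consensus.shape or brain_mask.shape != consensus.shape:
            raise ContractError("intensity/mask shape mismatch")
        nonzero = intensity != 0
        consensus = consensus.copy()
        consensus[(consensus == 0) & brain_mask & nonzero] = UNLABELED_IN_MASK
        consensus[(consensus == 0) & ~brain_mask & nonzero] = OUTSIDE_MASK
    return consensus


def largest_component_mask(labels: np.ndarray,
                           subset: Sequence[int]) -> np.ndarray:
    """Keep only the largest 26-connected component of a label subset.

    The subset labels are binarized, the largest connected component found,
    and subset labels outside it zeroed; labels not in the subset are never
    modified.
    """
    labels = np.asarray(labels)
    binary = np.isin(labels, subset)
    if not np.any(binary):
        warnings.warn("label subset empty; nothing to mask", stacklevel=2)
        return labels.copy()
    comps, n = ndimage.label(binary, structure=_CONNECTIVITY)
    if n <= 1:
        return labels.copy()
    sizes = ndimage.sum_labels(binary, comps, index=np.arange(1, n + 1))
    keep = comps == (int(np.argmax(sizes)) + 1)
    out = labels.copy()
    out[binary & ~keep] = 0
    return out
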
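"""Tissue contrast scoring and contrast-class assignment.

Given representative intensities I_l for a set of tissues L (by default
white matter, gray matter and cerebrospinal fluid), the pairwise absolute
intensity differences give each tissue its nearest and farthest neighbour
distances (d_l_min, d_l_max).  With R = max_l d_l_max the overall contrast
range, two scores in [0, 1] follow:

    single-tissue   S_l = d_l_min / R
    multi-tissue    S   = (|L| - 1) * min_l d_l_min / R

S = 1 exactly when the tissues are equidistant (e.g. intensities 0, 0.5, 1);
any coincident pair drives S to 0.  Both scores are invariant to affine
intensity rescaling.  Strict orderings of the WM/GM/CSF intensities define
six contrast classes (class 1, WM > GM > CSF, is T1-weighted-like; class 5,
CSF > GM > WM, T2-weighted-like; class 3, GM > WM > CSF, FLAIR-like).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import ContractError, DomainError

__all__ = [
    "TissueReference",
    "CONTRAST_CLASS_ORDERINGS",
    "inter_tissue_distances",
    "single_tissue_score",
    "multi_tissue_score",
    "multi_tissue_score_array",
    "contrast_class",
    "contrast_class_array",
]

# class id -> tissue names in decreasing intensity order
CONTRAST_CLASS_ORDERINGS: dict[int, tuple[str, str, str]] = {
    1: ("WM", "GM", "CSF"),
    2: ("WM", "CSF", "GM"),
    3: ("GM", "WM", "CSF"),
    4: ("GM", "CSF", "WM"),
    5: ("CSF", "GM", "WM"),
    6: ("CSF", "WM", "GM"),
}


@dataclass(frozen=True)
class TissueReference:
    """Representative (T1 ms, T2 ms) per tissue label."""

    tissues: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ContractError("at least two tissues are required")
        for name, (t1, t2) in self.tissues.items():
            if t1 <= 0 or t2 <= 0:
                raise DomainError(f"{name}: relaxation times must be positive")

    @classmethod
    def default(cls) -> "TissueReference":
        """Canonical adult 3T values: WM (850, 40), GM (1400, 70), CSF (3000, 300)."""
        return cls({"WM": (850.0, 40.0), "GM": (1400.0, 70.0),
                    "CSF": (3000.0, 300.0)})

    @classmethod
    def from_segmentation(cls, t1_map: np.ndarray, t2_map: np.ndarray,
                          labels: np.ndarray,
                          label_names: Mapping[int, str]) -> "TissueReference":
        """Subject-specific references: median T1/T2 within each labeled class."""
        tissues = {}
        for label_id, name in label_names.items():
            mask = labels == label_id
            if not np.any(mask):
                raise ContractError(f"label {label_id} ({name}) empty in segmentation")
            tissues[name] = (float(np.median(t1_map[mask])),
                             float(np.median(t2_map[mask])))
        return cls(tissues)

    def names(self) -> list[str]:
        return list(self.tissues.keys())

    def values(self):
        return self.tissues.values()


def _pairwise_min_max(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-tissue nearest/farthest absolute differences and the range R.

    values : (..., L) intensity array.  Returns (d_min, d_max) of shape
    (..., L) and R of shape (...,).
    """
    diff = np.abs(values[..., :, None] - values[..., None, :])
    il = np.arange(values.shape[-1])
    diff[..., il, il] = np.inf
    d_min = diff.min(axis=-1)
    diff[..., il, il] = -np.inf
    d_max = diff.max(axis=-1)
    return d_min, d_max, d_max.max(axis=-1)


def inter_tissue_distances(intensities: Mapping[str, float]):
    """Nearest/farthest inter-tissue distances and the contrast range.

    Returns ({tissue: (d_min, d_max)}, R).
    """
    if len(intensities) < 2:
        raise ContractError("at least two tissue intensities are required")
    names = list(intensities.keys())
    vals = np.asarray([intensities[n] for n in names], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DomainError("intensities must be finite")
    d_min, d_max, r = _pairwise_min_max(vals)
    dists = {n: (float(d_min[i]), float(d_max[i])) for i, n in enumerate(names)}
    return dists, float(r)


def single_tissue_score(intensities: Mapping[str, float], tissue: str) -> float:
    """S_l = d_l_min / R; 0 for a contrast-free (R = 0) input."""
    if tissue not in intensities:
        raise ContractError(f"unknown tissue label {tissue!r}")
    dists, r = inter_tissue_distances(intensities)
    if r == 0.0:
        return 0.0
    return dists[tissue][0] / r


def multi_tissue_score(intensities: Mapping[str, float]) -> float:
    """S = (|L| - 1) * min_l d_l_min / R; 0 for a contrast-free input."""
    dists, r = inter_tissue_distances(intensities)
    if r == 0.0:
        return 0.0
    n = len(intensities)
    return (n - 1) * min(d[0] for d in dists.values()) / r


def multi_tissue_score_array(intensities: np.ndarray) -> np.ndarray:
    """Vectorised multi-tissue score for an (..., L) intensity array."""
    vals = np.asarray(intensities, dtype=float)
    d_min, _, r = _pairwise_min_max(vals)
    out = np.zeros(vals.shape[:-1])
    nz = r > 0
    out[nz] = (vals.shape[-1] - 1) * d_min.min(axis=-1)[nz] / r[nz]
    return out


def contrast_class(i_wm: float, i_gm: float, i_csf: float) -> Optional[int]:
    """Class id (1..6) of the strict WM/GM/CSF intensity ordering.

    Returns None for any exact tie (classes are defined by strict
    inequalities only).
    """
    for v in (i_wm, i_gm, i_csf):
        if not np.isfinite(v):
            raise DomainError("intensities must be finite")
    out = contrast_class_array(np.asarray([i_wm]), np.asarray([i_gm]),
                               np.asarray([i_csf]))[0]
    return int(out) if out > 0 else None


def contrast_class_array(i_wm: np.ndarray, i_gm: np.ndarray,
                         i_csf: np.ndarray) -> np.ndarray:
    """Vectorised class assignment; 0 marks unclassifiable (tied) inputs."""
    wm, gm, csf = (np.asarray(a, dtype=float) for a in (i_wm, i_gm, i_csf))
    out = np.zeros(wm.shape, dtype=int)
    out[(wm > gm) & (gm > csf)] = 1
    out[(wm > csf) & (csf > gm)] = 2
    out[(gm > wm) & (wm > csf)] = 3
    out[(gm > csf) & (csf > wm)] = 4
    out[(csf > gm) & (gm > wm)] = 5
    out[(csf > wm) & (wm > gm)] = 6
    return out
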
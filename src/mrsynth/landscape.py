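"""Eigencontrast landscape: SVD compression of the signal dictionary and
coefficient-vector sampling.

The dense dictionary D (rows: (T1, T2) combinations; columns: acquisition
combinations, each column one contrast) is centered by removing the mean
contrast — the per-row mean over all acquisition columns — and factorised by
a truncated SVD,

    D - mu 1^T = U S V^T  ~  U_K S_K V_K^T,

keeping the top K = 10 eigencontrasts.  A new contrast is a point
c in [-1, 1]^K of the landscape, rendered as the column D_c = U_K S_K c
(one signed intensity per (T1, T2) grid node).  Sampling utilities cover
the uniform grid scheme (more samples along directions with larger singular
values) and stratified sampling within one of the six WM/GM/CSF ordering
classes, spread evenly over percentile bins of the multi-tissue contrast
score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product

import h5py
import numpy as np

from .contrast import TissueReference, contrast_class_array, multi_tissue_score_array
from .errors import ConfigurationError, ContractError, DomainError, SamplingError
from .spin import SignalDictionary, TissueAxis

__all__ = [
    "ContrastLandscape",
    "ContrastColumn",
    "decompose",
    "synthesize_contrast",
    "sample_allocation",
    "uniform_sample",
    "stratified_class_sample",
    "threshold_class_sample",
    "tissue_intensity_matrix",
]

# Matrices up to this many elements use an exact dense SVD; larger ones go
# through the (cheaper, memory-bounded) Gram eigendecomposition.
_DENSE_SVD_MAX_ELEMENTS = 4_000_000

_RANK_RTOL = 1e-12  # singular values below s_max * rtol count as numerical zeros


@dataclass
class ContrastLandscape:
    """Truncated SVD factors of the centered dictionary.

    basis : (n_rows, K) orthonormal eigencontrast columns (U_K)
    singular_values : (K,) strictly positive, non-increasing
    row_mean : (n_rows,) mean contrast removed before the SVD
    retained_energy : fraction of total squared singular-value mass kept
    """

    basis: np.ndarray
    singular_values: np.ndarray
    row_mean: np.ndarray
    retained_energy: float
    tissue_axis: TissueAxis

    @property
    def k(self) -> int:
        return self.singular_values.size

    def save(self, path) -> None:
        from . import __version__
        with h5py.File(path, "w") as f:
            f.create_dataset("basis", data=self.basis)
            f.create_dataset("singular_values", data=self.singular_values)
            f.create_dataset("row_mean", data=self.row_mean)
            f.create_dataset("t1_values", data=self.tissue_axis.t1_values)
            f.create_dataset("t2_values", data=self.tissue_axis.t2_values)
            f.attrs["retained_energy"] = self.retained_energy
            f.attrs["provenance"] = json.dumps({
                "format": "mrsynth-contrast-landscape",
                "version": __version__,
                "k": int(self.k),
            })

    @classmethod
    def load(cls, path) -> "ContrastLandscape":
        with h5py.File(path, "r") as f:
            return cls(f["basis"][()], f["singular_values"][()],
                       f["row_mean"][()],
                       float(f.attrs["retained_energy"]),
                       TissueAxis(f["t1_values"][()], f["t2_values"][()]))


@dataclass
class ContrastColumn:
    """One synthesized contrast: a signed intensity per (T1, T2) grid node."""

    values: np.ndarray
    tissue_axis: TissueAxis

    def __post_init__(self) -> None:
        if self.values.shape != (self.tissue_axis.n_rows,):
            raise ContractError("column length must equal the dictionary row count")


def decompose(dictionary: SignalDictionary, k: int = 10,
              center: str = "contrast") -> ContrastLandscape:
    """Compress the dictionary into its top-k eigencontrasts.

    Parameters
    ----------
    dictionary : SignalDictionary
    k : retained rank (default 10, preserving >99.95% of the energy at the
        default grids).
    center : "contrast" removes the mean contrast (per-row mean over
        acquisition columns, the default); "column" removes the per-column
        mean instead (exposed for comparison; note the rendered columns then
        have no well-typed mean to re-add).

    Notes
    -----
    If the numerical rank of the centered matrix is below ``k``, the retained
    rank is reduced to it (with a warning) so the stored singular values stay
    strictly positive.
    """
    d = dictionary.values
    m, n = d.shape
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > min(m, n):
        raise ConfigurationError(
            f"k={k} exceeds the maximal rank min{d.shape}={min(m, n)}")
    if center == "contrast":
        mu = d.mean(axis=1)
    elif center == "column":
        mu = d.mean(axis=0)
    else:
        raise ConfigurationError(f"unknown centering mode {center!r}")

    if d.size <= _DENSE_SVD_MAX_ELEMENTS:
        dc = d - (mu[:, None] if center == "contrast" else mu[None, :])
        u, s, _ = np.linalg.svd(dc, full_matrices=False)
        energies = s**2
    else:
        u, s, energies = _gram_svd(d, mu, center)

    total = energies.sum()
    if total <= 0:
        raise ConfigurationError("centered dictionary is identically zero")
    rank = int(np.count_nonzero(s > s[0] * _RANK_RTOL))
    if rank < k:
        warnings.warn(f"numerical rank {rank} < k={k}; retaining {rank} "
                      "eigencontrasts", stacklevel=2)
        k = rank
    retained = float(energies[:k].sum() / total)
    row_mean = mu if center == "contrast" else np.full(m, np.nan)
    return ContrastLandscape(np.ascontiguousarray(u[:, :k]), s[:k].copy(),
                             row_mean, retained, dictionary.tissue_axis)


def _gram_svd(d: np.ndarray, mu: np.ndarray, center: str):
    """Left singular vectors + full spectrum via the column Gram matrix.

    Avoids materialising a centered copy of a large dictionary: with
    Dc = D - mu 1^T (contrast centering), the n x n Gram is
    D^T D - a 1^T - 1 a^T + (mu.mu) 1 1^T with a = D^T mu.
    """
    m, n = d.shape
    g = d.T @ d
    if center == "contrast":
        a = d.T @ mu
        g -= np.outer(a, np.ones(n))
        g -= np.outer(np.ones(n), a)
        g += float(mu @ mu) * np.ones((n, n))
    else:  # column centering: Gram of (D - 1 mu^T)
        g -= m * np.outer(mu, mu)
    w, v = np.linalg.eigh(g)
    w = np.clip(w[::-1], 0.0, None)
    v = v[:, ::-1]
    s = np.sqrt(w)
    kmax = int(np.count_nonzero(s > (s[0] if s[0] > 0 else 1.0) * _RANK_RTOL))
    kmax = max(kmax, 1)
    if center == "contrast":
        u = d @ v[:, :kmax]
        u -= np.outer(mu, v[:, :kmax].sum(axis=0))
    else:
        u = d @ v[:, :kmax]
        u -= np.outer(np.ones(m), mu @ v[:, :kmax])
    u /= s[:kmax]
    return u, s, w


def synthesize_contrast(landscape: ContrastLandscape, c: np.ndarray,
                        add_mean: bool = False) -> ContrastColumn:
    """Render the contrast column D_c = U_K S_K c.

    Coefficients outside [-1, 1] are clipped with a warning.  ``add_mean``
    re-adds the removed mean contrast (off by default: the synthesis formula
    as used omits it, and downstream percentile normalization makes the two
    choices nearly equivalent).
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (landscape.k,):
        raise ContractError(f"coefficient vector must have length {landscape.k}")
    if np.any(np.abs(c) > 1.0):
        warnings.warn("coefficients outside [-1, 1] clipped", stacklevel=2)
        c = np.clip(c, -1.0, 1.0)
    values = landscape.basis @ (landscape.singular_values * c)
    if add_mean:
        values = values + landscape.row_mean
    return ContrastColumn(values, landscape.tissue_axis)


def project_contrast(landscape: ContrastLandscape,
                     column: ContrastColumn) -> np.ndarray:
    """Recover the coefficient vector of a rendered column: S^-1 U^T D_c."""
    return (landscape.basis.T @ column.values) / landscape.singular_values


def sample_allocation(singular_values: np.ndarray) -> np.ndarray:
    """Per-dimension sample counts r_i = round(s_i / min_j s_j).

    Rounding is half-away-from-zero; every r_i >= 1.
    """
    s = np.asarray(singular_values, dtype=float)
    if np.any(s <= 0):
        raise DomainError("singular values must be strictly positive")
    ratio = s / s.min()
    r = np.floor(ratio + 0.5).astype(int)  # half-away-from-zero for positives
    return np.maximum(r, 1)


def uniform_sample(landscape: ContrastLandscape,
                   max_vectors: int | None = None) -> np.ndarray:
    """Deterministic grid of coefficient vectors over the landscape.

    Dimension i contributes r_i linearly spaced points in [-1, 1]
    (r_i = 1 contributes the single midpoint 0); the result is their
    Cartesian product, shape (prod r_i, K).
    """
    r = sample_allocation(landscape.singular_values)
    total = int(np.prod(r.astype(object)))
    if max_vectors is not None and total > max_vectors:
        raise ConfigurationError(
            f"uniform grid would contain {total} vectors > max_vectors={max_vectors}")
    axes = [np.linspace(-1.0, 1.0, ri) if ri > 1 else np.array([0.0]) for ri in r]
    out = np.empty((total, r.size))
    for i, combo in enumerate(product(*axes)):
        out[i] = combo
    return out


def uniform_sample_subset(landscape: ContrastLandscape, n: int,
                          rng_seed: int = 0) -> np.ndarray:
    """n random points of the uniform sampling grid, without materialising it.

    A uniform draw over the Cartesian product grid factorises into
    independent per-dimension draws from each dimension's linspace; use this
    when the full grid (prod r_i vectors) is too large to enumerate.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    r = sample_allocation(landscape.singular_values)
    rng = np.random.default_rng(rng_seed)
    out = np.empty((n, r.size))
    for i, ri in enumerate(r):
        axis = np.linspace(-1.0, 1.0, ri) if ri > 1 else np.array([0.0])
        out[:, i] = axis[rng.integers(0, ri, size=n)]
    return out


def tissue_intensity_matrix(landscape: ContrastLandscape,
                            tissue_refs: TissueReference,
                            coefficients: np.ndarray,
                            add_mean: bool = False) -> np.ndarray:
    """Rendered intensities of the reference tissues for many coefficient
    vectors at once: shape (n_vectors, n_tissues)."""
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=float))
    rows = [landscape.tissue_axis.nearest_row(t1, t2)
            for (t1, t2) in tissue_refs.values()]
    proj = landscape.basis[rows, :] * landscape.singular_values  # (L, K)
    out = coefficients @ proj.T
    if add_mean:
        out = out + landscape.row_mean[rows][None, :]
    return out


def _class_candidates(landscape, class_id, tissue_refs, rng, pool_size):
    if not 1 <= class_id <= 6:
        raise ConfigurationError("class_id must be in 1..6")
    pool = rng.uniform(-1.0, 1.0, size=(pool_size, landscape.k))
    inten = tissue_intensity_matrix(landscape, tissue_refs, pool)
    cls = contrast_class_array(inten[:, 0], inten[:, 1], inten[:, 2])
    keep = cls == class_id
    if not np.any(keep):
        raise SamplingError(
            f"no candidate among {pool_size} random vectors falls in contrast "
            f"class {class_id}; increase pool_size")
    scores = multi_tissue_score_array(inten[keep])
    return pool[keep], scores


def stratified_class_sample(landscape: ContrastLandscape, class_id: int,
                            h: int, tissue_refs: TissueReference | None = None,
                            rng_seed: int = 0,
                            pool_size: int = 50_000) -> np.ndarray:
    """Draw h coefficient vectors from one contrast class, stratified by
    contrast quality.

    A seeded pool of ``pool_size`` uniform random vectors is filtered to the
    requested WM/GM/CSF ordering class, scored with the multi-tissue contrast
    score, split into h percentile bins of that score distribution, and one
    vector is drawn (uniformly, seeded) from each bin.
    """
    if h < 1:
        raise ConfigurationError("h must be >= 1")
    tissue_refs = tissue_refs if tissue_refs is not None else TissueReference.default()
    rng = np.random.default_rng(rng_seed)
    cand, scores = _class_candidates(landscape, class_id, tissue_refs, rng, pool_size)
    if cand.shape[0] < h:
        raise SamplingError(
            f"only {cand.shape[0]} candidates in class {class_id} for h={h} bins")
    edges = np.percentile(scores, np.linspace(0.0, 100.0, h + 1))
    out = np.empty((h, landscape.k))
    for b in range(h):
        lo, hi = edges[b], edges[b + 1]
        in_bin = (scores >= lo) & ((scores <= hi) if b == h - 1 else (scores < hi))
        if not np.any(in_bin):  # ties collapsed a bin; fall back to nearest score
            in_bin = np.abs(scores - 0.5 * (lo + hi)) == \
                np.min(np.abs(scores - 0.5 * (lo + hi)))
        out[b] = cand[rng.choice(np.nonzero(in_bin)[0])]
    return out


def threshold_class_sample(landscape: ContrastLandscape, class_id: int,
                           n: int, tissue_refs: TissueReference | None = None,
                           rng_seed: int = 0, score_percentile: float = 60.0,
                           pool_size: int = 50_000) -> np.ndarray:
    """Draw n vectors from the higher-contrast subset of one class.

    The class's multi-tissue score distribution is split at
    ``score_percentile`` (default 60) and vectors are drawn uniformly from
    the upper part — the protocol used to pick consensus-labeling contrasts.
    """
    tissue_refs = tissue_refs if tissue_refs is not None else TissueReference.default()
    rng = np.random.default_rng(rng_seed)
    cand, scores = _class_candidates(landscape, class_id, tissue_refs, rng, pool_size)
    cut = np.percentile(scores, score_percentile)
    upper = cand[scores >= cut]
    if upper.shape[0] == 0:
        raise SamplingError("score threshold left no candidates")
    idx = rng.choice(upper.shape[0], size=n, replace=upper.shape[0] < n)
    return upper[idx]
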
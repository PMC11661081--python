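"""Training-time image corruptions: the eight-step augmentation chain.

Each synthetic image is passed through, in order: (1) a skull mode — keep
the head unchanged, strip to brain + CSF, or extend a synthetic neck from
non-brain label statistics; (2) multiplicative bias-field corruption;
(3) random quarter-turn reorientation, per-axis flipping and bounded
translation; (4) a probabilistic resolution-downsampling cascade; (5)
uniform Gaussian background noise; (6) non-uniform noise in random
background prisms.  Every stochastic draw is taken from one
``numpy.random.Generator`` and recorded in a machine-readable log, so a
fixed seed reproduces the output bit for bit.

The cascade (4) enters with probability 1/2 and, after each downsampled
axis, continues to another with probability 1/2, yielding the branch law
50% untouched / 25% one axis / 12.5% two axes / 12.5% three axes; each
downsampled axis drops to 2 mm or 4 mm with equal odds and the image is
always resampled back to the input grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .errors import ConfigurationError, ContractError

__all__ = [
    "AugmentConfig",
    "compute_nonbrain_stats",
    "apply_skull_mode",
    "synth_neck",
    "bias_field",
    "reorient_flip_translate",
    "downsample_cascade",
    "uniform_noise",
    "nonuniform_noise",
    "augment",
]

_ROTATION_PLANES = {2: (0, 1), 1: (0, 2), 0: (1, 2)}  # rotate about z, y, x


@dataclass
class AugmentConfig:
    """Probabilities and hyperparameters of the augmentation chain.

    Defaults follow the training protocol: equal thirds for the skull modes,
    0.5 for every Bernoulli gate, bias hyperparameter b_B = 0.6 (the
    SynthSeg-style corruption strength), candidate low resolutions 2/4 mm.
    """

    skull_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    brain_labels: tuple[int, ...] = (1, 2, 3)
    bias_b: float = 0.6
    reorient_prob: float = 1.0
    flip_prob: float = 0.5
    translate_prob: float = 1.0
    downsample_prob: float = 0.5
    downsample_continue_prob: float = 0.5
    resolutions_mm: tuple[float, float] = (2.0, 4.0)
    uniform_noise_prob: float = 0.5
    nonuniform_noise_prob: float = 0.5
    noise_continue_prob: float = 0.5

    def __post_init__(self) -> None:
        probs = (self.reorient_prob, self.flip_prob, self.translate_prob,
                 self.downsample_prob, self.downsample_continue_prob,
                 self.uniform_noise_prob, self.nonuniform_noise_prob,
                 self.noise_continue_prob, *self.skull_weights)
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if abs(sum(self.skull_weights) - 1.0) > 1e-9:
            raise ConfigurationError("skull mode weights must sum to 1")
        if self.bias_b < 0:
            raise ConfigurationError("bias_b must be non-negative")
        if any(r <= 0 for r in self.resolutions_mm):
            raise ConfigurationError("resolutions must be positive")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        """A configuration under which augment() is the identity transform."""
        return cls(skull_weights=(1.0, 0.0, 0.0), bias_b=0.0,
                   reorient_prob=0.0, flip_prob=0.0, translate_prob=0.0,
                   downsample_prob=0.0, uniform_noise_prob=0.0,
                   nonuniform_noise_prob=0.0)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)

    @classmethod
    def from_yaml(cls, path) -> "AugmentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        for key in ("skull_weights", "brain_labels", "resolutions_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def compute_nonbrain_stats(image: np.ndarray, nonbrain_labels: np.ndarray,
                           fov_mask: Optional[np.ndarray] = None
                           ) -> dict[int, tuple[float, float]]:
    """Mean/std of the image within each non-brain label inside the FOV."""
    fov = (image != 0) if fov_mask is None else fov_mask
    stats: dict[int, tuple[float, float]] = {}
    for label in np.unique(nonbrain_labels):
        if label == 0:
            continue
        vox = image[(nonbrain_labels == label) & fov]
        if vox.size:
            stats[int(label)] = (float(vox.mean()), float(vox.std()))
    return stats


def synth_neck(image: np.ndarray, nonbrain_labels: np.ndarray,
               stats: Mapping[int, tuple[float, float]],
               rng: np.random.Generator,
               fov_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Fill labeled regions outside the original field of view with
    per-label Gaussian draws; FOV voxels are untouched.

    A label present in the extension but absent from ``stats`` falls back to
    the global FOV foreground statistics, with a warning.
    """
    if nonbrain_labels.shape != image.shape:
        raise ContractError("nonbrain label map shape mismatch")
    fov = (image != 0) if fov_mask is None else fov_mask
    out = image.copy()
    fill_region = (nonbrain_labels > 0) & ~fov
    fg = image[fov & (image != 0)]
    global_stats = (float(fg.mean()), float(fg.std())) if fg.size else (0.0, 0.0)
    for label in np.unique(nonbrain_labels[fill_region]):
        if int(label) in stats:
            mean, std = stats[int(label)]
        else:
            warnings.warn(f"no stats for non-brain label {label}; using global "
                          "foreground statistics", stacklevel=2)
            mean, std = global_stats
        vox = fill_region & (nonbrain_labels == label)
        out[vox] = rng.normal(mean, std, size=int(vox.sum())) if std > 0 else mean
    return out


def apply_skull_mode(image: np.ndarray, labels: np.ndarray,
                     rng: np.random.Generator,
                     weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
                     brain_labels: Sequence[int] = (1, 2, 3),
                     nonbrain_labels: Optional[np.ndarray] = None,
                     stats: Optional[Mapping] = None):
    """Draw one of {keep, strip, neck} and apply it.

    strip zeroes every voxel outside the brain + CSF label mask; neck calls
    :func:`synth_neck` (requires a non-brain label map).  Returns
    (image, labels, mode_name).
    """
    mode = int(rng.choice(3, p=np.asarray(weights, dtype=float)))
    name = ("keep", "strip", "neck")[mode]
    if mode == 0:
        return image.copy(), labels.copy(), name
    if mode == 1:
        mask = np.isin(labels, brain_labels)
        out = np.where(mask, image, 0.0)
        return out, labels.copy(), name
    if nonbrain_labels is None:
        raise ConfigurationError("neck mode requires a non-brain label map")
    if stats is None:
        stats = compute_nonbrain_stats(image, nonbrain_labels)
    return synth_neck(image, nonbrain_labels, stats, rng), labels.copy(), name


def bias_field(shape: Sequence[int], b_b: float,
               rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias field in (0, 1].

    A 3x3x3 low-resolution volume is drawn voxel-wise from N(0, sigma^2)
    with sigma ~ U(0, b_B), upsampled to ``shape`` by cubic splines,
    exponentiated, and rescaled by its maximum so the field lies in (0, 1].
    b_B = 0 yields a spatially uniform field of ones.
    """
    if b_b < 0:
        raise ConfigurationError("b_b must be non-negative")
    sigma = rng.uniform(0.0, b_b, size=(3, 3, 3)) if b_b > 0 else np.zeros((3, 3, 3))
    low = rng.normal(0.0, 1.0, size=(3, 3, 3)) * sigma
    zoom = [s / 3 for s in shape]
    up = ndimage.zoom(low, zoom, order=3, mode="nearest", grid_mode=True)
    if up.shape != tuple(shape):  # rounding guard
        up = up[tuple(slice(0, s) for s in shape)]
    f = np.exp(up)
    return f / f.max()


def _shift_volume(arr: np.ndarray, shifts: Sequence[int]) -> np.ndarray:
    """Integer translation with zero fill (no wrap-around)."""
    out = np.zeros_like(arr)
    src, dst = [], []
    for n, s in zip(arr.shape, shifts):
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def reorient_flip_translate(image: np.ndarray, labels: np.ndarray,
                            rng: np.random.Generator,
                            reorient_prob: float = 1.0,
                            flip_prob: float = 0.5,
                            translate_prob: float = 1.0):
    """Random quarter-turn rotations, per-axis flips, bounded translation.

    The identical spatial transform is applied to image and labels; the
    translation bounds keep every foreground (nonzero) label voxel inside
    the grid.  Returns (image, labels, log).
    """
    if image.shape != labels.shape:
        raise ContractError("image and labels must be aligned")
    img, lab = image, labels
    log: dict = {"rotations": [0, 0, 0], "flips": [False] * 3,
                 "translation": [0, 0, 0]}
    if rng.random() < reorient_prob:
        for axis in (2, 1, 0):  # about z, then y, then x
            k = int(rng.integers(0, 4))
            log["rotations"][axis] = 90 * k
            if k:
                plane = _ROTATION_PLANES[axis]
                img = np.rot90(img, k, axes=plane)
                lab = np.rot90(lab, k, axes=plane)
    for axis in range(3):
        if rng.random() < flip_prob:
            log["flips"][axis] = True
            img = np.flip(img, axis=axis)
            lab = np.flip(lab, axis=axis)
    if rng.random() < translate_prob:
        fg = np.nonzero(lab > 0)
        if fg[0].size == 0:
            warnings.warn("no foreground labels; translation skipped",
                          stacklevel=2)
        else:
            shifts = []
            for axis in range(3):
                lo = -int(fg[axis].min())
                hi = lab.shape[axis] - 1 - int(fg[axis].max())
                shifts.append(int(rng.integers(lo, hi + 1)))
            log["translation"] = shifts
            if any(shifts):
                img = _shift_volume(img, shifts)
                lab = _shift_volume(lab, shifts)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab), log


def _resample_axis(arr: np.ndarray, axis: int, new_len: int) -> np.ndarray:
    """Linear resampling of one axis to ``new_len`` samples."""
    n = arr.shape[axis]
    if new_len == n:
        return arr
    x = np.linspace(0.0, n - 1.0, new_len)
    i0 = np.clip(np.floor(x).astype(int), 0, n - 2)
    w = x - i0
    a = np.moveaxis(arr, axis, -1)
    out = a[..., i0] * (1.0 - w) + a[..., i0 + 1] * w
    return np.moveaxis(out, -1, axis)


def downsample_cascade(image: np.ndarray, rng: np.random.Generator,
                       spacing_mm: float = 1.0,
                       enter_prob: float = 0.5, continue_prob: float = 0.5,
                       resolutions_mm: Sequence[float] = (2.0, 4.0),
                       log: Optional[dict] = None) -> np.ndarray:
    """Probabilistic through-plane resolution degradation.

    With probability ``enter_prob`` one random axis is linearly downsampled
    to 2 or 4 mm (equal odds); with probability ``continue_prob`` a second
    axis follows, then likewise a third.  The image is always resampled back
    to its input grid, so the output shape equals the input shape.
    """
    if log is None:
        log = {}
    log["axes"], log["factors"] = [], []
    if rng.random() >= enter_prob:
        return image.copy()
    axes = [int(a) for a in rng.permutation(3)]
    chosen = [axes[0]]
    while len(chosen) < 3 and rng.random() < continue_prob:
        chosen.append(axes[len(chosen)])
    out = image
    for axis in chosen:
        res = float(rng.choice(np.asarray(resolutions_mm, dtype=float)))
        factor = res / spacing_mm
        n = image.shape[axis]
        coarse_len = max(2, int(round(n / factor)))
        out = _resample_axis(out, axis, coarse_len)
        out = _resample_axis(out, axis, n)
        log["axes"].append(axis)
        log["factors"].append(res)
    return np.ascontiguousarray(out)


def _foreground_mask(labels: np.ndarray,
                     fg_labels: Optional[Sequence[int]]) -> np.ndarray:
    return labels > 0 if fg_labels is None else np.isin(labels, fg_labels)


def uniform_noise(image: np.ndarray, labels: np.ndarray,
                  rng: np.random.Generator,
                  fg_labels: Optional[Sequence[int]] = None) -> np.ndarray:
    """Zero-mean Gaussian background noise outside the reference labels.

    The noise standard deviation is |one draw from N(q5, q5^2)| where q5 is
    the 5th percentile of foreground intensities; foreground voxels are
    untouched.
    """
    fg = _foreground_mask(labels, fg_labels)
    if not np.any(fg):
        warnings.warn("no foreground labels; uniform noise skipped", stacklevel=2)
        return image.copy()
    q5 = float(np.percentile(image[fg], 5))
    level = abs(float(rng.normal(q5, abs(q5))))
    out = image.copy()
    bg = ~fg
    if level > 0 and np.any(bg):
        out[bg] += rng.normal(0.0, level, size=int(bg.sum()))
    return out


def nonuniform_noise(image: np.ndarray, labels: np.ndarray,
                     rng: np.random.Generator,
                     fg_labels: Optional[Sequence[int]] = None,
                     continue_prob: float = 0.5,
                     log: Optional[dict] = None) -> np.ndarray:
    """Gaussian-noise fills in random background-only rectangular prisms.

    Each prism's mean and standard deviation are drawn uniformly between the
    5th and 95th foreground percentiles; after each prism the process
    repeats with probability ``continue_prob`` (so the expected count is 2).
    Prism voxels intersecting the foreground are excluded.
    """
    if log is None:
        log = {}
    log["prisms"] = []
    fg = _foreground_mask(labels, fg_labels)
    if not np.any(fg) or not np.any(~fg):
        warnings.warn("no foreground or no background; non-uniform noise "
                      "skipped", stacklevel=2)
        return image.copy()
    q5, q95 = np.percentile(image[fg], [5, 95])
    out = image.copy()
    while True:
        origin, sides = [], []
        for n in image.shape:
            lo = min(4, n)
            hi = max(lo, n // 3)
            s = int(rng.integers(lo, hi + 1))
            sides.append(s)
            origin.append(int(rng.integers(0, n - s + 1)))
        sl = tuple(slice(o, o + s) for o, s in zip(origin, sides))
        region = np.zeros(image.shape, dtype=bool)
        region[sl] = True
        region &= ~fg
        mean = float(rng.uniform(q5, q95))
        std = abs(float(rng.uniform(q5, q95)))
        if np.any(region):
            out[region] = rng.normal(mean, std, size=int(region.sum()))
        log["prisms"].append({"origin": origin, "sides": sides,
                              "mean": mean, "std": std})
        if rng.random() >= continue_prob:
            break
    return out


def augment(image: np.ndarray, labels: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator | int,
            nonbrain_labels: Optional[np.ndarray] = None,
            nonbrain_stats: Optional[Mapping] = None):
    """Apply the full augmentation chain and return (image, labels, log).

    Order: skull mode -> bias field -> reorient/flip/translate ->
    downsampling cascade -> uniform noise -> non-uniform noise.  ``rng`` may
    be a Generator or an integer seed; with a fixed seed the output is
    bit-identical across runs, and the log (which records the seed when one
    is given) replays by re-running augment with the same seed and config.
    """
    log: dict = {}
    if isinstance(rng, (int, np.integer)):
        log["seed"] = int(rng)
        rng = np.random.default_rng(int(rng))
    img, lab, mode = apply_skull_mode(
        image, labels, rng, weights=config.skull_weights,
        brain_labels=config.brain_labels, nonbrain_labels=nonbrain_labels,
        stats=nonbrain_stats)
    log["skull_mode"] = mode
    if config.bias_b > 0:
        fieldvol = bias_field(img.shape, config.bias_b, rng)
        img = img * fieldvol
        log["bias_b"] = config.bias_b
    img, lab, geo_log = reorient_flip_translate(
        img, lab, rng, reorient_prob=config.reorient_prob,
        flip_prob=config.flip_prob, translate_prob=config.translate_prob)
    log["geometry"] = geo_log
    ds_log: dict = {}
    img = downsample_cascade(img, rng, enter_prob=config.downsample_prob,
                             continue_prob=config.downsample_continue_prob,
                             resolutions_mm=config.resolutions_mm, log=ds_log)
    log["downsample"] = ds_log
    log["uniform_noise"] = bool(rng.random() < config.uniform_noise_prob)
    if log["uniform_noise"]:
        img = uniform_noise(img, lab, rng, fg_labels=config.brain_labels)
    log["nonuniform_noise"] = bool(rng.random() < config.nonuniform_noise_prob)
    if log["nonuniform_noise"]:
        nu_log: dict = {}
        img = nonuniform_noise(img, lab, rng, fg_labels=config.brain_labels,
                               continue_prob=config.noise_continue_prob,
                               log=nu_log)
        log["nonuniform_noise_log"] = nu_log
    return img, lab, log
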
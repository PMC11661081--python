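# Methods

## Signal model

The synthesizer treats each voxel as a single isochromat. An ideal
180° inversion pulse followed by a delay TI leaves the longitudinal
magnetization at

    Mz(TI, T1) = 1 − 2·exp(−TI/T1),

so Mz sweeps the full range [−1, 1] as TI varies (the preparation is
"ideal": full initial polarization, perfect inversion). An RF pulse with
flip angle α and phase φ then rotates the magnetization by
Q(α, φ) = Rz(φ)·Rx(α)·Rz(−φ), and relaxation acts until the echo time TE
through the diagonal operator R(T1, T2, TE). The recorded value is the
signed in-phase transverse component — the projection of (Mx, My) onto the
RF phase direction — which reduces analytically to

    s = Mz(TI, T1) · sin(α) · exp(−TE/T2).

Two conventions matter:

* **Signed readout.** The dictionary stores the signed component, not the
  magnitude: the achievable signal genuinely spans [−1, 1] (inverted
  magnetization yields negative readouts), and the sign carries contrast
  information through the SVD. A `signal_magnitude` accessor exists for
  consumers that want magnitude images.
* **No phase encoding.** Field-inhomogeneity phase is not simulated; φ is a
  scalar configuration (default 0), not a sampled axis — the in-phase
  readout is independent of it, which the operator-based and closed-form
  code paths verify against each other.

Degenerate inputs: T1 = 0 or T2 = 0 is interpreted as instantaneous decay
(e^{−t/0} := 0 for t > 0) and produces signal 0. These rows are retained in
the dictionary — the grid is a full T1 × T2 cross product, and no T2 ≤ T1
constraint is imposed — so the landscape covers the whole rectangle even
where combinations are biophysically implausible.

## Dictionary grids

Default axes (all configurable):

| axis | default | count |
|------|---------|-------|
| T1   | 0–5000 ms, step 25 ms | 201 |
| T2   | 0–2000 ms, step 20 ms | 101 |
| α    | 10°–180°, step 10°    | 18  |
| TI   | uniform 1–5000 ms     | 20  |
| TE   | uniform 1–400 ms      | 10  |

giving a 20 301 × 3 600 matrix (≈ 73 M entries, ~0.6 GB, built in ~10 s).
TI and TE are spaced *uniformly* over their ranges: the inversion time is
conceptually "randomly varied without physical limitation", and uniform
spacing is the grid analogue. (Log-spacing the TI/TE axes concentrates
samples at short times, inflates the effective rank, and drops the top-10
retained energy from 99.98 % to 99.90 % — below the > 99.95 % property the
compression is designed around.) Flip angles above 180° only duplicate
columns with flipped sign (sin α is antisymmetric about 180°) and are
omitted from the default grid.

## Eigencontrast landscape

The dictionary is centered by removing the **mean contrast** — the per-row
mean over all acquisition columns, a vector μ with one entry per (T1, T2)
node — and factorised by truncated SVD. Centering along the acquisition
(sample) axis is the PCA convention with columns as samples, and it is the
only convention under which "re-add the mean when rendering" is well-typed
(the optional `add_mean` flag; off by default, since the synthesis formula
is used without it and percentile normalization downstream makes the two
choices nearly equivalent). A `center="column"` flag exposes the per-column
alternative for comparison.

For matrices above 4 M elements the factorisation goes through the
eigendecomposition of the 3 600² column Gram matrix (exact, and an order of
magnitude cheaper in time and memory than a dense SVD; the two routes agree
to 1e−8 in the tests). K = 10 retains 99.98 % of the squared singular-value
mass at the default grids. If the numerical rank falls below the requested
K, K is reduced with a warning so stored singular values stay strictly
positive; requesting K above min(rows, cols) is a configuration error.

Sampling the landscape:

* `uniform_sample` allocates r_i = round(σ_i/σ_min) linearly spaced points
  in [−1, 1] to dimension i (round half-away-from-zero; a dimension with
  r_i = 1 contributes the interval midpoint 0) and returns the Cartesian
  product. At the default grids this product is ~45 M vectors;
  `uniform_sample_subset` draws n random grid points without materialising
  it (a uniform draw over a product grid factorises per dimension).
* `stratified_class_sample` draws a seeded pool of 50 000 uniform random
  vectors (pool size is a free choice; diminishing returns beyond ~10⁴ per
  class), keeps those whose rendered WM/GM/CSF intensities satisfy the
  requested strict ordering, splits the multi-tissue score distribution of
  the survivors into h percentile bins, and returns one draw per bin.
* `threshold_class_sample` implements the consensus-labeling protocol:
  random draws from the subset of a class above the 60th score percentile.

Coefficients outside [−1, 1] are clipped with a warning (the bound is the
empirical plausibility constraint on the landscape coordinates).

## Contrast scores and classes

Tissue references default to WM (T1 850/T2 40 ms), GM (1400/70), CSF
(3000/300); subject-specific references can be estimated as per-class
medians from a segmentation. Scores follow the nearest/farthest-neighbour
construction: d_l^min and d_l^max are the min/max absolute intensity
differences between tissue l and the others, R = max_l d_l^max, and

    S_l = d_l^min / R,    S = (|L| − 1) · min_l d_l^min / R.

The grouping of the multi-tissue score (the (|L|−1) factor and the division
by R applied to the minimum distance) is the only reading under which
S ∈ [0, 1] with equality exactly at equidistant intensities. R = 0 (no
contrast at all) returns score 0 rather than dividing by zero. Both scores
are affine-invariant in intensity. Contrast classes are the six strict
orderings of (I_WM, I_GM, I_CSF), numbered 1: WM>GM>CSF, 2: WM>CSF>GM,
3: GM>WM>CSF, 4: GM>CSF>WM, 5: CSF>GM>WM, 6: CSF>WM>GM; exact ties are
*unclassifiable* (returned as `None`/0), never broken arbitrarily.

## Rendering

`lookup_image` snaps each voxel's (T1, T2) to the nearest grid node
(out-of-grid values clamp to the extremes) and multiplies the looked-up
column value by the voxel's proton density — PD scales the signal
amplitude but is not a dictionary dimension; zero-PD voxels render as 0.
Bilinear interpolation over the (T1, T2) grid is available behind a flag.
When a B1 map is present the effective flip angle is α·B1 per voxel; this
needs a per-scale column stack and is off by default.

`normalize_percentile` maps the [P1, P99] band onto [0, 1] and clips.
Percentiles are order statistics (`lower` for the low cut, `higher` for the
high cut) computed over all voxels, which makes the operation *exactly*
idempotent: after one pass ≥ 1 % of voxels sit exactly at 0 and ≥ 1 %
exactly at 1, so a second pass finds lo = 0, hi = 1 and is the identity.
(Restricting the percentiles to nonzero voxels would break idempotence,
because clipping merges the sub-P1 voxels into the zero set and shrinks the
support between passes.) Constant images map to all zeros.

## Augmentation

Fixed order: skull mode → bias field → reorientation/flip/translation →
downsampling cascade → uniform noise → non-uniform noise. Every stochastic
draw comes from one `numpy.random.Generator` and is recorded in a log;
replay is by re-running with the logged seed and config (bit-identical by
the determinism contract). Defaults: equal thirds for keep/strip/neck,
0.5 for every Bernoulli gate, b_B = 0.6 for the bias strength (the
SynthSeg-style corruption does not pin this value; 0.6 produces visually
strong but plausible shading on unit-scaled images).

Step notes:

* **Neck synthesis** fills labeled regions outside the field of view
  (default FOV: nonzero voxels) with per-label Gaussian draws from
  statistics computed inside the FOV; labels missing from the statistics
  fall back to global foreground statistics with a warning. Atlas fitting
  is out of scope — the non-brain label map is a user-supplied input (the
  phantom can generate a schematic one).
* **Bias field**: 3×3×3 low-resolution volume, per-voxel σ ~ U(0, b_B) and
  value ~ N(0, σ²), cubic-spline upsampled, exponentiated and divided by
  its maximum — exp alone is not bounded by 1, so the rescale enforces the
  (0, 1] range. The field is strictly positive, hence the zero set of the
  image is preserved.
* **Translation** bounds are computed from the foreground-label bounding
  box so no labeled voxel ever leaves the grid; quarter-turn rotations and
  flips are pure index permutations applied identically to image and
  labels.
* **Downsampling cascade**: enter with probability 0.5; axes are drawn
  without replacement; each downsampled axis drops to 2 or 4 mm with equal
  odds (linear resampling down and back up to the original grid), and a
  further axis follows with probability 0.5. Branch law: 50 % untouched,
  25 % one axis, 12.5 % two, 12.5 % three.
* **Noise**: the uniform-noise level is |N(q5, q5²)| with q5 the foreground
  5th percentile (the absolute value guards the rare negative draw, since
  the draw is used as a standard deviation); non-uniform noise fills
  random rectangular prisms (sides uniform in [4, axis/3] voxels — no size
  law is prescribed, this keeps prisms visible but sub-dominant), with
  prism∩foreground voxels excluded and a 0.5 continuation probability
  (expected prism count 2). Noise is applied after resampling back to the
  original grid; the seeded log lets users re-order if they need the
  alternative reading.

## Consistency metrics

The volume-weighted Dice weights per-label overlap by the label's voxel
share in the *first* argument, treated as the reference/consensus — the
measure is intentionally asymmetric and tested as such. Majority voting
uses the per-voxel mode with ties resolved to the smallest label id
(deterministic; `scipy.stats.mode` implements exactly this rule). PDM is
(1/J)·(J − #votes for the majority)·100 % per voxel; summaries are
mean ± sd over voxels whose majority label is non-background (noise
classes excluded); a subject-first reducer can be had by summarising per
stack and averaging. LVV is the mean absolute relative deviation of a
label's volume across images, in percent; labels with zero mean volume are
reported as NaN. The consensus pipeline condenses fine labels through a
user-supplied map (every observed label must be mapped — unmapped labels
are listed in the error), votes, then assigns label 17 to in-mask unlabeled
nonzero-intensity voxels and 18 to nonzero voxels outside the mask; ids
19/20 are reserved for the background-noise classes. Connected-component
post-processing uses 26-connectivity (the most permissive 3-D
neighbourhood; the choice only matters for diagonal bridges).

## Phantom

Nested superellipsoid shells (exponent 2.5, mildly anisotropic semi-axes)
with a smooth low-frequency radial perturbation (amplitude 6 %) give a
non-spherical head: WM core, GM and CSF shells, optional fat-like
skull/scalp shell (T1 380 ms, T2 110 ms, PD 0.9). Tissue values carry 3 %
voxel-wise Gaussian jitter (typical intra-tissue spread of quantitative
maps) and the parameter maps are blurred by a 1-voxel Gaussian to emulate
partial volume; labels store the pre-smoothing assignments. Default grid
64³ at 1 mm for tests (192³ recommended for demo-quality images). The
optional neck extension appends zero-intensity slices carrying schematic
bone/muscle/skin labels for the neck-synthesis augmentation.

What the phantom does *not* emulate: cortical folding, realistic
partial-volume mixtures of more than two tissues, pathology, B0/B1
inhomogeneity of real acquisitions, or myelination-driven parameter drift.
A green end-to-end test therefore establishes that the physics, sampling,
rendering and metric code are mutually consistent on ideal anatomy — not
that the synthesizer matches any scanner's output.

Boundary-perturbed label stacks flip each boundary voxel (6-neighbourhood)
to a fixed, deterministically chosen neighbouring label with a stated
probability, independently per copy — so expected disagreement statistics
follow a binomial law that the tests verify against exhaustive outcome
enumeration.

## Seeds and reproducibility

Every stochastic routine takes an explicit seed or Generator. The CLI
derives per-stage child seeds as `SeedSequence((seed, stage_id))` with a
fixed stage-id table, so any stage can be reproduced in isolation from the
global seed; batch synthesis spawns one child stream per image. All child
seeds are reduced below 2³¹.

## Known limitations

* Single-isochromat physics: no diffusion, perfusion, magnetization
  transfer, flow, or multi-compartment relaxation; no k-space, gradient or
  coil effects; signal phase deferred.
* Nearest-node lookup quantises tissue values to the grid step (25/20 ms by
  default); interpolation is available but not the default because the
  dictionary is intentionally index-addressed.
* The stratified sampler characterises a class by three representative
  tissue points; contrasts that reorder only at extreme proton densities
  are not distinguished (empirically the class regions are robust to
  realistic PD ratios).
* The exact acquisition grid behind the original 122 M-entry dictionary is
  not recoverable from its stated ranges; the defaults here reproduce the
  compression property, not the entry count.
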
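# Methods

This note documents the models, conventions and numerical choices behind
`gliaquant`, and what the synthetic phantoms do and do not establish.

## Conventions

Arrays are indexed `(z, y, x)`. The `y` axis is the apicobasal tissue
axis with apical at `y = 0` and basal at `y = max`; every module
(subregion anchoring, zonation profiles, soma-band detection, orientation
profiles) depends on this. Calibration is `(dx, dy, dz)` in µm, read from
ImageJ TIFF metadata or supplied explicitly; operations that report
physical units refuse to run uncalibrated rather than assuming 1 µm/px.
All pipelines are deterministic: the same input, parameters and seed give
bit-identical outputs.

## Subregion standardization

A single manual line (basal start at the endfeet, apical end) defines the
rotation that maps the apicobasal axis onto `y` with apical up. The
rotation angle is `−90° − atan2(vy, vx)` for the line vector `v`,
applied about the image center with bilinear interpolation and zero fill
(background stays black for downstream masking). The bounding box is
`width_um` wide (default 60 µm), horizontally centred on the rotated
apical endpoint, and runs from that endpoint down over the line length
plus a basal extension `sigma_um` (default 10 µm, covering the underlying
vasculature and retinal curvature). Overflow handling: a box past the
right edge is shifted to `xT − bT`, past the left edge to `x = 0`; if the
basal extension leaves the frame the output is truncated to the line
length and the report records that sigma could not be attached. The z
dimension is cut to a centred substack of `depth_um` (default 10 µm); too
few slices is a hard error naming the file. Output xy shape is therefore
a function of line length, parameters and calibration only — the property
that makes group-wise overlays and comparisons valid.

Open choices made here: rotation about the image center (not the line
midpoint) and horizontal centring of the box on the apical endpoint.
Both are recorded in the per-file report for auditability; users
comparing against other implementations should check these two
conventions first.

## Zonation profiles

Stacks are min–max converted to 8-bit, maximum-projected along `z` and
then along `x`, leaving `p(y) = max_{z,x} I` (a mean reducer is available
for saturation-prone data and is recorded in the profile metadata).
Profiles are rescaled to a common 1920-sample axis by linear
interpolation (the 2D bilinear rescale degenerates to 1D on a profile);
endpoints are preserved and interpolation cannot overshoot the input
range. Group aggregation reports per-position mean and sample sd
(ddof = 1). Measurements: `I_N` = image height in µm, `R_N = I_N −
sigma_um` — retina height net of the basal extension added during
standardization.

## Nyquist calculator and theoretical PSF

With half-angle `α = arcsin(NA/n)`, the Nyquist voxel spacing is
`λ_ex / (8 n sin α)` laterally and `λ_ex / (4 n (1 − cos α))` axially,
truncated to whole nanometres. For the reference acquisition (NA 1.3,
λ_ex 488 nm, n 1.338) this gives 46/46/119 nm.

The theoretical PSF is the scalar-diffraction (Born–Wolf) widefield
intensity PSF: `h(r, z) = |∫₀¹ J₀(k·NA·r·ρ) exp(−i·k·NA²·z·ρ²/(2n)) ρ dρ|²`
with `k = 2π/λ_em`, evaluated by 96-point Gauss–Legendre quadrature on a
voxel grid of odd shape (peak on-grid) and normalized to sum 1. Its
lateral FWHM reproduces the Airy-pattern value 0.51 λ_em/NA within a few
percent when finely sampled. Sampling the kernel at voxels much coarser
than Nyquist produces a near-delta kernel; a warning says so.

## Deconvolution

The imaging model is `y = Hx + n`. All spatial-domain operators use the
exact adjoint pair — zero-padded convolution and zero-padded correlation —
so that adjoint identities hold to float precision; this is what makes
Richardson–Lucy conserve total flux exactly (≤ 10⁻⁶ relative in tests)
for a normalized PSF.

* **Regularized Inverse Filter:** `X = H*Y / (|H|² + λ|L|²)` in the
  Fourier domain, `L` the 3×3×3 discrete Laplacian, λ default 10⁻¹⁸
  (numerically almost unregularized). FFTs run on zero-padded arrays of
  the next fast regular size. Spectral coefficients with zero gain are
  suppressed with a warning (the λ = 0 problem is ill-posed there).
* **Landweber:** projected gradient descent from `x₀ = 0`, step γ = 1.5,
  15 iterations, non-negativity clamp each step. For a delta PSF the
  recursion has the closed form `x_M = y(1 − (1−γ)^M)`, i.e. a relative
  deviation of exactly 0.5¹⁵ ≈ 3.05·10⁻⁵ at the defaults — used as an
  oracle. A norm blow-up beyond 10⁶× the data norm raises, naming γ.
* **Richardson–Lucy:** multiplicative updates from `x₀ = y` under the
  Poisson noise model, 1 or 5 iterations typical; zero denominators are
  guarded at 10⁻¹² of the data maximum. More iterations sharpen but can
  erode fine protrusions — both regimes are exposed.

CNR = (µ_s − µ_ns)/σ_bg and SNR = µ_s/σ_bg from circular ROIs of 3–5 µm
diameter (signal on structure, non-signal inside tissue, background
outside); σ_bg is the population sd of the background ROI. The SNR form
µ_s/σ_bg is this package's documented definition.

## Segmentation

The cytosolic recipe chains simple-ratio bleach correction (slice z
scaled by `mean(slice₀)/mean(slice_z)`, background 0), per-stack min–max
8-bit conversion, 3D median filtering over the discrete Euclidean ball of
radius 2 (shrinking window at borders), Otsu thresholding computed from
the middle slice's 256-bin histogram and applied to the whole stack,
another radius-2 median, majority-vote binarization, and keep-largest-
region (26-connectivity, ties to the first label in scan order). The
middle slice is `floor(Nz/2)`. Otsu maximizes `ω₀ω₁(µ₀−µ₁)²` with class 0
= intensities ≤ t and ties resolved to the lowest t; it is verified
against exhaustive search. Because the 8-bit step is per-stack min–max,
the recipe is invariant to global linear rescaling of the input
(bit-exact for power-of-two gains; rounding ties can flip under arbitrary
affine maps).

The membrane recipe first applies a membrane-enhancement filter — 3D
gradient magnitude blended (α = 0.5) with an opposing-gradient-pair
radial-symmetry accumulation over distances up to 10 voxels (subsampled
by 2, distance-tempered by 1 + d/10) — then the core recipe, and fills
3D cavities (background components not 6-connected to the border)
instead of keep-largest smoothing. The enhancement filter is a documented
approximation of the interactive membrane pre-filters common in the
field; the tested contract is the final mask's properties (cavities
filled, shells solidified), not numeric parity of the intermediate image.
Foreground/background connectivity is the standard 26/6 pairing.

Simple-ratio bleach correction assumes every slice contains comparable
tissue content — true for standardized substacks cut inside the retina.
On stacks with empty slices the per-slice rescaling distorts the
intensity scale and a global threshold fails; the phantom generator
therefore emulates full-depth tissue (below).

## Feature extraction

* `V_N` = foreground voxels × voxel volume; `VC_N` = 100 × foreground /
  total voxels.
* `S_N` counts foreground voxels with a 6-neighbour background voxel
  (the image border counts as background), reported as a volume —
  orientation and voxel-size normalization of a true surface area are
  deliberately avoided.
* Skeletons come from topology-preserving 3D thinning (Lee-class, via
  scikit-image). Voxels are classified by 26-neighbour count: 1 =
  endpoint, 2 = slab, > 2 = junction; 26-connected junction voxels merge
  into one junction node. Branches are traced between nodes through slab
  chains; pure cycles (e.g. a ring skeleton) are traced and counted
  separately. `L_N` uses the voxel-count convention (skeleton voxels ×
  lateral voxel size) while branch lengths sum diagonal-aware Euclidean
  steps in µm — the two conventions differ slightly and are both kept
  deliberately.
* `EDM` is the exact anisotropy-aware Euclidean distance transform;
  voxels beyond the image border are not background, so structures
  touching the frame are not artificially thinned. `T_N` is the mean EDM
  over skeleton voxels — a radius, not a diameter.
* `N_N` crops to a soma ROI (a user rectangle, or an automatic y-band of
  ± 12.5 µm around the soma layer, located as the apicobasal row where
  the object is thickest — the per-row EDM maximum, searched in the
  central 25–75 % of the height because the apical lattice and basal
  endfoot sheet can rival the somas in mass but not in thickness). Inside
  the ROI, h-maxima of the lightly smoothed EDM (dynamics ≥ 0.5 µm, which
  merges discrete-ellipsoid plateau bumps into their parent soma) seed a
  watershed on the inverted EDM, and particles of ≥ 8 voxels are counted.

## Orientation analysis

Images (2D maximum projections of standardized stacks, optionally
size-normalized by a 0.35 % percentile stretch plus top-aligned zero
padding to the largest image in the batch) are tiled into 100-px windows
with 50 % overlap. Each tile is Hann-windowed; the power spectrum's
second-moment tensor about DC gives the dominant spectral direction, and
the real-space fibre orientation is its perpendicular, folded into
[0°, 180°). Constant or spectrally isotropic tiles carry no defined
orientation and are marked invalid (retaining them with an undefined
angle would be meaningless). The order parameter of window i is the
nematic statistic `S_i = mean_j cos 2(θ_i − θ_j)` over valid neighbours
within Chebyshev radius 3; windows at or below mean intensity 5 are
treated as background and excluded. `S = 1` is perfect alignment; an
isotropic angle field gives `S → 0`. Apicobasal profiles are row means of
valid S values, apical first. On analytic stripe fields the recovered
angle is exact to well under a degree and S = 1; on randomly oriented
tiles |mean S| stays near 0.

## Phantoms

`geometric_fixture` rasterizes boxes, spheres, cylinders, Y-tubes, slabs,
tori and stripe/ramp/banded intensity patterns with analytic ground truth
where closed-form (e.g. a 5³ box has exactly 125 voxels and 98 surface
voxels).

`make_mg_phantom` builds a radial-glia-like tissue in a default
120 × 240 × 20-voxel field at (0.5, 0.5, 0.5) µm — the scale of a
standardized subregion. Each of `n_cells` cells has a vertical trunk
(radius 3 voxels), a soma ellipsoid in a mid band with seeded y-jitter, a
basal endfoot pad, and lateral branches in an inner-plexiform band. Cells
are joined by a continuous apical cap plate and a basal endfoot sheet
spanning the full substack depth — radial glia tile into a connected
epithelium-like sheet, and the connectedness also means keep-largest-
region retains the whole tissue and every slice carries content (the
regime bleach correction assumes). Neighbouring cells sit at seeded,
different depths. Branches lie on fixed y-levels with one direction per
level, so protrusions never fuse tip-to-tip and the true endpoint count
is stable under the random draws; the `maturity` parameter (0–1) raises
the branch count from 4 to 8 per cell and thins branches from radius 3
to 2 — more endpoints, lower mean thickness, the direction of
developmental elaboration. The apical plate is rasterized solid: at this
resolution honeycomb fenestrations are 2–3 voxels wide and their skeleton
is dominated by rasterization artefacts rather than biology.

`apply_imaging_model` simulates acquisition: PSF blur, geometric
per-slice decay `(1 − z_decay)^z`, seeded Gaussian and/or Poisson noise,
clipping to the input dtype. The end-to-end study condition used in the
acceptance checks is a 5-cell phantom imaged with the theoretical PSF
sampled at the phantom's own voxel size, 10-gray-level Gaussian noise on
a foreground/background of 200/20 (SNR ≈ 20, comfortably above the ≥ 5
regime the recipes target) and 2 %/slice depth decay.

What the phantoms do *not* emulate: sub-voxel fine protrusions,
reporter-specific texture (cytosolic granularity, membrane-only
labelling), anisotropic optical sectioning worse than the stated PSF,
tissue curvature, and inter-animal variability. Passing the phantom
suite therefore demonstrates that the pipeline's geometry, topology and
photometry are implemented correctly and deterministically — not that
segmentation accuracy on real stacks will match the phantom numbers.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems: 1000 histograms for the Otsu oracle, 100 masks up to 16³ for
the EDM oracle, 250² stripe fields for orientation, one 120 × 240 × 20
phantom (twice, for the determinism check) for the end-to-end recovery.
These sizes give exact or tightly-bounded oracles while keeping the whole
suite in the half-minute range on one CPU.

## Known limitations

* The membrane-enhancement filter approximates, not reproduces, the
  interactive plugins used in common practice; only final-mask properties
  are contracted.
* `L_N`'s voxel-count convention under-measures diagonal paths relative
  to the Euclidean branch lengths; use `BL_N` and branch sums when path
  metric length matters.
* Simple-ratio bleach correction requires tissue in every slice (see
  above); it is not a flat-field correction.
* The Fourier-domain inverse filter with λ → 0 amplifies noise at
  frequencies where the OTF is small; it is kept primarily as the
  fast/linear baseline, with Richardson–Lucy as the workhorse.
* Cell counting assumes somata are the thickest structures in the ROI;
  heavily gliotic morphologies with soma-scale varicosities would need a
  rectangle ROI instead of the automatic band.
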
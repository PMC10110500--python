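# gliaquant

Quantitative 3D morphometry of radial glia — Müller glia in particular —
from confocal fluorescence z-stacks of the retina.

Müller glia span the retina from the outer limiting membrane (apical) to
the basal endfeet at the inner surface, and their shape changes are a
sensitive readout of development and disease. Quantifying that shape from
confocal stacks is hard to do reproducibly by hand: stacks arrive at
arbitrary orientations and fields of view, image quality varies with depth
and reporter, and most morphological features only make sense after the
tissue axis has been standardized. `gliaquant` is a modular pipeline that
makes the whole chain scriptable and deterministic:

1. **subregion** — standardize a stack to a comparable 3D ROI from one
   manual line selection (basal start at the endfeet, apical end), with
   rotation to the apicobasal *y*-axis, a 60 µm default box, a 10 µm basal
   *σ* extension and a 10 µm z-substack; plus 90° pre-rotation and
   left/right-eye mirroring.
2. **zonation** — collapse a stack to a 1D apicobasal intensity profile
   `p(y) = max_{z,x} I(z, y, x)`, rescale profiles to a common 1920-sample
   axis, aggregate groups (mean ± sd), and derive image height *I_N* and
   retina height *R_N = I_N − σ*.
3. **restoration** — Nyquist sampling calculator (for NA 1.3, λ_ex 488 nm,
   n 1.338 it returns 46/46/119 nm), a Born–Wolf scalar-diffraction
   theoretical PSF, and three deconvolution solvers for the imaging model
   *y = Hx + n*: Regularized Inverse Filter
   `X = H*Y / (|H|² + λ|L|²)` (λ = 10⁻¹⁸, L = 3D Laplacian), projected
   Landweber `x_{k+1} = P₊[x_k + γHᵀ(y − Hx_k)]` (γ = 1.5, 15 iterations)
   and Richardson–Lucy `x_{k+1} = x_k · Hᵀ(y / Hx_k)` (1 or 5 iterations),
   plus ROI-based CNR = (µ_s − µ_ns)/σ_bg and SNR = µ_s/σ_bg.
4. **segmentation** — deterministic binary-mask recipes for cytosolic
   reporters (simple-ratio bleach correction → 8-bit → 3D median r = 2 →
   Otsu threshold from the middle slice → median → keep largest region)
   and membrane reporters (edge/symmetry enhancement → core recipe →
   3D hole filling).
5. **quantify** — the feature set per mask: height, volume *V_N*, volume
   coverage *VC_N* (%), surface *S_N* and *S:V_N*, 3D-thinning skeleton
   network length *L_N*, junctions *J_N*, endpoints *EP_N*, mean branch
   length *BL_N*, EDM-based average thickness *T_N* (Euclidean distance
   map sampled at the centreline — a radius), and cell count *N_N* via
   distance-transform watershed in an automatically detected soma band.
6. **orientation** — alignment analysis by windowed FFT: per-tile
   orientation θ ∈ [0°, 180°) from the power spectrum's second-moment
   tensor (100 px windows, 50 % overlap) and the nematic order parameter
   S = ⟨cos 2Δθ⟩ over a radius-3 window neighborhood, with background
   masking and apicobasal order profiles.
7. **phantoms** — deterministic geometric fixtures and a seeded Müller-
   glia-like phantom generator with ground truth, so the entire pipeline
   is testable without any raw data.

Everything is exposed both as a Python library (arrays are `(z, y, x)`,
apical at `y = 0`, calibration `(dx, dy, dz)` in µm mandatory for physical
measurements) and as a batch-capable CLI (`gliaquant subregion | zonation |
deconv | segment | quantify | orient | phantom | split-channels |
pipeline`).

## Worked example

Simulate an acquisition of a 5-cell phantom (PSF blur, 2 %/slice depth
attenuation, Gaussian read noise), segment it, and extract the feature
set:

```python
import gliaquant as gq

params = gq.AcquisitionParams(na=1.3, lambda_ex=488, lambda_em=520, ri=1.338)
print("Nyquist (dx, dy, dz) nm:", gq.nyquist_sampling(params))

grid, truth, gt = gq.make_mg_phantom(seed=7, n_cells=5)
psf = gq.theoretical_psf(
    gq.AcquisitionParams(na=1.1, lambda_ex=488, lambda_em=520),
    voxel_size=(0.5, 0.5, 0.5), shape=(3, 5, 5),
)
image = gq.apply_imaging_model(grid, psf=psf, gaussian_sd=10.0, z_decay=0.02, seed=7)

mask = gq.segment_cytosolic(image)
jaccard = (mask.data & truth.data).sum() / (mask.data | truth.data).sum()
print(f"segmentation Jaccard vs truth: {jaccard:.3f}")

report = gq.full_report(image, mask, filename="phantom_seed7")
for key, value in report.to_row().items():
    print(f"  {key:>10}: {value if not isinstance(value, float) else round(value, 2)}")
```

which prints:

```
Nyquist (dx, dy, dz) nm: (46, 46, 119)
segmentation Jaccard vs truth: 0.857
        file: phantom_seed7
   height_um: 120.0
         V_N: 7855.12
        VC_N: 10.91
         S_N: 3545.62
        SV_N: 0.45
         L_N: 745.5
         J_N: 30
        EP_N: 24
        BL_N: 13.76
         T_N: 1.5
         N_N: 5
```

Reading: the 120 × 120 × 20-voxel (60 × 60 × 10 µm) standardized field
holds ≈ 7855 µm³ of glial signal (10.9 % coverage); its skeleton has 24
endpoints and 30 junction clusters with 13.8 µm mean branch length; the
average local radius along the centreline is 1.5 µm; and the watershed
recovers all 5 cell bodies. Segmentation overlaps the known ground truth
at Jaccard 0.857.

The same chain runs from the shell:

```sh
gliaquant phantom --preset mg --seed 7 --out ph/
gliaquant segment ph/phantom.tif --out masks/
gliaquant quantify masks/phantom.tif --out features.csv
```

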
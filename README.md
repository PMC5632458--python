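# epifat

Semiautomatic epicardial fat segmentation and quantification for cardiac CT.

Epicardial fat — the visceral adipose tissue between the myocardium and the
pericardium — is a recognized marker of cardiovascular risk, and its volume
is routinely estimated from contrast chest CT.  Fully manual delineation is
slow and poorly reproducible; `epifat` implements a slice-by-slice pipeline
that needs a single user interaction per patient (one seed point on a fat
patch) plus a handful of expert-set control angles:

1. **Preprocessing** — histogram-adaptive tone mapping onto [0, 1], then
   whole-heart ROI extraction by grayscale *opening by reconstruction*
   (disk diameter `ms1`), per-slice Otsu thresholding, largest-component
   selection and dilation (disk diameter `ms2`).
2. **Seeded fuzzy clustering** — R×R patches sampled on a stride grid in
   the ROI are summarized by texture features `u = (u₁, u₂)` (patch mean
   and biased variance) and soft-partitioned by fuzzy c-means
   (memberships `μ_c(k) ∈ [0,1]`, `Σ_c μ_c(k) = 1`).  The epicardial-fat
   cluster `c^res` is the one whose membership-pondered mean feature is
   closest (squared Euclidean) to the feature `u*` of the user-marked
   reference patch; patch memberships are averaged back onto pixels.
3. **Referent-ellipse fitting** — the soft cluster is summarized by a
   geometric prior `(x_c, y_c, φ₀, a, b)`: center of gravity from
   luminance-and-membership weighted image moments, orientation from PCA
   of the diagonally loaded covariance of the soft point cloud, and
   semi-axes from a bounded least-squares fit of the parametric ellipse
   in the rotated frame, `B_l < a, b < B_u`.
4. **Postfiltering** — α-cut defuzzification (`μ ≥ α`), then retention of
   pixels whose polar angle lies in the per-slice control arc `[φ₁, φ₂]`
   (linearly interpolated between expert-labelled slices) and whose radial
   distance to the referent ellipse is at most `ε` px, followed by a
   morphological closing.
5. **Evaluation** — Dice coefficient `D(A,B) = 2|A∩B|/(|A|+|B|)`, physical
   fat volume, normalized volume (mm³ per kg body weight) and relative
   volume error.

Shipped defaults are the cross-validated optima
`(ms1, ms2, α, ε) = (40, 20, 0.7, 20)` with axis bounds `(200, 450)` px on
512-wide slices; all pixel-valued parameters rescale automatically for
other matrix sizes.

A synthetic cardiac phantom (`epifat.phantom`) renders 12-bit slices with
dark lung fields, a bright textured heart ellipse, a fat ring with a known
epicardial arc, bone distractors and Gaussian noise — with exact
ground-truth masks — so the whole pipeline is testable without patient
data.

## Worked example

```python
import numpy as np
from epifat import (PhantomSpec, PipelineConfig, SeedPoint, dice,
                    generate_volume, run_pipeline)

spec = PhantomSpec(n_slices=4)            # drifting 4-slice phantom
vol = generate_volume(spec)
res = run_pipeline(PipelineConfig(), vol.slices,
                   SeedPoint(0, spec.seed_point(0)),   # one seed point
                   vol.control_angles(L=3))            # 3 labelled slices

print(f"slices segmented: {sum(r.ok for r in res.reports)}/{len(res.reports)}")
e = res.reports[0].ellipse
print(f"slice 0 referent ellipse: center=({e.center[0]:.1f}, {e.center[1]:.1f}), "
      f"phi0={np.degrees(e.phi0):.1f} deg, a={e.a:.1f} px, b={e.b:.1f} px")
print(f"fat volume: {res.volume.volume_mm3:.0f} mm^3 ({res.volume.voxel_count} voxels)")
print(f"3D Dice vs ground truth: {dice(res.mask3d, vol.fat_masks):.3f}")
print(f"normalized volume at 80 kg: {res.volume.normalized(80.0)['nv_mm3_per_kg']:.2f} mm^3/kg")
```

Output:

```
slices segmented: 4/4
slice 0 referent ellipse: center=(255.9, 256.2), phi0=17.3 deg, a=224.2 px, b=200.0 px
fat volume: 10895 mm^3 (87161 voxels)
3D Dice vs ground truth: 0.862
normalized volume at 80 kg: 136.19 mm^3/kg
```

The fitted ellipse tracks the phantom's generating fat mid-line
(center (256, 256), 17.2°, a = 230, b = 205 px); the Dice of 0.86 reflects
the method's systematic few-pixel under-segmentation at the rim edges
(see `docs/methods.md`).

## Command line

```bash
# synthetic series with ground truth and a manifest of generating parameters
epifat phantom --out ph/ --n-slices 8

# segment a DICOM directory (or NIfTI volume)
epifat segment --input ph/series --seed-slice 0 --seed-row 93 --seed-col 391 \
               --controls controls.csv --weight 80 --out seg/

# compare against a reference mask volume
epifat evaluate --pred seg/fat_mask.nii.gz --truth ph/fat_truth.nii.gz
```

`controls.csv` holds `slice_index, phi1_deg, phi2_deg` rows; angles on
unlabeled slices are interpolated.  The segment command writes the fat
mask (NIfTI), per-slice ellipse parameters (CSV), QC overlays (PNG) and a
volume report (JSON).

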
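# contourvar

Multi-observer contour-agreement analysis for 3D segmentations.

When several clinicians delineate the same structure — a radiotherapy
target, a cardiac segment, the spinal canal — on one scan, how much do they
disagree, and where? `contourvar` quantifies interobserver variability of
co-registered binary masks the way delineation-QA studies report it:

- **Median structure**: the set of voxels delineated by at least 50% of the
  observers, with its surface extracted as the sub-voxel 0.5-isosurface of
  the per-voxel coverage fraction.
- **Surface-distance variation**: for every median-surface point, the
  signed perpendicular distance (positive outside, negative inside) to each
  observer's contour surface, with magnitudes clipped at 20 mm; the SD of
  those distances per point (the local SD map), and the overall statistic

  RMS-SD = sqrt( mean over surface points p of SD(p)^2 ), reported in cm.

- **Volume statistics**: per-observer volumes (voxel count x voxel volume),
  mean +/- SD and range, and the median-structure volume, in cm^3.
- **Dice overlap**: pairwise Dice 2|A∩B|/(|A|+|B|) for all observer pairs
  (mean +/- SD), and the generalized multi-observer Dice
  2 Σ_pairs |A_i∩A_j| / Σ_pairs (|A_i|+|A_j|).

Because real multi-observer delineations are rarely shareable, the package
includes a simulator: star-convex phantoms (sphere, tube, blob) perturbed
per observer by a global radial offset (systematic error) plus a smooth,
band-limited random surface field with controllable pointwise SD and
angular correlation length. The simulator's noise SD maps directly onto
the RMS-SD the pipeline measures, so the whole chain is testable without
patient data.

## Worked example

Simulate ten observers delineating a 20 mm sphere with 2 mm correlated
surface noise, then analyse the cohort:

```bash
contourvar simulate --phantom sphere --radius-mm 20 --grid-size 96 \
    --n-obs 10 --sigma-sys 0 --sigma-rand 2 --corr-mm 15 --seed 1 \
    --out demo/sim
contourvar analyze --case-id demo --out demo/out --export-sd-mesh \
    --masks demo/sim/obs01.nii.gz ... --masks demo/sim/obs10.nii.gz
```

which prints

```
demo: RMS-SD 0.171 cm, Dice mean 0.846, median structure 34.55 cm^3
```

Read it as: the per-point SD of observer surface distances, pooled over the
median surface, is 1.71 mm — close to the 2 mm noise that was injected
(the residual gap is the nearest-distance shrink on curved, noisy surfaces;
see `docs/methods.md`). The average pairwise Dice of 0.85 and the
median-structure volume of 34.55 cm^3 (analytic sphere: 33.5 cm^3)
summarise overlap and consensus size. `demo/out/` holds the full report as
CSV + JSON (with a provenance block sufficient to reproduce every number)
and `demo_sd_map.ply`, the median surface with the local SD (cm) as a
per-vertex scalar channel for rendering disagreement hot-spots.

The same analysis is available as a library:

```python
from contourvar import (PhantomSpec, VolumeGrid, ObserverErrorModel,
                        make_phantom, simulate_cohort, analyze_case)

grid = VolumeGrid(shape=(96, 96, 96), spacing=(1, 1, 1))
ref = make_phantom(PhantomSpec(kind="sphere", grid=grid,
                               center_mm=(47.5,) * 3, radius_mm=20.0))
cohort = simulate_cohort(ref, ObserverErrorModel(0.0, 2.0, 15.0, seed=1), 10)
report = analyze_case(cohort, case_id="demo")
print(report.rms_sd_cm, report.dice_mean, report.generalized_dice)
```

Real data enters through `read_mask` (NIfTI, one file per observer, nonzero
= inside, identical grid required) or through the per-slice polygon JSON
format (`read_polygon_json`), and batches run via
`contourvar batch --manifest manifest.csv --out results/`.

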
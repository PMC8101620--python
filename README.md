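# bonemicrokit

Quantification of peripheral cortical and trabecular bone microstructure
from high-resolution volumetric CT, together with the statistical
framework used to validate such measurements (accuracy calibration
against a gold standard, repeat-scan reproducibility, group comparison,
and power analysis).

It is written for researchers working on CT-based assessment of bone
quality — osteoporosis and fracture-risk imaging at peripheral sites
such as the distal tibia — who need the full chain from a calibrated
density image to a per-subject panel of microstructural measures, and a
synthetic-phantom harness that validates every step against known
ground truth.

## What it computes

Given a bone mineral density (BMD) image of the distal tibia (Hounsfield
units are first mapped to mg/cc by rod-phantom calibration, then
resampled to 150 μm isotropic voxels by windowed-sinc interpolation),
the pipeline derives a subject-specific anatomic frame — the distal
**end plateau** (the slice just proximal to the first cross-section
containing a 2-D hole in the filled bone), and the **tibial axis** (an
MSE-optimal line through the deep filled-bone voxels) — and measures:

| measure | unit | meaning |
|---|---|---|
| Tb.vBMD | mg/cc | mean volumetric BMD over the ROI |
| Tb.tBMD | mg/cc | partial BMD contributed by transverse trabeculae |
| Tb.NA | mm²/mm³ | trabecular network area density (skeleton face area per volume) |
| Tb.PW | μm | mean local plate width from tensor-scale analysis |
| Tb.Th | μm | mean trabecular thickness (star-line minimum intercept) |
| Tb.Sp | μm | mean marrow spacing (star-line on the marrow phase) |
| EI | – | erosion index: curve-type / surface-type skeleton voxel counts |
| SMI | – | structure model index = 6·V·S′/S² under simulated thickening |
| Cb.Th | mm | mean cortical wall thickness at the medial surface |
| Cb.Poro | – | cortical pore volume fraction |

Trabecular measures are computed at the 4–6 % percent-of-tibial-length
site over the inner (60 % peel) and outer (30–60 % peel annulus) ROIs;
cortical measures at the 14–16 % site.  The trabecular network is
represented fuzzily — a membership ramp between marrow and bone
reference densities — and skeletonized by fuzzy-distance-ordered,
topology-preserving thinning, so partial-volume trabeculae are not
destroyed by binarization.

The statistics module provides Pearson/OLS accuracy calibration,
one-way random-effects ICC with exact F confidence bounds, pooled-t
group comparisons with Cohen's d, covariate-adjusted least-squares
means (effect size = LS-mean difference / √MSE), exact noncentral-t
power for the two-sample t-test, and Spearman association.

## Worked example

```bash
python examples/tibia_pipeline.py
```

generates a distal-tibia-like phantom (cortical shell with 15 % pore
fraction around a mixed plate/rod lattice) and runs the full pipeline.
Output (abbreviated):

```
     roi measure       value
   inner tb_vbmd  339.105864
   inner   tb_th  406.773415
   inner   tb_sp  569.860361
   inner      ei    0.272597
   inner     smi    3.032237
cortical   cb_th    1.768268
cortical cb_poro    0.133296

plateau slice   35 (generator truth 35)
cortical truth: wall 1.75 mm, porosity 0.143
```

The detected plateau matches the generator's ground truth exactly;
`cb_th` recovers the 1.75 mm wall within a tenth of a voxel and
`cb_poro` the seeded pore fraction within 0.01.  An SMI near 3 and a
moderate EI reflect the predominantly rod-like synthetic lattice.  The
other examples cover calibration (`calibrate_and_resample.py`), ideal
structures (`structure_metrics.py`), reproducibility
(`reproducibility_icc.py`) and group statistics
(`group_comparison_power.py`).

A thin command-line interface wraps the same functions:

```bash
bonemicrokit phantom --kind tibia_like --seed 7 --out vol.nii.gz --truth truth.json
bonemicrokit run --in vol.nii.gz --tibial-length 100 --out metrics.csv
```

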
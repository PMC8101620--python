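"""Density calibration from a rod phantom, then isotropic resampling.

Builds a synthetic calibration phantom whose rods lie exactly on a known
HU -> mg/cc line, fits the calibration by OLS over mean rod intensities,
applies it to the phantom volume, and resamples to 150 um isotropic
voxels with windowed-sinc interpolation.
"""

from bonemicrokit import apply_calibration, fit_density_calibration, resample_isotropic
from bonemicrokit.phantoms import make_calibration_phantom

volume_hu, spec, truth = make_calibration_phantom(noise_sd_hu=15.0, seed=1)
line = fit_density_calibration(volume_hu, spec)
print(f"fitted slope     {line.slope:8.4f}   (true {truth['slope']})")
print(f"fitted intercept {line.intercept:8.2f}   (true {truth['intercept']})")
print(f"Pearson r        {line.r:8.4f}")

bmd = apply_calibration(volume_hu, line)
iso = resample_isotropic(bmd, 0.15)
print(f"calibrated volume: units={bmd.units.value}, "
      f"resampled {bmd.shape} @ {bmd.spacing[0]} mm -> {iso.shape} @ {iso.spacing[0]} mm")
# The slope/intercept recover the scanner's HU->density law despite noise;
# r close to 1 confirms the rods are well modeled by a single affine map.
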
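"""HU → BMD calibration from a density rod phantom.

A calibration phantom contains rods of known hydroxyapatite-equivalent
density.  Scanning the phantom and regressing known density on the mean
observed CT number inside each rod yields an affine map from Hounsfield
units to mg/cc, applied voxelwise to subject scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, stats

from .volume import ConfigurationError, DensityVolume, UnitError, Units


class DegenerateFitError(ValueError):
    """Calibration regression has no unique solution (zero HU variance)."""


@dataclass(frozen=True)
class RodSpec:
    """One calibration rod: a cylinder along z with known density.

    ``center_mm`` is the (z, y, x) physical center; the rod is treated as
    a sphere-of-influence cylinder of ``radius_mm`` spanning
    ``half_length_mm`` axially.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    density_mg_cc: float
    half_length_mm: float = 5.0


@dataclass(frozen=True)
class PhantomSpec:
    """Rod layout of a density-calibration phantom."""

    rods: tuple[RodSpec, ...]

    def __post_init__(self) -> None:
        if len(self.rods) < 2:
            raise ConfigurationError("phantom needs at least 2 rods")
        if len({r.density_mg_cc for r in self.rods}) < 2:
            raise ConfigurationError("phantom needs at least 2 distinct densities")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        """Load a rod layout from YAML (keys: rods -> center_mm, radius_mm, density_mg_cc)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rods = tuple(
            RodSpec(
                center_mm=tuple(r["center_mm"]),
                radius_mm=float(r["radius_mm"]),
                density_mg_cc=float(r["density_mg_cc"]),
                half_length_mm=float(r.get("half_length_mm", 5.0)),
            )
            for r in raw["rods"]
        )
        return cls(rods=rods)


@dataclass(frozen=True)
class CalibrationLine:
    """Affine HU → mg/cc map fitted by ordinary least squares.

    ``density = slope * HU + intercept``; ``r`` is the Pearson correlation
    of the fit over the rods used.
    """

    slope: float
    intercept: float
    r: float
    n_rods: int

    def __post_init__(self) -> None:
        if self.n_rods < 2:
            raise ConfigurationError("calibration needs >= 2 rods")
        if not np.isfinite(self.slope):
            raise ConfigurationError("slope must be finite")
        if abs(self.r) > 1 + 1e-12:
            raise ConfigurationError("|r| must be <= 1")


def _rod_mask(v: DensityVolume, rod: RodSpec, erode_voxels: int = 1) -> np.ndarray:
    """Boolean mask of a rod region, eroded to drop partial-volume rims."""
    zz, yy, xx = np.meshgrid(
        *[np.arange(n) * s + o for n, s, o in zip(v.shape, v.spacing, v.origin)],
        indexing="ij",
    )
    cz, cy, cx = rod.center_mm
    in_plane = (yy - cy) ** 2 + (xx - cx) ** 2 <= rod.radius_mm**2
    axial = np.abs(zz - cz) <= rod.half_length_mm
    mask = in_plane & axial
    if erode_voxels > 0 and mask.any():
        eroded = ndimage.binary_erosion(mask, iterations=erode_voxels)
        if eroded.any():
            mask = eroded
    return mask


def fit_density_calibration(
    phantom_volume: DensityVolume,
    spec: PhantomSpec,
    erode_voxels: int = 1,
) -> CalibrationLine:
    """Fit the OLS line mapping mean rod HU to known rod density.

    Each rod region is eroded by ``erode_voxels`` before averaging so the
    summary is not biased by partial-volume voxels at the rod rim.

    Raises
    ------
    ConfigurationError
        If a rod region falls outside the volume or is empty.
    DegenerateFitError
        If all rods have the same mean HU.
    """
    if phantom_volume.units is not Units.HU:
        raise UnitError("calibration phantom must be in HU")
    mean_hu, densities = [], []
    for rod in spec.rods:
        mask = _rod_mask(phantom_volume, rod, erode_voxels)
        if not mask.any():
            raise ConfigurationError(f"rod at {rod.center_mm} lies outside the volume")
        mean_hu.append(float(phantom_volume.values[mask].mean()))
        densities.append(rod.density_mg_cc)
    x = np.asarray(mean_hu)
    y = np.asarray(densities)
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero HU variance across rods")
    slope, intercept = np.polyfit(x, y, 1)
    r = 1.0 if np.ptp(y) == 0 else float(stats.pearsonr(x, y)[0])
    return CalibrationLine(slope=float(slope), intercept=float(intercept), r=r, n_rods=len(spec.rods))


def apply_calibration(v: DensityVolume, c: CalibrationLine) -> DensityVolume:
    """Map an HU volume to mg/cc voxelwise; geometry unchanged.

    Out-of-range densities are kept as-is — downstream fuzzy membership
    construction clamps instead.
    """
    if v.units is not Units.HU:
        raise UnitError("apply_calibration expects an HU volume")
    return v.with_values(c.slope * v.values + c.intercept, units=Units.MG_CC)
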
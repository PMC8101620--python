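"""Subject-specific anatomy frame and standardized ROI generation.

Bone-measure ROIs are anchored to two anatomic landmarks so that sites are
comparable across subjects of different size and positioning:

* the **distal end plateau** — found as the slice just proximal to the
  first cross-section (tracing proximal → distal) whose filled-bone mask
  contains a 2-D hole, i.e. where the articular rim opens up;
* the **tibial axis** — the mean-squared-error optimal line through the
  deep (60 % peel) filled-bone voxels proximal to the 8 % site, used to
  realign the bone with the image z-axis.

Axial "pseudo-cylindrical" ROIs are then slabs between two percent-of-
tibial-length sites, optionally intersected with percent peels.  A percent
peel keeps, per axial slice, the voxels whose 2-D distance to the mask
boundary is at least the stated fraction of that slice's maximum inscribed
distance.

Convention: the proximal direction is +z (increasing slice index); a
configuration override is available where image metadata says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import ConfigurationError, DensityVolume


class SegmentationFailureError(RuntimeError):
    """Bone segmentation produced an empty or unusable mask."""


class PlateauNotFoundError(RuntimeError):
    """No 2-D hole found in any slice; end plateau undetectable."""


class AxisFitError(RuntimeError):
    """Voxel cloud too degenerate for a stable line fit."""


class EmptyRoiError(RuntimeError):
    """Requested ROI contains no voxels."""


class SamplingError(RuntimeError):
    """Could not place the requested spherical ROIs inside the region."""


@dataclass
class RoiMask:
    """Boolean voxel mask aligned to a :class:`DensityVolume` grid.

    ``site_range_pct`` / ``peel_range_pct`` record provenance for axial
    bands; ``kind`` is ``axial_band``, ``sphere`` or ``filled_bone``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    kind: str = "filled_bone"
    site_range_pct: tuple[float, float] | None = None
    peel_range_pct: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * float(np.prod(self.spacing))

    def intersect(self, other: "RoiMask") -> "RoiMask":
        return RoiMask(self.voxels & other.voxels, self.spacing, kind=self.kind,
                       site_range_pct=self.site_range_pct, peel_range_pct=self.peel_range_pct)


@dataclass
class AnatomyFrame:
    """Anatomic reference frame of one distal-tibia scan."""

    plateau_slice: int
    tibial_length_mm: float
    axis_direction: np.ndarray  # unit vector (z, y, x), distal -> proximal
    realign_transform: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(self.axis_direction)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ConfigurationError("axis_direction must be a unit vector")


# ----------------------------------------------------------------- filling


def _close_edt(bw: np.ndarray, r_mm: float, spacing) -> np.ndarray:
    """Morphological closing with a Euclidean ball, via distance transforms.

    The erosion threshold carries a quarter-voxel correction: voxel-
    center distance fields place the dilation boundary a fraction of a
    voxel beyond r, so eroding at ``dist > r`` alone grows the set by
    about half a voxel per closing while a half-voxel correction shrinks
    it by about as much; the quarter-voxel compromise is unbiased on
    convex bodies to within a few tenths of a percent.
    """
    corr = 0.25 * float(min(spacing))
    pad = int(np.ceil(r_mm / min(spacing))) + 1  # room for the dilation reach
    padded = np.pad(bw, pad, constant_values=False)
    dilated = ndimage.distance_transform_edt(~padded, sampling=spacing) <= r_mm
    eroded = ndimage.distance_transform_edt(dilated, sampling=spacing) > r_mm + corr
    core = tuple(slice(pad, -pad) for _ in range(3))
    return eroded[core] | bw  # closing is extensive; the correction may nick edges


def fill_bone_volume(
    v: DensityVolume,
    bone_threshold: float = 300.0,
    closing_radii_mm: tuple[float, ...] = (0.6, 1.2),
) -> RoiMask:
    """Compute the filled-in bone volume of the largest bone.

    Thresholds at ``bone_threshold`` (mg/cc), applies multiscale
    morphological closing to bridge the trabecular lattice with the
    cortex, keeps the largest 26-connected component, and fills internal
    cavities.  Hole filling treats both axial image boundaries as closed
    (the scan truncates the shaft there), so the marrow cavity fills,
    while the open articular rim at the distal end keeps its 2-D hole
    because the air below the bone end connects it to the lateral
    background.
    """
    bw = v.values >= bone_threshold
    if not bw.any():
        raise SegmentationFailureError("no voxels above bone_threshold")
    for r_mm in sorted(closing_radii_mm):
        bw = _close_edt(bw, r_mm, v.spacing)
    labels, n = ndimage.label(bw, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise SegmentationFailureError("closing removed all foreground")
    largest = np.argmax(ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))) + 1
    bw = labels == largest
    # cap both axial faces so scan-truncated cavities are fillable
    cap = np.ones((1,) + bw.shape[1:], dtype=bool)
    capped = np.concatenate([cap, bw, cap], axis=0)
    filled = ndimage.binary_fill_holes(capped)[1:-1]
    return RoiMask(filled, v.spacing, kind="filled_bone")


# ----------------------------------------------------------------- plateau


def _slice_has_hole(slice_mask: np.ndarray) -> bool:
    """True if background enclosed by foreground exists in the 2-D slice.

    Background is 4-connected, foreground 8-connected (standard digital-
    topology pairing): a hole is a 4-component of background not touching
    the slice border.
    """
    if not slice_mask.any():
        return False
    bg = ~slice_mask
    labels, n = ndimage.label(bg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    if n == 0:
        return False
    border = np.zeros_like(bg)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border & bg])) - {0}
    return n > len(border_labels)


def locate_end_plateau(filled: RoiMask, exclude_top_mm: float = 3.0) -> int:
    """Slice index of the distal end plateau.

    Traces slices from proximal (+z) to distal; the plateau is the slice
    immediately proximal to the first slice containing a 2-D hole.  The
    topmost ``exclude_top_mm`` are skipped: the scan (or a realignment)
    truncates the shaft there, which can leave spurious 2-D holes, and
    the end plateau is by definition distal.
    """
    if not filled.voxels.any():
        raise SegmentationFailureError("filled mask is empty")
    nz = filled.voxels.shape[0]
    start = nz - 1 - int(np.ceil(exclude_top_mm / filled.spacing[0]))
    if start < 0:  # volume shorter than the margin: trace everything
        start = nz - 1
    for z in range(start, -1, -1):
        if _slice_has_hole(filled.voxels[z]):
            return min(z + 1, nz - 1)
    raise PlateauNotFoundError("no slice contains a 2-D hole")


# -------------------------------------------------------------------- axis


def compute_peel(filled: RoiMask, peel_pct: float) -> RoiMask:
    """Percent peel by per-slice 2-D distance-transform thresholding.

    Keeps voxels whose in-plane Euclidean distance to the mask boundary is
    at least ``peel_pct``/100 of that slice's maximum inscribed distance.
    Peel 0 is the identity; peels are monotone (larger peel ⊆ smaller).
    """
    if not 0 <= peel_pct <= 100:
        raise ConfigurationError("peel_pct must be in [0, 100]")
    out = np.zeros_like(filled.voxels)
    sy, sx = filled.spacing[1], filled.spacing[2]
    for z in range(filled.voxels.shape[0]):
        sl = filled.voxels[z]
        if not sl.any():
            continue
        dist = ndimage.distance_transform_edt(sl, sampling=(sy, sx))
        out[z] = sl & (dist >= (peel_pct / 100.0) * dist.max())
    return RoiMask(out, filled.spacing, kind=filled.kind,
                   peel_range_pct=(peel_pct, 100.0))


def fit_tibial_axis(
    filled: RoiMask,
    plateau_slice: int,
    tibial_length_mm: float,
    fit_proximal_of_pct: float = 8.0,
    peel_pct: float = 60.0,
    min_slices: int = 10,
    exclude_top_mm: float = 2.0,
) -> AnatomyFrame:
    """Fit the tibial long axis by a mean-squared-error optimal line.

    The fit region is the ``peel_pct`` peel of the filled bone proximal to
    the ``fit_proximal_of_pct`` percent-of-length site; the topmost
    ``exclude_top_mm`` of the scan are excluded because the field of view
    truncates the shaft obliquely there.  The MSE-optimal line through a
    point cloud passes through its centroid along the first principal
    direction; the sign is canonicalized distal → proximal (+z).
    """
    dz = filled.spacing[0]
    z0 = plateau_slice + int(np.ceil(fit_proximal_of_pct / 100.0 * tibial_length_mm / dz))
    nz = filled.voxels.shape[0]
    z1 = nz - int(np.ceil(exclude_top_mm / dz))
    if z1 - z0 < min_slices:
        raise AxisFitError(f"fewer than {min_slices} slices proximal to the {fit_proximal_of_pct}% site")
    sub = RoiMask(filled.voxels.copy(), filled.spacing, kind=filled.kind)
    sub.voxels[:z0] = False
    sub.voxels[z1:] = False
    peeled = compute_peel(sub, peel_pct)
    # MSE line through the per-slice centroids of the peel region: the
    # centroid of each cross-section lies on the shaft center line, so the
    # fit is unbiased by the elongation of oblique cross-sections
    zs, cys, cxs = [], [], []
    for z in range(z0, z1):
        sl = peeled.voxels[z]
        if not sl.any():
            continue
        yy, xx = np.nonzero(sl)
        zs.append(z * filled.spacing[0])
        cys.append(yy.mean() * filled.spacing[1])
        cxs.append(xx.mean() * filled.spacing[2])
    if len(zs) < min_slices:
        raise AxisFitError("peel region too small for a line fit")
    zs_a = np.asarray(zs)
    if np.ptp(zs_a) == 0:
        raise AxisFitError("degenerate (planar) voxel cloud")
    slope_y = np.polyfit(zs_a, np.asarray(cys), 1)[0]
    slope_x = np.polyfit(zs_a, np.asarray(cxs), 1)[0]
    axis = np.array([1.0, slope_y, slope_x])
    axis /= np.linalg.norm(axis)
    frame = AnatomyFrame(
        plateau_slice=plateau_slice,
        tibial_length_mm=tibial_length_mm,
        axis_direction=axis / np.linalg.norm(axis),
    )
    frame.realign_transform = _rotation_to_z(frame.axis_direction)
    return frame


def _rotation_to_z(axis_zyx: np.ndarray) -> np.ndarray:
    """4×4 rigid transform rotating ``axis`` onto +z (zyx convention)."""
    a = np.asarray(axis_zyx, dtype=float)
    z = np.array([1.0, 0.0, 0.0])  # +z in (z, y, x) ordering
    v = np.cross(a, z)
    c = float(np.dot(a, z))
    T = np.eye(4)
    if np.linalg.norm(v) < 1e-12:
        if c < 0:
            T[:3, :3] = np.diag([-1.0, -1.0, 1.0])
        return T
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    T[:3, :3] = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    return T


def realign_to_axis(
    v: DensityVolume, frame: AnatomyFrame, interpolator: str = "linear"
) -> DensityVolume:
    """Resample the volume so the fitted tibial axis is parallel to +z.

    Rotation is about the volume's physical center.  Linear
    interpolation is the default: windowed-sinc preserves edges more
    sharply but its ringing perturbs the fuzzy membership around thin
    trabeculae, which destabilizes the topological class counts;
    ``"sinc"`` and ``"nearest"`` (for label maps) are also available.
    """
    import SimpleITK as sitk

    R = frame.realign_transform[:3, :3]
    img = v.to_sitk()
    center_mm = [
        o + (n - 1) * s / 2.0 for o, n, s in zip(reversed(v.origin), img.GetSize(), img.GetSpacing())
    ]
    tf = sitk.AffineTransform(3)
    # sitk works in (x, y, z); our rotation matrix is (z, y, x)
    R_xyz = R[::-1, ::-1].T  # inverse (output->input) in xyz ordering
    tf.SetMatrix(R_xyz.ravel())
    tf.SetCenter(center_mm)
    interp = {
        "sinc": sitk.sitkLanczosWindowedSinc,
        "linear": sitk.sitkLinear,
        "nearest": sitk.sitkNearestNeighbor,
    }[interpolator]
    out = sitk.Resample(img, img, tf, interp, float(v.values.min()))
    return v.with_values(sitk.GetArrayFromImage(out).astype(np.float64))


# -------------------------------------------------------------------- ROIs


def make_axial_roi(
    frame: AnatomyFrame,
    filled: RoiMask,
    site_pct: tuple[float, float],
    peel: str | None = None,
) -> RoiMask:
    """Axial slab between two percent-of-tibial-length sites.

    ``site_pct`` = (lo, hi) percent of tibial length measured proximally
    from the end plateau.  ``peel`` selects the radial sub-region:
    ``None`` (whole filled bone, the cortical analysis band),
    ``"inner60"`` (deeper than the 60 % peel) or ``"annulus30-60"`` (the
    ring between the 30 % and 60 % peels).
    """
    lo, hi = site_pct
    if not (0 <= lo < hi <= 100):
        raise ConfigurationError("site_pct must satisfy 0 <= lo < hi <= 100")
    dz = filled.spacing[0]
    z_lo = frame.plateau_slice + int(np.ceil(lo / 100.0 * frame.tibial_length_mm / dz))
    z_hi = frame.plateau_slice + int(np.floor(hi / 100.0 * frame.tibial_length_mm / dz))
    slab = np.zeros_like(filled.voxels)
    slab[z_lo : z_hi + 1] = filled.voxels[z_lo : z_hi + 1]
    if peel is None:
        vox, peel_range = slab, None
    elif peel == "inner60":
        inner = compute_peel(filled, 60.0)
        vox, peel_range = slab & inner.voxels, (60.0, 100.0)
    elif peel == "annulus30-60":
        p30 = compute_peel(filled, 30.0)
        p60 = compute_peel(filled, 60.0)
        vox, peel_range = slab & p30.voxels & ~p60.voxels, (30.0, 60.0)
    else:
        raise ConfigurationError(f"unknown peel {peel!r}")
    roi = RoiMask(vox, filled.spacing, kind="axial_band",
                  site_range_pct=(lo, hi), peel_range_pct=peel_range)
    if roi.count == 0:
        raise EmptyRoiError(f"axial ROI at site {site_pct} peel {peel} is empty")
    return roi


def sphere_mask(shape, spacing, center_vox, diameter_mm) -> np.ndarray:
    """Boolean ball of the given physical diameter centered on a voxel."""
    r = diameter_mm / 2.0
    grids = np.meshgrid(*[(np.arange(n) - c) * s for n, c, s in zip(shape, center_vox, spacing)],
                        indexing="ij")
    return sum(g * g for g in grids) <= r * r


def sample_spherical_rois(
    region: RoiMask,
    n: int,
    diameter_mm: float,
    seed: int,
    allow_overlap: bool = True,
    max_retries: int = 200,
) -> list[RoiMask]:
    """Randomly place ``n`` spheres fully inside ``region``.

    Centers are drawn uniformly over the voxels whose distance to the
    region boundary admits the full sphere; deterministic for fixed seed.
    With ``allow_overlap=False``, rejection sampling enforces
    center-to-center distance ≥ one diameter.
    """
    if n == 0:
        return []
    r = diameter_mm / 2.0
    dist = ndimage.distance_transform_edt(region.voxels, sampling=region.spacing)
    feasible = np.argwhere(dist >= r)
    if len(feasible) == 0:
        raise SamplingError("region cannot contain a sphere of the requested diameter")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_retries * n:
            raise SamplingError(f"could not place {n} spheres after {tries} tries")
        c = feasible[rng.integers(len(feasible))]
        if not allow_overlap:
            if any(np.linalg.norm((c - c0) * region.spacing) < diameter_mm for c0 in centers):
                continue
        centers.append(c)
    return [
        RoiMask(sphere_mask(region.voxels.shape, region.spacing, c, diameter_mm),
                region.spacing, kind="sphere")
        for c in centers
    ]
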
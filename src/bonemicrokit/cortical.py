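"""Cortical bone segmentation, thickness and porosity at the 14–16 % site.

The cortical shell is the dense connected layer between the periosteal
(outer) surface of the filled bone and the endosteal surface facing the
marrow cavity.  Segmentation is slice-wise: high-density voxels are
closed morphologically, the ring component is kept, and low-density
components enclosed by the ring that are not the marrow cavity are the
intracortical pores.  Thickness is the mean local wall thickness — twice
the Euclidean distance to the wall boundary evaluated on the wall's
medial surface — and porosity is the pore volume fraction of the shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .anatomy import RoiMask, SegmentationFailureError
from .volume import DensityVolume


@dataclass(frozen=True)
class CbMetrics:
    """Cortical outcome measures: thickness (mm) and porosity (fraction)."""

    cb_th: float
    cb_poro: float

    def __post_init__(self) -> None:
        if not self.cb_th > 0:
            raise ValueError("cb_th must be positive")
        if not 0 <= self.cb_poro <= 1:
            raise ValueError("cb_poro must be in [0, 1]")


def segment_cortex(
    v: DensityVolume,
    band: RoiMask,
    cortical_threshold: float = 600.0,
    closing_radius_vox: int = 2,
    min_pore_voxels: int = 2,
    max_discontinuous_fraction: float = 0.25,
) -> tuple[RoiMask, RoiMask]:
    """Segment the cortical shell and its enclosed pores within a band.

    Per axial slice of the band: threshold at ``cortical_threshold``
    (mg/cc) and keep the dense components that touch the periosteal
    boundary (the outer contour of the filled bone) — this separates the
    cortical ring from trabecular structures in the cavity without any
    scale assumption.  A closing with a disk of ``closing_radius_vox``
    regularizes the endosteal margin.  Low-density regions enclosed by
    the ring that are not connected to the marrow cavity are the pores;
    pores smaller than ``min_pore_voxels`` (3-D, after stacking) are
    discarded as noise.

    Raises
    ------
    SegmentationFailureError
        If no voxel clears the threshold, or the shell is missing on more
        than ``max_discontinuous_fraction`` of the band's slices.
    """
    zs = np.where(band.voxels.any(axis=(1, 2)))[0]
    if len(zs) == 0:
        raise SegmentationFailureError("band contains no slices")
    dense = (v.values >= cortical_threshold) & band.voxels
    if not dense.any():
        raise SegmentationFailureError("no density contrast above cortical_threshold")
    disk = np.zeros((2 * closing_radius_vox + 1,) * 2, dtype=bool)
    yy, xx = np.mgrid[-closing_radius_vox : closing_radius_vox + 1,
                      -closing_radius_vox : closing_radius_vox + 1]
    disk[yy * yy + xx * xx <= closing_radius_vox**2] = True
    eight = np.ones((3, 3), dtype=bool)

    cortex = np.zeros_like(band.voxels)
    pores = np.zeros_like(band.voxels)
    bad_slices = 0
    for z in zs:
        sl = dense[z]
        support = band.voxels[z]
        if not sl.any():
            bad_slices += 1
            continue
        # periosteal contour of the filled bone on this slice
        contour = support & ~ndimage.binary_erosion(support, structure=eight)
        labels, n = ndimage.label(sl, structure=eight)
        peri_ids = np.unique(labels[contour & sl])
        peri_ids = peri_ids[peri_ids != 0]
        if len(peri_ids) == 0:
            bad_slices += 1
            continue
        ring = np.isin(labels, peri_ids)
        closed = ndimage.binary_closing(ring, structure=disk)
        inner = ndimage.binary_fill_holes(closed)
        enclosed = inner & ~closed
        if not enclosed.any():
            bad_slices += 1  # solid cross-section: no marrow cavity -> not a shell
            cortex[z] = ring
            continue
        cortex[z] = ring
        # pore candidates: low-density voxels inside the filled ring;
        # components connected to the marrow cavity (the enclosed
        # component not separated from the interior) are not pores
        cand = inner & ~sl
        clabels, ncc = ndimage.label(cand, structure=eight)
        if ncc:
            four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
            bg_labels, nb = ndimage.label(enclosed, structure=four)
            sizes = ndimage.sum_labels(np.ones_like(bg_labels), bg_labels, range(1, nb + 1))
            cavity = bg_labels == (np.argmax(sizes) + 1)
            cav_ids = np.unique(clabels[cavity & cand])
            pores[z] = cand & ~np.isin(clabels, cav_ids[cav_ids != 0]) & ~ndimage.binary_dilation(
                ~inner, structure=eight
            )
    if bad_slices > max_discontinuous_fraction * len(zs):
        raise SegmentationFailureError(
            f"cortical shell missing/solid on {bad_slices}/{len(zs)} slices"
        )
    if pores.any():
        plabels, np_ = ndimage.label(pores, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = ndimage.sum_labels(np.ones_like(plabels), plabels, range(1, np_ + 1))
        keep = np.isin(plabels, np.where(sizes >= min_pore_voxels)[0] + 1)
        pores = pores & keep
    return (RoiMask(cortex, v.spacing, kind="filled_bone"),
            RoiMask(pores, v.spacing, kind="filled_bone"))


def cortical_thickness(cortex: RoiMask, pores: RoiMask | None = None) -> float:
    """Cb.Th (mm): mean local wall thickness on the shell's medial surface.

    The wall (cortex plus enclosed pores, so pores do not bias the
    distance field) is distance-transformed per slice; the medial surface
    is the 2-D skeleton of the wall, and thickness is the mean of twice
    the distance there.
    """
    wall = cortex.voxels if pores is None else (cortex.voxels | pores.voxels)
    if not wall.any():
        raise SegmentationFailureError("empty cortical shell")
    sy, sx = cortex.spacing[1], cortex.spacing[2]
    vals = []
    for z in range(wall.shape[0]):
        sl = wall[z]
        if not sl.any():
            continue
        dist = ndimage.distance_transform_edt(sl, sampling=(sy, sx))
        medial = skeletonize(sl)
        if medial.any():
            vals.append(2.0 * dist[medial])
    if not vals:
        raise SegmentationFailureError("no medial surface found")
    return float(np.mean(np.concatenate(vals)))


def cortical_porosity(cortex: RoiMask, pores: RoiMask) -> float:
    """Cb.Poro: pore volume fraction of the cortical shell."""
    nc, np_ = cortex.count, pores.count
    if nc == 0:
        raise SegmentationFailureError("empty cortical shell")
    return np_ / (nc + np_)
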
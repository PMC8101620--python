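"""Tensor-scale analysis: local plate width, plate/rod and orientation
classification, and the density measures Tb.vBMD, Tb.tBMD and Tb.PW.

At every skeleton voxel the *tensor scale* is the largest ellipsoid
centered there that fits inside the local structure.  It is found by
casting antipodal ray pairs to the fuzzy boundary (membership < 0.5 by
trilinear interpolation) and least-squares fitting a centered quadric to
the ray endpoints.  The sorted semi-axes a1 ≥ a2 ≥ a3 summarize local
geometry: a3 is the half-thickness, 2·a2 the local plate width, and the
a2/a3 anisotropy separates plate-like from rod-like trabeculae.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .anatomy import AnatomyFrame, EmptyRoiError, RoiMask
from .skeleton import MembershipVolume, SkeletonMap
from .volume import ConfigurationError, DensityVolume


@dataclass
class LocalStructure:
    """Per-skeleton-voxel tensor-scale summary.

    All arrays are aligned with the owning :class:`SkeletonMap`'s
    ``coords``.  ``semi_axes_mm[:, 0] >= [:, 1] >= [:, 2]``;
    ``a1_dir`` / ``a3_dir`` are the unit eigenvectors (z, y, x) of the
    largest and smallest semi-axes.
    """

    semi_axes_mm: np.ndarray      # (n, 3)
    a1_dir: np.ndarray            # (n, 3)
    a3_dir: np.ndarray            # (n, 3)
    max_scale_mm: float

    @property
    def plate_width_mm(self) -> np.ndarray:
        return 2.0 * self.semi_axes_mm[:, 1]


def _hemisphere_directions(n: int) -> np.ndarray:
    """Deterministic spiral point set on the upper hemisphere (z >= 0)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(k / n)              # polar angle in [0, pi/2)
    theta = np.pi * (1 + 5**0.5) * k    # golden-angle azimuth
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )  # (z, y, x)


def tensor_scale_at(
    s: SkeletonMap,
    m: MembershipVolume,
    max_scale_mm: float = 3.0,
    n_ray_pairs: int = 45,
    boundary_level: float = 0.5,
) -> LocalStructure:
    """Fit the local-structure ellipsoid at every skeleton voxel.

    For each of ``n_ray_pairs`` antipodal directions the ray is marched
    from the voxel center in steps of half a voxel until the
    trilinearly-interpolated membership drops below ``boundary_level`` or
    ``max_scale_mm`` is reached; the pair's half-length is the smaller of
    the two sides, which keeps a centered ellipsoid inside the structure.
    A symmetric quadric x^T A x = 1 is least-squares fitted to the
    endpoints and its eigensystem gives semi-axes and directions.
    Semi-axes are clamped to [half voxel, max_scale_mm]; widths at the
    ``max_scale`` cap are reported as capped, not an error.
    """
    spacing = np.asarray(m.spacing)
    if max_scale_mm <= min(spacing):
        raise ConfigurationError("max_scale_mm must exceed the voxel size")
    n = len(s)
    if n == 0:
        return LocalStructure(np.empty((0, 3)), np.empty((0, 3)), np.empty((0, 3)), max_scale_mm)
    dirs = _hemisphere_directions(n_ray_pairs)
    step = min(spacing) / 2.0
    n_steps = int(np.ceil(max_scale_mm / step))
    t = (np.arange(1, n_steps + 1)) * step                      # (T,)
    # sample offsets in voxel units: (P, T, 3)
    offsets = dirs[:, None, :] * t[None, :, None] / spacing[None, None, :]

    vals = m.values
    semi = np.empty((n, 3))
    a1d = np.empty((n, 3))
    a3d = np.empty((n, 3))
    eps = 1e-9
    for i, (z, y, x) in enumerate(s.coords):
        center = np.array([z, y, x], dtype=float)
        pts_pos = (center[None, None, :] + offsets).reshape(-1, 3)
        pts_neg = (center[None, None, :] - offsets).reshape(-1, 3)
        mv_pos = ndimage.map_coordinates(vals, pts_pos.T, order=1, mode="constant", cval=0.0)
        mv_neg = ndimage.map_coordinates(vals, pts_neg.T, order=1, mode="constant", cval=0.0)
        inside_pos = (mv_pos.reshape(len(dirs), n_steps) >= boundary_level)
        inside_neg = (mv_neg.reshape(len(dirs), n_steps) >= boundary_level)

        def first_exit(inside: np.ndarray) -> np.ndarray:
            out = ~inside
            has_exit = out.any(axis=1)
            idx = np.where(has_exit, out.argmax(axis=1), n_steps)
            return idx * step  # ray length to boundary (capped)

        lengths = np.minimum(first_exit(inside_pos), first_exit(inside_neg))
        lengths = np.clip(lengths, step, max_scale_mm)
        # LS fit of the radial quadratic form u^T A u = 1/L(u)^2 over the
        # unit directions: every ray pair contributes with equal weight,
        # so long capped rays cannot dominate the fit, and ideal slabs
        # and rods are represented exactly
        uz, uy, ux = dirs[:, 0], dirs[:, 1], dirs[:, 2]
        design = np.stack([uz * uz, uy * uy, ux * ux, 2 * uz * uy, 2 * uz * ux, 2 * uy * ux], axis=1)
        coef, *_ = np.linalg.lstsq(design, 1.0 / lengths**2, rcond=None)
        A = np.array([
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ])
        w, vecs = np.linalg.eigh(A)
        w = np.maximum(w, 1.0 / max_scale_mm**2)                 # clamp axes to <= max_scale
        axes = 1.0 / np.sqrt(np.maximum(w, eps))                 # ascending eigvals -> descending axes
        axes = np.clip(axes, min(spacing) / 2.0, max_scale_mm)
        semi[i] = axes
        a1d[i] = vecs[:, 0] / np.linalg.norm(vecs[:, 0])
        a3d[i] = vecs[:, 2] / np.linalg.norm(vecs[:, 2])
    ls = LocalStructure(semi, a1d, a3d, max_scale_mm)
    s.width_mm = ls.plate_width_mm.copy()
    return ls


def classify_plate_rod(ls: LocalStructure, ratio_threshold: float = 2.0) -> np.ndarray:
    """Label each skeleton voxel ``plate`` or ``rod`` by a2/a3 anisotropy.

    Plate-like voxels have in-plane extent well beyond their thickness
    (a2/a3 ≥ ``ratio_threshold``); rods are locally isotropic in
    cross-section.
    """
    ratio = ls.semi_axes_mm[:, 1] / np.maximum(ls.semi_axes_mm[:, 2], 1e-12)
    return np.where(ratio >= ratio_threshold, "plate", "rod")


def classify_orientation(
    ls: LocalStructure,
    frame: AnatomyFrame,
    plate_rod: np.ndarray,
    angle_threshold_deg: float = 45.0,
) -> np.ndarray:
    """Label each skeleton voxel ``transverse`` or ``longitudinal``.

    Rule table (axis = tibial long axis, assumed realigned to +z):

    ==========  ==========================  ==============================
    morphology  local reference direction    transverse when
    ==========  ==========================  ==============================
    rod         dominant direction (a1)     a1 within threshold of the
                                            axial plane (angle from axis
                                            > threshold)
    plate       plate normal (a3)           normal within threshold of the
                                            axis (a horizontal plate is a
                                            transverse element)
    ==========  ==========================  ==============================
    """
    axis = np.asarray(frame.axis_direction, dtype=float)
    out = np.empty(len(plate_rod), dtype=object)
    cos_thr = np.cos(np.deg2rad(angle_threshold_deg))
    cos_a1 = np.abs(ls.a1_dir @ axis)
    cos_a3 = np.abs(ls.a3_dir @ axis)
    rods = plate_rod == "rod"
    out[rods] = np.where(cos_a1[rods] >= cos_thr, "longitudinal", "transverse")
    out[~rods] = np.where(cos_a3[~rods] >= cos_thr, "transverse", "longitudinal")
    return out.astype(str)


def propagate_class_to_support(
    s: SkeletonMap,
    m: MembershipVolume,
    labels: np.ndarray,
    select: str,
    support_threshold: float = 0.25,
) -> RoiMask:
    """Dilate a skeleton-voxel class back onto the structure support.

    Every support voxel (membership ≥ threshold) inherits the class of
    its nearest skeleton voxel (Euclidean, via the feature transform), so
    class-wise masses partition the structure exactly.  The default
    threshold 0.25 extends the support into partial-volume voxels so
    that the mass bookkeeping captures bone spread across boundaries.
    """
    support = m.values >= support_threshold
    skel_mask = s.mask
    if not skel_mask.any():
        return RoiMask(np.zeros_like(support), m.spacing, kind="filled_bone")
    label_grid = np.zeros(s.shape, dtype=np.int8)
    sel = labels == select
    coords_sel = s.coords[sel]
    coords_other = s.coords[~sel]
    label_grid[tuple(coords_sel.T)] = 1
    if len(coords_other):
        label_grid[tuple(coords_other.T)] = 2
    _, (iz, iy, ix) = ndimage.distance_transform_edt(
        ~skel_mask, sampling=m.spacing, return_indices=True
    )
    nearest = label_grid[iz, iy, ix]
    return RoiMask(support & (nearest == 1), m.spacing, kind="filled_bone")


# -------------------------------------------------------------- densities


def tb_vbmd(v: DensityVolume, roi: RoiMask) -> float:
    """Tb.vBMD (mg/cc): mean BMD over the ROI."""
    if roi.count == 0:
        raise EmptyRoiError("Tb.vBMD over an empty ROI")
    return float(v.values[roi.voxels].mean())


def tb_tbmd(v: DensityVolume, roi: RoiMask, transverse_support: RoiMask) -> float:
    """Tb.tBMD (mg/cc): ROI BMD contributed by transverse trabeculae.

    Sum of BMD over ROI ∩ transverse support divided by the *full* ROI
    voxel count, i.e. a partial density that adds with the longitudinal
    part to the structural density — hence tb_tbmd ≤ tb_vbmd always.
    """
    if roi.count == 0:
        raise EmptyRoiError("Tb.tBMD over an empty ROI")
    sel = roi.voxels & transverse_support.voxels
    return float(v.values[sel].sum() / roi.count)


def tb_pw(ls: LocalStructure, s: SkeletonMap, roi: RoiMask, plates_only: bool = False,
          plate_rod: np.ndarray | None = None) -> float:
    """Tb.PW (μm): mean local plate width over skeleton voxels in the ROI.

    By default all skeleton voxels are averaged; ``plates_only=True``
    restricts to plate-classified voxels (requires ``plate_rod``).
    """
    sel = s.in_roi(roi)
    if plates_only:
        if plate_rod is None:
            raise ConfigurationError("plates_only requires plate_rod labels")
        sel = sel & (plate_rod == "plate")
    if not sel.any():
        raise EmptyRoiError("no skeleton voxels in ROI for Tb.PW")
    return float(ls.plate_width_mm[sel].mean() * 1000.0)
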
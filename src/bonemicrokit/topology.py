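"""Digital topological analysis of the skeleton, erosion index, and SMI.

Each skeleton voxel is classified by the topology of its 3×3×3
neighborhood — the number of 26-connected object components among its
neighbors, the number of 6-connected background components adjacent to
it, and the component sizes.  Surface (plate-like) and curve (rod-like)
classes are then aggregated into the **erosion index** (EI), the ratio of
curve-type to surface-type voxel counts: erosion of trabecular plates
perforates them into rods, so EI rises with structural deterioration.

The **structure model index** (SMI) takes the complementary, continuous
view: for an ideal plate, cylinder and sphere the derivative of surface
area with respect to half-thickness gives SMI = 0, 3 and 4 respectively.
It is computed here exactly as defined: triangulate the 0.5-level surface
of the structure, displace vertices outward along vertex normals by a
small ``dr``, and form SMI = 6·V·S′/S².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from . import _topo3d
from .skeleton import SkeletonMap
from .volume import ConfigurationError

TOPO_CLASSES = (
    "surface_interior",
    "surface_edge",
    "curve_interior",
    "curve_edge",
    "junction_ss",
    "junction_sc",
    "junction_cc",
    "profile",
    "isolated",
)

#: EI numerator / denominator class compositions (config-exposed).
EI_CURVE_CLASSES = ("curve_interior", "curve_edge", "junction_cc", "profile", "isolated")
EI_SURFACE_CLASSES = ("surface_interior", "surface_edge", "junction_ss", "junction_sc")


class NonThinSkeletonError(RuntimeError):
    """DTA requires a thin skeleton (no voxel with a full 26-neighborhood)."""


class EmptyStructureError(RuntimeError):
    """SMI of an empty structure is undefined."""


@dataclass
class TopoCensus:
    """Counts of topological classes over skeleton voxels in an ROI."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in TOPO_CLASSES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@lru_cache(maxsize=1 << 20)
def _component_sizes_cached(code: int) -> tuple[int, ...]:
    block = _topo3d._decode(code)
    block[1, 1, 1] = False
    if not block.any():
        return ()
    labels, n = ndimage.label(block, structure=np.ones((3, 3, 3), dtype=bool))
    return tuple(int((labels == i).sum()) for i in range(1, n + 1))


def _classify_code(code: int) -> str:
    """Rule table mapping local topological numbers to a class.

    Let ξ = number of 26-object components among the neighbors, δ =
    number of 6-background components adjacent to the center, n = object
    neighbor count, and sizes the ξ component sizes:

    * n = 0                        → isolated
    * δ = 0                        → profile (enclosed residue)
    * ξ = 1, δ ≥ 2                 → surface interior (object sheet
                                      separates two background sides)
    * ξ = 1, δ = 1, n ≤ 2          → curve edge (line endpoint)
    * ξ = 1, δ = 1, n > 2          → surface edge (plate rim)
    * ξ = 2, all sizes ≤ 2         → curve interior (line passes through)
    * ξ = 2, some size ≥ 3         → surface–curve junction
    * ξ ≥ 3, all sizes ≤ 2         → curve–curve junction
    * ξ ≥ 3, one size ≥ 3          → surface–curve junction
    * ξ ≥ 3, two+ sizes ≥ 3        → surface–surface junction

    Precedence surface > junction > curve is implicit in the ordering and
    deterministic.
    """
    n = _topo3d.neighbor_count(code)
    if n == 0:
        return "isolated"
    xi = _topo3d.object_components_26(code)
    delta = _topo3d.background_components_6(code)
    if delta == 0:
        return "profile"
    sizes = _component_sizes_cached(code)
    big = sum(1 for s in sizes if s >= 3)
    if xi == 1:
        if delta >= 2:
            return "surface_interior"
        return "curve_edge" if n <= 2 else "surface_edge"
    if xi == 2:
        return "curve_interior" if big == 0 else "junction_sc"
    if big == 0:
        return "junction_cc"
    return "junction_ss" if big >= 2 else "junction_sc"


def dta_classify(s: SkeletonMap) -> SkeletonMap:
    """Fill ``topo_class`` for every skeleton voxel (in place; returns s)."""
    mask = s.mask
    classes = np.empty(len(s), dtype=object)
    for i, (z, y, x) in enumerate(s.coords):
        code = _topo3d.encode(_topo3d.extract_block(mask, z, y, x))
        if _topo3d.neighbor_count(code) == 26:
            raise NonThinSkeletonError(f"interior voxel at {(z, y, x)}: skeleton is not thin")
        classes[i] = _classify_code(code)
    s.topo_class = classes.astype(str)
    return s


def topo_census(s: SkeletonMap, roi=None) -> TopoCensus:
    """Tabulate topological classes over the ROI (or the whole skeleton)."""
    if s.topo_class is None:
        raise ConfigurationError("run dta_classify first")
    sel = np.ones(len(s), dtype=bool) if roi is None else s.in_roi(roi)
    census = TopoCensus()
    classes, counts = np.unique(s.topo_class[sel], return_counts=True)
    for c, n in zip(classes, counts):
        census.counts[str(c)] = int(n)
    return census


def erosion_index(
    census: TopoCensus,
    curve_classes: tuple[str, ...] = EI_CURVE_CLASSES,
    surface_classes: tuple[str, ...] = EI_SURFACE_CLASSES,
) -> float:
    """EI: curve-type voxel count over surface-type voxel count.

    Returns ``inf`` (with a warning) when no surface-type voxels exist —
    a fully rod-like census.
    """
    num = sum(census.counts.get(c, 0) for c in curve_classes)
    den = sum(census.counts.get(c, 0) for c in surface_classes)
    if den == 0:
        import warnings

        warnings.warn("EI denominator is zero (no surface-type voxels); returning inf")
        return float("inf")
    return num / den


# ----------------------------------------------------------------------- SMI


def smi(
    structure: np.ndarray,
    spacing: tuple[float, float, float],
    dr_mm: float | None = None,
    level: float = 0.5,
    smooth_sigma_vox: float = 1.0,
) -> float:
    """Structure model index by simulated thickening of the triangulated
    surface.

    ``structure`` is a membership (or binary) volume; the ``level``
    isosurface is extracted by marching cubes after a light Gaussian
    smoothing (``smooth_sigma_vox``) that suppresses voxelization
    stair-casing.  Vertices are displaced by ``dr`` (default ¼ voxel)
    along outward vertex normals, and

        SMI = 6 · V · S′ / S²,   S′ = (S(r + dr) − S(r)) / dr.

    If the displaced surface degenerates (non-finite area), ``dr`` is
    halved once before giving up.
    """
    vals = np.asarray(structure, dtype=float)
    if not (vals >= level).any():
        raise EmptyStructureError("empty structure")
    if smooth_sigma_vox > 0:
        vals = ndimage.gaussian_filter(vals, smooth_sigma_vox)
        if not (vals > level).any():
            raise EmptyStructureError("structure vanished under smoothing")
    vals = np.pad(vals, 1, constant_values=0.0)
    sp = tuple(float(x) for x in spacing)
    verts, faces, normals, _ = measure.marching_cubes(vals, level=level, spacing=sp)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # orient outward so vertex normals point out
        mesh.invert()
    S = float(mesh.area)
    V = float(abs(mesh.volume))
    if S <= 0 or V <= 0:
        raise EmptyStructureError("degenerate surface")
    dr = dr_mm if dr_mm is not None else min(sp) / 4.0
    for attempt in range(2):
        offset = trimesh.Trimesh(
            vertices=mesh.vertices + dr * mesh.vertex_normals, faces=faces, process=False
        )
        S2 = float(offset.area)
        if np.isfinite(S2) and S2 > 0:
            return 6.0 * V * ((S2 - S) / dr) / (S * S)
        dr /= 2.0
    raise RuntimeError("offset surface degenerated at both dr and dr/2")
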
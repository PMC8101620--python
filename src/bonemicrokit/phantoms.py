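"""Synthetic phantoms with known ground truth.

Every metric in the package is validated against geometry it can be
checked on analytically: parallel plate stacks, straight-rod lattices,
spheres, hollow shafts with seeded cortical pores, and a distal-tibia-
like phantom (cortical shell, internal trabecular lattice, a solid end
plateau whose distal rim cross-sections contain a 2-D hole, and an
optionally tilted long axis).  Generators are bit-reproducible for a
fixed seed and return the analytic ground truth alongside the volume.

Default densities are plausible mg/cc magnitudes for the application —
bone 800, marrow 100, cortical 1200 — chosen as synthetic test
conditions, not physiologic claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import ConfigurationError, DensityVolume, Units

BONE = 800.0
MARROW = 100.0
CORTICAL = 1200.0
DEFAULT_SPACING = 0.15


class InfeasibleSpecError(ValueError):
    """Requested structure cannot be represented at the voxel size."""


@dataclass
class GroundTruth:
    """Analytic truth recorded by a generator; fields used per phantom."""

    thickness_mm: float | None = None
    spacing_mm: float | None = None
    diameter_mm: float | None = None
    plate_area_mm2: float | None = None
    transverse_mass_fraction: float | None = None
    porosity: float | None = None
    wall_thickness_mm: float | None = None
    outer_radius_mm: float | None = None
    smi_limit: float | None = None
    axis_direction: np.ndarray | None = None
    plateau_slice: int | None = None
    tilt_deg: float | None = None
    lattice: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _finish(
    bone_mask: np.ndarray,
    spacing: float,
    noise_sd: float,
    seed: int,
    bone_density: float = BONE,
    marrow_density: float = MARROW,
    density_map: np.ndarray | None = None,
) -> DensityVolume:
    vals = (
        density_map
        if density_map is not None
        else np.where(bone_mask, bone_density, marrow_density).astype(float)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, vals.shape)
    return DensityVolume(vals, (spacing,) * 3, units=Units.MG_CC)


# ------------------------------------------------------------- structures


def make_plate_stack(
    thickness_mm: float = 0.3,
    gap_mm: float = 0.5,
    n_plates: int = 8,
    lateral_mm: float = 9.0,
    spacing: float = DEFAULT_SPACING,
    normal_axis: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DensityVolume, GroundTruth]:
    """Stack of parallel slabs: truth thickness = slab, spacing = gap."""
    if thickness_mm < spacing:
        raise InfeasibleSpecError("plate thinner than one voxel")
    t_vox = int(round(thickness_mm / spacing))
    g_vox = int(round(gap_mm / spacing))
    lat = int(round(lateral_mm / spacing))
    period = t_vox + g_vox
    n_axis = n_plates * period + g_vox
    shape = [lat, lat, lat]
    shape[normal_axis] = n_axis
    mask = np.zeros(shape, dtype=bool)
    idx = [slice(None)] * 3
    for p in range(n_plates):
        start = g_vox + p * period
        idx[normal_axis] = slice(start, start + t_vox)
        mask[tuple(idx)] = True
    gt = GroundTruth(
        thickness_mm=t_vox * spacing,
        spacing_mm=g_vox * spacing,
        plate_area_mm2=(lat * spacing) ** 2,
        smi_limit=0.0,
    )
    return _finish(mask, spacing, noise_sd, seed), gt


def make_rod_lattice(
    diameter_mm: float = 0.45,
    pitch_mm: float = 1.5,
    extent_mm: float = 9.0,
    transverse_fraction: float = 0.0,
    spacing: float = DEFAULT_SPACING,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DensityVolume, GroundTruth]:
    """Lattice of straight rods with a controlled transverse/longitudinal mix.

    Longitudinal rods run along z on a square (y, x) grid; transverse
    rods run along x on a (z, y) grid.  ``transverse_fraction`` is the
    requested fraction of rods that are transverse; the recorded ground
    truth is the realized *mass* fraction from the voxelized masks
    (overlap voxels split evenly).
    """
    if diameter_mm < spacing:
        raise InfeasibleSpecError("rod thinner than one voxel")
    n = int(round(extent_mm / spacing))
    # voxel centers at integer multiples of the spacing so that rod
    # centers snapped to the grid voxelize symmetrically
    coords = np.arange(n) * spacing
    z, y, x = np.meshgrid(coords, coords, coords, indexing="ij")
    r = diameter_mm / 2.0
    centers = np.round(np.arange(pitch_mm / 2.0, extent_mm, pitch_mm) / spacing) * spacing
    n_sites = len(centers) ** 2
    rng = np.random.default_rng(seed)
    n_trans = int(round(transverse_fraction * n_sites))
    site_idx = rng.permutation(n_sites)
    trans_sites = set(site_idx[:n_trans].tolist())

    long_mask = np.zeros((n, n, n), dtype=bool)
    trans_mask = np.zeros((n, n, n), dtype=bool)
    for k, (cy, cx) in enumerate((cy, cx) for cy in centers for cx in centers):
        if k in trans_sites:
            # transverse rod along x at (z=cy, y=cx) -- reuse grid positions
            trans_mask |= (z - cy) ** 2 + (y - cx) ** 2 <= r * r
        else:
            long_mask |= (y - cy) ** 2 + (x - cx) ** 2 <= r * r
    mask = long_mask | trans_mask
    overlap = long_mask & trans_mask
    t_mass = trans_mask.sum() - 0.5 * overlap.sum()
    gt = GroundTruth(
        diameter_mm=diameter_mm,
        spacing_mm=pitch_mm - diameter_mm,
        transverse_mass_fraction=float(t_mass / max(mask.sum(), 1)),
        smi_limit=3.0,
        lattice={"pitch_mm": pitch_mm, "n_sites": n_sites, "n_transverse": n_trans},
    )
    return _finish(mask, spacing, noise_sd, seed), gt


def make_sphere(
    radius_mm: float = 1.8,
    spacing: float = DEFAULT_SPACING,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DensityVolume, GroundTruth]:
    """Solid sphere; SMI limit 4."""
    n = int(round(2 * radius_mm / spacing)) + 8
    c = (n - 1) / 2.0 * spacing
    coords = np.arange(n) * spacing
    z, y, x = np.meshgrid(coords, coords, coords, indexing="ij")
    mask = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_mm**2
    gt = GroundTruth(diameter_mm=2 * radius_mm, smi_limit=4.0)
    return _finish(mask, spacing, noise_sd, seed), gt


def make_hollow_cylinder(
    outer_radius_mm: float = 6.0,
    wall_mm: float = 2.0,
    length_mm: float = 9.0,
    porosity: float = 0.0,
    pore_radius_mm: float = 0.45,
    spacing: float = DEFAULT_SPACING,
    noise_sd: float = 0.0,
    seed: int = 0,
    wall_density: float = CORTICAL,
    inner_density: float = MARROW,
) -> tuple[DensityVolume, GroundTruth]:
    """Hollow shaft (cortical wall around marrow) with optional seeded pores.

    Pores are marrow-density spheres placed on a regular angular × axial
    grid inside the wall mid-surface until the requested volume fraction
    is reached, so the realized porosity is near-uniform along the shaft.
    Truth records the realized pore-voxel fraction of the wall.
    """
    if not 0 <= porosity < 1:
        raise ConfigurationError("porosity must be in [0, 1)")
    nz = int(round(length_mm / spacing))
    nxy = int(round(2 * (outer_radius_mm + 0.6) / spacing))
    c = (nxy - 1) / 2.0 * spacing
    zc = np.arange(nz) * spacing
    yc = np.arange(nxy) * spacing
    z, y, x = np.meshgrid(zc, yc, yc, indexing="ij")
    rr = np.sqrt((y - c) ** 2 + (x - c) ** 2)
    inner_r = outer_radius_mm - wall_mm
    wall = (rr <= outer_radius_mm) & (rr > inner_r)
    interior = rr <= inner_r

    pores = np.zeros_like(wall)
    if porosity > 0:
        mid_r = outer_radius_mm - wall_mm / 2.0
        pore_vol = 4.0 / 3.0 * np.pi * pore_radius_mm**3
        wall_vol = wall.sum() * spacing**3
        n_pores = int(np.ceil(porosity * wall_vol / pore_vol))
        # regular placement: ring of pores every dz_p axially
        circ = 2 * np.pi * mid_r
        per_ring = max(1, int(circ // (2.6 * pore_radius_mm)))
        n_rings = int(np.ceil(n_pores / per_ring))
        z_lo, z_hi = 2 * pore_radius_mm, length_mm - 2 * pore_radius_mm
        ring_z = np.linspace(z_lo, z_hi, n_rings)
        rng = np.random.default_rng(seed)
        placed = 0
        for i, zr in enumerate(ring_z):
            phase = rng.uniform(0, 2 * np.pi)
            for j in range(per_ring):
                if placed >= n_pores:
                    break
                ang = phase + 2 * np.pi * j / per_ring
                py, px = c + mid_r * np.sin(ang), c + mid_r * np.cos(ang)
                pores |= (z - zr) ** 2 + (y - py) ** 2 + (x - px) ** 2 <= pore_radius_mm**2
                placed += 1
    pores &= wall
    vals = np.full(wall.shape, 0.0)
    vals[interior] = inner_density
    vals[wall] = wall_density
    vals[pores] = inner_density
    realized = float(pores.sum() / max(wall.sum(), 1))
    gt = GroundTruth(
        wall_thickness_mm=wall_mm,
        outer_radius_mm=outer_radius_mm,
        porosity=realized,
        smi_limit=3.0,
        extra={"inner_radius_mm": inner_r, "length_mm": length_mm},
    )
    return _finish(wall, spacing, noise_sd, seed, density_map=vals), gt


# ------------------------------------------------------------ tibia-like


def make_tibia_phantom(
    length_mm: float = 27.0,
    outer_radius_mm: float = 7.0,
    wall_mm: float = 1.75,
    rim_mm: float = 4.8,
    cap_mm: float = 1.5,
    rod_diameter_mm: float = 0.6,
    rod_pitch_mm: float = 1.05,
    transverse_fraction: float = 0.5,
    plate_fraction: float = 0.25,
    plate_width_mm: float = 1.8,
    lattice_margin_mm: float = 0.65,
    tilt_deg: float = 0.0,
    wall_porosity: float = 0.0,
    pore_radius_mm: float = 0.55,
    spacing: float = DEFAULT_SPACING,
    supersample: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DensityVolume, GroundTruth]:
    """Distal-tibia-like phantom.

    From distal (z = 0) to proximal: an open articular **rim** (annular
    cross-sections containing a 2-D hole), a solid **end plateau** cap,
    then the **shaft**: a cortical wall (optionally pored) around a
    mixed trabecular lattice — longitudinal rods and plate fins plus a
    controlled fraction of transverse rods — separated from the wall by
    a ``lattice_margin_mm`` marrow moat (the endosteal clear zone).
    ``tilt_deg`` tilts the long axis about the x-axis; the volume is
    generated analytically in tilted coordinates (no resampling) on a
    ``supersample``-times finer grid and box-averaged down, so voxel
    values carry partial-volume fractions and the tilted and untilted
    phantoms realize the same continuum geometry to sub-voxel accuracy.
    Truth records the plateau slice (untilted convention), the tilted
    axis direction, wall thickness, realized wall porosity, realized
    transverse mass fraction and lattice parameters.
    """
    if tilt_deg > 20.0:
        raise InfeasibleSpecError("tilt above 20 degrees is unsupported")
    # the shaft is truncated by the array top (as a scan's field of view
    # truncates the bone), so the marrow cavity is closed by the fill rule
    margin = length_mm * np.tan(np.deg2rad(abs(tilt_deg))) + 1.0
    nz = int((length_mm - 1.6 - margin * 0.2) / spacing)
    ny = int(round((2 * outer_radius_mm + margin + 1.0) / spacing))
    nx = int(round((2 * outer_radius_mm + 1.0) / spacing))
    ss = max(1, int(supersample))
    fine = spacing / ss
    half = spacing / 2.0 - fine / 2.0
    zc = (np.arange(nz * ss, dtype=np.float32) * fine - half).astype(np.float32)
    yc = np.arange(ny * ss, dtype=np.float32) * fine - half
    xc = np.arange(nx * ss, dtype=np.float32) * fine - half
    z, y, x = np.meshgrid(zc, yc, xc, indexing="ij")
    cy, cx = outer_radius_mm + 0.5, outer_radius_mm + 0.5
    cz = 0.0
    # tilted bone frame: rotate about x through (cz, cy)
    th = np.deg2rad(tilt_deg)
    zb = (z - cz) * np.cos(th) + (y - cy) * np.sin(th)
    yb = -(z - cz) * np.sin(th) + (y - cy) * np.cos(th)
    xb = x - cx
    rr = np.sqrt(yb**2 + xb**2)

    inner_r = outer_radius_mm - wall_mm
    in_bone_z = (zb >= 0.4) & (zb <= length_mm)
    rim = in_bone_z & (zb < 0.4 + rim_mm) & (rr <= outer_radius_mm) & (rr > inner_r)
    cap = (
        (zb >= 0.4 + rim_mm)
        & (zb < 0.4 + rim_mm + cap_mm)
        & (rr <= outer_radius_mm)
    )
    shaft_z = in_bone_z & (zb >= 0.4 + rim_mm + cap_mm)
    wall = shaft_z & (rr <= outer_radius_mm) & (rr > inner_r)
    interior = shaft_z & (rr <= inner_r)

    # mixed trabecular lattice inside the shaft, defined in the bone
    # frame: longitudinal rods (or plate fins, for a seeded fraction of
    # sites) along z at a square (y, x) grid, plus transverse rods along
    # x at a (z, y) grid of slots; everything stays a marrow moat away
    # from the endosteal surface
    r_rod = rod_diameter_mm / 2.0
    r_lat = inner_r - lattice_margin_mm
    in_lattice = interior & (rr <= r_lat)
    centers = np.arange(-r_lat + rod_pitch_mm / 2.0, r_lat, rod_pitch_mm)
    z_shaft0 = 0.4 + rim_mm + cap_mm + rod_pitch_mm / 2.0
    z_slots = np.arange(z_shaft0, length_mm, rod_pitch_mm)
    rng = np.random.default_rng(seed)
    t_slots = [(zm, a) for zm in z_slots for a in centers]
    n_trans = int(round(transverse_fraction * len(t_slots)))
    order = rng.permutation(len(t_slots))
    trans_set = set(order[:n_trans].tolist())
    sites = [(a, b) for a in centers for b in centers]
    n_plates = int(round(plate_fraction * len(sites)))
    plate_set = set(rng.permutation(len(sites))[:n_plates].tolist())
    long_mask = np.zeros_like(wall)
    trans_mask = np.zeros_like(wall)
    # bounding boxes in array index space keep each element's voxel
    # update local instead of touching the whole grid
    cos_t, sin_t = float(np.cos(th)), float(np.sin(th))
    NZ, NY, NX = wall.shape

    def _box(czb, cyb, cxb, hz, hy, hx):
        za = czb * cos_t - cyb * sin_t
        ya = czb * sin_t + cyb * cos_t + cy
        xa = cxb + cx
        ez = abs(hz * cos_t) + abs(hy * sin_t) + 2 * fine
        ey = abs(hz * sin_t) + abs(hy * cos_t) + 2 * fine
        ex = hx + 2 * fine
        z0 = max(0, int((za - ez + half) / fine))
        z1 = min(NZ, int((za + ez + half) / fine) + 1)
        y0 = max(0, int((ya - ey + half) / fine))
        y1 = min(NY, int((ya + ey + half) / fine) + 1)
        x0 = max(0, int((xa - ex + half) / fine))
        x1 = min(NX, int((xa + ex + half) / fine) + 1)
        return (slice(z0, z1), slice(y0, y1), slice(x0, x1))

    z_mid = length_mm / 2.0
    for k, (a, b) in enumerate(sites):
        if a * a + b * b > r_lat**2:
            continue
        if k in plate_set:  # longitudinal plate fin, normal along x
            sl = _box(z_mid, a, b, z_mid, plate_width_mm / 2.0, r_rod * 0.75)
            long_mask[sl] |= in_lattice[sl] & (np.abs(xb[sl] - b) <= r_rod * 0.75) & (
                np.abs(yb[sl] - a) <= plate_width_mm / 2.0
            )
        else:
            sl = _box(z_mid, a, b, z_mid, r_rod, r_rod)
            long_mask[sl] |= in_lattice[sl] & ((yb[sl] - a) ** 2 + (xb[sl] - b) ** 2 <= r_rod**2)
    for k in trans_set:
        zm, a = t_slots[k]
        sl = _box(zm, a, 0.0, r_rod, r_rod, r_lat)
        trans_mask[sl] |= in_lattice[sl] & ((zb[sl] - zm) ** 2 + (yb[sl] - a) ** 2 <= r_rod**2)
    lattice = long_mask | trans_mask

    # cortical pores on a regular grid in the wall (bone frame); the
    # ring pitch matches the lattice pitch so any axial analysis window
    # spanning whole pitches sees the same porosity
    pores = np.zeros_like(wall)
    if wall_porosity > 0:
        mid_r = outer_radius_mm - wall_mm / 2.0
        circ = 2 * np.pi * mid_r
        pore_vol = 4.0 / 3.0 * np.pi * pore_radius_mm**3
        ring_pitch = rod_pitch_mm
        per_ring = int(round(wall_porosity * circ * wall_mm * ring_pitch / pore_vol))
        per_ring = max(1, min(per_ring, int(circ // (2.6 * pore_radius_mm))))
        z0 = 0.4 + rim_mm + cap_mm + 2 * pore_radius_mm
        ring_z = np.arange(z0, length_mm - 2 * pore_radius_mm, ring_pitch)
        ang0 = rng.uniform(0, 2 * np.pi)
        pr = pore_radius_mm
        for i, zr in enumerate(ring_z):
            for j in range(per_ring):
                ang = ang0 + 2 * np.pi * (j + 0.5 * (i % 2)) / per_ring
                py, px = mid_r * np.sin(ang), mid_r * np.cos(ang)
                sl = _box(zr, py, px, pr, pr, pr)
                pores[sl] |= (zb[sl] - zr) ** 2 + (yb[sl] - py) ** 2 + (xb[sl] - px) ** 2 <= pr**2
        pores &= wall

    vals = np.zeros(wall.shape, dtype=np.float32)
    vals[interior] = MARROW
    vals[lattice] = BONE
    vals[rim | cap | wall] = CORTICAL
    vals[pores] = MARROW
    if ss > 1:  # box-average the supersampled field down to the grid
        vals = vals.reshape(nz, ss, ny, ss, nx, ss).mean(axis=(1, 3, 5))

    realized_poro = float(pores.sum() / max(wall.sum(), 1))
    overlap = long_mask & trans_mask
    t_mass = trans_mask.sum() - 0.5 * overlap.sum()
    axis = np.array([np.cos(th), np.sin(th), 0.0])  # (z, y, x)
    plateau_slice = int(np.ceil((0.4 + rim_mm) / spacing))
    gt = GroundTruth(
        wall_thickness_mm=wall_mm,
        outer_radius_mm=outer_radius_mm,
        porosity=realized_poro,
        transverse_mass_fraction=float(t_mass / max(lattice.sum(), 1)),
        diameter_mm=rod_diameter_mm,
        spacing_mm=rod_pitch_mm - rod_diameter_mm,
        axis_direction=axis,
        plateau_slice=plateau_slice,
        tilt_deg=tilt_deg,
        lattice={"pitch_mm": rod_pitch_mm, "n_transverse": n_trans, "n_sites": len(sites)},
        extra={"rim_mm": rim_mm, "cap_mm": cap_mm, "length_mm": length_mm},
    )
    vol = DensityVolume(np.asarray(vals, dtype=np.float64), (spacing,) * 3, units=Units.MG_CC)
    if noise_sd > 0:
        rng2 = np.random.default_rng(seed + 1)
        vol = vol.with_values(vol.values + rng2.normal(0, noise_sd, vol.values.shape))
    return vol, gt


# ----------------------------------------------------- calibration phantom


def make_calibration_phantom(
    densities_mg_cc: tuple[float, ...] = (0.0, 200.0, 400.0, 800.0, 1200.0),
    true_slope: float = 0.8,
    true_intercept: float = -20.0,
    rod_radius_mm: float = 2.0,
    spacing: float = 0.5,
    noise_sd_hu: float = 0.0,
    seed: int = 0,
):
    """HU phantom with density rods on a known affine HU → mg/cc law.

    Returns (volume in HU, PhantomSpec, true CalibrationLine-equivalent
    dict).  Rod HU values satisfy density = true_slope·HU +
    true_intercept exactly (before noise).
    """
    from .calibration import PhantomSpec, RodSpec

    n_rods = len(densities_mg_cc)
    if n_rods < 2:
        raise ConfigurationError("need >= 2 rod densities")
    pitch = 4 * rod_radius_mm
    nx = int(round((n_rods * pitch + 2 * rod_radius_mm) / spacing))
    ny = int(round(6 * rod_radius_mm / spacing))
    nz = int(round(12.0 / spacing))
    vals = np.full((nz, ny, nx), -50.0)  # water-ish background HU
    zc = np.arange(nz) * spacing
    yc = np.arange(ny) * spacing
    xc = np.arange(nx) * spacing
    z, y, x = np.meshgrid(zc, yc, xc, indexing="ij")
    rods = []
    cy = ny * spacing / 2.0
    cz = nz * spacing / 2.0
    for i, d in enumerate(densities_mg_cc):
        cx = (i + 1) * pitch
        hu = (d - true_intercept) / true_slope
        in_rod = ((y - cy) ** 2 + (x - cx) ** 2 <= rod_radius_mm**2) & (np.abs(z - cz) <= 5.0)
        vals[in_rod] = hu
        rods.append(RodSpec(center_mm=(cz, cy, cx), radius_mm=rod_radius_mm,
                            density_mg_cc=d, half_length_mm=5.0))
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0, noise_sd_hu, vals.shape)
    vol = DensityVolume(vals, (spacing,) * 3, units=Units.HU)
    return vol, PhantomSpec(rods=tuple(rods)), {"slope": true_slope, "intercept": true_intercept}


# ------------------------------------------------------- simulated tables


def simulate_replicates(
    n_units: int,
    k_replicates: int,
    var_between: float,
    var_within: float,
    mean: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Repeat-scan table: unit random effect + replicate noise.

    Expected one-way ICC = var_between / (var_between + var_within).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(var_between), n_units)
    e = rng.normal(0, np.sqrt(var_within), (n_units, k_replicates))
    return mean + u[:, None] + e


def simulate_measure_table(
    n_group_a: int,
    n_group_b: int,
    effect_size: float = 0.0,
    covariate_effect: float = 0.0,
    covariate_imbalance: float = 0.0,
    sd: float = 1.0,
    mean: float = 0.0,
    measure: str = "tb_vbmd",
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format measure table from a two-group linear model.

    group a carries ``effect_size``·sd above group b; a binary covariate
    (e.g. a comorbidity) adds ``covariate_effect``·sd and can be made
    more prevalent in group b by ``covariate_imbalance`` (difference of
    prevalences).  Ground-truth parameters are in ``df.attrs``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in (("a", n_group_a), ("b", n_group_b)):
        p_cov = 0.5 + (covariate_imbalance / 2.0 if g == "b" else -covariate_imbalance / 2.0)
        for i in range(n):
            cov = int(rng.uniform() < p_cov)
            val = (
                mean
                + (effect_size * sd if g == "a" else 0.0)
                + covariate_effect * sd * cov
                + rng.normal(0, sd)
            )
            rows.append({"unit_id": f"{g}{i}", "group": g, "covariate": cov,
                         "measure": measure, "value": val})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "effect_size": effect_size, "covariate_effect": covariate_effect,
        "sd": sd, "mean": mean,
    }
    return df
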
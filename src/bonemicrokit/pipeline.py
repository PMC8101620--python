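"""End-to-end orchestration: calibrated volume → full bone-measure panel.

One run takes a calibrated (mg/cc) distal-tibia volume and produces the
ten-measure panel: the eight trabecular measures at the 4–6 % site over
the inner (60 % peel) and outer (30–60 % annulus) ROIs, and the two
cortical measures at the 14–16 % site.  Every stage parameter is logged
into the provenance record, and the run is deterministic for a fixed
volume, configuration and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import anatomy, cortical, skeleton, starline, tensorscale, topology
from .volume import ConfigurationError, DensityVolume, Units

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run.

    Site ranges are percent of tibial length measured proximally from
    the end plateau; ``tibial_length_mm`` must be supplied because the
    scan covers only the distal bone.
    """

    tibial_length_mm: float = 360.0
    tb_site_pct: tuple[float, float] = (4.0, 6.0)
    cb_site_pct: tuple[float, float] = (14.0, 16.0)
    bone_threshold: float = 300.0
    closing_radii_mm: tuple[float, ...] = (0.6, 1.2)
    marrow_ref: float = 0.0
    bone_ref: float = 800.0
    cortical_threshold: float = 600.0
    max_scale_mm: float = 3.0
    plate_rod_ratio: float = 2.0
    orientation_threshold_deg: float = 45.0
    starline: starline.StarLineConfig = field(default_factory=starline.StarLineConfig)
    realign_tolerance_deg: float = 0.5
    target_spacing_mm: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for lo, hi in (self.tb_site_pct, self.cb_site_pct):
            if not (0 <= lo < hi <= 100):
                raise ConfigurationError("site ranges must satisfy 0 <= lo < hi <= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "starline" in raw:
            raw["starline"] = starline.StarLineConfig(**raw["starline"])
        for key in ("tb_site_pct", "cb_site_pct", "closing_radii_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _crop_band(mask: np.ndarray, pad: int = 2) -> tuple[slice, ...]:
    zs = np.where(mask.any(axis=(1, 2)))[0]
    lo = max(int(zs.min()) - pad, 0)
    hi = min(int(zs.max()) + pad + 1, mask.shape[0])
    return (slice(lo, hi), slice(None), slice(None))


def run_pipeline(volume: DensityVolume, config: PipelineConfig | None = None) -> dict:
    """Run the full measurement pipeline on a calibrated volume.

    Returns ``{"metrics": DataFrame, "provenance": dict}``.  The metrics
    table has one row per (roi, measure).  Stage failures raise with the
    stage name in the message.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    if volume.units is not Units.MG_CC:
        raise ConfigurationError("run_pipeline expects a calibrated (mg/cc) volume")
    provenance: dict = {"schema_version": SCHEMA_VERSION, "config": _config_dict(cfg)}

    if cfg.target_spacing_mm is not None and not np.allclose(
        volume.spacing, cfg.target_spacing_mm
    ):
        from .volume import resample_isotropic

        volume = resample_isotropic(volume, cfg.target_spacing_mm)
        provenance["resampled_to_mm"] = cfg.target_spacing_mm

    # --- anatomy frame ----------------------------------------------------
    filled = anatomy.fill_bone_volume(volume, cfg.bone_threshold, cfg.closing_radii_mm)
    plateau = anatomy.locate_end_plateau(filled)
    frame = anatomy.fit_tibial_axis(filled, plateau, cfg.tibial_length_mm)
    tilt = float(np.rad2deg(np.arccos(np.clip(frame.axis_direction[0], -1, 1))))
    provenance["initial_axis_tilt_deg"] = tilt
    if tilt > cfg.realign_tolerance_deg:
        volume = anatomy.realign_to_axis(volume, frame)
        filled = anatomy.fill_bone_volume(volume, cfg.bone_threshold, cfg.closing_radii_mm)
        plateau = anatomy.locate_end_plateau(filled)
        frame = anatomy.fit_tibial_axis(filled, plateau, cfg.tibial_length_mm)
        provenance["realigned"] = True
    provenance["plateau_slice"] = int(plateau)
    provenance["axis_direction"] = [float(a) for a in frame.axis_direction]

    # --- trabecular ROIs --------------------------------------------------
    roi_inner = anatomy.make_axial_roi(frame, filled, cfg.tb_site_pct, peel="inner60")
    roi_outer = anatomy.make_axial_roi(frame, filled, cfg.tb_site_pct, peel="annulus30-60")
    cb_band = anatomy.make_axial_roi(frame, filled, cfg.cb_site_pct, peel=None)

    # --- trabecular measures over a cropped band --------------------------
    tb_union = roi_inner.voxels | roi_outer.voxels
    band = _crop_band(tb_union)
    sub_vol = DensityVolume(volume.values[band], volume.spacing, units=Units.MG_CC)
    membership = skeleton.bone_membership(sub_vol, cfg.marrow_ref, cfg.bone_ref)
    skel = skeleton.fuzzy_skeletonize(membership)
    ls = tensorscale.tensor_scale_at(skel, membership, cfg.max_scale_mm)
    plate_rod = tensorscale.classify_plate_rod(ls, cfg.plate_rod_ratio)
    orient = tensorscale.classify_orientation(ls, frame, plate_rod, cfg.orientation_threshold_deg)
    skel.orient_class = orient
    trans_support = tensorscale.propagate_class_to_support(skel, membership, orient, "transverse")
    topology.dta_classify(skel)

    records = []
    for roi_name, roi in (("inner", roi_inner), ("outer", roi_outer)):
        sub_roi = anatomy.RoiMask(roi.voxels[band], roi.spacing, kind=roi.kind,
                                  site_range_pct=roi.site_range_pct,
                                  peel_range_pct=roi.peel_range_pct)
        vals = {}
        vals["tb_vbmd"] = tensorscale.tb_vbmd(sub_vol, sub_roi)
        vals["tb_tbmd"] = tensorscale.tb_tbmd(sub_vol, sub_roi, trans_support)
        vals["tb_na"] = skeleton.network_area_density(skel, sub_roi)
        vals["tb_pw"] = tensorscale.tb_pw(ls, skel, sub_roi)
        vals["tb_th"] = starline.tb_th(membership, sub_roi, cfg.starline)
        vals["tb_sp"] = starline.tb_sp(membership, sub_roi, cfg.starline)
        census = topology.topo_census(skel, sub_roi)
        vals["ei"] = topology.erosion_index(census)
        vals["smi"] = topology.smi(
            np.where(sub_roi.voxels, membership.values, 0.0), membership.spacing
        )
        for measure, value in vals.items():
            records.append({"roi": roi_name, "measure": measure, "value": float(value)})

    # --- cortical measures ------------------------------------------------
    cortex, pores = cortical.segment_cortex(volume, cb_band, cfg.cortical_threshold)
    records.append({"roi": "cortical", "measure": "cb_th",
                    "value": cortical.cortical_thickness(cortex, pores)})
    records.append({"roi": "cortical", "measure": "cb_poro",
                    "value": cortical.cortical_porosity(cortex, pores)})

    metrics = pd.DataFrame(records)
    return {"metrics": metrics, "provenance": provenance}


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["starline"] = asdict(cfg.starline)
    return d
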
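"""Run configuration: every tunable of the pipeline, with provenance.

Unknown keys are rejected; the effective configuration is serialized next
to the outputs so any artifact can be reproduced from (inputs, config,
seed).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OCTConfig(_Strict):
    sigma_spatial_px: float = 5.0
    sigma_range: float = 0.1
    fm_epsilon: float = 0.01          # speed-function floor for the lumen path
    fm_max_jump_px: int = 3
    fm_overlap_alines: int = 12
    vesselness_threshold: float = 0.05
    frangi_thickness_px: int = 31
    adventitia_margin_px: int = 15
    gw_shadow_mean_max: float = 0.06
    gw_bright_max: float = 0.4


class StrutConfig(_Strict):
    percentile: float = 99.5
    min_shadow_len_px: int = 150
    max_slope: float = 0.05
    shadow_gap_px: int = 10
    shadow_level_frac: float = 0.2
    dbscan_eps_mm: float = 0.15
    dbscan_min_pts: int = 1
    bvs_threshold: float = 0.15
    bvs_area_range: Tuple[int, int] = (10, 40)
    bvs_max_aspect: float = 5.0
    bvs_band_width_px: int = 10
    strut_thickness_mm: float = 0.1
    malappose_threshold_mm: float = 0.1
    fracture_gap_frames: int = 3


class CTCAConfig(_Strict):
    scales_mm: Tuple[float, ...] = (1.0, 1.5, 2.0)
    path_epsilon: float = 1e-3
    smooth_window: int = 5
    kappa: float = 0.2
    dt: float = 0.4
    max_iter: int = 500
    station_mm: float = 0.5
    stent_run_threshold: float = 0.1


class FusionConfig(_Strict):
    ring_size: int = 90
    centerline_step_mm: float = 0.25
    station_mm: float = 0.5
    link_radius_mm: float = 0.3
    smooth_mesh: bool = False


class RunConfig(_Strict):
    """Top-level configuration; mirrors the tool's user-settings surface."""

    seed: int = 0
    oct: OCTConfig = OCTConfig()
    struts: StrutConfig = StrutConfig()
    ctca: CTCAConfig = CTCAConfig()
    fusion: FusionConfig = FusionConfig()

    @classmethod
    def from_yaml(cls, path: Optional[str]) -> "RunConfig":
        if path is None:
            return cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
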
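"""YAML analysis configuration.

Keys (all optional, shown with defaults)::

    section:
      axis: x            # sectioning axis; x = mediolateral (sagittal)
      thickness_um: 300
      origin_um: 0
    shrinkage:
      volume_factor: 3.32
      enabled: true      # disable for inputs already shrinkage-corrected
    puncta:
      min_diameter_px: 5
      threshold: otsu    # or a fixed intensity
      pixel_size_um: 0.6451612903225806
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .imaging import DEFAULT_PIXEL_SIZE_UM


@dataclass(frozen=True)
class AnalysisConfig:
    section_axis: str = "x"
    section_thickness_um: float = 300.0
    section_origin_um: float = 0.0
    shrinkage_volume_factor: float = 3.32
    shrinkage_enabled: bool = True
    puncta_min_diameter_px: float = 5.0
    puncta_threshold: "float | str" = "otsu"
    puncta_pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        section = raw.get("section", {})
        shrink = raw.get("shrinkage", {})
        puncta = raw.get("puncta", {})
        return cls(
            section_axis=section.get("axis", cls.section_axis),
            section_thickness_um=section.get("thickness_um", cls.section_thickness_um),
            section_origin_um=section.get("origin_um", cls.section_origin_um),
            shrinkage_volume_factor=shrink.get(
                "volume_factor", cls.shrinkage_volume_factor
            ),
            shrinkage_enabled=shrink.get("enabled", cls.shrinkage_enabled),
            puncta_min_diameter_px=puncta.get(
                "min_diameter_px", cls.puncta_min_diameter_px
            ),
            puncta_threshold=puncta.get("threshold", cls.puncta_threshold),
            puncta_pixel_size_um=puncta.get("pixel_size_um", cls.puncta_pixel_size_um),
        )
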
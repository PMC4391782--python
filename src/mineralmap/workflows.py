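"""End-to-end convenience pipelines tying the modules together.

These wrap the canonical analysis orders — raw volume -> HU -> calibration ->
watershed -> segment statistics, and raw XRF counts -> area -> volume
concentrations -> ratio statistics — so examples, tests and the acceptance
script exercise one shared code path.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .calibrate import CalibrationModel, fit_calibration, phantom_roi_stats, scale_to_hu
from .images import ElementMap, LabelMap, Volume
from .ratios import RatioMap, ratio_with_denominator
from .segment import (SegmentStats, gradient_magnitude, histogram2d,
                      segment_stats, select_seed_loci, watershed_segment)
from .xrf import AbsorptionContext, ElementStandard, calibrate_counts, thickness_correct

__all__ = ["calibrate_from_phantom", "segment_volume", "quantify_xrf", "ratio_map"]


def calibrate_from_phantom(raw: Volume, rois: Mapping[str, np.ndarray],
                           nominal_md: Mapping[str, float],
                           air_intensity: float, water_intensity: float
                           ) -> tuple[CalibrationModel, Volume]:
    """Raw phantom volume + known densities -> fitted calibration and HU volume."""
    hu = scale_to_hu(raw, air_intensity, water_intensity)
    measurements = phantom_roi_stats(hu, rois, nominal_md)
    return fit_calibration(measurements), hu


def segment_volume(raw: Volume, calib: CalibrationModel,
                   air_intensity: float | None = None,
                   water_intensity: float | None = None,
                   mask: np.ndarray | None = None,
                   bins: tuple[int, int] = (256, 64),
                   loci=None, **loci_kwargs
                   ) -> tuple[LabelMap, list[SegmentStats], list]:
    """Raw or HU volume -> watershed label map + per-segment MD statistics."""
    if raw.units == "raw":
        air = raw.meta.get("air_intensity") if air_intensity is None else air_intensity
        water = raw.meta.get("water_intensity") if water_intensity is None else water_intensity
        if air is None or water is None:
            raise ValueError("raw volume needs air/water reference intensities")
        vol_hu = scale_to_hu(raw, air, water)
    elif raw.units == "HU":
        vol_hu = raw
    else:
        raise ValueError(f"cannot segment a volume in units {raw.units!r}")
    gradmag = gradient_magnitude(vol_hu.data)
    if loci is None:
        hist = histogram2d(vol_hu.data, gradmag, bins=bins, mask=mask)
        loci = select_seed_loci(hist, mode="auto", **loci_kwargs)
    label_map = watershed_segment(vol_hu, loci, mask=mask, gradmag=gradmag)
    stats = segment_stats(label_map, vol_hu, calib)
    return label_map, stats, loci


def quantify_xrf(counts: Mapping[str, ElementMap],
                 standards: Mapping[str, ElementStandard],
                 ctx: AbsorptionContext) -> dict[str, ElementMap]:
    """Raw count maps -> volume concentrations (mmol/cm3) per element."""
    out: dict[str, ElementMap] = {}
    for el, m in counts.items():
        area = calibrate_counts(m, standards[el])
        out[el] = thickness_correct(area, ctx)
    return out


def ratio_map(quantified: Mapping[str, ElementMap], numerator: str,
              denominator: str, floor: float = 0.0) -> RatioMap:
    """Per-pixel molar ratio of two quantified maps (denominator stashed so
    both masked-statistics methods are exact)."""
    return ratio_with_denominator(quantified[numerator], quantified[denominator],
                                  denominator_floor=floor)
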
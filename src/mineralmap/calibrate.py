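"""Hounsfield scaling and phantom-based mineral-density calibration.

The micro-CT convention here anchors air at 0 HU and water at 1000 HU
(standard Hounsfield + 1000); standard-HU data can be imported by passing the
matching reference intensities. Mineral density (MD, mg/cc hydroxyapatite) is
obtained from HU through an ordinary-least-squares line fitted MD-on-HU over a
set of phantoms of known density scanned alongside the specimens.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .images import Volume

__all__ = [
    "CalibrationModel",
    "PhantomMeasurement",
    "GravimetricComparison",
    "scale_to_hu",
    "phantom_roi_stats",
    "fit_calibration",
    "md_from_hu",
    "hu_from_md",
    "compare_with_gravimetric",
]


@dataclass
class CalibrationModel:
    """Linear HU -> mineral-density map ``MD = slope * HU + intercept``.

    ``residuals`` (when fitted) is a table with one row per phantom:
    phantom_id, mean_hu, nominal_md, predicted_md, residual (y - yhat).
    """

    slope: float
    intercept: float
    r_squared: float = 1.0
    residuals: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not -1e-12 <= 1.0 - self.r_squared <= 1.0 + 1e-12:
            if not 0.0 <= self.r_squared <= 1.0:
                raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class PhantomMeasurement:
    """Mean/sd HU over one phantom ROI plus a per-slice mean-HU series."""

    phantom_id: str
    nominal_md: float
    mean_hu: float
    sd_hu: float
    n_voxels: int
    slice_means: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError(f"phantom {self.phantom_id!r}: n_voxels must be > 0")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be non-negative")


@dataclass
class GravimetricComparison:
    """CT calibration line vs gravimetric (ash) line over the phantom HU range."""

    ash_slope: float
    ash_intercept: float
    hu_grid: np.ndarray
    residual_curve: np.ndarray  # CT prediction - ash prediction at each grid HU
    prediction_correlation: float


def scale_to_hu(raw: Volume | np.ndarray, air_intensity: float,
                water_intensity: float) -> Volume:
    """Affinely rescale raw intensities so air maps to 0 HU and water to 1000 HU.

    Values outside the [air, water] bracket extrapolate linearly, so mineralized
    voxels land well above 1000 HU.
    """
    if water_intensity == air_intensity:
        raise ValueError("degenerate scaling: water and air reference intensities are equal")
    if isinstance(raw, Volume):
        data, vox, meta = raw.data, raw.voxel_size_um, dict(raw.meta)
    else:
        data, vox, meta = np.asarray(raw, dtype=float), 3.84, {}
    hu = 1000.0 * (data - air_intensity) / (water_intensity - air_intensity)
    meta.update(air_intensity=air_intensity, water_intensity=water_intensity,
                hu_convention="air=0, water=1000")
    return Volume(hu, voxel_size_um=vox, units="HU", meta=meta)


def phantom_roi_stats(volume_hu: Volume, rois: Mapping[str, np.ndarray],
                      nominal_md: Mapping[str, float],
                      slice_axis: int = 0) -> list[PhantomMeasurement]:
    """Per-phantom HU statistics over ROI masks, with per-slice mean series.

    ``rois`` maps phantom id -> boolean mask over the volume; masks must be
    non-empty and pairwise disjoint. ``nominal_md`` gives the known density of
    each phantom in mg/cc.
    """
    data = volume_hu.data
    seen = np.zeros(data.shape, dtype=bool)
    out: list[PhantomMeasurement] = []
    for pid, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise ValueError(f"ROI for phantom {pid!r} has shape {mask.shape}, "
                             f"volume has {data.shape}")
        if not mask.any():
            raise ValueError(f"ROI for phantom {pid!r} is empty")
        if (seen & mask).any():
            raise ValueError(f"ROI for phantom {pid!r} overlaps a previous ROI")
        seen |= mask
        vals = data[mask]
        idx = np.nonzero(mask.any(axis=tuple(a for a in range(3) if a != slice_axis)))[0]
        slice_means = pd.Series(
            [data.take(i, axis=slice_axis)[mask.take(i, axis=slice_axis)].mean()
             for i in idx],
            index=idx, name=pid)
        out.append(PhantomMeasurement(
            phantom_id=str(pid), nominal_md=float(nominal_md[pid]),
            mean_hu=float(vals.mean()), sd_hu=float(vals.std(ddof=0)),
            n_voxels=int(vals.size), slice_means=slice_means))
    return out


def fit_calibration(measurements: Sequence[PhantomMeasurement]) -> CalibrationModel:
    """Ordinary least squares of nominal MD on mean HU over the phantom set.

    The fit is unweighted and MD-on-HU (the direction in which the line is
    applied downstream). Requires at least two distinct mean-HU values.
    """
    if len(measurements) < 2:
        raise ValueError("need at least two phantom measurements")
    hu = np.array([m.mean_hu for m in measurements], dtype=float)
    md = np.array([m.nominal_md for m in measurements], dtype=float)
    if np.ptp(hu) == 0:
        raise ValueError("rank-deficient fit: all phantom mean HU values are identical")
    res = _sps.linregress(hu, md)
    pred = res.slope * hu + res.intercept
    ss_res = float(np.sum((md - pred) ** 2))
    ss_tot = float(np.sum((md - md.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    table = pd.DataFrame({
        "phantom_id": [m.phantom_id for m in measurements],
        "mean_hu": hu, "nominal_md": md,
        "predicted_md": pred, "residual": md - pred,
    })
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=r2, residuals=table)


def md_from_hu(x: Volume | np.ndarray | float, calib: CalibrationModel):
    """Convert HU to mineral density (mg/cc): ``slope * HU + intercept``.

    Negative densities (possible below the calibration intercept, e.g. air)
    are preserved, not clamped; for Volume input the count of negative voxels
    is recorded in ``meta['negative_md_voxels']``.
    """
    if isinstance(x, Volume):
        md = calib.slope * x.data + calib.intercept
        meta = dict(x.meta)
        meta["negative_md_voxels"] = int(np.sum(md < 0))
        return Volume(md, voxel_size_um=x.voxel_size_um, units="mg/cc", meta=meta)
    return calib.slope * np.asarray(x, dtype=float) + calib.intercept


def hu_from_md(md, calib: CalibrationModel):
    """Exact inverse of :func:`md_from_hu`: ``HU = (MD - intercept) / slope``."""
    if calib.slope == 0:
        raise ValueError("invalid calibration: zero slope cannot be inverted")
    return (np.asarray(md, dtype=float) - calib.intercept) / calib.slope


def compare_with_gravimetric(calib: CalibrationModel,
                             ash_points: Sequence[tuple[str, float]],
                             hu_grid: np.ndarray | None = None) -> GravimetricComparison:
    """Compare the CT calibration line with a gravimetric (ash) density line.

    Ash densities are matched to fitted phantoms by id (their mean HU comes
    from the calibration residual table), an ash MD-on-HU line is fitted, and
    the pointwise residual (CT prediction - ash prediction) plus the Pearson
    correlation of the two lines' predictions are evaluated over ``hu_grid``
    (default: 101 points spanning the fitted phantom HU range).
    """
    if calib.residuals is None:
        raise ValueError("calibration model carries no phantom table; fit it first")
    if len(ash_points) < 2:
        raise ValueError("need at least two ash points")
    lookup = dict(zip(calib.residuals["phantom_id"], calib.residuals["mean_hu"]))
    hu, ash = [], []
    for pid, ash_md in ash_points:
        if str(pid) not in lookup:
            raise KeyError(f"ash point references unknown phantom {pid!r}")
        hu.append(lookup[str(pid)])
        ash.append(float(ash_md))
    hu_arr, ash_arr = np.array(hu), np.array(ash)
    if np.ptp(hu_arr) == 0:
        raise ValueError("ash points cover a single HU value; cannot fit a line")
    res = _sps.linregress(hu_arr, ash_arr)
    if hu_grid is None:
        lo, hi = calib.residuals["mean_hu"].min(), calib.residuals["mean_hu"].max()
        hu_grid = np.linspace(lo, hi, 101)
    hu_grid = np.asarray(hu_grid, dtype=float)
    ct_pred = calib.slope * hu_grid + calib.intercept
    ash_pred = res.slope * hu_grid + res.intercept
    # Pearson r of two affine functions of the same grid is +/-1; compute it
    # anyway so non-linear extensions keep working.
    with np.errstate(invalid="ignore"):
        corr = float(np.corrcoef(ct_pred, ash_pred)[0, 1])
    return GravimetricComparison(
        ash_slope=float(res.slope), ash_intercept=float(res.intercept),
        hu_grid=hu_grid, residual_curve=ct_pred - ash_pred,
        prediction_correlation=corr)
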
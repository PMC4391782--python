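"""Elemental ratio maps, masked ROI statistics and cross-modality correlation.

Per-pixel Ca/P and Ca/Zn molar-ratio maps are formed by map arithmetic on
quantified (mmol/cm3) element maps; masked region statistics, joint-density
(correlation) plots with peak detection, bicolor overlays and line profiles
support the same analyses that relate elemental footprints to segmented
mineral-density volumes. All views are pure: they never alter stored data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as _sps

from .images import ElementMap

__all__ = [
    "RatioMap", "MaskedStats", "DensityPlot", "map_math", "masked_stats",
    "density_plot", "bicolor_overlay", "line_profile",
    "md_vs_ratio_correlation",
]


@dataclass
class RatioMap:
    """Per-pixel ratio of two element maps with a validity mask.

    Pixels whose denominator falls below the detection floor (or is NaN) are
    invalid and excluded from every downstream statistic.
    """

    numerator: str
    denominator: str
    data: np.ndarray
    valid: np.ndarray
    pixel_size_um: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class MaskedStats:
    roi: str
    mean: float
    sd: float
    n_pixels: int
    method: str

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be positive")


@dataclass
class DensityPlot:
    """Joint histogram of two element maps plus detected concentration peaks."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    peaks: list[tuple[int, int]]
    character: str  # "localized" (>=2 separated peaks) or "spread"


def _check_geometry(a: ElementMap, b: ElementMap) -> None:
    if a.shape != b.shape:
        raise ValueError(f"map geometry mismatch: {a.shape} vs {b.shape}")
    if not np.isclose(a.pixel_size_um, b.pixel_size_um):
        raise ValueError("pixel sizes differ between maps")


def map_math(a: ElementMap, b: ElementMap, op: str = "/",
             denominator_floor: float = 0.0):
    """Pixelwise arithmetic between aligned maps.

    ``+``/``-`` require identical units and return an ElementMap; ``*``
    likewise (units tracked as a product label); ``/`` between same-unit maps
    returns a dimensionless :class:`RatioMap` whose validity mask excludes
    pixels with denominator <= ``denominator_floor`` or non-finite entries.
    """
    _check_geometry(a, b)
    if a.units != b.units:
        raise ValueError(f"unit mismatch: {a.units!r} vs {b.units!r}")
    if op == "/":
        valid = np.isfinite(a.data) & np.isfinite(b.data) & (b.data > denominator_floor)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(valid, a.data / np.where(valid, b.data, 1.0), np.nan)
        return RatioMap(numerator=a.element, denominator=b.element, data=ratio,
                        valid=valid, pixel_size_um=a.pixel_size_um,
                        meta={"units": a.units, "floor": denominator_floor})
    ops = {"+": np.add, "-": np.subtract, "*": np.multiply}
    if op not in ops:
        raise ValueError(f"unknown operation {op!r}")
    units = a.units if op in "+-" else f"({a.units})^2"
    return ElementMap(element=f"{a.element}{op}{b.element}",
                      data=ops[op](a.data, b.data), units=a.units,
                      pixel_size_um=a.pixel_size_um,
                      meta={"derived_units": units})


def masked_stats(ratio: RatioMap, mask: np.ndarray | None = None,
                 method: str = "mean-of-ratios", roi: str = "roi") -> MaskedStats:
    """Mean +/- sd of a ratio map over the valid pixels of a mask.

    ``mean-of-ratios`` (default) averages the per-pixel ratios — the
    map-math-then-average reading. ``ratio-of-means`` divides the masked mean
    numerator by the masked mean denominator; it is exact when the ratio map
    was built with :func:`ratio_with_denominator` (which stashes denominator
    values), and otherwise falls back to the harmonic mean of the per-pixel
    ratios, which equals ratio-of-means when the numerator is spatially
    constant. Both methods agree exactly on constant-ratio fields.
    """
    if mask is None:
        mask = np.ones(ratio.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ratio.shape:
        raise ValueError("mask shape must match ratio map shape")
    sel = mask & ratio.valid
    if not sel.any():
        raise ValueError("mask contains no valid pixels")
    vals = ratio.data[sel]
    if method == "mean-of-ratios":
        mean = float(vals.mean())
        sd = float(vals.std(ddof=0))
    elif method == "ratio-of-means":
        den = ratio.meta.get("denominator_values")
        if den is not None:
            d = np.asarray(den)[sel]
            mean = float((vals * d).sum() / d.sum())
        else:
            mean = float(1.0 / np.mean(1.0 / vals)) if np.all(vals != 0) else float("nan")
        sd = float(vals.std(ddof=0))
    else:
        raise ValueError(f"unknown method {method!r}")
    return MaskedStats(roi=roi, mean=mean, sd=sd, n_pixels=int(sel.sum()),
                       method=method)


def ratio_with_denominator(a: ElementMap, b: ElementMap,
                           denominator_floor: float = 0.0) -> RatioMap:
    """Like ``map_math(a, b, '/')`` but stashing denominator values so
    ratio-of-means statistics are exact."""
    rm = map_math(a, b, "/", denominator_floor=denominator_floor)
    rm.meta["denominator_values"] = b.data.copy()
    return rm


def density_plot(a: ElementMap, b: ElementMap, mask: np.ndarray | None = None,
                 bins: int | tuple[int, int] = 64,
                 min_peak_fraction: float = 0.05,
                 min_separation_bins: int = 3) -> DensityPlot:
    """Joint (a, b) histogram over the mask, with concentration-peak detection.

    A bin is a peak when it is a strict local maximum (8-neighborhood) holding
    at least ``min_peak_fraction`` of the masked counts; peaks closer than
    ``min_separation_bins`` (Chebyshev) are merged, keeping the taller. Two or
    more surviving peaks classify the joint distribution as "localized"
    (distinct concentrated zones); otherwise it is "spread".
    """
    _check_geometry(a, b)
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sel = mask & np.isfinite(a.data) & np.isfinite(b.data)
    if not sel.any():
        raise ValueError("mask contains no valid pixels")
    counts, xe, ye = np.histogram2d(a.data[sel], b.data[sel], bins=bins)
    total = counts.sum()
    local_max = counts == ndi.maximum_filter(counts, size=3, mode="constant")
    cand = np.argwhere(local_max & (counts >= min_peak_fraction * total))
    cand = sorted(map(tuple, cand), key=lambda ij: -counts[ij])
    peaks: list[tuple[int, int]] = []
    for ij in cand:
        if all(max(abs(ij[0] - p[0]), abs(ij[1] - p[1])) >= min_separation_bins
               for p in peaks):
            peaks.append((int(ij[0]), int(ij[1])))
    character = "localized" if len(peaks) >= 2 else "spread"
    return DensityPlot(x_edges=xe, y_edges=ye, counts=counts,
                       peaks=peaks, character=character)


def bicolor_overlay(a: ElementMap, b: ElementMap,
                    percentiles: tuple[float, float] = (1.0, 99.0),
                    a_channel: str = "blue", b_channel: str = "red"
                    ) -> tuple[np.ndarray, dict]:
    """Two-channel composite of two maps (e.g. Ca in blue, Zn in red).

    Each map is normalized to [0, 1] over its stated percentile range; the
    returned RGB float image mixes the channels so overlap reads as shades of
    pink/purple. Normalization parameters are returned as metadata; inputs
    are not modified.
    """
    _check_geometry(a, b)
    chan_idx = {"red": 0, "green": 1, "blue": 2}
    if a_channel == b_channel:
        raise ValueError("maps must use distinct color channels")
    rgb = np.zeros(a.shape + (3,))
    norms = {}
    for m, chan in ((a, a_channel), (b, b_channel)):
        finite = m.data[np.isfinite(m.data)]
        lo, hi = np.percentile(finite, percentiles)
        span = hi - lo if hi > lo else 1.0
        rgb[..., chan_idx[chan]] = np.clip(
            (np.nan_to_num(m.data, nan=lo) - lo) / span, 0.0, 1.0)
        norms[m.element] = {"channel": chan, "lo": float(lo), "hi": float(hi)}
    return rgb, {"percentiles": percentiles, "normalization": norms}


def line_profile(m: ElementMap, polyline: Sequence[tuple[float, float]],
                 width: int = 1) -> pd.Series:
    """Values along a polyline, averaged across ``width`` perpendicular samples.

    ``polyline`` is a sequence of (y, x) pixel coordinates; samples are taken
    at pixel pitch by bilinear interpolation and the index of the returned
    series is distance in millimetres from the first vertex.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must contain at least two (y, x) vertices")
    ny, nx = m.shape
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > ny - 1) \
            or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > nx - 1):
        raise ValueError("polyline must lie inside the raster")
    samples, dists = [], []
    travelled = 0.0
    for p0, p1 in zip(pts[:-1], pts[1:]):
        seg = p1 - p0
        seg_len = float(np.hypot(*seg))
        if seg_len == 0:
            continue
        n = max(int(np.ceil(seg_len)), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        if travelled > 0:
            t = t[1:]  # avoid duplicating the shared vertex
        pos = p0[None, :] + t[:, None] * seg[None, :]
        normal = np.array([-seg[1], seg[0]]) / seg_len
        offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
        acc = np.zeros(len(pos))
        for off in offsets:
            coords = (pos + off * normal[None, :]).T
            acc += ndi.map_coordinates(m.data, coords, order=1, mode="nearest")
        samples.append(acc / len(offsets))
        dists.append(travelled + t * seg_len)
        travelled += seg_len
    dist_px = np.concatenate(dists)
    values = np.concatenate(samples)
    dist_mm = dist_px * m.pixel_size_um * 1e-3
    return pd.Series(values, index=pd.Index(dist_mm, name="distance_mm"),
                     name=m.element)


def md_vs_ratio_correlation(points: Sequence[tuple[str, float, float]]):
    """OLS fit and Pearson r of mean mineral density vs mean elemental ratio.

    ``points`` are (tissue, mean_md_mgcc, mean_ratio) tuples, one per tissue
    or zone. Returns a DataFrame of per-point residuals plus the fit
    (slope, intercept, r).
    """
    if len(points) < 3:
        raise ValueError("need at least three (tissue, MD, ratio) points")
    df = pd.DataFrame(points, columns=["tissue", "mean_md", "mean_ratio"])
    if df["mean_ratio"].nunique() == 1:
        slope, intercept, r = 0.0, float(df["mean_md"].mean()), 0.0
    else:
        res = _sps.linregress(df["mean_ratio"], df["mean_md"])
        slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    df["predicted_md"] = slope * df["mean_ratio"] + intercept
    df["residual"] = df["mean_md"] - df["predicted_md"]
    return {"slope": slope, "intercept": intercept, "r": r, "points": df}
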
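"""Mineral-density segmentation via intensity-gradient histogram seeding.

A calibrated volume is discretized into mineral-density segments in four
steps: (1) compute the gradient-magnitude landscape; (2) build the joint 2D
histogram of intensity vs gradient magnitude — material phases appear as
low-gradient modes, interfaces as high-gradient arches between them; (3)
choose seed loci (rectangles in the histogram plane) over the modes, either
manually or automatically from low-gradient intensity peaks; (4) flood the
gradient landscape from the seed voxels with a marker-based watershed, which
places segment boundaries on gradient crests. Per-segment HU statistics are
converted to mineral density through the phantom calibration line.

Watershed determinism contract
------------------------------
The flood is a priority queue ordered by ``(landscape value, insertion
index)``. Marker voxels are scanned in raster (C) order at initialization;
neighbor candidates are visited in fixed axis order (-z, +z, -y, +y, -x, +x
for 3D). A queued voxel is claimed by the earliest insertion among ties, so
results are platform-stable and reproducible by any re-implementation of the
same contract (e.g. a linear-scan flood without a heap).
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import find_peaks

from .calibrate import CalibrationModel, md_from_hu
from .config import tissue_config
from .images import LabelMap, Volume

__all__ = [
    "Histogram2D", "SeedLocus", "SegmentStats", "DentinZoneClass",
    "gradient_magnitude", "histogram2d", "select_seed_loci", "locus_markers",
    "watershed_segment", "flood_from_markers", "segment_stats",
    "slice_profile", "classify_dentin_zones", "default_zone_cutoffs",
    "iterate_segmentation", "dice_coefficient",
]


@dataclass
class Histogram2D:
    """Joint (intensity, gradient magnitude) histogram of masked voxels."""

    intensity_edges: np.ndarray
    gradient_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.intensity_edges) <= 0) or \
                np.any(np.diff(self.gradient_edges) <= 0):
            raise ValueError("histogram edges must be strictly increasing")


@dataclass
class SeedLocus:
    """A rectangle in the (intensity, gradient) plane seeding one segment."""

    locus_id: int
    intensity_lo: float
    intensity_hi: float
    gradient_lo: float
    gradient_hi: float
    expected_tissue: str | None = None

    def __post_init__(self) -> None:
        if not (self.intensity_lo < self.intensity_hi
                and self.gradient_lo < self.gradient_hi):
            raise ValueError(f"locus {self.locus_id}: ranges must satisfy lo < hi")


@dataclass
class SegmentStats:
    label_id: int
    n_voxels: int
    volume_mm3: float
    mean_hu: float
    sd_hu: float
    mean_md: float
    sd_md: float
    md_min: float
    md_max: float
    zone: str | None = None

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")
        if not self.md_min - 1e-9 <= self.mean_md <= self.md_max + 1e-9:
            raise ValueError("mean_md must lie within [md_min, md_max]")


@dataclass
class DentinZoneClass:
    """Ordered, non-overlapping HU intervals classifying dentin segments."""

    cutoffs: dict[str, tuple[float, float | None]] = field(
        default_factory=lambda: default_zone_cutoffs())

    def __post_init__(self) -> None:
        items = sorted(self.cutoffs.items(), key=lambda kv: kv[1][0])
        prev_hi = -np.inf
        for name, (lo, hi) in items:
            hi_val = np.inf if hi is None else hi
            if lo >= hi_val:
                raise ValueError(f"zone {name!r}: lo must be < hi")
            if lo < prev_hi:
                raise ValueError("zone intervals must be non-overlapping and ordered")
            prev_hi = hi_val

    def classify(self, mean_hu: float) -> str:
        for name, (lo, hi) in self.cutoffs.items():
            hi_val = np.inf if hi is None else hi
            if lo <= mean_hu <= hi_val:
                return name
        return "unclassified"


def default_zone_cutoffs() -> dict[str, tuple[float, float | None]]:
    raw = tissue_config()["dentin_zone_cutoffs_hu"]
    return {k: (float(v[0]), None if v[1] is None else float(v[1]))
            for k, v in raw.items()}


# ---------------------------------------------------------------------------
# gradient and histogram

def gradient_magnitude(volume: Volume | np.ndarray, method: str = "central") -> np.ndarray:
    """Euclidean norm of the per-axis gradient (HU per voxel).

    ``central`` uses central differences with edge replication (exact on
    linear ramps); ``sobel`` uses the smoothing Sobel operator, normalized so
    a linear ramp of slope s also yields magnitude s in the interior.
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=float)
    if any(n < 2 for n in data.shape):
        raise ValueError("volume must have at least 2 voxels per axis")
    sq = np.zeros_like(data)
    if method == "central":
        padded = np.pad(data, 1, mode="edge")
        core = tuple(slice(1, -1) for _ in range(data.ndim))
        for ax in range(data.ndim):
            up = list(core)
            dn = list(core)
            up[ax] = slice(2, None)
            dn[ax] = slice(None, -2)
            g = (padded[tuple(up)] - padded[tuple(dn)]) / 2.0
            sq += g * g
    elif method == "sobel":
        norm = 2.0 * 4.0 ** (data.ndim - 1)
        for ax in range(data.ndim):
            g = ndi.sobel(data, axis=ax, mode="nearest") / norm
            sq += g * g
    else:
        raise ValueError(f"unknown gradient method {method!r}")
    return np.sqrt(sq)


def histogram2d(volume: Volume | np.ndarray, gradmag: np.ndarray,
                bins: tuple[int, int] = (256, 64),
                mask: np.ndarray | None = None) -> Histogram2D:
    """Joint histogram of intensity vs gradient magnitude over the mask.

    Counts sum to the number of masked voxels; the high-gradient arches
    between material modes are an interface diagnostic.
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=float)
    gradmag = np.asarray(gradmag, dtype=float)
    if gradmag.shape != data.shape:
        raise ValueError("gradient magnitude shape must match volume shape")
    if mask is None:
        vals, grads = data.ravel(), gradmag.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise ValueError("mask shape must match volume shape")
        if not mask.any():
            raise ValueError("mask selects no voxels")
        vals, grads = data[mask], gradmag[mask]
    counts, ie, ge = np.histogram2d(vals, grads, bins=bins)
    return Histogram2D(intensity_edges=ie, gradient_edges=ge, counts=counts)


# ---------------------------------------------------------------------------
# seed loci

def select_seed_loci(hist: Histogram2D, mode: str = "auto",
                     boxes: Sequence[SeedLocus] | None = None,
                     gradient_quantile: float = 0.5,
                     min_separation_bins: int = 8,
                     prominence_frac: float = 0.05,
                     height_frac: float = 0.2,
                     min_mass_frac: float = 3e-4) -> list[SeedLocus]:
    """Seed loci from the 2D histogram.

    ``manual`` validates user boxes (pairwise disjoint in the histogram
    plane). ``auto`` restricts to the low-gradient band (cumulative gradient
    quantile), then finds intensity peaks on the log-scaled, lightly smoothed
    count profile — material modes can differ by orders of magnitude in
    height (a homogeneous tissue concentrates its mass in a few bins, a
    heterogeneous one spreads it), so prominence is assessed on the log
    scale. Peaks must be separated by ``min_separation_bins``, have log
    prominence at least ``prominence_frac`` of the log-profile maximum, and
    hold at least ``min_mass_frac`` of the masked voxels in their (smoothed)
    peak bin — rejecting log-scale wiggles in sparse tails; each
    is widened until the raw profile drops below ``height_frac`` of its own
    peak height (clipped at midpoints between neighbors, keeping loci
    disjoint).
    """
    if hist.counts.sum() == 0:
        raise ValueError("histogram is empty")
    if mode == "manual":
        if not boxes:
            raise ValueError("manual mode requires locus boxes")
        for i, a in enumerate(boxes):
            for b in list(boxes)[i + 1:]:
                if (a.intensity_lo < b.intensity_hi and b.intensity_lo < a.intensity_hi
                        and a.gradient_lo < b.gradient_hi and b.gradient_lo < a.gradient_hi):
                    raise ValueError(f"loci {a.locus_id} and {b.locus_id} overlap")
        return list(boxes)
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    # gradient cutoff: smallest gradient-bin prefix holding >= quantile of mass
    gmass = hist.counts.sum(axis=0)
    cum = np.cumsum(gmass) / gmass.sum()
    gbin = int(np.searchsorted(cum, gradient_quantile) + 1)
    profile = hist.counts[:, :gbin].sum(axis=1)
    smooth = np.convolve(profile, np.ones(3) / 3.0, mode="same")
    log_prof = np.log1p(smooth)
    padded = np.concatenate([[0.0], log_prof, [0.0]])
    peaks, _ = find_peaks(padded, distance=max(min_separation_bins, 1),
                          prominence=prominence_frac * padded.max())
    peaks = peaks - 1
    # a material mode must hold real mass, not just a log-scale tail wiggle
    total = hist.counts.sum()
    peaks = peaks[smooth[peaks] >= min_mass_frac * total]
    if len(peaks) == 0:
        raise ValueError("no histogram peaks found; try more bins, a lower "
                         "prominence threshold, or a higher gradient quantile")
    centers = 0.5 * (hist.intensity_edges[:-1] + hist.intensity_edges[1:])
    loci: list[SeedLocus] = []
    for i, p in enumerate(peaks):
        height = smooth[p]
        lo_bin = p
        while lo_bin > 0 and smooth[lo_bin - 1] >= height_frac * height:
            lo_bin -= 1
        hi_bin = p
        while hi_bin < len(profile) - 1 and smooth[hi_bin + 1] >= height_frac * height:
            hi_bin += 1
        # keep loci disjoint: clip at midpoints to neighboring peaks
        if i > 0:
            lo_bin = max(lo_bin, (peaks[i - 1] + p) // 2 + 1)
        if i < len(peaks) - 1:
            hi_bin = min(hi_bin, (p + peaks[i + 1]) // 2 - 1)
        hi_bin = max(hi_bin, lo_bin)
        loci.append(SeedLocus(
            locus_id=i + 1,
            intensity_lo=float(hist.intensity_edges[lo_bin]),
            intensity_hi=float(hist.intensity_edges[hi_bin + 1]),
            gradient_lo=float(hist.gradient_edges[0]),
            gradient_hi=float(hist.gradient_edges[gbin]),
        ))
    # ensure peak-center bins stay inside their locus after clipping
    for locus, p in zip(loci, peaks):
        if not locus.intensity_lo <= centers[p] < locus.intensity_hi:
            raise AssertionError("internal error: peak fell outside its locus")
    return loci


def locus_markers(volume_hu: np.ndarray, gradmag: np.ndarray,
                  loci: Sequence[SeedLocus],
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Marker label array: voxels whose (intensity, gradient) falls in a locus.

    Upper edges are inclusive so histogram-derived loci capture their peak
    bins exactly. Raises if any locus produces no marker voxels.
    """
    if mask is None:
        mask = np.ones(volume_hu.shape, dtype=bool)
    markers = np.zeros(volume_hu.shape, dtype=np.int32)
    for locus in loci:
        sel = (mask & (markers == 0)
               & (volume_hu >= locus.intensity_lo) & (volume_hu <= locus.intensity_hi)
               & (gradmag >= locus.gradient_lo) & (gradmag <= locus.gradient_hi))
        if not sel.any():
            raise ValueError(f"locus {locus.locus_id} selects no marker voxels")
        markers[sel] = locus.locus_id
    return markers


# ---------------------------------------------------------------------------
# watershed flood

def _neighbor_steps(shape: tuple[int, ...]) -> list[tuple[int, int, int]]:
    """(axis, direction, flat offset) in the documented fixed order."""
    strides = []
    acc = 1
    for n in reversed(shape):
        strides.append(acc)
        acc *= n
    strides = strides[::-1]
    return [(ax, d, d * strides[ax]) for ax in range(len(shape)) for d in (-1, +1)]


def flood_from_markers(landscape: np.ndarray, markers: np.ndarray,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Marker-based priority flood of a scalar landscape (the watershed core).

    Implements the determinism contract in the module docstring: pops ordered
    by (landscape value, insertion index); markers scanned in raster order;
    neighbors in fixed axis order. Face connectivity (6-neighborhood in 3D).
    """
    landscape = np.asarray(landscape, dtype=float)
    markers = np.asarray(markers)
    if markers.shape != landscape.shape:
        raise ValueError("markers shape must match landscape shape")
    if mask is None:
        mask = np.ones(landscape.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    labels = np.where(mask, markers, 0).astype(np.int32)
    shape = landscape.shape
    steps = _neighbor_steps(shape)
    flat_land = landscape.ravel()
    flat_lab = labels.ravel()
    flat_mask = mask.ravel()
    # axis coordinate per flat index, for boundary checks without unravel
    sizes = shape
    divisors = []
    acc = 1
    for n in reversed(sizes):
        divisors.append(acc)
        acc *= n
    divisors = divisors[::-1]

    def coord(idx: int, ax: int) -> int:
        return (idx // divisors[ax]) % sizes[ax]

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    # initial frontier: restrict the raster scan to marker voxels that touch
    # an unlabeled masked voxel (same order as scanning all markers)
    lab_nd = flat_lab.reshape(shape)
    boundary = np.zeros(shape, dtype=bool)
    inside = lab_nd > 0
    for ax in range(len(shape)):
        for d in (-1, +1):
            shifted = np.roll(inside, -d, axis=ax)
            # roll wraps; invalidate wrapped slots
            sl = [slice(None)] * len(shape)
            sl[ax] = slice(-1, None) if d > 0 else slice(0, 1)
            shifted[tuple(sl)] = False
            boundary |= inside & ~shifted & np.roll(flat_mask.reshape(shape), -d, axis=ax)
    # (the roll of mask may wrap too, but boundary voxels are only used as
    # scan candidates; neighbor validity is re-checked per push below)
    for idx in np.flatnonzero(boundary.ravel()):
        lab = flat_lab[idx]
        for ax, d, off in steps:
            c = coord(idx, ax)
            if (d < 0 and c == 0) or (d > 0 and c == sizes[ax] - 1):
                continue
            n_idx = idx + off
            if flat_mask[n_idx] and flat_lab[n_idx] == 0:
                heapq.heappush(heap, (flat_land[n_idx], counter, lab, n_idx))
                counter += 1
    while heap:
        _, _, lab, idx = heapq.heappop(heap)
        if flat_lab[idx] != 0:
            continue
        flat_lab[idx] = lab
        for ax, d, off in steps:
            c = coord(idx, ax)
            if (d < 0 and c == 0) or (d > 0 and c == sizes[ax] - 1):
                continue
            n_idx = idx + off
            if flat_mask[n_idx] and flat_lab[n_idx] == 0:
                heapq.heappush(heap, (flat_land[n_idx], counter, lab, n_idx))
                counter += 1
    return flat_lab.reshape(shape)


def watershed_segment(volume_hu: Volume | np.ndarray, loci: Sequence[SeedLocus],
                      mask: np.ndarray | None = None,
                      gradmag: np.ndarray | None = None) -> LabelMap:
    """Marker-based watershed on the gradient-magnitude landscape.

    Every masked voxel ends up with exactly one label; label ids follow locus
    ids. With a single locus all masked voxels receive its label directly.
    """
    data = volume_hu.data if isinstance(volume_hu, Volume) else np.asarray(volume_hu, dtype=float)
    if not loci:
        raise ValueError("at least one seed locus is required")
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if gradmag is None:
        gradmag = gradient_magnitude(data)
    markers = locus_markers(data, gradmag, loci, mask)
    if len(loci) == 1:
        labels = np.where(mask, loci[0].locus_id, 0).astype(np.int32)
    else:
        labels = flood_from_markers(gradmag, markers, mask)
    return LabelMap(labels=labels, mask=mask,
                    meta={"loci": [vars(l).copy() for l in loci]})


# ---------------------------------------------------------------------------
# statistics

def segment_stats(labels: LabelMap | np.ndarray, volume_hu: Volume | np.ndarray,
                  calib: CalibrationModel,
                  voxel_size_um: float | None = None,
                  zones: DentinZoneClass | None = None) -> list[SegmentStats]:
    """Per-segment HU and mineral-density statistics.

    Means/sds are computed in HU and converted through the affine calibration
    (for an affine map the mean converts exactly; sd converts as
    ``|slope| * sd_hu``). Volume is ``n_voxels * voxel_size^3``.
    """
    if isinstance(labels, LabelMap):
        lab, mask = labels.labels, labels.mask
    else:
        lab = np.asarray(labels)
        mask = lab > 0
    if isinstance(volume_hu, Volume):
        data = volume_hu.data
        vox = volume_hu.voxel_size_um if voxel_size_um is None else voxel_size_um
    else:
        data = np.asarray(volume_hu, dtype=float)
        vox = 3.84 if voxel_size_um is None else voxel_size_um
    if lab.shape != data.shape:
        raise ValueError("labels shape must match volume shape")
    out: list[SegmentStats] = []
    ids = np.unique(lab[mask])
    ids = ids[ids > 0]
    for lid in ids:
        vals = data[(lab == lid) & mask]
        if vals.size == 0:
            continue
        mean_hu = float(vals.mean())
        sd_hu = float(vals.std(ddof=0))
        md_lo = float(md_from_hu(vals.min(), calib))
        md_hi = float(md_from_hu(vals.max(), calib))
        st = SegmentStats(
            label_id=int(lid), n_voxels=int(vals.size),
            volume_mm3=float(vals.size) * (vox * 1e-3) ** 3,
            mean_hu=mean_hu, sd_hu=sd_hu,
            mean_md=float(md_from_hu(mean_hu, calib)),
            sd_md=abs(calib.slope) * sd_hu,
            md_min=min(md_lo, md_hi), md_max=max(md_lo, md_hi))
        if zones is not None:
            st.zone = zones.classify(st.mean_hu)
        out.append(st)
    return out


def stats_table(stats: Sequence[SegmentStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats])


def slice_profile(volume_hu: Volume | np.ndarray, roi: np.ndarray | None = None,
                  axis: int = 0, calib: CalibrationModel | None = None) -> pd.Series:
    """Per-slice mean HU (or MD, if a calibration is given) within an ROI."""
    data = volume_hu.data if isinstance(volume_hu, Volume) else np.asarray(volume_hu, dtype=float)
    if roi is None:
        roi = np.ones(data.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    other = tuple(a for a in range(data.ndim) if a != axis)
    span = np.nonzero(roi.any(axis=other))[0]
    vals = []
    for i in span:
        m = roi.take(i, axis=axis)
        vals.append(data.take(i, axis=axis)[m].mean())
    prof = pd.Series(vals, index=span, name="mean_hu")
    if calib is not None:
        prof = pd.Series(md_from_hu(prof.to_numpy(), calib), index=span, name="mean_md")
    return prof


def classify_dentin_zones(stats: Sequence[SegmentStats],
                          cutoffs: DentinZoneClass | None = None) -> list[SegmentStats]:
    """Assign each segment a dentin zone by its mean HU (in place and returned)."""
    zones = cutoffs or DentinZoneClass()
    for st in stats:
        st.zone = zones.classify(st.mean_hu)
    return list(stats)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * float((a & b).sum()) / float(denom)


def iterate_segmentation(volume_hu: Volume | np.ndarray,
                         calib: CalibrationModel,
                         mask: np.ndarray | None = None,
                         bins: tuple[int, int] = (256, 64),
                         alpha: float = 0.05,
                         max_iter: int = 5,
                         max_sample: int = 20000,
                         seed: int = 0,
                         initial_loci: Sequence[SeedLocus] | None = None,
                         **loci_kwargs):
    """Iterative locus refinement: re-segment until all segments differ.

    Mirrors the manual refine-and-rerun workflow with an automatic acceptance
    criterion: after each pass, Welch t-tests compare every pair of segment
    HU samples (subsampled to ``max_sample`` voxels); if a pair is not
    significantly different at ``alpha`` (Bonferroni over the pairs), their
    loci are merged and the flood repeats.

    Returns ``(LabelMap, list[SegmentStats], loci)``.
    """
    from scipy.stats import ttest_ind

    data = volume_hu.data if isinstance(volume_hu, Volume) else np.asarray(volume_hu, dtype=float)
    gradmag = gradient_magnitude(data)
    if initial_loci is not None:
        loci = list(initial_loci)
    else:
        hist = histogram2d(data, gradmag, bins=bins, mask=mask)
        loci = select_seed_loci(hist, mode="auto", **loci_kwargs)
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        label_map = watershed_segment(data, loci, mask=mask, gradmag=gradmag)
        stats = segment_stats(label_map, volume_hu, calib)
        if len(stats) < 2:
            return label_map, stats, loci
        m = len(stats) * (len(stats) - 1) // 2
        merge_pair = None
        worst_p = alpha
        for i in range(len(stats)):
            for j in range(i + 1, len(stats)):
                va = data[label_map.labels == stats[i].label_id]
                vb = data[label_map.labels == stats[j].label_id]
                if va.size > max_sample:
                    va = rng.choice(va, max_sample, replace=False)
                if vb.size > max_sample:
                    vb = rng.choice(vb, max_sample, replace=False)
                p = float(ttest_ind(va, vb, equal_var=False).pvalue)
                p_adj = min(1.0, m * p)
                if p_adj >= worst_p:
                    worst_p = p_adj
                    merge_pair = (stats[i].label_id, stats[j].label_id)
        if merge_pair is None:
            return label_map, stats, loci
        a, b = merge_pair
        keep = [l for l in loci if l.locus_id != b]
        la = next(l for l in keep if l.locus_id == a)
        lb = next(l for l in loci if l.locus_id == b)
        la.intensity_lo = min(la.intensity_lo, lb.intensity_lo)
        la.intensity_hi = max(la.intensity_hi, lb.intensity_hi)
        loci = [SeedLocus(locus_id=k + 1, intensity_lo=l.intensity_lo,
                          intensity_hi=l.intensity_hi, gradient_lo=l.gradient_lo,
                          gradient_hi=l.gradient_hi, expected_tissue=l.expected_tissue)
                for k, l in enumerate(keep)]
    label_map = watershed_segment(data, loci, mask=mask, gradmag=gradmag)
    return label_map, segment_stats(label_map, volume_hu, calib), loci
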
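"""Synthetic tomograms, calibration phantoms and XRF maps with known truth.

Every downstream stage of the pipeline (HU scaling, calibration fitting,
watershed segmentation, XRF quantification, ratio statistics) has a recovery
target generated here. The forward models mirror the acquisition chain:

* micro-CT: per-region mineral density fields -> HU via the emulated
  instrument's calibration line -> detector PSF blur -> additive Gaussian HU
  noise -> raw intensities under an (air, water) affine convention.
* XRF: per-pixel volume concentrations (mmol/cm3) -> area concentrations via
  the same single-layer self-absorption model the quantifier inverts ->
  detector counts via per-element gains -> optional multiplicative
  (log-normal) and Poisson noise.

All stochastic operations take an explicit integer seed (numpy PCG64).
Geometry is limited to axis-aligned boxes and z-axis cylinders; specimen
shape does not enter any recovered quantity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibrate import CalibrationModel, hu_from_md
from .config import tissue_config, xrf_config
from .images import ElementMap, Volume
from .xrf import AbsorptionContext, effective_thickness

__all__ = [
    "AcquisitionSpec", "RegionSpec", "TissuePhantomSpec", "ElementFieldSpec",
    "GroundTruth", "instrument_line", "default_acquisition",
    "make_phantom_volume", "make_tissue_volume", "make_xrf_maps",
    "tissue_region", "PHANTOM_DENSITIES",
]

#: calibration-phantom nominal densities (mg/cc) of the emulated scanner setup
PHANTOM_DENSITIES: tuple[float, ...] = tuple(
    float(v) for v in tissue_config()["phantom_densities_mgcc"])


def instrument_line() -> CalibrationModel:
    """True HU->MD line used to synthesize volumes (the recovery target)."""
    row = tissue_config()["instrument_line"]
    return CalibrationModel(slope=row["slope"], intercept=row["intercept"])


@dataclass
class AcquisitionSpec:
    """Emulated micro-CT acquisition parameters.

    ``air_intensity``/``water_intensity`` define the raw->HU affine map
    (the raw volume stores detector intensities; HU = 1000 at water, 0 at
    air). Blur is applied before noise: the PSF acts on the physical signal,
    counting noise on the recorded one.
    """

    voxel_size_um: float = 3.84
    noise_sd_hu: float = 50.0
    blur_sigma_vox: float = 1.0
    air_intensity: float = 500.0
    water_intensity: float = 1500.0

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.noise_sd_hu < 0 or self.blur_sigma_vox < 0:
            raise ValueError("noise and blur parameters must be non-negative")
        if self.water_intensity == self.air_intensity:
            raise ValueError("water_intensity must differ from air_intensity")


def default_acquisition(**overrides) -> AcquisitionSpec:
    cfg = tissue_config()["acquisition"]
    base = dict(voxel_size_um=cfg["voxel_size_um"], noise_sd_hu=cfg["noise_sd_hu"],
                blur_sigma_vox=cfg["blur_sigma_vox"])
    base.update(overrides)
    return AcquisitionSpec(**base)


@dataclass
class RegionSpec:
    """One tissue region: geometry primitive + mineral-density model.

    ``geometry`` is one of
      ``{"kind": "full"}``                                  whole volume,
      ``{"kind": "box", "lo": (z,y,x), "hi": (z,y,x)}``      fractional corners,
      ``{"kind": "cylinder", "center": (y,x), "radius": r,
         "zlo": z0, "zhi": z1}``                             fractions of shape.
    ``gradient`` is ``None`` or
      ``{"kind": "ramp", "axis": 0, "delta": d}``  (linear, -d/2..+d/2) or
      ``{"kind": "step", "axis": 0, "position": 0.5, "delta": d}``.
    """

    region_id: int
    geometry: dict[str, Any]
    md_mean: float
    md_sd: float = 0.0
    gradient: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.region_id <= 0:
            raise ValueError("region_id must be a positive integer (0 is background)")
        if self.md_mean < 0:
            raise ValueError("md_mean must be non-negative")
        if self.md_sd < 0:
            raise ValueError("md_sd must be non-negative")


@dataclass
class TissuePhantomSpec:
    shape: tuple[int, int, int] = (128, 128, 128)
    regions: Sequence[RegionSpec] = field(default_factory=list)


@dataclass
class GroundTruth:
    """What the generator actually put in: labels, true values, true line."""

    labels: np.ndarray
    region_truth: dict[int, dict[str, Any]]
    calibration: CalibrationModel | None = None
    fields: dict[str, np.ndarray] = field(default_factory=dict)
    spec: Any = None

    def __post_init__(self) -> None:
        # label partition invariant: every voxel exactly one label
        if not np.issubdtype(np.asarray(self.labels).dtype, np.integer):
            raise ValueError("ground-truth labels must be integer")


def tissue_region(name: str, region_id: int = 1,
                  geometry: dict[str, Any] | None = None,
                  gradient: dict[str, Any] | None = None) -> RegionSpec:
    """Build a RegionSpec from a named row of the packaged tissue table."""
    row = tissue_config()["tissues"][name]
    return RegionSpec(region_id=region_id,
                      geometry=geometry or {"kind": "full"},
                      md_mean=row["md_mean"], md_sd=row["md_sd"],
                      gradient=gradient)


# ---------------------------------------------------------------------------
# geometry rasterization

def _region_mask(geometry: dict[str, Any], shape: tuple[int, int, int]) -> np.ndarray:
    kind = geometry["kind"]
    nz, ny, nx = shape
    if kind == "full":
        return np.ones(shape, dtype=bool)
    if kind == "box":
        lo = [int(round(f * n)) for f, n in zip(geometry["lo"], shape)]
        hi = [int(round(f * n)) for f, n in zip(geometry["hi"], shape)]
        if any(h <= l for l, h in zip(lo, hi)) or any(l < 0 for l in lo) \
                or any(h > n for h, n in zip(hi, shape)):
            raise ValueError(f"box geometry out of bounds or empty: {geometry}")
        m = np.zeros(shape, dtype=bool)
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return m
    if kind == "cylinder":
        cy, cx = geometry["center"]
        r = geometry["radius"]
        z0 = int(round(geometry.get("zlo", 0.0) * nz))
        z1 = int(round(geometry.get("zhi", 1.0) * nz))
        if not (0 <= z0 < z1 <= nz):
            raise ValueError(f"cylinder z-range out of bounds: {geometry}")
        yy, xx = np.mgrid[0:ny, 0:nx]
        disc = (yy - cy * ny) ** 2 + (xx - cx * nx) ** 2 <= (r * min(ny, nx)) ** 2
        if not disc.any():
            raise ValueError(f"cylinder geometry rasterizes to nothing: {geometry}")
        m = np.zeros(shape, dtype=bool)
        m[z0:z1] = disc
        return m
    raise ValueError(f"unknown geometry kind {kind!r}")


def _paint_labels(spec: TissuePhantomSpec) -> np.ndarray:
    labels = np.zeros(spec.shape, dtype=np.int32)
    occupied = np.zeros(spec.shape, dtype=bool)
    for reg in spec.regions:
        m = _region_mask(reg.geometry, spec.shape)
        if (occupied & m).any():
            raise ValueError(f"region {reg.region_id} overlaps a previous region")
        occupied |= m
        labels[m] = reg.region_id
    return labels


def _gradient_field(grad: dict[str, Any] | None, mask: np.ndarray) -> np.ndarray:
    """Additive MD modulation over a region, zero-mean by construction."""
    if grad is None:
        return np.zeros(mask.shape)
    axis = int(grad.get("axis", 0))
    idx = np.nonzero(mask.any(axis=tuple(a for a in range(mask.ndim) if a != axis)))[0]
    lo, hi = idx.min(), idx.max()
    coord = np.arange(mask.shape[axis], dtype=float)
    frac = np.clip((coord - lo) / max(hi - lo, 1), 0.0, 1.0)
    if grad["kind"] == "ramp":
        prof = (frac - 0.5) * grad["delta"]
    elif grad["kind"] == "step":
        pos = grad.get("position", 0.5)
        prof = np.where(frac < pos, -0.5, 0.5) * grad["delta"]
    else:
        raise ValueError(f"unknown gradient kind {grad['kind']!r}")
    shape = [1] * mask.ndim
    shape[axis] = mask.shape[axis]
    return np.broadcast_to(prof.reshape(shape), mask.shape).copy()


# ---------------------------------------------------------------------------
# micro-CT forward model

def _hu_to_raw(hu: np.ndarray, acq: AcquisitionSpec) -> np.ndarray:
    return acq.air_intensity + (acq.water_intensity - acq.air_intensity) * hu / 1000.0


def _acquire(hu_clean: np.ndarray, acq: AcquisitionSpec, seed: int | None) -> np.ndarray:
    """Blur then noise in HU space; return raw detector intensities."""
    hu = hu_clean
    if acq.blur_sigma_vox > 0:
        hu = gaussian_filter(hu, acq.blur_sigma_vox, mode="nearest")
    if acq.noise_sd_hu > 0:
        if seed is None:
            raise ValueError("seed is required when noise_sd_hu > 0")
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, acq.noise_sd_hu, size=hu.shape)
    return _hu_to_raw(hu, acq)


def make_phantom_volume(densities: Sequence[float],
                        acq: AcquisitionSpec | None = None,
                        calib_truth: CalibrationModel | None = None,
                        shape: tuple[int, int, int] = (32, 160, 160),
                        seed: int | None = None,
                        ) -> tuple[Volume, GroundTruth]:
    """Raw-intensity volume of cylindrical density inserts on an air background.

    One z-axis cylinder per requested density, laid out on a square grid.
    The ground truth records the insert labels and the true MD of each.
    """
    densities = [float(d) for d in densities]
    if not densities:
        raise ValueError("densities must be non-empty")
    if any(d < 0 for d in densities):
        raise ValueError("densities must be non-negative")
    acq = acq or default_acquisition()
    calib_truth = calib_truth or instrument_line()
    n = len(densities)
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    radius = 0.5 / max(ncol, nrow) * 0.6  # fraction of min(ny, nx)
    regions = []
    for k, d in enumerate(densities):
        r, c = divmod(k, ncol)
        regions.append(RegionSpec(
            region_id=k + 1,
            geometry={"kind": "cylinder",
                      "center": ((r + 0.5) / nrow, (c + 0.5) / ncol),
                      "radius": radius},
            md_mean=d))
    spec = TissuePhantomSpec(shape=shape, regions=regions)
    labels = _paint_labels(spec)
    hu = np.zeros(shape)  # background: air at 0 HU
    truth: dict[int, dict[str, Any]] = {}
    for reg, d in zip(regions, densities):
        m = labels == reg.region_id
        hu[m] = hu_from_md(d, calib_truth)
        truth[reg.region_id] = {"md": d, "hu": float(hu_from_md(d, calib_truth))}
    raw = _acquire(hu, acq, seed)
    vol = Volume(raw, voxel_size_um=acq.voxel_size_um, units="raw",
                 meta={"seed": seed, "kind": "phantom",
                       "air_intensity": acq.air_intensity,
                       "water_intensity": acq.water_intensity})
    gt = GroundTruth(labels=labels, region_truth=truth,
                     calibration=calib_truth, spec=spec)
    return vol, gt


def make_tissue_volume(spec: TissuePhantomSpec,
                       acq: AcquisitionSpec | None = None,
                       calib_truth: CalibrationModel | None = None,
                       seed: int | None = None,
                       background_hu: float = 0.0,
                       ) -> tuple[Volume, GroundTruth]:
    """Raw-intensity volume of tissue regions with per-voxel MD variation.

    Each region's voxel MD is drawn Normal(md_mean, md_sd), modulated by its
    gradient descriptor, mapped through the true calibration line, blurred and
    noised. Background voxels (label 0) sit at ``background_hu`` (air).
    """
    acq = acq or default_acquisition()
    calib_truth = calib_truth or instrument_line()
    labels = _paint_labels(spec)
    rng = np.random.default_rng(seed)
    md = np.zeros(spec.shape)
    truth: dict[int, dict[str, Any]] = {}
    needs_seed = acq.noise_sd_hu > 0 or any(r.md_sd > 0 for r in spec.regions)
    if needs_seed and seed is None:
        raise ValueError("seed is required for stochastic synthesis")
    for reg in spec.regions:
        m = labels == reg.region_id
        field_md = np.full(spec.shape, float(reg.md_mean))
        field_md += _gradient_field(reg.gradient, m)
        if reg.md_sd > 0:
            field_md = field_md + rng.normal(0.0, reg.md_sd, size=spec.shape)
        md[m] = field_md[m]
        truth[reg.region_id] = {"md_mean": reg.md_mean, "md_sd": reg.md_sd,
                                "n_voxels": int(m.sum()),
                                "hu_mean": float(hu_from_md(reg.md_mean, calib_truth))}
    hu = np.where(labels > 0, hu_from_md(md, calib_truth), background_hu)
    raw = _acquire(hu, acq, seed + 1 if seed is not None else None)
    vol = Volume(raw, voxel_size_um=acq.voxel_size_um, units="raw",
                 meta={"seed": seed, "kind": "tissue",
                       "air_intensity": acq.air_intensity,
                       "water_intensity": acq.water_intensity})
    gt = GroundTruth(labels=labels, region_truth=truth, calibration=calib_truth,
                     fields={"md_clean": md}, spec=spec)
    return vol, gt


# ---------------------------------------------------------------------------
# XRF forward model

@dataclass
class ElementFieldSpec:
    """Scene description for synthetic Ca/P/Zn maps.

    ``scene`` selects the spatial layout:

    * ``{"kind": "uniform", "ratio_ca_p": m, "ratio_ca_p_sd": s,
       "ratio_ca_zn": m2, "ratio_ca_zn_sd": s2}`` — one tissue filling the map.
    * ``{"kind": "lesion", "axis": 0, "zones": [ {"frac": f, "ca_factor": c,
       "ratio_ca_p": m, "ratio_ca_p_sd": s}, ... ]}`` — stacked bands along an
      axis (e.g. severe lesion cap, adjacent zone, normal dentin); zone labels
      1..k in listed order.
    * ``{"kind": "bands", "axis": 0, "period_px": p,
       "rich": {"ratio_ca_zn": m, "ratio_ca_zn_sd": s},
       "poor": {...}, "ratio_ca_p": m3, "ratio_ca_p_sd": s3}`` — alternating
      Zn-rich (label 1) / Zn-poor (label 2) cementum layers, band width p/2.

    Per-pixel molar ratios are drawn Normal(mean, sd) and floored at a small
    positive value; element fields follow as Ca / ratio. Measurement noise is
    multiplicative log-normal with coefficient of variation ``noise_cv``
    (mean 1), applied independently per element, plus optional Poisson
    counting noise. ``thin_limit=True`` bypasses self-absorption (area
    concentration = volume concentration x thickness).
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    ca_base_mmol_cm3: float | None = None
    scene: dict[str, Any] = field(default_factory=lambda: {"kind": "uniform"})
    thickness_um: float | np.ndarray | None = None
    gains: dict[str, float] | None = None
    noise_cv: float | None = None
    poisson: bool = False
    thin_limit: bool = False
    absorption: AbsorptionContext | None = None

    def resolved(self) -> "ElementFieldSpec":
        cfg = xrf_config()
        out = replace(self)
        if out.ca_base_mmol_cm3 is None:
            out.ca_base_mmol_cm3 = cfg["ca_base_mmol_cm3"]
        if out.thickness_um is None:
            out.thickness_um = cfg["thickness_um"]
        if out.gains is None:
            out.gains = dict(cfg["gains_counts_per_mmolcm2"])
        if out.noise_cv is None:
            out.noise_cv = cfg["noise_cv"]
        if out.absorption is None:
            out.absorption = AbsorptionContext(thickness_um=out.thickness_um)
        else:
            out.absorption = replace(out.absorption, thickness_um=out.thickness_um)
        thick = np.asarray(out.thickness_um, dtype=float)
        if np.any(thick <= 0):
            raise ValueError("thickness must be positive everywhere")
        if out.ca_base_mmol_cm3 < 0:
            raise ValueError("concentrations must be non-negative")
        return out


def _ratio_field(rng: np.random.Generator, shape, mean: float, sd: float) -> np.ndarray:
    field_r = np.full(shape, float(mean))
    if sd > 0:
        field_r = field_r + rng.normal(0.0, sd, size=shape)
    return np.maximum(field_r, 1e-6)


def _scene_fields(spec: ElementFieldSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, dict[str, np.ndarray], dict[int, dict]]:
    """Labels, true volume-concentration fields, per-zone truth table."""
    sc = dict(spec.scene)
    kind = sc.pop("kind", "uniform")
    shape = spec.shape
    ca = np.full(shape, float(spec.ca_base_mmol_cm3))
    labels = np.ones(shape, dtype=np.int32)
    zone_truth: dict[int, dict] = {}

    def band_coord(axis: int) -> np.ndarray:
        coord = np.arange(shape[axis])
        view = coord.reshape([-1, 1] if axis == 0 else [1, -1])
        return np.broadcast_to(view, shape)

    if kind == "uniform":
        p_ratio = _ratio_field(rng, shape, sc.get("ratio_ca_p", 1.67),
                               sc.get("ratio_ca_p_sd", 0.0))
        zn_ratio = _ratio_field(rng, shape, sc.get("ratio_ca_zn", 1000.0),
                                sc.get("ratio_ca_zn_sd", 0.0))
        zone_truth[1] = {"ratio_ca_p": sc.get("ratio_ca_p", 1.67),
                         "ratio_ca_zn": sc.get("ratio_ca_zn", 1000.0)}
    elif kind == "lesion":
        axis = int(sc.get("axis", 0))
        zones = sc["zones"]
        fracs = np.cumsum([z["frac"] for z in zones])
        if not np.isclose(fracs[-1], 1.0):
            raise ValueError("lesion zone fractions must sum to 1")
        coord = band_coord(axis) / shape[axis]
        p_ratio = np.empty(shape)
        zn_ratio = _ratio_field(rng, shape, sc.get("ratio_ca_zn", 1000.0),
                                sc.get("ratio_ca_zn_sd", 0.0))
        lo = 0.0
        falloff = float(sc.get("falloff_px", 0.0))
        for i, (z, hi) in enumerate(zip(zones, fracs), start=1):
            m = (coord >= lo) & (coord < hi + (1e-9 if i == len(zones) else 0.0))
            labels[m] = i
            ca[m] *= float(z.get("ca_factor", 1.0))
            p_ratio[m] = _ratio_field(rng, shape, z["ratio_ca_p"],
                                      z.get("ratio_ca_p_sd", 0.0))[m]
            zone_truth[i] = {"ratio_ca_p": z["ratio_ca_p"],
                             "ca_factor": z.get("ca_factor", 1.0),
                             "ratio_ca_zn": sc.get("ratio_ca_zn", 1000.0)}
            lo = hi
        if falloff > 0:  # soften concentration transitions, not labels
            ca = gaussian_filter(ca, falloff)
    elif kind == "bands":
        axis = int(sc.get("axis", 0))
        period = int(sc["period_px"])
        if period < 2:
            raise ValueError("band period must be at least 2 px")
        half = period / 2.0
        rich = (band_coord(axis) % period) < half
        labels = np.where(rich, 1, 2).astype(np.int32)
        p_ratio = _ratio_field(rng, shape, sc.get("ratio_ca_p", 1.51),
                               sc.get("ratio_ca_p_sd", 0.0))
        zn_ratio = np.empty(shape)
        for lab, key in ((1, "rich"), (2, "poor")):
            z = sc[key]
            m = labels == lab
            zn_ratio[m] = _ratio_field(rng, shape, z["ratio_ca_zn"],
                                       z.get("ratio_ca_zn_sd", 0.0))[m]
            zone_truth[lab] = {"ratio_ca_zn": z["ratio_ca_zn"],
                               "ratio_ca_p": sc.get("ratio_ca_p", 1.51)}
    else:
        raise ValueError(f"unknown scene kind {kind!r}")

    fields = {"Ca": ca, "P": ca / p_ratio, "Zn": ca / zn_ratio}
    return labels, fields, zone_truth


def make_xrf_maps(spec: ElementFieldSpec, seed: int | None = None,
                  elements: Sequence[str] = ("Ca", "P", "Zn"),
                  ) -> tuple[dict[str, ElementMap], GroundTruth]:
    """Forward-model raw-count maps for the requested elements.

    Returns the count maps plus a GroundTruth holding the zone labels, the
    true volume-concentration fields (mmol/cm3) and per-zone ratio truth.
    """
    spec = spec.resolved()
    stochastic = spec.noise_cv > 0 or spec.poisson or any(
        "sd" in k and v for k, v in _flatten(spec.scene))
    if stochastic and seed is None:
        raise ValueError("seed is required for stochastic XRF synthesis")
    rng = np.random.default_rng(seed)
    labels, fields, zone_truth = _scene_fields(spec, rng)
    thick = np.broadcast_to(np.asarray(spec.thickness_um, dtype=float), spec.shape)
    maps: dict[str, ElementMap] = {}
    for el in elements:
        vol_conc = fields[el]
        if spec.thin_limit:
            t_eff_um = thick
        else:
            t_eff_um = effective_thickness(spec.absorption, el)
            t_eff_um = np.broadcast_to(np.asarray(t_eff_um, dtype=float), spec.shape)
        area = vol_conc * t_eff_um * 1e-4  # um -> cm; mmol/cm2
        counts = area * spec.gains[el]
        if spec.noise_cv > 0:
            s = np.sqrt(np.log1p(spec.noise_cv ** 2))
            counts = counts * rng.lognormal(-0.5 * s * s, s, size=spec.shape)
        if spec.poisson:
            counts = rng.poisson(np.maximum(counts, 0.0)).astype(float)
        maps[el] = ElementMap(element=el, data=counts, units="counts",
                              pixel_size_um=spec.pixel_size_um,
                              meta={"seed": seed, "gain": spec.gains[el],
                                    "thin_limit": spec.thin_limit})
    gt = GroundTruth(labels=labels, region_truth=zone_truth,
                     fields={el: fields[el] for el in elements}, spec=spec)
    return maps, gt


def _flatten(d: dict, prefix: str = "") -> list[tuple[str, Any]]:
    out: list[tuple[str, Any]] = []
    for k, v in d.items():
        if isinstance(v, dict):
            out.extend(_flatten(v, f"{prefix}{k}."))
        elif isinstance(v, list):
            for i, item in enumerate(v):
                if isinstance(item, dict):
                    out.extend(_flatten(item, f"{prefix}{k}[{i}]."))
        else:
            out.append((f"{prefix}{k}", v))
    return out
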
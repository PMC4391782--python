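"""XRF quantification: counts -> area concentration -> volume concentration.

Raw fluorescence counts are converted to area concentrations (mmol/cm2)
through thin-film standard gains, then to volume concentrations (mmol/cm3)
by inverting a single-layer self-absorption model. For a uniform matrix with
incident beam attenuation length ``L_in`` (at the excitation energy) and
fluorescence attenuation length ``L_f`` (at the element's emission line), the
measured area concentration of a specimen of thickness ``t`` is

    A = C * t_eff,     t_eff = (1 - exp(-mu * t)) / mu,
    mu = (1/L_in)/sin(theta_in) + (1/L_f)/sin(theta_out),

so the volume concentration is recovered as ``C = A / t_eff``. In the thin
limit (mu*t -> 0) this reduces to a plain division by thickness.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import xrf_config
from .images import ElementMap

__all__ = [
    "ElementStandard", "AbsorptionContext", "calibrate_counts",
    "effective_thickness", "thickness_correct", "default_standard",
    "default_context",
]


@dataclass
class ElementStandard:
    """Thin-film standard calibration for one element."""

    element: str
    counts_per_mmolcm2: float
    line_energy_kev: float
    fluorescence_yield: float = 1.0

    def __post_init__(self) -> None:
        if self.counts_per_mmolcm2 <= 0:
            raise ValueError("detector gain must be positive")
        if self.line_energy_kev <= 0:
            raise ValueError("fluorescence line energy must be positive")


@dataclass
class AbsorptionContext:
    """Geometry and attenuation inputs for the self-absorption correction.

    Absorption lengths are 1/e attenuation depths (um) of the specimen matrix
    at the incident energy and at each element's fluorescence line; they are
    supplied (e.g. from tabulations), not computed from stoichiometry.
    """

    incident_energy_kev: float = 10.0
    thickness_um: float | np.ndarray = 5.0
    absorption_length_incident_um: float = 110.0
    absorption_lengths_um: Mapping[str, float] = field(
        default_factory=lambda: dict(xrf_config()["absorption_lengths_um"]))
    incidence_angle_deg: float = 45.0
    takeoff_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        # scalar thickness must be positive outright; a thickness *map* may
        # carry non-positive pixels, which thickness_correct flags invalid
        if np.ndim(self.thickness_um) == 0 and float(self.thickness_um) <= 0:
            raise ValueError("thickness must be positive")
        if self.absorption_length_incident_um <= 0:
            raise ValueError("absorption lengths must be positive")
        for el, L in self.absorption_lengths_um.items():
            if L <= 0:
                raise ValueError(f"absorption length for {el} must be positive")
        for ang in (self.incidence_angle_deg, self.takeoff_angle_deg):
            if not 0.0 < ang <= 90.0:
                raise ValueError("angles must lie in (0, 90] degrees")

    def total_attenuation_per_um(self, element: str) -> float:
        """mu = (1/L_in)/sin(theta_in) + (1/L_f)/sin(theta_out), in 1/um."""
        if element not in self.absorption_lengths_um:
            raise KeyError(f"no absorption length configured for element {element!r}")
        th_in = np.deg2rad(self.incidence_angle_deg)
        th_out = np.deg2rad(self.takeoff_angle_deg)
        return (1.0 / self.absorption_length_incident_um / np.sin(th_in)
                + 1.0 / self.absorption_lengths_um[element] / np.sin(th_out))


def default_standard(element: str) -> ElementStandard:
    cfg = xrf_config()
    return ElementStandard(element=element,
                           counts_per_mmolcm2=cfg["gains_counts_per_mmolcm2"][element],
                           line_energy_kev=cfg["line_energies_kev"][element])


def default_context(thickness_um: float | np.ndarray | None = None) -> AbsorptionContext:
    cfg = xrf_config()
    return AbsorptionContext(
        incident_energy_kev=cfg["incident_energy_kev"],
        thickness_um=cfg["thickness_um"] if thickness_um is None else thickness_um,
        absorption_length_incident_um=cfg["absorption_length_incident_um"],
        absorption_lengths_um=dict(cfg["absorption_lengths_um"]),
        incidence_angle_deg=cfg["incidence_angle_deg"],
        takeoff_angle_deg=cfg["takeoff_angle_deg"])


def calibrate_counts(raw: ElementMap, std: ElementStandard) -> ElementMap:
    """Counts -> area concentration (mmol/cm2) by dividing out the gain."""
    if raw.units != "counts":
        raise ValueError(f"expected a counts map, got units {raw.units!r}")
    if raw.element != std.element:
        raise ValueError(f"standard is for {std.element!r}, map is {raw.element!r}")
    meta = dict(raw.meta)
    meta["gain_counts_per_mmolcm2"] = std.counts_per_mmolcm2
    return ElementMap(element=raw.element, data=raw.data / std.counts_per_mmolcm2,
                      units="mmol/cm2", pixel_size_um=raw.pixel_size_um, meta=meta)


def effective_thickness(ctx: AbsorptionContext, element: str):
    """Self-absorption effective thickness t_eff = (1 - exp(-mu t)) / mu, in um.

    Monotone increasing in t, bounded above by both t and 1/mu; equals t in
    the thin limit mu*t -> 0.
    """
    mu = ctx.total_attenuation_per_um(element)
    t = np.asarray(ctx.thickness_um, dtype=float)
    t_eff = -np.expm1(-mu * t) / mu
    return float(t_eff) if np.ndim(ctx.thickness_um) == 0 else t_eff


def thickness_correct(area: ElementMap, ctx: AbsorptionContext) -> ElementMap:
    """Area (mmol/cm2) -> volume (mmol/cm3) concentration via t_eff.

    Pixels with non-positive thickness are flagged invalid (NaN in the output,
    count recorded in ``meta['invalid_thickness_pixels']``) rather than
    propagated into downstream statistics.
    """
    if area.units != "mmol/cm2":
        raise ValueError(f"expected an area-concentration map, got {area.units!r}")
    t = np.broadcast_to(np.asarray(ctx.thickness_um, dtype=float), area.shape)
    bad = ~(t > 0)
    mu = ctx.total_attenuation_per_um(area.element)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_eff_um = np.where(bad, np.nan, -np.expm1(-mu * np.where(bad, 1.0, t)) / mu)
    vol = area.data / (t_eff_um * 1e-4)  # um -> cm
    vol = np.where(bad, np.nan, vol)
    meta = dict(area.meta)
    meta["invalid_thickness_pixels"] = int(bad.sum())
    meta["self_absorption_mu_per_um"] = mu
    return ElementMap(element=area.element, data=vol, units="mmol/cm3",
                      pixel_size_um=area.pixel_size_um, meta=meta)
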
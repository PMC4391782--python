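"""Canonical synthetic study cases used for validation and examples.

Each preset builds one fixture at the study's stated conditions (tissue
parameter rows, 3.84 um voxels, 50 HU noise, 1-voxel PSF blur, 10% XRF
measurement noise) so that recovery checks, examples and reproduction
scripts all exercise identical inputs.
"""
from __future__ import annotations

import numpy as np

from .config import tissue_config, xrf_config
from .synth import (AcquisitionSpec, ElementFieldSpec, GroundTruth,
                    TissuePhantomSpec, default_acquisition, instrument_line,
                    make_phantom_volume, make_tissue_volume, make_xrf_maps,
                    tissue_region, PHANTOM_DENSITIES)
from .images import ElementMap, Volume

__all__ = [
    "phantom_case", "tissue_block_case", "lesion_volume_case",
    "xrf_tissue_case", "xrf_lesion_case", "xrf_banded_cementum_case",
]


def phantom_case(noise_sd_hu: float = 0.0, blur_sigma_vox: float = 0.0,
                 seed: int | None = None):
    """Calibration-phantom volume (seven densities) plus ROI/nominal tables.

    Returns ``(volume, ground_truth, rois, nominal_md, acq)``; ROIs are the
    exact insert labels.
    """
    acq = default_acquisition(noise_sd_hu=noise_sd_hu,
                              blur_sigma_vox=blur_sigma_vox)
    vol, gt = make_phantom_volume(PHANTOM_DENSITIES, acq=acq, seed=seed)
    rois = {str(i): gt.labels == i for i in gt.region_truth}
    nominal = {str(i): gt.region_truth[i]["md"] for i in gt.region_truth}
    return vol, gt, rois, nominal, acq


def tissue_block_case(tissue: str, seed: int,
                      shape: tuple[int, int, int] = (128, 128, 128)
                      ) -> tuple[Volume, GroundTruth, AcquisitionSpec]:
    """A volume fully occupied by one tissue at its configured MD parameters.

    Emulates an analysis ROI interior to a tissue (no partial-volume
    interface voxels), the setting in which tissue-mean mineral densities
    are quoted.
    """
    spec = TissuePhantomSpec(shape=shape, regions=[tissue_region(tissue)])
    acq = default_acquisition()
    vol, gt = make_tissue_volume(spec, acq=acq, seed=seed)
    return vol, gt, acq


def lesion_volume_case(seed: int, shape: tuple[int, int, int] = (128, 128, 128),
                       cap_fraction: float = 0.4
                       ) -> tuple[Volume, GroundTruth, AcquisitionSpec]:
    """Two-region diseased-dentin volume: hypomineralized cap over normal dentin.

    The cap occupies the top ``cap_fraction`` of the z-extent; region
    parameters come from the hypomineralized-dentin and dentin config rows.
    """
    spec = TissuePhantomSpec(shape=shape, regions=[
        tissue_region("hypomineralized_dentin", 1,
                      {"kind": "box", "lo": (0, 0, 0), "hi": (cap_fraction, 1, 1)}),
        tissue_region("dentin", 2,
                      {"kind": "box", "lo": (cap_fraction, 0, 0), "hi": (1, 1, 1)}),
    ])
    acq = default_acquisition()
    vol, gt = make_tissue_volume(spec, acq=acq, seed=seed)
    return vol, gt, acq


def _ratio_row(kind: str, name: str) -> dict:
    return xrf_config()["ratios"][kind][name]


def xrf_tissue_case(tissue: str, seed: int,
                    shape: tuple[int, int] = (256, 256)
                    ) -> tuple[dict[str, ElementMap], GroundTruth]:
    """Uniform-tissue Ca/P map pair at the tissue's configured molar ratio."""
    row = _ratio_row("ca_p", tissue)
    spec = ElementFieldSpec(shape=shape, scene={
        "kind": "uniform", "ratio_ca_p": row["mean"], "ratio_ca_p_sd": row["sd"]})
    return make_xrf_maps(spec, seed=seed, elements=("Ca", "P"))


def xrf_lesion_case(seed: int, shape: tuple[int, int] = (256, 256)
                    ) -> tuple[dict[str, ElementMap], GroundTruth]:
    """Diseased-dentin Ca/P maps: Ca-depleted lesion cap over normal dentin.

    Zone 1 (severe demineralization, top quarter) and zone 2 (adjacent,
    slightly higher mineralization) use the lesion config rows; the rest is
    normal dentin. Ca depletion factors scale the Ca field inside the zones.
    """
    z1 = _ratio_row("ca_p", "lesion_zone_1")
    z2 = _ratio_row("ca_p", "lesion_zone_2")
    nd = _ratio_row("ca_p", "dentin")
    spec = ElementFieldSpec(shape=shape, scene={
        "kind": "lesion", "axis": 0, "zones": [
            {"frac": 0.25, "ca_factor": 0.2,
             "ratio_ca_p": z1["mean"], "ratio_ca_p_sd": z1["sd"]},
            {"frac": 0.25, "ca_factor": 0.5,
             "ratio_ca_p": z2["mean"], "ratio_ca_p_sd": z2["sd"]},
            {"frac": 0.5, "ca_factor": 1.0,
             "ratio_ca_p": nd["mean"], "ratio_ca_p_sd": nd["sd"]},
        ]})
    return make_xrf_maps(spec, seed=seed, elements=("Ca", "P"))


def xrf_banded_cementum_case(seed: int, shape: tuple[int, int] = (256, 256),
                             period_px: int = 32
                             ) -> tuple[dict[str, ElementMap], GroundTruth]:
    """Banded cementum maps: alternating Zn-rich (acellular extrinsic, label 1)
    and Zn-poor (cellular intrinsic, label 2) layers."""
    rich = _ratio_row("ca_zn", "acellular_cementum")
    poor = _ratio_row("ca_zn", "cellular_cementum")
    cap = _ratio_row("ca_p", "cementum_zn_rich")
    spec = ElementFieldSpec(shape=shape, scene={
        "kind": "bands", "axis": 0, "period_px": period_px,
        "rich": {"ratio_ca_zn": rich["mean"], "ratio_ca_zn_sd": rich["sd"]},
        "poor": {"ratio_ca_zn": poor["mean"], "ratio_ca_zn_sd": poor["sd"]},
        "ratio_ca_p": cap["mean"], "ratio_ca_p_sd": cap["sd"]})
    return make_xrf_maps(spec, seed=seed, elements=("Ca", "P", "Zn"))
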
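"""Loaders for the packaged default parameter tables (tissues, XRF)."""
from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Any


@lru_cache(maxsize=None)
def _load(name: str) -> dict[str, Any]:
    with resources.files("mineralmap").joinpath("data", name).open() as fh:
        return json.load(fh)


def tissue_config() -> dict[str, Any]:
    """Tissue mineral-density rows, instrument/ash lines, phantom densities,
    acquisition defaults and dentin-zone HU cutoffs."""
    return _load("tissues.json")


def xrf_config() -> dict[str, Any]:
    """XRF quantification defaults: molar-ratio rows, line energies,
    absorption lengths, gains, detection floors."""
    return _load("xrf.json")
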
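"""TIFF + JSON-sidecar IO for volumes, element maps and label maps.

Volumes are written as multi-page 32-bit float TIFF stacks (one page per
z-slice); element maps as single-page float TIFFs; label maps as 16-bit
TIFF stacks. Each array file gets a ``<name>.json`` sidecar carrying voxel/
pixel size, units and any JSON-serializable metadata (seeds, spec echoes).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .images import ElementMap, LabelMap, Volume
from .segment import SeedLocus, SegmentStats

__all__ = [
    "save_volume", "load_volume", "save_element_map", "load_element_map",
    "save_label_map", "load_label_map", "segment_stats_to_csv",
    "save_loci", "load_loci",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


def save_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps(
        {"voxel_size_um": vol.voxel_size_um, "units": vol.units,
         "meta": _jsonable(vol.meta)}, indent=2))
    return path


def load_volume(path: str | Path) -> Volume:
    path = Path(path)
    data = tifffile.imread(path)
    side = json.loads(_sidecar(path).read_text())
    return Volume(np.asarray(data, dtype=float), voxel_size_um=side["voxel_size_um"],
                  units=side["units"], meta=side.get("meta", {}))


def save_element_map(m: ElementMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, m.data.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps(
        {"element": m.element, "pixel_size_um": m.pixel_size_um,
         "units": m.units, "meta": _jsonable(m.meta)}, indent=2))
    return path


def load_element_map(path: str | Path) -> ElementMap:
    path = Path(path)
    data = tifffile.imread(path)
    side = json.loads(_sidecar(path).read_text())
    return ElementMap(element=side["element"], data=np.asarray(data, dtype=float),
                      units=side["units"], pixel_size_um=side["pixel_size_um"],
                      meta=side.get("meta", {}))


def save_label_map(lm: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    if lm.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed 16-bit range")
    tifffile.imwrite(path, lm.labels.astype(np.uint16), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"meta": _jsonable(lm.meta)}, indent=2))
    return path


def load_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    side = json.loads(_sidecar(path).read_text())
    return LabelMap(labels=labels, meta=side.get("meta", {}))


def segment_stats_to_csv(stats: Sequence[SegmentStats], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([vars(s) for s in stats]).to_csv(path, index=False)
    return path


def save_loci(loci: Sequence[SeedLocus], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([vars(l) for l in loci], indent=2))
    return path


def load_loci(path: str | Path) -> list[SeedLocus]:
    return [SeedLocus(**d) for d in json.loads(Path(path).read_text())]
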
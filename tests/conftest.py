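import numpy as np
import pytest

import mineralmap as mm


@pytest.fixture(scope="session")
def true_line() -> mm.CalibrationModel:
    """The generator's HU->MD line (slope 0.11 mg/cc per HU, intercept -48.6)."""
    return mm.instrument_line()


@pytest.fixture(scope="session")
def quiet_acq() -> mm.AcquisitionSpec:
    """Noise-free, blur-free acquisition for exactness tests."""
    return mm.AcquisitionSpec(noise_sd_hu=0.0, blur_sigma_vox=0.0)


@pytest.fixture(scope="session")
def fitted_calibration(true_line, quiet_acq) -> mm.CalibrationModel:
    """Calibration fitted on a noise-free synthetic phantom volume."""
    vol, gt = mm.make_phantom_volume(mm.PHANTOM_DENSITIES, acq=quiet_acq)
    rois = {str(i): gt.labels == i for i in gt.region_truth}
    nominal = {str(i): gt.region_truth[i]["md"] for i in gt.region_truth}
    calib, _ = mm.calibrate_from_phantom(
        vol, rois, nominal, quiet_acq.air_intensity, quiet_acq.water_intensity)
    return calib


def oracle_flood(landscape: np.ndarray, markers: np.ndarray,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Brute-force flood: linear-scan re-simulation of the watershed contract.

    Independent of the package's heap implementation: candidates are kept in
    a plain list in insertion order (markers scanned in raster order,
    neighbors in -ax/+ax order) and each step extracts the lexicographic
    minimum by exhaustive scan.
    """
    import itertools

    land = np.asarray(landscape, dtype=float)
    shape = land.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    labels = np.where(mask, markers, 0).astype(int)

    def neighbors(pos):
        for ax in range(len(shape)):
            for d in (-1, +1):
                q = list(pos)
                q[ax] += d
                if 0 <= q[ax] < shape[ax]:
                    yield tuple(q)

    cand: list[tuple[float, int, int, tuple]] = []
    counter = 0
    for pos in itertools.product(*map(range, shape)):
        if labels[pos] > 0:
            for q in neighbors(pos):
                if mask[q] and labels[q] == 0:
                    cand.append((land[q], counter, labels[pos], q))
                    counter += 1
    while cand:
        k = min(range(len(cand)), key=lambda i: (cand[i][0], cand[i][1]))
        _, _, lab, pos = cand.pop(k)
        if labels[pos] != 0:
            continue
        labels[pos] = lab
        for q in neighbors(pos):
            if mask[q] and labels[q] == 0:
                cand.append((land[q], counter, lab, q))
                counter += 1
    return labels


def random_flood_case(rng: np.random.Generator, max_voxels: int = 1000):
    """A random landscape + markers + mask with at most ``max_voxels`` voxels."""
    while True:
        shape = tuple(int(v) for v in rng.integers(3, 11, size=3))
        if np.prod(shape) <= max_voxels:
            break
    land = rng.random(shape)
    n = int(np.prod(shape))
    k = int(rng.integers(2, 5))
    seeds = rng.choice(n, size=k, replace=False)
    markers = np.zeros(shape, dtype=np.int32)
    for i, f in enumerate(seeds, start=1):
        markers[np.unravel_index(f, shape)] = i
    mask = rng.random(shape) > 0.1
    for f in seeds:
        mask[np.unravel_index(f, shape)] = True
    return land, markers, mask
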
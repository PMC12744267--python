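import numpy as np
import pytest

from follimech.presets import make_preset
from follimech.synthetic import simulate_oct_volume


@pytest.fixture(scope="session")
def young0():
    return make_preset("young", 0, "control")


@pytest.fixture(scope="session")
def symmetric_preset(young0):
    """Young 0 h preset with a rotationally symmetric wall."""
    d = young0.to_dict()
    d["thickness_asymmetry"] = 0.0
    d["sigmoid_params"] = tuple(d["sigmoid_params"])
    return type(young0)(**d)


@pytest.fixture(scope="session")
def oct_phantom_noiseless(young0):
    """One noiseless OCT phantom, shared across tests (generation is the
    slow part)."""
    return simulate_oct_volume(young0, seed=7, speckle_looks=0)


@pytest.fixture(scope="session")
def oct_phantom_noisy(young0):
    return simulate_oct_volume(young0, seed=7)


def brute_force_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive largest-inscribed-disk oracle (pixel units).

    For every mask pixel p, scan all candidate disk centres c (every
    mask pixel, radius EDT(c)) and take the largest diameter among
    disks covering p. Same discrete convention as the production code
    (diameter 2*EDT - 1) but computed by an independent all-pairs scan.
    """
    from scipy.ndimage import distance_transform_edt

    mask = mask.astype(bool)
    edt = distance_transform_edt(mask)
    ys, xs = np.nonzero(mask)
    radii = edt[ys, xs]
    out = np.zeros_like(edt)
    pys, pxs = np.nonzero(mask)
    for py, px in zip(pys, pxs):
        d2 = (ys - py) ** 2 + (xs - px) ** 2
        covering = d2 <= radii**2
        if covering.any():
            out[py, px] = 2.0 * radii[covering].max() - 1.0
    return out
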
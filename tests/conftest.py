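import numpy as np
import pytest

from mcsquant.core import Mask, PunctaField
from mcsquant.simulate import SceneSpec, make_cell_and_mito_masks, place_puncta


@pytest.fixture(scope="session")
def spec():
    return SceneSpec(seed=7)


@pytest.fixture(scope="session")
def masks(spec):
    return make_cell_and_mito_masks(spec, mito_area_fraction=0.25)


@pytest.fixture(scope="session")
def truth(masks):
    cell, mito = masks
    return place_puncta(
        cell, mito, n_ref=200, n_partner=200, f_coloc=0.3, f_mito=0.25,
        offset_sigma_nm=50.0, seed=11,
    )


@pytest.fixture(scope="session")
def fields(truth, spec):
    ref = PunctaField(truth.ref_points, pixel_size_nm=spec.pixel_size_nm)
    partner = PunctaField(truth.partner_points, pixel_size_nm=spec.pixel_size_nm)
    return ref, partner


def brute_force_nnd(ref_xy: np.ndarray, partner_xy: np.ndarray):
    """Independent O(n^2) oracle: exhaustive all-pairs nearest neighbour."""
    dists = np.empty(len(ref_xy))
    idx = np.empty(len(ref_xy), dtype=int)
    for i, p in enumerate(ref_xy):
        d = np.sqrt(((partner_xy - p) ** 2).sum(axis=1))
        idx[i] = int(np.argmin(d))  # argmin returns the lowest index on ties
        dists[i] = d[idx[i]]
    return dists, idx
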
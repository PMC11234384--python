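"""Object-based colocalization: nearest-neighbour distances between puncta fields.

For each reference punctum the Euclidean centre-to-centre distance (nm) to
the closest partner punctum is computed; two puncta count as colocalized
when that distance is strictly below a physical threshold (default 233 nm,
about the lateral resolution of a confocal microscope, i.e. 3 px at
77.7 nm/px).  The comparison is directional: NND(ref->partner) differs from
NND(partner->ref) in general, and both directions are computable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import ndimage as ndi
from skimage import morphology

from .core import Mask, PunctaField

DEFAULT_THRESHOLD_NM = 233.0


@dataclass
class NNDResult:
    """Per-reference-punctum nearest-partner distances and classification."""

    distances_nm: np.ndarray
    partner_indices: np.ndarray
    threshold_nm: float = DEFAULT_THRESHOLD_NM

    @property
    def colocalized_flags(self) -> np.ndarray:
        # strict inequality: exact-boundary distances are not colocalized
        return self.distances_nm < self.threshold_nm

    @property
    def fraction_colocalized(self) -> float:
        if len(self.distances_nm) == 0:
            return 0.0
        return float(self.colocalized_flags.mean())

    def __len__(self) -> int:
        return len(self.distances_nm)


def nearest_neighbour_distances(
    ref: PunctaField, partner: PunctaField, threshold_nm: float = DEFAULT_THRESHOLD_NM
) -> NNDResult:
    """Distance from each ref centroid to its nearest partner centroid.

    Ties are broken by the lowest partner index, matching an exhaustive
    all-pairs argmin.
    """
    if len(partner) == 0:
        raise ValueError("no partner puncta")
    if len(ref) == 0:
        return NNDResult(np.empty(0), np.empty(0, dtype=int), threshold_nm)
    tree = cKDTree(partner.centroids_nm)
    dists, idx = tree.query(ref.centroids_nm)
    # resolve ties deterministically: lowest partner index at the min distance
    for i, (p, d) in enumerate(zip(ref.centroids_nm, dists)):
        cand = tree.query_ball_point(p, d * (1 + 1e-12) + 1e-9)
        if len(cand) > 1:
            cd = np.hypot(*(partner.centroids_nm[cand] - p).T)
            best = cd.min()
            idx[i] = min(c for c, dd in zip(cand, cd) if dd <= best * (1 + 1e-12))
            dists[i] = best
    return NNDResult(dists, idx.astype(int), threshold_nm)


def classify_colocalized(nnd: NNDResult, threshold_nm: float = DEFAULT_THRESHOLD_NM) -> NNDResult:
    """Re-threshold an NND result (strict '<' at the boundary)."""
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be positive")
    return replace(nnd, threshold_nm=threshold_nm)


def subset_by_mask(
    puncta: PunctaField, mask: Mask, dilation_px: int = 0
) -> tuple[PunctaField, PunctaField]:
    """Partition puncta by centroid-in-mask association.

    A punctum is "inside" when its centroid pixel falls on the mask,
    optionally after dilating the mask by ``dilation_px``.  The two returned
    fields always partition the input.
    """
    m = mask.data
    if dilation_px > 0:
        m = ndi.binary_dilation(m, structure=morphology.disk(dilation_px))
    rows, cols = puncta.pixel_indices()
    rows = np.clip(rows, 0, m.shape[0] - 1)
    cols = np.clip(cols, 0, m.shape[1] - 1)
    inside = m[rows, cols] if len(puncta) else np.zeros(0, dtype=bool)
    return puncta.select(inside), puncta.select(~inside)


def nnd_histogram(nnd: NNDResult, bin_width_nm: float = 50.0) -> pd.DataFrame:
    """Left-closed frequency table of NND values; counts sum to len(nnd)."""
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be positive")
    d = np.asarray(nnd.distances_nm)
    if len(d) == 0:
        return pd.DataFrame({"bin_left_nm": [], "bin_right_nm": [], "count": []})
    idx = np.floor(d / bin_width_nm).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    left = np.arange(n_bins) * bin_width_nm
    return pd.DataFrame(
        {"bin_left_nm": left, "bin_right_nm": left + bin_width_nm, "count": counts}
    )


def nnd_to_frame(nnd: NNDResult, mito_flags: np.ndarray | None = None) -> pd.DataFrame:
    """Tidy per-punctum table (ref_id, nnd_nm, partner_id, colocalized[, in_mito_mask])."""
    df = pd.DataFrame(
        {
            "ref_id": np.arange(len(nnd)),
            "nnd_nm": nnd.distances_nm,
            "partner_id": nnd.partner_indices,
            "colocalized": nnd.colocalized_flags,
        }
    )
    if mito_flags is not None:
        df["in_mito_mask"] = np.asarray(mito_flags, dtype=bool)
    return df
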
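"""Pixel-based colocalization: Manders split coefficients and a Costes test.

M1 is the fraction of channel A's supra-threshold integrated intensity
found in pixels where channel B is also above its threshold (M2
symmetrically).  The Costes test scrambles one channel in blocks larger
than the PSF autocorrelation length and reports the percentage of
scrambles whose Pearson correlation falls below the observed one; 100%
indicates colocalization stronger than any spatial rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from skimage import filters

from .core import Image, Mask


@dataclass
class PixelColocResult:
    m1: float
    m2: float
    pearson_r: float
    costes_pvalue_pct: float | None
    thr_a: float
    thr_b: float
    block_size_px: int | None = None
    n_randomizations: int | None = None

    def to_dict(self) -> dict:
        return {
            "M1": self.m1,
            "M2": self.m2,
            "pearson_r": self.pearson_r,
            "costes_pvalue_pct": self.costes_pvalue_pct,
            "threshold_A": self.thr_a,
            "threshold_B": self.thr_b,
            "block_size_px": self.block_size_px,
            "n_randomizations": self.n_randomizations,
        }


def _auto_threshold(data: np.ndarray, mask: np.ndarray | None) -> float:
    sel = data[mask] if mask is not None else data.ravel()
    if sel.max() == sel.min():
        return float(sel.max())
    return float(filters.threshold_otsu(sel))


def manders_split(
    imgA: Image,
    imgB: Image,
    thrA: float | None = None,
    thrB: float | None = None,
    mask: Mask | None = None,
) -> tuple[float, float]:
    """Thresholded Manders split coefficients (M1, M2), each in [0, 1].

    Thresholds default to per-channel Otsu within the cell mask.  A channel
    with no supra-threshold signal has an undefined coefficient and raises.
    """
    if imgA.shape != imgB.shape:
        raise ValueError("images must have the same shape")
    a, b = imgA.data.astype(float), imgB.data.astype(float)
    m = mask.data if mask is not None else None
    if thrA is None:
        thrA = _auto_threshold(a, m)
    if thrB is None:
        thrB = _auto_threshold(b, m)
    if thrA < 0 or thrB < 0:
        raise ValueError("thresholds must be >= 0")
    sel = np.ones(a.shape, bool) if m is None else m
    a_pos = (a > thrA) & sel
    b_pos = (b > thrB) & sel
    denom1 = a[a_pos].sum()
    denom2 = b[b_pos].sum()
    if denom1 == 0 or denom2 == 0:
        raise ValueError("no supra-threshold signal: Manders coefficient undefined")
    m1 = a[a_pos & b_pos].sum() / denom1
    m2 = b[a_pos & b_pos].sum() / denom2
    return float(m1), float(m2)


def _blockify(shape: tuple[int, int], block: int) -> tuple[int, int]:
    return shape[0] // block, shape[1] // block


def costes_pvalue(
    imgA: Image,
    imgB: Image,
    block_size_px: int = 5,
    n_rand: int = 100,
    mask: Mask | None = None,
    seed: int = 0,
) -> float:
    """Costes randomization: % of block-scrambles of A with r below observed.

    Channel A is cut into ``block_size_px`` squares (within the mask's
    bounding box) and the blocks are permuted; blocks must exceed the PSF
    autocorrelation length for a valid null.  Returns a percentage in
    [0, 100]; 100% means no scramble correlates as strongly as the data.
    """
    if imgA.shape != imgB.shape:
        raise ValueError("images must have the same shape")
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    a, b = imgA.data.astype(float), imgB.data.astype(float)
    if mask is not None:
        rows, cols = np.nonzero(mask.data)
        if len(rows) == 0:
            raise ValueError("empty mask")
        a = a[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
        b = b[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
        msel = mask.data[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    else:
        msel = None
    nby, nbx = _blockify(a.shape, block_size_px)
    if nby * nbx < 2:
        raise ValueError("region smaller than two scramble blocks")
    H, W = nby * block_size_px, nbx * block_size_px
    a, b = a[:H, :W], b[:H, :W]
    sel = msel[:H, :W] if msel is not None else np.ones((H, W), bool)

    def pearson(x: np.ndarray) -> float:
        xs, ys = x[sel], b[sel]
        if xs.std() == 0 or ys.std() == 0:
            return 0.0
        return float(sps.pearsonr(xs, ys).statistic)

    r_obs = pearson(a)
    blocks = (
        a.reshape(nby, block_size_px, nbx, block_size_px)
        .swapaxes(1, 2)
        .reshape(nby * nbx, block_size_px, block_size_px)
    )
    rng = np.random.default_rng(seed)
    below = 0
    for _ in range(n_rand):
        perm = rng.permutation(len(blocks))
        scr = (
            blocks[perm]
            .reshape(nby, nbx, block_size_px, block_size_px)
            .swapaxes(1, 2)
            .reshape(H, W)
        )
        if pearson(scr) < r_obs:
            below += 1
    return 100.0 * below / n_rand


def pixel_coloc_report(
    imgA: Image,
    imgB: Image,
    mask: Mask | None = None,
    block_size_px: int = 5,
    n_rand: int = 100,
    seed: int = 0,
) -> PixelColocResult:
    """Manders + Pearson + Costes in one record, with thresholds reported."""
    m = mask.data if mask is not None else None
    thrA = _auto_threshold(imgA.data.astype(float), m)
    thrB = _auto_threshold(imgB.data.astype(float), m)
    m1, m2 = manders_split(imgA, imgB, thrA, thrB, mask)
    a, b = imgA.data.astype(float), imgB.data.astype(float)
    if mask is not None:
        sel = mask.data
    else:
        # without a cell mask, correlate over the union of supra-threshold pixels
        sel = (a > thrA) | (b > thrB)
    r = float(sps.pearsonr(a[sel], b[sel]).statistic) if sel.sum() > 2 else 0.0
    p = costes_pvalue(imgA, imgB, block_size_px, n_rand, mask, seed)
    return PixelColocResult(
        m1=m1,
        m2=m2,
        pearson_r=r,
        costes_pvalue_pct=p,
        thr_a=thrA,
        thr_b=thrB,
        block_size_px=block_size_px,
        n_randomizations=n_rand,
    )
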
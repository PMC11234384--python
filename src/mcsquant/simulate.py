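"""Synthetic microscopy scenes, PLA fields and Ca2+ traces with known ground truth.

Every generator is deterministic under a fixed seed and serializes its
ground truth alongside the rendered data, so downstream recovery tests are
self-contained and need no external downloads.

The generators emulate the statistical structure the downstream analyses
assume, not the physics of image formation: diffraction-limited puncta are
isotropic 2D Gaussians at the PSF scale, mitochondria are smoothed random
walks dilated to tubule width, nuclei are disjoint blurred discs, and
camera noise is Poisson shot noise plus Gaussian read noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import draw, morphology

from .core import Image, Mask, PunctaField

# Default pixel size chosen so that 3 px = 233.1 nm, i.e. the object-based
# colocalization threshold corresponds to 3 pixels, matching confocal
# acquisition near the optical resolution limit.
DEFAULT_PIXEL_SIZE_NM = 77.7


@dataclass
class NoiseModel:
    """Camera noise: Poisson shot noise (scaled) plus Gaussian read noise."""

    gaussian_sd: float = 2.0
    poisson_scaling: float = 1.0  # photons per intensity unit; 0 disables shot noise


@dataclass
class SceneSpec:
    """Geometry, optics and noise of a simulated field of view."""

    width_px: int = 256
    height_px: int = 256
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    psf_sigma_nm: float = 80.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be non-negative")
        if isinstance(self.noise_model, dict):
            self.noise_model = NoiseModel(**self.noise_model)

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass
class PunctaGroundTruth:
    """True punctum positions and pairings of a simulated two-channel scene.

    ``pair_map`` lists ``(ref_idx, partner_idx)`` for the truly colocalized
    pairs; ``mito_flags`` marks which reference puncta were placed on the
    mitochondrial mask.
    """

    ref_points: np.ndarray  # (n_ref, 2) nm, columns (x, y)
    partner_points: np.ndarray  # (n_partner, 2) nm
    pair_map: list[tuple[int, int]]
    mito_flags: np.ndarray  # (n_ref,) bool
    f_coloc: float
    f_mito: float
    offset_sigma_nm: float

    def to_json(self) -> str:
        d = {
            "ref_points": np.asarray(self.ref_points).tolist(),
            "partner_points": np.asarray(self.partner_points).tolist(),
            "pair_map": [list(p) for p in self.pair_map],
            "mito_flags": np.asarray(self.mito_flags).astype(int).tolist(),
            "f_coloc": self.f_coloc,
            "f_mito": self.f_mito,
            "offset_sigma_nm": self.offset_sigma_nm,
        }
        return json.dumps(d, sort_keys=True)


def _wobbly_disc(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """A single connected cell-shaped blob: an ellipse with a smooth
    low-order radial perturbation of the boundary."""
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    theta = np.arctan2(yy - cy, xx - cx)
    r = np.hypot((yy - cy) / (0.42 * h), (xx - cx) / (0.42 * w))
    wobble = np.zeros_like(theta)
    for k in range(2, 5):
        amp = rng.uniform(0.0, 0.06)
        phase = rng.uniform(0, 2 * np.pi)
        wobble += amp * np.cos(k * theta + phase)
    return r <= 1.0 + wobble


def make_cell_and_mito_masks(
    spec: SceneSpec,
    mito_area_fraction: float = 0.25,
    tubule_width_px: int = 4,
    max_walks: int = 400,
) -> tuple[Mask, Mask]:
    """Generate a cell mask and a tubular mitochondrial mask inside it.

    The mitochondrial mask is built from smoothed random walks (persistent
    heading) dilated to ``tubule_width_px``, added until the target area
    fraction of the cell is covered.
    """
    if not 0 <= mito_area_fraction <= 0.9:
        raise ValueError(
            "mito_area_fraction must be in [0, 0.9]: a tubular network cannot "
            "cover more of the cell"
        )
    rng = np.random.default_rng(spec.seed)
    cell = _wobbly_disc(spec, rng)
    if not cell.any():
        raise ValueError("degenerate scene: empty cell mask")
    cell_area = int(cell.sum())
    target = mito_area_fraction * cell_area

    mito = np.zeros_like(cell)
    if target > 0:
        cell_rows, cell_cols = np.nonzero(cell)
        selem = morphology.disk(max(1, tubule_width_px // 2))
        n_walks = 0
        while mito.sum() < target and n_walks < max_walks:
            n_walks += 1
            i = rng.integers(len(cell_rows))
            y, x = float(cell_rows[i]), float(cell_cols[i])
            heading = rng.uniform(0, 2 * np.pi)
            length = int(rng.integers(30, 90))
            path = np.zeros_like(cell)
            for _ in range(length):
                heading += rng.normal(0, 0.3)
                y += np.sin(heading)
                x += np.cos(heading)
                iy, ix = int(round(y)), int(round(x))
                if not (0 <= iy < cell.shape[0] and 0 <= ix < cell.shape[1]):
                    break
                if not cell[iy, ix]:
                    break
                path[iy, ix] = True
            mito |= ndi.binary_dilation(path, structure=selem)
        mito &= cell
        if mito.sum() < 0.5 * target:
            raise ValueError("could not reach requested mito area fraction")
    return (
        Mask(cell, kind="cell", pixel_size_nm=spec.pixel_size_nm),
        Mask(mito, kind="mitochondria", pixel_size_nm=spec.pixel_size_nm),
    )


def _sample_in_mask(
    mask: np.ndarray,
    n: int,
    pixel_size_nm: float,
    rng: np.random.Generator,
    min_spacing_nm: float,
    existing: list[np.ndarray],
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform points (nm) over mask pixels with a minimum mutual spacing.

    Rejection sampling: a candidate is a uniformly chosen mask pixel plus
    uniform sub-pixel jitter.
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0 and n > 0:
        raise ValueError("cannot place puncta: target region is empty")
    placed: list[np.ndarray] = list(existing)
    out = []
    for _ in range(n):
        for attempt in range(max_tries):
            i = rng.integers(len(rows))
            jitter = rng.uniform(-0.5, 0.5, size=2)
            pt = np.array(
                [
                    (cols[i] + jitter[0]) * pixel_size_nm,
                    (rows[i] + jitter[1]) * pixel_size_nm,
                ]
            )
            if min_spacing_nm > 0 and placed:
                d = np.min(np.hypot(*(np.array(placed) - pt).T))
                if d < min_spacing_nm:
                    continue
            placed.append(pt)
            out.append(pt)
            break
        else:
            raise ValueError(
                f"could not place {n} puncta at min_spacing_nm={min_spacing_nm}: "
                "spacing constraint unsatisfiable in this region"
            )
    return np.array(out) if out else np.empty((0, 2))


def place_puncta(
    cell: Mask,
    mito: Mask,
    n_ref: int = 200,
    n_partner: int = 200,
    f_coloc: float = 0.3,
    f_mito: float = 0.25,
    offset_sigma_nm: float = 50.0,
    seed: int = 0,
    min_spacing_nm: float = 300.0,
    mito_margin_px: int = 2,
) -> PunctaGroundTruth:
    """Place reference and partner puncta with known colocalized fraction.

    ``round(f_mito * n_ref)`` reference puncta are constrained to the
    mitochondrial mask; the rest go to the cell mask minus a
    ``mito_margin_px``-dilated mitochondrial mask, so ground-truth
    mitochondrial association remains unambiguous under a dilated
    centroid-in-mask rule.  ``round(f_coloc * n_ref)`` reference puncta get
    a partner at an isotropic Gaussian offset (sd ``offset_sigma_nm``,
    sub-resolution by default); remaining partner puncta are uniform over
    the cell mask.
    """
    if not (0 <= f_coloc <= 1 and 0 <= f_mito <= 1):
        raise ValueError("f_coloc and f_mito must be in [0, 1]")
    if cell.shape != mito.shape:
        raise ValueError("cell and mito masks must come from the same scene")
    rng = np.random.default_rng(seed)
    px = cell.pixel_size_nm

    n_mito = round(f_mito * n_ref)
    n_pairs = round(f_coloc * n_ref)

    margin = ndi.binary_dilation(mito.data, structure=morphology.disk(mito_margin_px))
    nonmito_region = cell.data & ~margin
    ref_mito = _sample_in_mask(mito.data, n_mito, px, rng, min_spacing_nm, [])
    ref_other = _sample_in_mask(
        nonmito_region, n_ref - n_mito, px, rng, min_spacing_nm, list(ref_mito)
    )
    ref = (
        np.vstack([p for p in (ref_mito, ref_other) if len(p)])
        if n_ref
        else np.empty((0, 2))
    )
    mito_flags = np.zeros(n_ref, dtype=bool)
    mito_flags[:n_mito] = True
    # shuffle so mito-associated refs are not a contiguous prefix
    order = rng.permutation(n_ref)
    ref = ref[order]
    mito_flags = mito_flags[order]

    pair_ref_idx = rng.choice(n_ref, size=n_pairs, replace=False) if n_pairs else []
    partners = []
    pair_map = []
    for j, ri in enumerate(sorted(pair_ref_idx)):
        offset = rng.normal(0, offset_sigma_nm, size=2) if offset_sigma_nm > 0 else 0.0
        partners.append(ref[ri] + offset)
        pair_map.append((int(ri), j))
    free = _sample_in_mask(
        cell.data, n_partner - n_pairs, px, rng, min_spacing_nm, list(partners)
    )
    partner = (
        np.vstack([p for p in ([np.array(partners)] if partners else []) + [free] if len(p)])
        if n_partner
        else np.empty((0, 2))
    )

    return PunctaGroundTruth(
        ref_points=ref,
        partner_points=partner,
        pair_map=pair_map,
        mito_flags=mito_flags,
        f_coloc=f_coloc,
        f_mito=f_mito,
        offset_sigma_nm=offset_sigma_nm,
    )


def render_channel(
    points: np.ndarray,
    spec: SceneSpec,
    amplitudes: float | np.ndarray = 200.0,
    noise: bool = True,
    seed: int | None = None,
    channel: str = "",
) -> Image:
    """Render points (nm) as Gaussian spots at the PSF scale, plus noise.

    Each point contributes ``A * exp(-r^2 / (2 sigma^2))`` (peak amplitude
    ``A``); noise follows the spec's camera model.  Points must lie inside
    the scene bounds.
    """
    h, w = spec.shape
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        points = np.empty((0, 2))
    img = np.zeros((h, w), dtype=float)
    sigma = spec.psf_sigma_px
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(points),))
    half = max(1, int(np.ceil(4 * max(sigma, 0.5))))
    for (x_nm, y_nm), amp in zip(points, amps):
        xc = x_nm / spec.pixel_size_nm
        yc = y_nm / spec.pixel_size_nm
        if not (-0.5 <= xc < w - 0.5 and -0.5 <= yc < h - 0.5):
            raise ValueError(f"point ({x_nm}, {y_nm}) nm outside scene bounds")
        x0, x1 = max(0, int(xc) - half), min(w, int(xc) + half + 1)
        y0, y1 = max(0, int(yc) - half), min(h, int(yc) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        if sigma > 0:
            patch = amp * np.exp(-((xx - xc) ** 2 + (yy - yc) ** 2) / (2 * sigma**2))
        else:
            patch = np.zeros(yy.shape)
            patch[int(round(yc)) - y0, int(round(xc)) - x0] = amp
        img[y0:y1, x0:x1] += patch
    if noise:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        nm = spec.noise_model
        if nm.poisson_scaling > 0:
            img = rng.poisson(img * nm.poisson_scaling) / nm.poisson_scaling
        if nm.gaussian_sd > 0:
            img = img + rng.normal(0, nm.gaussian_sd, size=img.shape)
        img = np.clip(img, 0, None)
    return Image(img, pixel_size_nm=spec.pixel_size_nm, channel=channel)


@dataclass
class PLAGroundTruth:
    n_cells: int
    nucleus_centers: np.ndarray  # (n_cells, 2) nm
    n_spots: int
    spot_points: np.ndarray  # (n_spots, 2) nm

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_cells": self.n_cells,
                "nucleus_centers": np.asarray(self.nucleus_centers).tolist(),
                "n_spots": self.n_spots,
                "spot_points": np.asarray(self.spot_points).tolist(),
            },
            sort_keys=True,
        )


def make_pla_scene(
    n_cells: int = 10,
    spots_per_cell_mean: float = 20.0,
    spec: SceneSpec | None = None,
    seed: int = 0,
    nucleus_radius_px: float = 12.0,
    spot_amplitude: float = 300.0,
    n_spots: int | None = None,
) -> tuple[Image, Image, PLAGroundTruth]:
    """Simulate a PLA field: disjoint nuclei plus a Poisson spot field.

    The total spot count is drawn ``Poisson(spots_per_cell_mean * n_cells)``
    (or fixed via ``n_spots``); spots are uniform over the field outside
    nuclei so each remains a resolvable object.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    spec = spec or SceneSpec(seed=seed)
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    px = spec.pixel_size_nm

    # disjoint nuclei: rejection-sample centres at >= 2.5 radii separation
    centers = []
    margin = nucleus_radius_px + 2
    for _ in range(10000):
        if len(centers) == n_cells:
            break
        c = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(c - o)) > 2.5 * nucleus_radius_px for o in centers):
            centers.append(c)
    if len(centers) < n_cells:
        raise ValueError("field too small for requested nucleus count")
    centers = np.array(centers)

    dapi = np.zeros((h, w))
    nuclei_mask = np.zeros((h, w), dtype=bool)
    for cx, cy in centers:
        rr, cc = draw.disk((cy, cx), nucleus_radius_px, shape=(h, w))
        dapi[rr, cc] = 500.0
        nuclei_mask[rr, cc] = True
    dapi = ndi.gaussian_filter(dapi, 1.5)

    total = int(rng.poisson(spots_per_cell_mean * n_cells)) if n_spots is None else int(n_spots)
    spot_region = ~ndi.binary_dilation(nuclei_mask, structure=morphology.disk(2))
    spot_region[: 4, :] = spot_region[-4:, :] = False
    spot_region[:, :4] = spot_region[:, -4:] = False
    spots_nm = _sample_in_mask(spot_region, total, px, rng, min_spacing_nm=6 * px, existing=[])

    spot_img = render_channel(
        spots_nm, spec, amplitudes=spot_amplitude, noise=True, seed=seed + 1, channel="PLA"
    )
    dapi_rng = np.random.default_rng(seed + 2)
    dapi = np.clip(dapi + dapi_rng.normal(0, spec.noise_model.gaussian_sd, dapi.shape), 0, None)
    truth = PLAGroundTruth(
        n_cells=n_cells,
        nucleus_centers=centers * px,
        n_spots=total,
        spot_points=spots_nm,
    )
    return spot_img, Image(dapi, pixel_size_nm=px, channel="DAPI"), truth


@dataclass
class CalciumTraceSpec:
    """Shape of a simulated indicator trace in F_max-relative units.

    Baseline sits at ``baseline_frac * F_max``; a stimulus at ``stim_frame``
    triggers a double-exponential transient peaking at ``peak_frac * F_max``;
    at ``fmax_frame`` the trace steps to the F_max saturation plateau
    (pharmacological saturation of the indicator at the end of the
    recording).
    """

    n_frames: int = 600
    frame_interval_s: float = 1.0
    baseline_frac: float = 0.2
    peak_frac: float = 0.55
    stim_frame: int = 60
    fmax_frame: int = 480
    rise_tau_s: float = 3.0
    decay_tau_s: float = 40.0
    noise_sd_frac: float = 0.01
    f_max: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.baseline_frac <= self.peak_frac <= 1):
            raise ValueError("need 0 < baseline_frac <= peak_frac <= 1")
        if not (0 <= self.stim_frame < self.fmax_frame < self.n_frames):
            raise ValueError("need stim_frame < fmax_frame < n_frames")

    @property
    def true_delta(self) -> float:
        """Ground-truth peak ΔF/F_max."""
        return self.peak_frac - self.baseline_frac


def simulate_trace(spec: CalciumTraceSpec) -> pd.DataFrame:
    """One noisy trace as a DataFrame (frame, time_s, F) plus ground truth columns."""
    t = np.arange(spec.n_frames, dtype=float)
    f = np.full(spec.n_frames, spec.baseline_frac)
    ts = (t[spec.stim_frame : spec.fmax_frame] - spec.stim_frame) * spec.frame_interval_s
    if spec.peak_frac > spec.baseline_frac and len(ts):
        shape = (1 - np.exp(-ts / spec.rise_tau_s)) * np.exp(-ts / spec.decay_tau_s)
        m = shape.max()
        if m > 0:
            shape = shape / m
        f[spec.stim_frame : spec.fmax_frame] += (spec.peak_frac - spec.baseline_frac) * shape
    f[spec.fmax_frame :] = 1.0
    f = f * spec.f_max
    if spec.noise_sd_frac > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0, spec.noise_sd_frac * spec.f_max, size=spec.n_frames)
    return pd.DataFrame(
        {"frame": t.astype(int), "time_s": t * spec.frame_interval_s, "F": f}
    )


def make_calcium_trace_pair(
    cyto: CalciumTraceSpec, mito: CalciumTraceSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simultaneously recorded cytosolic and mitochondrial indicator traces."""
    return simulate_trace(cyto), simulate_trace(mito)


# ---------------------------------------------------------------------------
# serialization helpers

def write_scene(
    out_dir: str | Path,
    name: str,
    channels: dict[str, Image],
    truth_json: str,
) -> Path:
    """Write a multichannel TIFF plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = sorted(channels)
    stack = np.stack([channels[k].data.astype(np.float32) for k in labels])
    tif = out_dir / f"{name}.tif"
    tifffile.imwrite(
        tif, stack, photometric="minisblack",
        metadata={"axes": "CYX", "channels": labels},
    )
    (out_dir / f"{name}.truth.json").write_text(truth_json)
    return tif


def write_trace_pair(
    out_dir: str | Path, name: str, cyto: pd.DataFrame, mito: pd.DataFrame
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "frame": cyto["frame"],
            "time_s": cyto["time_s"],
            "F_cyto": cyto["F"],
            "F_mito": mito["F"],
        }
    )
    path = out_dir / f"{name}.csv"
    df.to_csv(path, index=False)
    return path
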
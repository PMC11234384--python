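"""Shared containers for images, binary masks and punctum fields.

Coordinates follow a single convention throughout the package: array axes
are (y, x) (row, column), while punctum centroids are stored as (x, y)
pairs in nanometres.  A pixel index ``i`` maps to the physical coordinate
``i * pixel_size_nm`` (0-based pixel centres), so the object-based
colocalization threshold — a physical length — is independent of pixel
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Image:
    """An intensity image with physical pixel size.

    ``data`` is a 2D ``(y, x)`` array, or 3D ``(z, y, x)`` for z-stacks and
    ``(t, y, x)`` for time series.  ``background_corrected`` records whether
    the mean intensity of an extracellular region has been subtracted.
    """

    data: np.ndarray
    pixel_size_nm: float
    channel: str = ""
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"Image data must be 2D or 3D, got ndim={self.data.ndim}")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def is_stack(self) -> bool:
        return self.data.ndim == 3

    def with_data(self, data: np.ndarray, **changes) -> "Image":
        return replace(self, data=data, **changes)


@dataclass
class Mask:
    """A binary region (cell outline, mitochondria, nuclei) on the image grid."""

    data: np.ndarray
    kind: str = ""
    pixel_size_nm: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("Mask must be 2D")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())

    @property
    def area_nm2(self) -> float:
        return self.n_pixels * self.pixel_size_nm**2

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass
class PunctaField:
    """A set of punctum centroids with per-punctum intensity and area.

    ``centroids_nm`` has shape ``(n, 2)`` with columns ``(x, y)`` in nm.
    """

    centroids_nm: np.ndarray
    intensities: np.ndarray = None
    areas_px: np.ndarray = None
    source_channel: str = ""
    pixel_size_nm: float = 1.0

    def __post_init__(self) -> None:
        self.centroids_nm = np.atleast_2d(np.asarray(self.centroids_nm, dtype=float))
        if self.centroids_nm.size == 0:
            self.centroids_nm = np.empty((0, 2), dtype=float)
        if self.centroids_nm.shape[1] != 2:
            raise ValueError("centroids_nm must have shape (n, 2)")
        n = len(self.centroids_nm)
        if self.intensities is None:
            self.intensities = np.ones(n)
        if self.areas_px is None:
            self.areas_px = np.ones(n)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.areas_px = np.asarray(self.areas_px, dtype=float)
        if len(self.intensities) != n or len(self.areas_px) != n:
            raise ValueError("intensities/areas_px length mismatch with centroids")

    def __len__(self) -> int:
        return len(self.centroids_nm)

    def pixel_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Nearest (row, col) pixel index of each centroid."""
        cols = np.rint(self.centroids_nm[:, 0] / self.pixel_size_nm).astype(int)
        rows = np.rint(self.centroids_nm[:, 1] / self.pixel_size_nm).astype(int)
        return rows, cols

    def select(self, keep: np.ndarray) -> "PunctaField":
        keep = np.asarray(keep)
        return PunctaField(
            centroids_nm=self.centroids_nm[keep],
            intensities=self.intensities[keep],
            areas_px=self.areas_px[keep],
            source_channel=self.source_channel,
            pixel_size_nm=self.pixel_size_nm,
        )


def derive_seed(global_seed: int, *stream: int) -> int:
    """Fan a global seed out to an independent per-stage seed (< 2**31).

    Counter-based: the same (global_seed, stream...) pair always yields the
    same stage seed, so any stage can be rerun in isolation.
    """
    ss = np.random.SeedSequence([int(global_seed), *map(int, stream)])
    return int(ss.generate_state(1)[0] % (2**31))
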
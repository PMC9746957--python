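"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import MM_PER_PX_X, MM_PER_PX_Y


@dataclass
class PSOCTVolume:
    """Two-channel complex PS-OCT tomogram of one sub-field acquisition.

    Both channels are indexed ``(b_scan, a_scan, depth)``.  ``noise_level``
    is the mean background intensity (sum over both channels) used for the
    intensity threshold mask; it is carried as metadata rather than
    re-estimated from the data.
    """

    channel_h: np.ndarray
    channel_v: np.ndarray
    pixel_spacing_um: tuple[float, float]  # (axial, lateral)
    subfield_center_deg: tuple[float, float] = (0.0, 0.0)
    noise_level: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel_h.shape != self.channel_v.shape:
            raise ValueError("channel dimensions differ")
        if self.channel_h.ndim != 3:
            raise ValueError("expected (n_bscans, n_ascans, n_depth) arrays")
        if not self.noise_level > 0:
            raise ValueError("noise_level must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channel_h.shape


@dataclass
class StokesVolume:
    """Per-voxel Stokes vector (I, Q, U, V) with a validity mask.

    Invariants: I >= 0 and Q^2 + U^2 + V^2 <= I^2 up to float rounding.
    """

    I: np.ndarray
    Q: np.ndarray
    U: np.ndarray
    V: np.ndarray
    valid: np.ndarray
    subfield_center_deg: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.I.shape


@dataclass
class DOPUVolume:
    """Degree of polarization uniformity per voxel, NaN where invalid."""

    dopu: np.ndarray
    kernel: tuple[int, int] = (10, 10)  # (axial px, lateral px)
    subfield_center_deg: tuple[float, float] = (0.0, 0.0)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.dopu)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dopu.shape


@dataclass
class RPELine:
    """Depth index of the RPE center per (B-scan, A-scan)."""

    depth: np.ndarray  # integer depth indices
    valid: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depth.shape != self.valid.shape:
            raise ValueError("depth and valid must have the same shape")

    def copy(self) -> "RPELine":
        return RPELine(self.depth.copy(), self.valid.copy())


@dataclass
class EnFaceMap:
    """DOPU sampled at the RPE line over one sub-field, NaN where invalid.

    Rows follow the B-scan order with row 0 at the superior edge (+y);
    columns follow A-scans left (-x) to right (+x).
    """

    values: np.ndarray
    center_deg: tuple[float, float] = (0.0, 0.0)
    mm_per_px: tuple[float, float] = (MM_PER_PX_Y, MM_PER_PX_X)  # (y, x)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class WideFieldMap:
    """Fovea-centered mosaic of DOPU-at-RPE on an isotropic mm grid.

    ``origin_px`` is the (row, col) of the fovea; physical coordinates of a
    pixel are ``x = (col - origin_col) * mm_per_px`` and
    ``y = (origin_row - row) * mm_per_px`` (y increases upward/superior).
    Pixels where ``onh_mask`` is True are excluded from all statistics.
    """

    values: np.ndarray
    mm_per_px: float
    origin_px: tuple[float, float]
    onh_mask: np.ndarray | None = None
    onh_center_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.onh_mask is None:
            self.onh_mask = np.zeros(self.values.shape, dtype=bool)

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (x_mm, y_mm) grids."""
        rows = np.arange(self.values.shape[0])[:, None]
        cols = np.arange(self.values.shape[1])[None, :]
        x = (cols - self.origin_px[1]) * self.mm_per_px
        y = (self.origin_px[0] - rows) * self.mm_per_px
        return np.broadcast_to(x, self.values.shape), np.broadcast_to(y, self.values.shape)

    @property
    def usable(self) -> np.ndarray:
        """Valid and not ONH-masked."""
        return np.isfinite(self.values) & ~self.onh_mask
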
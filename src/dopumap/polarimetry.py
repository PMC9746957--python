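"""Stokes vectors and degree of polarization uniformity (DOPU).

From the two complex detection channels, per-voxel Stokes vectors are

    I = A_H^2 + A_V^2        Q = A_H^2 - A_V^2
    U = 2 A_H A_V cos(dphi)  V = 2 A_H A_V sin(dphi)

with dphi the phase difference between the channels.  Voxels whose
intensity falls below twice the background noise level are excluded.
DOPU is then computed per B-scan with a sliding window (default
10 x 10 px, i.e. ~20 um axial x ~78 um lateral at native spacing): each
valid voxel's Stokes vector is normalized to (Q/I, U/I, V/I), the three
components are averaged over the window, and DOPU is the Euclidean norm
of the average.  Fully polarization-preserving tissue gives DOPU = 1,
perfectly depolarizing tissue 0.
"""

from __future__ import annotations

import numpy as np

from .containers import DOPUVolume, PSOCTVolume, StokesVolume

__all__ = ["compute_stokes", "intensity_mask", "compute_dopu", "kernel_extent_um"]


def compute_stokes(volume: PSOCTVolume) -> StokesVolume:
    """Per-voxel Stokes vectors from the two complex channels.

    The validity mask is the intensity threshold of :func:`intensity_mask`.
    """
    h, v = volume.channel_h, volume.channel_v
    I = (np.abs(h) ** 2 + np.abs(v) ** 2).astype(np.float32)
    Q = (np.abs(h) ** 2 - np.abs(v) ** 2).astype(np.float32)
    cross = np.conj(h) * v
    U = (2.0 * cross.real).astype(np.float32)
    V = (2.0 * cross.imag).astype(np.float32)
    valid = I >= 2.0 * volume.noise_level
    return StokesVolume(I=I, Q=Q, U=U, V=V, valid=valid,
                        subfield_center_deg=volume.subfield_center_deg)


def intensity_mask(volume: PSOCTVolume) -> np.ndarray:
    """True where intensity reaches twice the noise level (inclusive)."""
    if volume.noise_level <= 0:
        raise ValueError("noise_level must be positive")
    I = np.abs(volume.channel_h) ** 2 + np.abs(volume.channel_v) ** 2
    return I >= 2.0 * volume.noise_level


def _sliding_sum(arr: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Truncated sliding-window sum with the window anchored so the output
    index sits at position floor(k/2) within the window."""
    arr = np.moveaxis(arr, axis, -1)
    n = arr.shape[-1]
    c = np.concatenate([np.zeros(arr.shape[:-1] + (1,), dtype=arr.dtype),
                        np.cumsum(arr, axis=-1)], axis=-1)
    i = np.arange(n)
    lo = np.clip(i - k // 2, 0, n)
    hi = np.clip(i + (k - k // 2), 0, n)
    out = c[..., hi] - c[..., lo]
    return np.moveaxis(out, -1, axis)


def compute_dopu(stokes: StokesVolume,
                 kernel: tuple[int, int] = (10, 10),
                 min_valid_frac: float = 0.25,
                 intensity_weighted: bool = False) -> DOPUVolume:
    """Sliding-window DOPU, evaluated within each B-scan.

    Parameters
    ----------
    kernel : (axial px, lateral px)
        Evaluation window; it slides within a B-scan only (no averaging
        across B-scans).  Windows are truncated at the image borders.
    min_valid_frac : float
        Minimum fraction of the full kernel that must be valid voxels;
        windows below it yield NaN.
    intensity_weighted : bool
        If True, average raw Q, U, V over the window and normalize by the
        summed intensity instead of normalizing each voxel first.  The
        default (per-voxel normalization) is the classical definition.
    """
    k_ax, k_lat = int(kernel[0]), int(kernel[1])
    nb, na, nz = stokes.shape
    if k_ax > nz or k_lat > na:
        raise ValueError("kernel does not fit within a B-scan")
    min_count = max(1, int(np.ceil(min_valid_frac * k_ax * k_lat)))

    dopu = np.empty((nb, na, nz), dtype=np.float32)
    for b in range(nb):
        valid = stokes.valid[b]
        I = stokes.I[b].astype(np.float64)
        safe_i = np.where(valid & (I > 0), I, 1.0)
        if intensity_weighted:
            comps = [np.where(valid, stokes.Q[b], 0.0).astype(np.float64),
                     np.where(valid, stokes.U[b], 0.0).astype(np.float64),
                     np.where(valid, stokes.V[b], 0.0).astype(np.float64)]
            norm_src = np.where(valid, I, 0.0)
        else:
            comps = [np.where(valid, stokes.Q[b] / safe_i, 0.0),
                     np.where(valid, stokes.U[b] / safe_i, 0.0),
                     np.where(valid, stokes.V[b] / safe_i, 0.0)]
            norm_src = valid.astype(np.float64)

        def wsum(a):
            return _sliding_sum(_sliding_sum(a, k_lat, axis=0), k_ax, axis=1)

        count = wsum(valid.astype(np.float64))
        denom = wsum(norm_src)
        sq = sum(wsum(c) ** 2 for c in comps)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt(sq) / denom
        d[count < min_count] = np.nan
        dopu[b] = np.clip(d, 0.0, 1.0)

    return DOPUVolume(dopu=dopu, kernel=(k_ax, k_lat),
                      subfield_center_deg=stokes.subfield_center_deg)


def kernel_extent_um(kernel: tuple[int, int],
                     pixel_spacing_um: tuple[float, float]) -> tuple[float, float]:
    """Physical (axial, lateral) extent in micrometers of a DOPU kernel."""
    return (kernel[0] * pixel_spacing_um[0], kernel[1] * pixel_spacing_um[1])
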
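"""En-face depolarization maps and wide-field mosaicking.

The DOPU value at the refined RPE line is extracted into a 2-D en-face
map per acquisition; the three repeats of each sub-field are averaged
pixel-wise; the seven averaged sub-fields are stitched into one
fovea-centered wide-field map (~45 deg) on an isotropic mm grid, and a
disc around the optic nerve head is excluded.

Stitching places each sub-field at its nominal scan offset, refined by a
translation-only registration (masked phase correlation against the
growing mosaic in the overlap region); overlaps are fused with
distance-to-edge feathering weights.  Repeats are assumed pre-aligned by
the instrument's retinal tracker, but the same translation registration
can optionally be applied between repeats.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from . import geometry
from .containers import DOPUVolume, EnFaceMap, RPELine, WideFieldMap

__all__ = ["extract_enface", "average_repeats", "register_translation",
           "stitch", "mask_onh"]

#: default ONH exclusion radius in native lateral pixels (~1.1 mm)
ONH_RADIUS_PX = 140


def extract_enface(dopu: DOPUVolume, line: RPELine) -> EnFaceMap:
    """Sample the DOPU volume at the RPE line.

    The map is NaN wherever the line is invalid or the sampled voxel
    itself is invalid.
    """
    nb, na, nz = dopu.shape
    if line.depth.shape != (nb, na):
        raise ValueError("line shape does not match the DOPU volume")
    depth = np.clip(line.depth, 0, nz - 1)
    vals = np.take_along_axis(dopu.dopu, depth[:, :, None], axis=2)[:, :, 0]
    vals = np.where(line.valid, vals, np.nan).astype(float)
    return EnFaceMap(vals, center_deg=dopu.subfield_center_deg)


def average_repeats(maps: list[EnFaceMap], register: bool = False) -> EnFaceMap:
    """Pixel-wise mean of repeated acquisitions of one sub-field.

    A pixel is invalid only where it is invalid in every repeat.  With
    ``register=True`` the second and later repeats are shifted onto the
    first by translation registration before averaging.
    """
    if not maps:
        raise ValueError("no maps given")
    shape = maps[0].values.shape
    center = maps[0].center_deg
    for m in maps[1:]:
        if m.values.shape != shape:
            raise ValueError("repeat dimensions differ")
        if m.center_deg != center:
            raise ValueError("repeats belong to different sub-fields")
    stack = []
    for i, m in enumerate(maps):
        v = m.values
        if register and i > 0:
            shift = register_translation(maps[0].values, v)
            v = _integer_shift(v, shift)
        stack.append(v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        mean = np.nanmean(np.stack(stack), axis=0)
    return EnFaceMap(mean, center_deg=center, mm_per_px=maps[0].mm_per_px)


def register_translation(reference: np.ndarray, moving: np.ndarray) -> tuple[int, int]:
    """Integer (row, col) shift that moves ``moving`` onto ``reference``.

    NaN pixels are excluded via masked phase correlation.  Returns (0, 0)
    when the overlap of finite pixels is too small to register.
    """
    ref_mask = np.isfinite(reference)
    mov_mask = np.isfinite(moving)
    if ref_mask.sum() < 64 or mov_mask.sum() < 64:
        return (0, 0)
    shift = phase_cross_correlation(
        np.nan_to_num(reference), np.nan_to_num(moving),
        reference_mask=ref_mask, moving_mask=mov_mask)
    if isinstance(shift, tuple):  # newer skimage returns (shift, error, phasediff)
        shift = shift[0]
    return (int(round(shift[0])), int(round(shift[1])))


def _integer_shift(img: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    out = np.full_like(img, np.nan)
    dr, dc = shift
    nr, nc = img.shape
    r0, r1 = max(dr, 0), min(nr + dr, nr)
    c0, c1 = max(dc, 0), min(nc + dc, nc)
    out[r0:r1, c0:c1] = img[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


def _resample_isotropic(emap: EnFaceMap, mm_per_px: float) -> np.ndarray:
    """Invalid-aware bilinear resampling onto an isotropic grid."""
    ny = int(round(emap.values.shape[0] * emap.mm_per_px[0] / mm_per_px))
    nx = int(round(emap.values.shape[1] * emap.mm_per_px[1] / mm_per_px))
    w = np.isfinite(emap.values).astype(float)
    v = np.nan_to_num(emap.values) * w
    num = resize(v, (ny, nx), order=1, mode="edge", anti_aliasing=False)
    den = resize(w, (ny, nx), order=1, mode="edge", anti_aliasing=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 0.5] = np.nan
    return out


def _feather_weight(valid: np.ndarray, feather_px: int) -> np.ndarray:
    w = ndimage.distance_transform_edt(valid)
    return np.minimum(w, feather_px)


def stitch(maps: list[EnFaceMap],
           mm_per_px: float = geometry.MM_PER_PX_X,
           registration: bool = True,
           max_shift_px: int = 40,
           min_overlap_px: int = 2000,
           corr_floor: float = 0.3,
           feather_px: int = 40) -> WideFieldMap:
    """Mosaic averaged sub-field maps into one fovea-centered map.

    Sub-fields are placed at their nominal scan offsets (the grid origin
    is the fovea, i.e. the center of the macular sub-field), processed
    from the fovea outward.  Each placement is refined by masked phase
    correlation against the mosaic built so far; a shift larger than
    ``max_shift_px`` or an overlap correlation below ``corr_floor`` falls
    back to the nominal offset with a warning.  Overlaps are blended with
    distance-to-edge feathering, which leaves values untouched wherever
    only a single map contributes.
    """
    if not maps:
        raise ValueError("no maps given")

    patches, tops, lefts = [], [], []
    for m in maps:
        cx = m.center_deg[0] * geometry.MM_PER_DEG
        cy = m.center_deg[1] * geometry.MM_PER_DEG
        hy = m.values.shape[0] * m.mm_per_px[0] / 2
        hx = m.values.shape[1] * m.mm_per_px[1] / 2
        tops.append(cy + hy)          # mm, top edge (max y)
        lefts.append(cx - hx)         # mm, left edge (min x)
        patches.append(_resample_isotropic(m, mm_per_px))

    margin = max_shift_px + 2
    top_mm = max(tops)
    left_mm = min(lefts)
    rows0 = [int(round((top_mm - t) / mm_per_px)) + margin for t in tops]
    cols0 = [int(round((l - left_mm) / mm_per_px)) + margin for l in lefts]
    nrows = max(r + p.shape[0] for r, p in zip(rows0, patches)) + margin
    ncols = max(c + p.shape[1] for c, p in zip(cols0, patches)) + margin

    num = np.zeros((nrows, ncols))
    den = np.zeros((nrows, ncols))

    order = np.argsort([np.hypot(*m.center_deg) for m in maps])
    for i in order:
        patch, r0, c0 = patches[i], rows0[i], cols0[i]
        pr, pc = patch.shape
        if registration and den.max() > 0:
            with np.errstate(invalid="ignore"):
                mosaic_crop = num[r0:r0 + pr, c0:c0 + pc] / np.where(
                    den[r0:r0 + pr, c0:c0 + pc] > 0, den[r0:r0 + pr, c0:c0 + pc], np.nan)
            overlap = np.isfinite(mosaic_crop) & np.isfinite(patch)
            dr = dc = 0
            if overlap.sum() >= min_overlap_px:
                dr, dc = register_translation(mosaic_crop, patch)
                shifted = _integer_shift(patch, (dr, dc))
                both = np.isfinite(mosaic_crop) & np.isfinite(shifted)
                ok = abs(dr) <= max_shift_px and abs(dc) <= max_shift_px
                if ok and both.sum() > 16:
                    a = mosaic_crop[both] - mosaic_crop[both].mean()
                    b = shifted[both] - shifted[both].mean()
                    denom = np.sqrt((a * a).sum() * (b * b).sum())
                    ok = denom > 0 and (a * b).sum() / denom >= corr_floor
                if not ok:
                    warnings.warn(f"sub-field {maps[i].center_deg}: registration "
                                  "rejected, using nominal offset")
                    dr = dc = 0
            r0, c0 = r0 + dr, c0 + dc
        valid = np.isfinite(patch)
        w = _feather_weight(valid, feather_px)
        num[r0:r0 + pr, c0:c0 + pc] += np.nan_to_num(patch) * w
        den[r0:r0 + pr, c0:c0 + pc] += w

    with np.errstate(invalid="ignore", divide="ignore"):
        mosaic = num / den
    mosaic[den == 0] = np.nan

    # fovea (0, 0) in canvas coordinates (pixel centers, hence the 0.5)
    origin_row = top_mm / mm_per_px + margin - 0.5
    origin_col = -left_mm / mm_per_px + margin - 0.5
    return WideFieldMap(values=mosaic, mm_per_px=mm_per_px,
                        origin_px=(origin_row, origin_col))


def mask_onh(wmap: WideFieldMap,
             onh_center_mm: tuple[float, float],
             radius_px: int = ONH_RADIUS_PX) -> WideFieldMap:
    """Exclude a disc around the optic nerve head.

    ``radius_px`` is in native lateral pixels; at the default spacing of
    8 mm / 1024 px, 140 px is ~1.1 mm.  The masked map shares the value
    array; only the mask and ONH metadata are new.
    """
    radius_mm = radius_px * geometry.MM_PER_PX_X
    x, y = wmap.coords_mm()
    mask = np.hypot(x - onh_center_mm[0], y - onh_center_mm[1]) <= radius_mm
    return WideFieldMap(values=wmap.values, mm_per_px=wmap.mm_per_px,
                        origin_px=wmap.origin_px,
                        onh_mask=wmap.onh_mask | mask,
                        onh_center_mm=tuple(onh_center_mm))
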
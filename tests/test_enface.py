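"""En-face extraction, repeat averaging, mosaicking and ONH masking."""

import numpy as np
import pytest

from dopumap import geometry, synth
from dopumap.containers import DOPUVolume, EnFaceMap, RPELine
from dopumap.enface import (average_repeats, extract_enface, mask_onh,
                            register_translation, stitch)

from conftest import uniform_widefield


def _emap(values, center_deg=(0.0, 0.0)):
    return EnFaceMap(np.asarray(values, dtype=float), center_deg=center_deg)


# --- extraction ------------------------------------------------------------

def test_extract_constant_volume_gives_constant_map():
    d = DOPUVolume(np.full((3, 4, 10), 0.4))
    line = RPELine(np.full((3, 4), 5), np.ones((3, 4), bool))
    m = extract_enface(d, line)
    assert np.allclose(m.values, 0.4)


def test_extract_respects_line_validity_and_depth():
    vol = np.zeros((1, 2, 6))
    vol[0, 0, 3] = 0.7
    valid = np.array([[True, False]])
    m = extract_enface(DOPUVolume(vol), RPELine(np.array([[3, 3]]), valid))
    assert m.values[0, 0] == pytest.approx(0.7)
    assert np.isnan(m.values[0, 1])


def test_extract_recovers_phantom_pattern():
    # en-face DOPU along the true line tracks the target pattern once the
    # protocol's noise reduction is applied: three repeats averaged, then
    # evaluated at the areal scale of the grid statistics (a single 10x10
    # window estimate has ~0.05 sd by itself)
    from dopumap.polarimetry import compute_dopu, compute_stokes
    spec = synth.PhantomSpec(n_bscans=32, n_ascans=160, n_depth=128,
                             retina_thickness_px=40, choroid_px=10,
                             onh_radius_mm=0.0, seed=11)
    maps, truth = [], None
    for rep in range(3):
        vol, truth = synth.make_volume(spec, seed=11 + rep)
        maps.append(extract_enface(compute_dopu(compute_stokes(vol)),
                                   truth.line))
    avg = average_repeats(maps).values
    # bin to 4 B-scans x 16 A-scans blocks (~1 x 0.125 mm)
    binned = np.nanmean(avg.reshape(8, 4, 10, 16), axis=(1, 3)).ravel()
    truth_binned = truth.target_dopu.reshape(8, 4, 10, 16).mean(axis=(1, 3)).ravel()
    r = np.corrcoef(binned, truth_binned)[0, 1]
    assert r > 0.95


# --- repeat averaging ------------------------------------------------------

def test_average_identical_maps_is_identity():
    m = _emap([[0.3, 0.5], [0.7, np.nan]])
    out = average_repeats([m, m, m])
    assert np.allclose(out.values, m.values, equal_nan=True)


def test_average_is_pixelwise_mean_with_invalid_skipped():
    maps = [_emap([[0.3]]), _emap([[0.4]]), _emap([[0.5]])]
    assert average_repeats(maps).values[0, 0] == pytest.approx(0.4)
    maps[2].values[0, 0] = np.nan
    assert average_repeats(maps).values[0, 0] == pytest.approx(0.35)
    for m in maps:
        m.values[0, 0] = np.nan
    assert np.isnan(average_repeats(maps).values[0, 0])


def test_average_never_widens_value_range(rng):
    maps = [_emap(rng.uniform(0.2, 0.8, (6, 6))) for _ in range(3)]
    out = average_repeats(maps)
    lo = min(np.nanmin(m.values) for m in maps)
    hi = max(np.nanmax(m.values) for m in maps)
    assert np.nanmin(out.values) >= lo and np.nanmax(out.values) <= hi


def test_average_rejects_mismatched_repeats():
    with pytest.raises(ValueError):
        average_repeats([_emap(np.zeros((2, 2))), _emap(np.zeros((3, 2)))])
    with pytest.raises(ValueError):
        average_repeats([_emap(np.zeros((2, 2)), (0, 0)),
                         _emap(np.zeros((2, 2)), (9, 0))])


# --- registration and stitching -------------------------------------------

def test_register_translation_recovers_known_shift(rng):
    base = synth.sample_subfield_map(synth.default_dopu_pattern, (0, 0),
                                     n_bscans=96, n_ascans=128).values
    shifted = np.full_like(base, np.nan)
    shifted[7:, 3:] = base[:-7, :-3]
    shift = register_translation(base, shifted)
    assert shift == (-7, -3)
    # applying the returned shift moves the image back onto the reference
    from dopumap.enface import _integer_shift
    back = _integer_shift(shifted, shift)
    ok = np.isfinite(back)
    assert np.allclose(back[ok], base[ok])


def test_stitch_single_map_identity_and_fovea_centering():
    m = synth.sample_subfield_map(synth.default_dopu_pattern, (0.0, 0.0),
                                  n_bscans=125, n_ascans=256)
    w = stitch([m], mm_per_px=8.0 / 256, registration=False)
    # values conserved where only one map contributes (everywhere here):
    # the mosaic equals the isotropic resampling of the single patch,
    # feathering notwithstanding
    from dopumap.enface import _resample_isotropic
    patch = _resample_isotropic(m, 8.0 / 256)
    finite = np.isfinite(w.values)
    assert finite.sum() == np.isfinite(patch).sum()
    dst = np.sort(w.values[finite])
    src = np.sort(patch[np.isfinite(patch)])
    assert np.allclose(dst, src, atol=1e-9)
    # the fovea sits at the pattern's symmetric center: value ~0.42 bump
    r0, c0 = (int(round(p)) for p in w.origin_px)
    x, y = w.coords_mm()
    assert abs(x[r0, c0]) < w.mm_per_px and abs(y[r0, c0]) < w.mm_per_px


def test_stitch_seven_subfields_roundtrip_against_truth():
    mm_per_px = 8.0 / 256
    maps = [synth.sample_subfield_map(synth.default_dopu_pattern, c,
                                      n_bscans=96, n_ascans=256)
            for c in geometry.subfield_centers_deg()]
    w = stitch(maps, mm_per_px=mm_per_px, registration=True,
               min_overlap_px=500)
    x, y = w.coords_mm()
    truth = synth.default_dopu_pattern(x, y)
    ok = np.isfinite(w.values)
    err = np.abs(w.values[ok] - truth[ok])
    assert err.mean() < 0.01


def test_stitch_recovers_perturbed_nominal_offsets():
    # simulate a fixation offset of one sub-field: its content is shifted
    # relative to its nominal center, registration must undo it
    mm_per_px = 8.0 / 256
    centers = [(0.0, 0.0), (9.0, 0.0)]
    true_shift_deg = 0.5  # ~4.6 px at this resolution
    maps = [synth.sample_subfield_map(synth.default_dopu_pattern, centers[0],
                                      96, 256),
            synth.sample_subfield_map(synth.default_dopu_pattern,
                                      (centers[1][0] + true_shift_deg, 0.0),
                                      96, 256)]
    maps[1].center_deg = centers[1]  # nominal center is wrong by the shift
    w = stitch(maps, mm_per_px=mm_per_px, registration=True,
               min_overlap_px=500)
    x, y = w.coords_mm()
    truth = synth.default_dopu_pattern(x, y)
    # content aligned to truth within the blending tolerance despite the
    # wrong nominal offset (without registration the error is ~10x larger)
    ok = np.isfinite(w.values)
    assert np.abs(w.values[ok] - truth[ok]).mean() < 0.012


# --- ONH masking -----------------------------------------------------------

def test_mask_onh_membership_and_area():
    w = uniform_widefield(0.5, half_mm=6.5, mm_per_px=geometry.MM_PER_PX_X)
    masked = mask_onh(w, onh_center_mm=(4.0, 0.0), radius_px=140)
    x, y = masked.coords_mm()
    at_center = np.argmin(np.hypot(x - 4.0, y - 0.0))
    assert masked.onh_mask.ravel()[at_center]          # center pixel masked
    far = np.hypot(x - 4.0, y) > 2.0
    assert not masked.onh_mask[far].any()              # 2 mm away unmasked
    # disc area ~ pi r^2 with r = 140 px (to within a one-pixel ring)
    r = 140.0
    area = masked.onh_mask.sum()
    assert abs(area - np.pi * r**2) < 2 * np.pi * (r + 1)
    # masked pixels never enter statistics
    assert not masked.usable[masked.onh_mask].any()
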
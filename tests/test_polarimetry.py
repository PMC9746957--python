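"""Stokes vectors, intensity masking and the DOPU kernel."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dopumap import geometry
from dopumap.containers import PSOCTVolume, StokesVolume
from dopumap.polarimetry import (compute_dopu, compute_stokes, intensity_mask,
                                 kernel_extent_um)
from dopumap.vmf import kappa_from_resultant, langevin, sample_vmf


def _volume_from_fields(h, v, noise_level=1.0):
    return PSOCTVolume(channel_h=np.asarray(h, dtype=np.complex128),
                       channel_v=np.asarray(v, dtype=np.complex128),
                       pixel_spacing_um=(2.0, 7.8125),
                       noise_level=noise_level)


def _stokes_from_directions(dirs, I=1.0, valid=None):
    """StokesVolume with fully polarized vectors of given directions."""
    dirs = np.asarray(dirs, dtype=float)
    I_arr = np.full(dirs.shape[:-1], float(I))
    s = StokesVolume(I=I_arr, Q=I_arr * dirs[..., 0], U=I_arr * dirs[..., 1],
                     V=I_arr * dirs[..., 2],
                     valid=np.ones(dirs.shape[:-1], bool) if valid is None else valid)
    return s


@pytest.mark.parametrize("h,v,expected", [
    (1.0, 0.0, (1, 1, 0, 0)),                              # pure horizontal
    (1 / np.sqrt(2), 1 / np.sqrt(2), (1, 0, 1, 0)),        # linear 45 deg
    (1 / np.sqrt(2), 1j / np.sqrt(2), (1, 0, 0, 1)),       # circular
])
def test_stokes_reference_states(h, v, expected):
    vol = _volume_from_fields(np.full((1, 1, 1), h), np.full((1, 1, 1), v),
                              noise_level=0.01)
    s = compute_stokes(vol)
    got = (s.I[0, 0, 0], s.Q[0, 0, 0], s.U[0, 0, 0], s.V[0, 0, 0])
    assert got == pytest.approx(expected, abs=1e-6)


def test_stokes_physical_invariant(rng):
    h = (rng.standard_normal((2, 8, 8)) + 1j * rng.standard_normal((2, 8, 8)))
    v = (rng.standard_normal((2, 8, 8)) + 1j * rng.standard_normal((2, 8, 8)))
    s = compute_stokes(_volume_from_fields(h, v))
    assert np.all(s.I >= 0)
    assert np.all(s.Q**2 + s.U**2 + s.V**2 <= s.I**2 * (1 + 1e-5))


def test_intensity_mask_threshold_inclusive():
    # I = 2 x noise exactly -> valid; I = 0 -> invalid; 3 x noise -> valid
    amp = np.sqrt(np.array([[[2.0, 0.0, 3.0]]]))
    vol = _volume_from_fields(amp, np.zeros_like(amp), noise_level=1.0)
    assert intensity_mask(vol).tolist() == [[[True, False, True]]]


def test_intensity_mask_rejects_bad_noise_level():
    with pytest.raises(ValueError):
        _volume_from_fields(np.ones((1, 1, 1)), np.ones((1, 1, 1)),
                            noise_level=0.0)


def test_dopu_identical_states_is_one_and_cancellation_is_zero():
    window = np.broadcast_to([0.0, 0.0, 1.0], (1, 10, 10, 3))
    d = compute_dopu(_stokes_from_directions(window, I=5.0), kernel=(10, 10))
    assert d.dopu[0, 5, 5] == 1.0

    half = np.concatenate([np.broadcast_to([0, 0, 1.0], (1, 10, 5, 3)),
                           np.broadcast_to([0, 0, -1.0], (1, 10, 5, 3))], axis=2)
    d0 = compute_dopu(_stokes_from_directions(half, I=2.0), kernel=(10, 10))
    assert d0.dopu[0, 5, 5] == pytest.approx(0.0, abs=1e-12)


def test_dopu_of_vmf_window_matches_langevin(rng):
    # a large window of kappa = 5 samples estimates L(5) = coth(5) - 1/5
    kappa = 5.0
    dirs = sample_vmf((0, 0, 1), kappa, size=(1, 100, 100), rng=rng)
    d = compute_dopu(_stokes_from_directions(dirs), kernel=(100, 100))
    assert d.dopu[0, 50, 50] == pytest.approx(langevin(kappa), abs=0.01)


def test_dopu_invariant_under_global_stokes_rotation(rng):
    dirs = sample_vmf((0, 0, 1), 2.0, size=(1, 16, 16), rng=rng)
    rot = Rotation.random(rng=42).as_matrix()
    d1 = compute_dopu(_stokes_from_directions(dirs), kernel=(6, 6))
    d2 = compute_dopu(_stokes_from_directions(dirs @ rot.T), kernel=(6, 6))
    assert np.allclose(d1.dopu, d2.dopu, atol=1e-9)


def test_dopu_monotone_in_concentration(rng):
    # less depolarization (larger kappa) never decreases window DOPU
    prev = -1.0
    for rho in (0.1, 0.3, 0.6, 0.9):
        dirs = sample_vmf((0, 0, 1), kappa_from_resultant(rho),
                          size=(1, 120, 120), rng=rng)
        d = compute_dopu(_stokes_from_directions(dirs), kernel=(120, 120))
        val = d.dopu[0, 60, 60]
        assert val > prev
        prev = val


def _dopu_loop_oracle(stokes, kernel):
    """Brute-force per-window reimplementation of the DOPU definition."""
    k_ax, k_lat = kernel
    na, nz = stokes.I.shape[1:]
    out = np.full((na, nz), np.nan)
    min_count = int(np.ceil(0.25 * k_ax * k_lat))
    for a in range(na):
        for z in range(nz):
            a0, a1 = max(a - k_lat // 2, 0), min(a + k_lat - k_lat // 2, na)
            z0, z1 = max(z - k_ax // 2, 0), min(z + k_ax - k_ax // 2, nz)
            acc, n = np.zeros(3), 0
            for ai in range(a0, a1):
                for zi in range(z0, z1):
                    if not stokes.valid[0, ai, zi]:
                        continue
                    I = float(stokes.I[0, ai, zi])
                    acc += np.array([stokes.Q[0, ai, zi], stokes.U[0, ai, zi],
                                     stokes.V[0, ai, zi]], dtype=float) / I
                    n += 1
            if n >= min_count:
                out[a, z] = min(np.linalg.norm(acc) / n, 1.0)
    return out


def test_dopu_matches_brute_force_oracle(rng):
    # vectorized sliding-window DOPU vs an explicit per-window loop,
    # including invalid pixels and truncated border windows
    dirs = sample_vmf((0, 0, 1), 1.5, size=(1, 20, 20), rng=rng)
    I = rng.uniform(0.5, 4.0, size=(1, 20, 20))
    valid = rng.random((1, 20, 20)) > 0.2
    s = StokesVolume(I=I, Q=I * dirs[..., 0], U=I * dirs[..., 1],
                     V=I * dirs[..., 2], valid=valid)
    d = compute_dopu(s, kernel=(10, 10))
    oracle = _dopu_loop_oracle(s, (10, 10))
    assert np.allclose(d.dopu[0], oracle, atol=1e-9, equal_nan=True)


def test_dopu_window_below_minimum_count_is_invalid():
    dirs = np.broadcast_to([0.0, 0.0, 1.0], (1, 12, 12, 3))
    valid = np.zeros((1, 12, 12), bool)
    valid[0, :3, :3] = True  # 9 < 25 valid voxels in any 10x10 window
    d = compute_dopu(_stokes_from_directions(dirs, valid=valid), kernel=(10, 10))
    assert np.all(np.isnan(d.dopu))


def test_dopu_bounds_and_kernel_too_large(rng):
    dirs = sample_vmf((0, 0, 1), 1.0, size=(2, 15, 15), rng=rng)
    s = _stokes_from_directions(dirs)
    d = compute_dopu(s, kernel=(5, 5))
    vals = d.dopu[np.isfinite(d.dopu)]
    assert np.all((vals >= 0) & (vals <= 1))
    with pytest.raises(ValueError):
        compute_dopu(s, kernel=(50, 5))


def test_kernel_extent_matches_scan_geometry():
    ext = kernel_extent_um((10, 10), (geometry.AXIAL_UM_PER_PX,
                                      geometry.LATERAL_UM_PER_PX))
    assert round(ext[0]) == 20
    assert round(ext[1]) == 78
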
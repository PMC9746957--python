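"""Synthetic PS-OCT data with known ground truth.

Every downstream stage of the pipeline (Stokes/DOPU computation, RPE line
refinement, en-face mosaicking, grid statistics, cohort analysis) is
exercised on data from this module, so each generator returns the ground
truth alongside the data.

The tissue model is deliberately minimal.  A layered retina is simulated
per A-scan: polarization-preserving neural retina above a depolarizing RPE
band, a short polarization-preserving tail below it, and below-noise
background elsewhere.  Depolarization is modeled by drawing each RPE
voxel's polarization direction from a von Mises-Fisher distribution on the
Poincare sphere whose concentration is chosen so that the mean resultant
length — which is what DOPU estimates — equals the locally prescribed
target.  Speckle, attenuation and shadowing are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import geometry
from .containers import PSOCTVolume, RPELine
from .vmf import kappa_from_resultant, sample_vmf

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "default_dopu_pattern",
    "constant_pattern",
    "make_volume",
    "make_initial_segmentation",
    "make_cohort",
    "sample_subfield_map",
    "subfield_grid_mm",
]


def default_dopu_pattern(x_mm, y_mm, texture_amp: float = 0.02):
    """Target DOPU versus fovea-centered position (mm).

    Emulates the healthy spatial pattern: strongest depolarization
    (DOPU ~0.33) in a perifoveal annulus, a partial recovery at the foveal
    center (~0.42), and a smooth rise toward ~0.52 in the periphery.  A
    small deterministic sinusoidal texture provides local contrast so that
    translation registration has something to lock onto; it is part of the
    ground truth, not noise.
    """
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    r = np.hypot(x, y)
    # periphery ramp: 0.33 inside r=1 mm rising to 0.52 by r=5 mm
    t = np.clip((r - 1.0) / 4.0, 0.0, 1.0)
    base = 0.33 + 0.19 * (3 * t**2 - 2 * t**3)
    # cosine-tapered foveal relief inside r = 0.5 mm
    bump = np.where(r < 0.5, 0.09 * 0.5 * (1 + np.cos(np.pi * r / 0.5)), 0.0)
    tex = texture_amp * np.sin(2 * np.pi * x / 1.3) * np.sin(2 * np.pi * y / 1.7)
    return np.clip(base + bump + tex, 0.0, 1.0)


def constant_pattern(value: float) -> Callable:
    """A spatially uniform target-DOPU pattern."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("target DOPU must lie in [0, 1]")

    def pattern(x_mm, y_mm):
        return np.full(np.broadcast(np.asarray(x_mm), np.asarray(y_mm)).shape, value)

    return pattern


@dataclass
class PhantomSpec:
    """Parameters of the layered-retina phantom.

    ``grid_truth`` maps fovea-centered position (mm) to target DOPU in
    [0, 1].  ``noise_sigma`` is the standard deviation per real/imaginary
    component of the additive complex detection noise in each channel, so
    the mean background intensity (both channels summed) is
    ``4 * noise_sigma**2``; ``tissue_snr`` sets the tissue signal intensity
    as a multiple of that noise level (default 100, i.e. 20 dB, typical of
    retinal OCT).
    """

    grid_truth: Callable = default_dopu_pattern
    rpe_depth_surface: Callable | None = None  # (x_mm, y_mm) -> depth px
    rpe_thickness_px: int = 14
    layer_state: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_sigma: float = 0.5
    tissue_snr: float = 100.0
    retina_thickness_px: int = 110
    choroid_px: int = 20
    onh_center_mm: tuple[float, float] = (4.0, 0.0)
    onh_radius_mm: float = 0.95
    n_bscans: int = geometry.N_BSCANS
    n_ascans: int = geometry.N_ASCANS
    n_depth: int = 512
    axial_um_per_px: float = geometry.AXIAL_UM_PER_PX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.rpe_thickness_px < 1:
            raise ValueError("rpe_thickness_px must be >= 1")
        if self.tissue_snr <= 0:
            raise ValueError("tissue_snr must be positive")

    @property
    def noise_level(self) -> float:
        """Mean background intensity (both channels), the masking reference."""
        return max(4.0 * self.noise_sigma**2, 1e-12)


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated volume."""

    line: RPELine              # RPE band center
    band_top: np.ndarray       # first depth index of the RPE band
    band_bot: np.ndarray       # one past the last depth index
    target_dopu: np.ndarray    # per (b, a) prescribed DOPU
    onh_mask: np.ndarray       # per (b, a) True inside the simulated ONH

    def in_band(self, line: RPELine) -> np.ndarray:
        """Whether each (valid) index of ``line`` lies inside the RPE band."""
        return (line.depth >= self.band_top) & (line.depth < self.band_bot)


def subfield_grid_mm(center_deg, n_bscans, n_ascans):
    """Fovea-centered (x_mm, y_mm) of every sub-field pixel center.

    Row 0 is the superior edge (largest y); columns run nasal-temporal with
    x increasing.
    """
    cx = center_deg[0] * geometry.MM_PER_DEG
    cy = center_deg[1] * geometry.MM_PER_DEG
    wx, wy = geometry.SUBFIELD_EXTENT_MM
    x = cx + (np.arange(n_ascans) + 0.5 - n_ascans / 2) * (wx / n_ascans)
    y = cy + (n_bscans / 2 - 0.5 - np.arange(n_bscans)) * (wy / n_bscans)
    return np.meshgrid(x, y)


def _default_surface(spec: PhantomSpec):
    z0 = 0.55 * spec.n_depth

    def surface(x_mm, y_mm):
        r2 = (np.asarray(x_mm) ** 2 + np.asarray(y_mm) ** 2) / 36.0
        return z0 + 0.04 * spec.n_depth * r2

    return surface


def make_volume(spec: PhantomSpec,
                subfield_center_deg: tuple[float, float] = (0.0, 0.0),
                seed: int | None = None) -> tuple[PSOCTVolume, PhantomTruth]:
    """Simulate one sub-field acquisition and its ground truth.

    The two detection channels are synthesized so that the noise-free
    Stokes vector of every tissue voxel is fully polarized with intensity
    ``tissue_snr * noise_level`` and direction equal to ``layer_state``
    (polarization-preserving layers) or a per-voxel vMF draw (RPE band).
    Independent complex Gaussian noise of scale ``noise_sigma`` is then
    added to each channel.  Inside the simulated optic nerve head the RPE
    band is absent (replaced by preserving tissue), which downstream shows
    up as A-scans without any low-DOPU batch.

    Bit-for-bit reproducible for a fixed ``seed`` (default ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nb, na, nz = spec.n_bscans, spec.n_ascans, spec.n_depth
    X, Y = subfield_grid_mm(subfield_center_deg, nb, na)

    target = np.clip(np.asarray(spec.grid_truth(X, Y), dtype=float), 0.0, 1.0)
    onh = np.hypot(X - spec.onh_center_mm[0], Y - spec.onh_center_mm[1]) < spec.onh_radius_mm

    surface = spec.rpe_depth_surface or _default_surface(spec)
    z_center = np.asarray(surface(X, Y), dtype=float)
    z_center = np.broadcast_to(z_center, (nb, na))
    band_top = np.rint(z_center).astype(int) - spec.rpe_thickness_px // 2
    band_bot = band_top + spec.rpe_thickness_px
    margin = 6  # kernel half-height plus one
    if band_top.min() < margin or band_bot.max() > nz - margin:
        raise ValueError("rpe_depth_surface too close to the volume top/bottom")

    zidx = np.arange(nz)[None, None, :]
    top3, bot3 = band_top[:, :, None], band_bot[:, :, None]
    ilm = np.maximum(top3 - spec.retina_thickness_px, 0)
    tissue = (zidx >= ilm) & (zidx < np.minimum(bot3 + spec.choroid_px, nz))
    choroid = tissue & (zidx >= bot3)
    rpe = (zidx >= top3) & (zidx < bot3) & ~onh[:, :, None]

    i_sig = spec.tissue_snr * spec.noise_level
    I = np.where(tissue, np.where(choroid, 0.5 * i_sig, i_sig), 0.0)

    # polarization direction field: preserving layer state everywhere ...
    d = np.empty((nb, na, nz, 3), dtype=np.float32)
    d[..., 0], d[..., 1], d[..., 2] = spec.layer_state
    # ... except vMF draws inside the RPE band
    kappa = kappa_from_resultant(target)
    kap_vox = np.broadcast_to(kappa[:, :, None], (nb, na, nz))[rpe]
    d[rpe] = sample_vmf(spec.layer_state, kap_vox, rng=rng).astype(np.float32)

    Q, U, V = (I * d[..., i] for i in range(3))
    del d
    a_h = np.sqrt(np.maximum(I + Q, 0.0) / 2.0).astype(np.float32)
    a_v = np.sqrt(np.maximum(I - Q, 0.0) / 2.0).astype(np.float32)
    dphi = np.arctan2(V, U).astype(np.float32)
    del Q, U, V, I

    noise = lambda: (rng.standard_normal((nb, na, nz), dtype=np.float32)
                     + 1j * rng.standard_normal((nb, na, nz), dtype=np.float32)
                     ) * np.float32(spec.noise_sigma)
    channel_h = a_h.astype(np.complex64) + noise()
    channel_v = (a_v * np.exp(1j * dphi)).astype(np.complex64) + noise()

    vol = PSOCTVolume(
        channel_h=channel_h,
        channel_v=channel_v,
        pixel_spacing_um=(spec.axial_um_per_px,
                          geometry.SUBFIELD_EXTENT_MM[0] * 1000.0 / na),
        subfield_center_deg=tuple(subfield_center_deg),
        noise_level=spec.noise_level,
        meta={"seed": int(spec.seed if seed is None else seed)},
    )
    truth = PhantomTruth(
        line=RPELine(np.rint(z_center).astype(int), ~onh),
        band_top=band_top,
        band_bot=band_bot,
        target_dopu=target,
        onh_mask=onh,
    )
    return vol, truth


def make_initial_segmentation(truth: RPELine,
                              jump_fraction: float,
                              jump_offset_px: int,
                              seed: int = 0,
                              n_depth: int | None = None) -> RPELine:
    """Perturb a true RPE line like an intensity-only segmenter would.

    Exactly ``floor(jump_fraction * N)`` A-scans are displaced by
    ``+/- jump_offset_px`` (random sign), emulating jumps to other
    hyper-reflective structures; the rest are copied unchanged.
    """
    if not 0.0 <= jump_fraction <= 1.0:
        raise ValueError("jump_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    depth = truth.depth.copy()
    flat = depth.reshape(-1)
    n_jump = int(np.floor(jump_fraction * flat.size))
    idx = rng.choice(flat.size, size=n_jump, replace=False)
    signs = rng.choice([-1, 1], size=n_jump)
    flat[idx] = flat[idx] + signs * int(jump_offset_px)
    if n_depth is not None:
        np.clip(flat, 0, n_depth - 1, out=flat)
    return RPELine(depth, np.ones_like(depth, dtype=bool))


def sample_subfield_map(pattern: Callable,
                        center_deg: tuple[float, float],
                        n_bscans: int = geometry.N_BSCANS,
                        n_ascans: int = geometry.N_ASCANS):
    """Evaluate a target-DOPU pattern on one sub-field's pixel grid.

    Convenience for mosaicking round trips: gives the en-face map an ideal
    pipeline would produce for that sub-field.
    """
    from .containers import EnFaceMap

    X, Y = subfield_grid_mm(center_deg, n_bscans, n_ascans)
    vals = np.asarray(pattern(X, Y), dtype=float)
    return EnFaceMap(vals, center_deg=tuple(center_deg),
                     mm_per_px=(geometry.SUBFIELD_EXTENT_MM[1] / n_bscans,
                                geometry.SUBFIELD_EXTENT_MM[0] / n_ascans))


_RING_BASELINES = {"A": 0.42, "B": 0.35, "C": 0.36, "D": 0.42,
                   "E": 0.47, "F": 0.50, "G": 0.52}


@dataclass
class CohortSpec:
    """Generative model of a study cohort's per-ring mean DOPU.

    Ring baselines are the DOPU at ``reference_age`` for a healthy female
    subject; defaults reflect the observed pattern of minima ~0.31-0.39 in
    the perifoveal rings and ~0.52 in the outermost ring.  Each subject's
    per-ring value is baseline + slope * (age - reference) + group and sex
    offsets + independent Gaussian noise, clipped to [0, 1].
    """

    n_healthy: int = 105
    n_glaucoma: int = 48
    age_range: tuple[float, float] = (21.0, 79.0)
    glaucoma_age_range: tuple[float, float] = (40.0, 78.0)
    dopu_age_slope: float = -0.0015   # DOPU per year
    reference_age: float = 60.0
    ring_baselines: dict = field(default_factory=lambda: dict(_RING_BASELINES))
    group_effect: float = -0.01       # added for glaucoma
    sex_effect: float = 0.005         # added for male
    subject_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy <= 0 or self.n_glaucoma < 0:
            raise ValueError("cohort sizes must be positive")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")
        bad = [k for k, v in self.ring_baselines.items() if not 0 <= v <= 1]
        if bad:
            raise ValueError(f"ring baselines outside [0, 1]: {bad}")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table: one row per subject, one column per ring.

    Ages are uniform within each group's range, sexes alternate (balanced
    to within one subject per group).  Columns: ``subject, group, sex,
    age`` and ``ring_A`` ... ``ring_G``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n, (lo, hi) in (("healthy", spec.n_healthy, spec.age_range),
                               ("glaucoma", spec.n_glaucoma, spec.glaucoma_age_range)):
        ages = rng.uniform(lo, hi, size=n)
        for i in range(n):
            rows.append({"subject": f"{group[0].upper()}{i:03d}",
                         "group": group,
                         "sex": "F" if i % 2 == 0 else "M",
                         "age": ages[i]})
    table = pd.DataFrame(rows)
    is_glaucoma = (table["group"] == "glaucoma").to_numpy(dtype=float)
    is_male = (table["sex"] == "M").to_numpy(dtype=float)
    age = table["age"].to_numpy()
    for ring, base in spec.ring_baselines.items():
        mean = (base
                + spec.dopu_age_slope * (age - spec.reference_age)
                + spec.group_effect * is_glaucoma
                + spec.sex_effect * is_male)
        noise = rng.normal(0.0, spec.subject_noise_sd, size=len(table)) \
            if spec.subject_noise_sd > 0 else 0.0
        table[f"ring_{ring}"] = np.clip(mean + noise, 0.0, 1.0)
    return table
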
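# dopumap

Quantitative wide-field mapping of depolarization caused by the retinal
pigment epithelium (RPE), from polarization-sensitive optical coherence
tomography (PS-OCT) tomograms.

The RPE's melanin depolarizes backscattered light while the neural retina
is largely polarization preserving. `dopumap` turns two-channel PS-OCT
volumes into regional depolarization statistics of the RPE, for
researchers studying how RPE pigmentation varies with retinal location,
age, sex and disease. Because raw clinical PS-OCT volumes are rarely
shareable, the package includes a first-class synthetic-data generator
with known ground truth, so the entire pipeline is testable end to end.

## The pipeline

1. **Polarimetry** — per voxel, from the complex channel amplitudes
   A_H, A_V and phase difference Δφ:

   I = A_H² + A_V², Q = A_H² − A_V², U = 2·A_H·A_V·cos Δφ,
   V = 2·A_H·A_V·sin Δφ.

   Voxels with I below twice the noise level are excluded. The **degree
   of polarization uniformity** is computed in a sliding window
   (10 × 10 px ≈ 20 μm axial × 78 μm lateral at native sampling), within
   single B-scans:

   DOPU = √(⟨Q/I⟩² + ⟨U/I⟩² + ⟨V/I⟩²),

   the resultant length of the window-averaged normalized Stokes vectors:
   1 for uniform polarization states, → 0 for fully randomized ones.
2. **RPE segmentation refinement** — per A-scan, batches of consecutive
   pixels with DOPU < 0.6 are located; the batch closest to the
   intensity-based input line is selected and the line is moved to the
   batch's DOPU minimum (the presumed RPE center).
3. **En-face mapping and mosaicking** — DOPU at the refined line gives a
   2-D map per acquisition; 3 repeats × 7 sub-fields (28° × 21° ≙
   8 × 6 mm² each) are averaged and stitched into one fovea-centered
   ~45° map; a 140-px (~1.1 mm) disc around the optic nerve head is
   excluded.
4. **Sectoral grid** — an extended ETDRS-style grid (central 0.5 mm
   circle + rings of 1, 2, 3, 6, 9, 12 mm diameter × 8 sectors = 49
   fields) yields mean DOPU ± SE per field.
5. **Cohort statistics** — unpaired Student's t-tests between groups per
   field (with age matching), paired t-tests between neighboring rings,
   and OLS regressions of ring DOPU on age (slope s, R², p).

The synthetic phantom draws each RPE voxel's polarization direction from
a von Mises–Fisher distribution on the Poincaré sphere whose
concentration κ satisfies coth κ − 1/κ = target DOPU, so every stage has
an exact expected value to recover.

## Worked example

`examples/02_rpe_refinement.py` simulates a sub-field whose RPE has a
known depolarization target of 0.35, displaces 20% of the true
segmentation line by 15 px to mimic intensity-segmentation jumps, and
repairs it with the DOPU-guided rule:

```
initial line inside the true RPE band: 80.0%
refined line inside the true RPE band: 99.1%
median |refined - truth|: 2.0 px
```

The displaced A-scans are pulled back into the depolarizing band; the
residual ~2 px offset is the distance between the band center and the
stochastic DOPU minimum. `examples/04_grid_statistics.py` mosaics seven
sub-fields and prints per-ring means:

```
ring means (center to periphery):
A    0.395
B    0.344
C    0.330
D    0.333
E    0.382
F    0.476
G    0.519
```

— strongest depolarization (lowest DOPU) in the perifoveal rings, partial
relief at the foveal center, weakest depolarization peripherally, as
prescribed by the phantom's spatial pattern. The other examples cover
volume simulation + DOPU (`01`), wide-field mosaicking with ONH exclusion
(`03`) and cohort-level group/age statistics (`05`).

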
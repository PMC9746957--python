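"""Acquisition geometry of the wide-field PS-OCT scan protocol.

A single sub-field raster covers 28 deg (x) by 21 deg (y), corresponding to
8 x 6 mm^2 on the retina of a standard eye, sampled with 250 B-scans of
1024 A-scans each.  Seven sub-fields (one centered on the macula, six
distributed around it) are each acquired three times, giving 21 volumes per
subject; averaging and mosaicking turns them into one ~45 deg map.
"""

from __future__ import annotations

import itertools
import math

#: sub-field extent in scan angle, (x, y) degrees
SUBFIELD_EXTENT_DEG = (28.0, 21.0)
#: sub-field extent on the retina, (x, y) mm (standard eye)
SUBFIELD_EXTENT_MM = (8.0, 6.0)
#: retinal mm per degree of scan angle (8 mm / 28 deg = 6 mm / 21 deg)
MM_PER_DEG = 8.0 / 28.0

#: native raster sampling of one sub-field
N_BSCANS = 250
N_ASCANS = 1024

#: native pixel spacing, mm per pixel, (y = slow axis, x = fast axis)
MM_PER_PX_Y = SUBFIELD_EXTENT_MM[1] / N_BSCANS   # 0.024 mm
MM_PER_PX_X = SUBFIELD_EXTENT_MM[0] / N_ASCANS   # 0.0078125 mm

#: default axial pixel spacing, micrometers per pixel
AXIAL_UM_PER_PX = 2.0
#: default lateral pixel spacing, micrometers per pixel
LATERAL_UM_PER_PX = MM_PER_PX_X * 1000.0

#: repeats per sub-field
N_REPEATS = 3

_HEX_RADIUS_DEG = 9.0


def subfield_centers_deg(radius_deg: float = _HEX_RADIUS_DEG) -> list[tuple[float, float]]:
    """Nominal sub-field centers: macula plus six on a hexagon around it.

    With the default 9 deg hexagon radius the seven slightly overlapping
    28 x 21 deg tiles span ~46 deg horizontally, comparable to a 45 deg
    fundus photograph.  Smaller radii increase the tile overlap.
    """
    centers = [(0.0, 0.0)]
    for k in range(6):
        ang = math.radians(60.0 * k)
        centers.append((round(radius_deg * math.cos(ang), 6),
                        round(radius_deg * math.sin(ang), 6)))
    return centers


def acquisition_manifest(subject_id: str = "S000",
                         n_repeats: int = N_REPEATS,
                         centers_deg: list[tuple[float, float]] | None = None) -> list[dict]:
    """Enumerate the volumes acquired for one subject.

    Returns one entry per (repeat, sub-field) pair — 21 with the default
    protocol — each carrying the nominal sub-field center and raster size.
    """
    if centers_deg is None:
        centers_deg = subfield_centers_deg()
    manifest = []
    for rep, (sf, center) in itertools.product(range(n_repeats),
                                               enumerate(centers_deg)):
        manifest.append({
            "subject": subject_id,
            "repeat": rep,
            "subfield": sf,
            "center_deg": tuple(center),
            "n_bscans": N_BSCANS,
            "n_ascans": N_ASCANS,
        })
    return manifest
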
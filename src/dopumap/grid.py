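"""Extended ETDRS-style sectoral grid and per-field statistics.

The fovea-centered grid consists of an inner circle of 0.5 mm diameter
(field A) surrounded by six rings with outer diameters 1, 2, 3, 6, 9 and
12 mm (rings B-G), each divided into 8 sectors — 49 fields in total.
Ring membership uses half-open annuli [inner, outer) so every inside
pixel belongs to exactly one field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import WideFieldMap

__all__ = ["GridSpec", "assign_field", "field_means", "RING_LABELS"]

RING_LABELS = "ABCDEFG"


@dataclass
class GridSpec:
    """Geometry and labeling of the sectoral grid.

    The sector anchor and direction are configurable because chart
    conventions differ: by default sector 1 starts at the positive-x
    (image-right) horizontal and sectors advance counterclockwise, with
    boundaries at multiples of 45 deg.
    """

    diameters_mm: tuple = (0.5, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0)
    n_sectors: int = 8
    anchor_deg: float = 0.0
    clockwise: bool = False
    ring_labels: str = RING_LABELS

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_mm, dtype=float)
        if not np.all(np.diff(d) > 0):
            raise ValueError("diameters must be strictly increasing")
        if len(self.ring_labels) != len(d):
            raise ValueError("one ring label per diameter required")

    @property
    def radii_mm(self) -> np.ndarray:
        return np.asarray(self.diameters_mm, dtype=float) / 2.0

    @property
    def n_fields(self) -> int:
        return 1 + (len(self.diameters_mm) - 1) * self.n_sectors

    def field_ids(self) -> list[str]:
        ids = [self.ring_labels[0]]
        for ring in self.ring_labels[1:]:
            ids += [f"{ring}{s}" for s in range(1, self.n_sectors + 1)]
        return ids


def assign_field(x_mm, y_mm, spec: GridSpec | None = None) -> np.ndarray:
    """Field label for fovea-centered positions; '' outside the grid.

    The central circle is one undivided field; ring fields are labeled
    ``<ring><sector>`` with sectors 1..8 anchored and oriented per the
    spec.
    """
    spec = spec or GridSpec()
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    r = np.hypot(x, y)
    radii = spec.radii_mm

    ring_idx = np.searchsorted(radii, r, side="right")  # 0 = central circle
    out = np.full(r.shape, "", dtype=object)
    inside = ring_idx < len(radii)
    out[inside & (ring_idx == 0)] = spec.ring_labels[0]

    theta = np.degrees(np.arctan2(y, x))
    if spec.clockwise:
        theta = -theta
    theta = np.mod(theta - spec.anchor_deg, 360.0)
    sector = (theta // (360.0 / spec.n_sectors)).astype(int) + 1
    sector = np.minimum(sector, spec.n_sectors)  # guard theta == 360 rounding

    ringed = inside & (ring_idx > 0)
    labels = np.array(list(spec.ring_labels), dtype=object)
    if np.any(ringed):
        out[ringed] = [f"{ring}{s}" for ring, s in
                       zip(labels[ring_idx[ringed]], sector[ringed])]
    return out if out.ndim else out[()]


def field_means(wmap: WideFieldMap, spec: GridSpec | None = None) -> pd.DataFrame:
    """Mean DOPU and standard error per grid field of a wide-field map.

    Only valid, non-ONH-masked pixels contribute.  Fields with no usable
    pixel are reported with NaN mean/SE and n = 0 rather than dropped, so
    the output always has one row per field (49 by default).
    """
    spec = spec or GridSpec()
    x, y = wmap.coords_mm()
    usable = wmap.usable
    labels = assign_field(x[usable], y[usable], spec)
    vals = wmap.values[usable]

    df = pd.DataFrame({"field_id": labels, "dopu": vals})
    df = df[df["field_id"] != ""]
    g = df.groupby("field_id")["dopu"]
    stats = pd.DataFrame({"mean_dopu": g.mean(),
                          "se": g.std(ddof=1) / np.sqrt(g.count()),
                          "n": g.count()})

    all_ids = spec.field_ids()
    stats = stats.reindex(all_ids)
    stats["n"] = stats["n"].fillna(0).astype(int)
    stats.index.name = "field_id"
    stats = stats.reset_index()
    stats["ring"] = stats["field_id"].str[0]
    stats["sector"] = [int(f[1:]) if len(f) > 1 else 0 for f in stats["field_id"]]
    return stats[["field_id", "ring", "sector", "mean_dopu", "se", "n"]]
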
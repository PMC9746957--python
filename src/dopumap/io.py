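"""File formats: raw complex volumes, TIFF maps, CSV lines and cohorts.

Volumes are stored as paired little-endian complex64 binaries (one per
channel) with a JSON sidecar carrying dimensions, pixel spacings,
sub-field center and noise level.  DOPU volumes and 2-D maps go to
32-bit float TIFF (one page per B-scan for volumes) with NaN marking
invalid pixels; segmentation lines and cohort tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import DOPUVolume, EnFaceMap, PSOCTVolume, RPELine, WideFieldMap

__all__ = ["save_volume", "load_volume", "save_dopu", "load_dopu",
           "save_line", "load_line", "save_widefield", "load_widefield",
           "save_cohort", "load_cohort"]


def save_volume(vol: PSOCTVolume, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    vol.channel_h.astype("<c8").tofile(d / "channel_h.bin")
    vol.channel_v.astype("<c8").tofile(d / "channel_v.bin")
    sidecar = {
        "shape": list(vol.shape),
        "pixel_spacing_um": list(vol.pixel_spacing_um),
        "subfield_center_deg": list(vol.subfield_center_deg),
        "noise_level": vol.noise_level,
        "meta": vol.meta,
    }
    (d / "volume.json").write_text(json.dumps(sidecar, indent=1))
    return d


def load_volume(directory: str | Path) -> PSOCTVolume:
    d = Path(directory)
    sidecar = json.loads((d / "volume.json").read_text())
    shape = tuple(sidecar["shape"])
    h = np.fromfile(d / "channel_h.bin", dtype="<c8").reshape(shape)
    v = np.fromfile(d / "channel_v.bin", dtype="<c8").reshape(shape)
    return PSOCTVolume(channel_h=h, channel_v=v,
                       pixel_spacing_um=tuple(sidecar["pixel_spacing_um"]),
                       subfield_center_deg=tuple(sidecar["subfield_center_deg"]),
                       noise_level=sidecar["noise_level"],
                       meta=sidecar.get("meta", {}))


def save_dopu(dopu: DOPUVolume, path: str | Path) -> Path:
    path = Path(path)
    # one page per B-scan, each (n_ascans, n_depth)
    tifffile.imwrite(path, dopu.dopu.astype(np.float32),
                     metadata={"kernel": list(dopu.kernel),
                               "center_deg": list(dopu.subfield_center_deg)})
    return path


def load_dopu(path: str | Path, kernel=(10, 10), center_deg=(0.0, 0.0)) -> DOPUVolume:
    arr = tifffile.imread(path)
    return DOPUVolume(dopu=arr, kernel=tuple(kernel), subfield_center_deg=tuple(center_deg))


def save_line(line: RPELine, path: str | Path) -> Path:
    path = Path(path)
    nb, na = line.depth.shape
    b, a = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    pd.DataFrame({"bscan": b.ravel(), "ascan": a.ravel(),
                  "depth_index": line.depth.ravel(),
                  "valid": line.valid.ravel().astype(int)}).to_csv(path, index=False)
    return path


def load_line(path: str | Path) -> RPELine:
    df = pd.read_csv(path)
    nb = int(df["bscan"].max()) + 1
    na = int(df["ascan"].max()) + 1
    depth = np.zeros((nb, na), dtype=int)
    valid = np.zeros((nb, na), dtype=bool)
    depth[df["bscan"], df["ascan"]] = df["depth_index"]
    valid[df["bscan"], df["ascan"]] = df["valid"].astype(bool)
    return RPELine(depth, valid)


def save_widefield(wmap: WideFieldMap, path: str | Path) -> Path:
    """32-bit TIFF plus a JSON sidecar with grid origin, spacing and mask."""
    path = Path(path)
    vals = wmap.values.astype(np.float32).copy()
    tifffile.imwrite(path, vals)
    sidecar = {
        "mm_per_px": wmap.mm_per_px,
        "origin_px": list(wmap.origin_px),
        "onh_center_mm": list(wmap.onh_center_mm) if wmap.onh_center_mm else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if wmap.onh_mask is not None and wmap.onh_mask.any():
        tifffile.imwrite(path.with_name(path.stem + "_onh_mask.tif"),
                         wmap.onh_mask.astype(np.uint8))
    return path


def load_widefield(path: str | Path) -> WideFieldMap:
    path = Path(path)
    vals = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    mask_path = path.with_name(path.stem + "_onh_mask.tif")
    mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    onh = sidecar.get("onh_center_mm")
    return WideFieldMap(values=vals, mm_per_px=sidecar["mm_per_px"],
                        origin_px=tuple(sidecar["origin_px"]),
                        onh_mask=mask,
                        onh_center_mm=tuple(onh) if onh else None)


def save_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
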
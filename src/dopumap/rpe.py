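"""DOPU-guided refinement of the RPE segmentation line.

An intensity-based layer segmentation can jump to other hyper-reflective
structures.  Because the RPE is the depolarizing layer, its pixel in the
DOPU image is expected to have a low (< 0.6) DOPU value; the line is
therefore corrected per A-scan: find batches of consecutive low-DOPU
pixels, select the batch closest to the initial line, and move the line
to the position of the batch's minimum DOPU (the presumed RPE center,
since the smoothing kernel lifts DOPU toward the band edges).

Tie-breaks are deterministic: between two equidistant batches the
shallower one wins, and within a batch the smallest index attains the
minimum.  A-scans without any sub-threshold batch are flagged invalid
(the initial index is retained as a fallback value for diagnostics);
optionally they can instead stay valid at the initial index.
"""

from __future__ import annotations

import numpy as np

from .containers import DOPUVolume, RPELine

__all__ = ["find_batches", "refine_line", "DOPU_THRESHOLD"]

#: DOPU below this marks a pixel as belonging to depolarizing tissue
DOPU_THRESHOLD = 0.6


def find_batches(dopu_ascan: np.ndarray, threshold: float = DOPU_THRESHOLD) -> list[tuple[int, int]]:
    """Maximal runs of consecutive pixels with valid DOPU strictly below
    ``threshold`` in one A-scan profile.

    Invalid (NaN) pixels break runs.  Returns ``(start, stop)`` pairs with
    ``stop`` exclusive, in increasing depth order.
    """
    profile = np.asarray(dopu_ascan, dtype=float)
    low = np.isfinite(profile) & (profile < threshold)
    padded = np.concatenate([[False], low, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    stops = np.flatnonzero(~padded[1:] & padded[:-1])
    return list(zip(starts.tolist(), stops.tolist()))


def refine_line(initial: RPELine,
                dopu: DOPUVolume,
                threshold: float = DOPU_THRESHOLD,
                keep_unmatched: bool = False) -> RPELine:
    """Correct an RPE line using the DOPU volume, A-scan by A-scan.

    For each A-scan the sub-threshold batch closest to the initial index
    is selected (distance zero if the index lies inside a batch, otherwise
    the gap to the nearest batch end) and the corrected index is the
    argmin of DOPU within it.  A-scans without any batch keep the initial
    index and are flagged invalid unless ``keep_unmatched`` is True.

    The operation is idempotent: a refined line refines to itself.
    """
    nb, na, nz = dopu.shape
    if initial.depth.shape != (nb, na):
        raise ValueError("line shape does not match the DOPU volume")

    prof = dopu.dopu.reshape(nb * na, nz).astype(float)
    init = initial.depth.reshape(nb * na).astype(np.int64)
    low = np.isfinite(prof) & (prof < threshold)

    # pad a False column on both sides of every A-scan so runs never cross rows
    width = nz + 2
    padded = np.zeros((nb * na, width), dtype=bool)
    padded[:, 1:-1] = low
    flat = padded.reshape(-1)
    run_starts = np.flatnonzero(flat[1:] & ~flat[:-1]) + 1
    run_stops = np.flatnonzero(~flat[1:] & flat[:-1]) + 1  # exclusive

    depth_out = init.copy()
    valid_out = np.zeros(nb * na, dtype=bool)

    if run_starts.size:
        row = run_starts // width
        z_start = run_starts % width - 1
        z_last = (run_stops - 1) % width - 1  # inclusive last index

        # per-run minimum DOPU and its first (shallowest) position;
        # reduceat segments extend to the next run start, but values in the
        # inter-run gap are >= threshold or +inf, so they never win
        dflat = np.full((nb * na, width), np.inf)
        dflat[:, 1:-1] = np.where(low, prof, np.inf)
        dflat = dflat.reshape(-1)
        run_min = np.minimum.reduceat(dflat, run_starts)
        seg_len = np.diff(np.append(run_starts, dflat.size))
        tail = dflat[run_starts[0]:]
        pos_tail = np.arange(run_starts[0], dflat.size)
        pos_if_min = np.where(tail == np.repeat(run_min, seg_len), pos_tail, dflat.size)
        argmin_flat = np.minimum.reduceat(pos_if_min, run_starts - run_starts[0])
        z_min = argmin_flat % width - 1

        init_r = init[row]
        dist = np.where(init_r < z_start, z_start - init_r,
                        np.where(init_r > z_last, init_r - z_last, 0))
        # lexicographic (distance, shallow start) as a single integer key
        key = dist * width + z_start
        order = np.lexsort((key, row))
        rows_sorted = row[order]
        first = np.unique(rows_sorted, return_index=True)[1]
        chosen = order[first]

        depth_out[row[chosen]] = z_min[chosen]
        valid_out[row[chosen]] = True

    if keep_unmatched:
        valid_out[:] = True
    return RPELine(depth_out.reshape(nb, na), valid_out.reshape(nb, na))
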
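"""Punctum detection, quantal-event detection, and event-to-AZ assignment.

``find_spots`` locates fluorescent peaks in structural images (the AZ/PSD
map); ``detect_events`` finds flash events in a baseline-subtracted stack by
per-pixel noise-scaled thresholding and connected components, merging flashes
that persist across consecutive frames; ``assign_events`` maps each event to
the nearest AZ centroid within a distance cap -- the nearest-centroid
formulation of fixed-size ROI capture, with well-defined behaviour when ROIs
would overlap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from azquant.containers import MovieStack, make_az_table


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def _refine_centroid(image: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Intensity-weighted subpixel centre in the 3x3 neighbourhood of a peak."""
    r0, r1 = max(r - 1, 0), min(r + 2, image.shape[0])
    c0, c1 = max(c - 1, 0), min(c + 2, image.shape[1])
    patch = image[r0:r1, c0:c1].astype(np.float64)
    patch = patch - patch.min()
    tot = patch.sum()
    if tot <= 0:
        return float(r), float(c)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return float((patch * rr).sum() / tot), float((patch * cc).sum() / tot)


def find_spots(
    image: np.ndarray,
    pixel_size_um: float,
    min_separation_um: float = 0.45,
    threshold: "str | float" = "auto",
    threshold_mult: float = 4.0,
) -> pd.DataFrame:
    """Detect fluorescent peaks ('find spot') with Euclidean suppression.

    Local maxima above threshold are kept brightest-first; any candidate
    closer than ``min_separation_um`` to an already-kept spot is suppressed.
    ``"auto"`` threshold is background median + ``threshold_mult`` robust SDs.
    Centroids are refined to subpixel by 3x3 intensity weighting.

    Returns an AZ table (``az_id, x_um, y_um, peak_f``).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("find_spots expects a 2-D image")
    if min_separation_um <= 0:
        raise ValueError("min_separation_um must be positive")
    if threshold == "auto":
        thr = float(np.median(img)) + threshold_mult * _robust_sd(img)
    else:
        thr = float(threshold)
    if (img > thr).mean() > 0.10:
        warnings.warn("more than 10% of pixels exceed the spot threshold; "
                      "image may be saturated or low-contrast")

    # local maxima (8-connected plateau-tolerant)
    mx = ndimage.maximum_filter(img, size=3, mode="reflect")
    cand = np.nonzero((img >= mx) & (img > thr))
    if cand[0].size == 0:
        return make_az_table([], [], peak_f=np.array([]))
    heights = img[cand]
    order = np.argsort(-heights, kind="stable")
    rr = cand[0][order].astype(float)
    cc = cand[1][order].astype(float)
    min_sep_px = min_separation_um / pixel_size_um

    kept: list[int] = []
    tree_pts: list[tuple[float, float]] = []
    for i in range(rr.size):
        p = (rr[i], cc[i])
        ok = True
        for q in tree_pts:  # counts are small; keep this simple and exact
            if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < min_sep_px**2:
                ok = False
                break
        if ok:
            kept.append(i)
            tree_pts.append(p)

    xs, ys, pk = [], [], []
    for i in kept:
        r_ref, c_ref = _refine_centroid(img, int(rr[i]), int(cc[i]))
        ys.append(r_ref * pixel_size_um)
        xs.append(c_ref * pixel_size_um)
        pk.append(img[int(rr[i]), int(cc[i])])
    tab = make_az_table(xs, ys, peak_f=np.asarray(pk))
    tab.attrs["threshold"] = thr
    return tab


def estimate_noise_sd(
    stack: MovieStack, max_frames: int = 300, subtract_frame_median: bool = True
) -> np.ndarray:
    """Per-pixel noise SD from the temporal median absolute deviation.

    Robust to sparse flashes; frames are strided down to at most
    ``max_frames`` to bound the sort cost on long recordings.  By default
    each frame's spatial median is removed first, so slow global background
    trends (residual photobleaching after composite subtraction) do not
    masquerade as per-pixel noise -- the same detrending the detector applies
    before thresholding.
    """
    data = stack.data
    step = max(1, data.shape[0] // max_frames)
    sub = data[::step].astype(np.float32)
    if subtract_frame_median:
        sub = sub - np.median(sub, axis=(1, 2), keepdims=True)
    med = np.median(sub, axis=0)
    sd = 1.4826 * np.median(np.abs(sub - med[None]), axis=0)
    return sd


def detect_events(
    stack: MovieStack,
    threshold_sd: float = 4.0,
    min_area_px: int = 8,
    merge_dist_um: float = 0.5,
    subtract_frame_median: bool = True,
    noise_sd: np.ndarray | None = None,
    peak_margin_sd: float = 3.0,
) -> pd.DataFrame:
    """Detect quantal flashes in a baseline-subtracted stack.

    Per frame, pixels above ``threshold_sd`` x per-pixel noise SD are grouped
    into 8-connected components; components of at least ``min_area_px``
    pixels whose peak additionally clears ``(threshold_sd + peak_margin_sd)``
    noise SDs become events with intensity-weighted centroids and peak dF.
    (Genuine single-vesicle flashes peak far above threshold after fine
    filtering; the peak margin rejects correlated-noise clusters that barely
    clear the area criterion without costing sensitivity.)
    A component within ``merge_dist_um`` of an event detected on the previous
    frame is treated as the same flash decaying and merged into it (reported
    once, at its onset frame); a gap of one frame starts a new event.  When
    ``subtract_frame_median`` is set, each frame's spatial median is removed
    before thresholding, absorbing residual global background (e.g. the slow
    photobleaching left over after composite subtraction).
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    data = stack.data
    px = stack.pixel_size_um
    if noise_sd is None:
        noise_sd = estimate_noise_sd(stack, subtract_frame_median=subtract_frame_median)
    sd_floor = float(np.median(noise_sd))
    if sd_floor <= 0:
        warnings.warn("estimated noise SD is 0 (noise-free input); "
                      "substituting an absolute threshold")
        pos = data[data > 0]
        abs_thr = 0.1 * float(pos.max()) if pos.size else np.inf
        thr_map = np.full(data.shape[1:], abs_thr, dtype=np.float32)
    else:
        thr_map = (threshold_sd * np.maximum(noise_sd, 0.25 * sd_floor)).astype(np.float32)

    merge_px2 = (merge_dist_um / px) ** 2
    eight = np.ones((3, 3), dtype=int)
    open_events: list[dict] = []   # events alive on the previous frame
    done: list[dict] = []
    for f in range(stack.n_frames):
        frame = data[f]
        if subtract_frame_median:
            # global background level; a coarse grid is plenty for a median
            med = float(np.median(frame[::4, ::4])) if frame.size > 65536 \
                else float(np.median(frame))
        else:
            med = 0.0
        mask = frame > thr_map + med
        cur: list[dict] = []
        if mask.any():
            lab, n = ndimage.label(mask, structure=eight)
            if n:
                # component stats on bounding boxes only (events are sparse)
                peak_factor = 1.0 + peak_margin_sd / threshold_sd
                for comp, sl in enumerate(ndimage.find_objects(lab), start=1):
                    sub = lab[sl] == comp
                    area = int(sub.sum())
                    if area < min_area_px:
                        continue
                    vals = np.where(sub, frame[sl] - med, 0.0)
                    pk_idx = np.unravel_index(vals.argmax(), vals.shape)
                    if vals[pk_idx] < peak_factor * thr_map[sl][pk_idx]:
                        continue
                    tot = float(vals.sum())
                    rr, cc = np.nonzero(sub)
                    w = vals[rr, cc]
                    r = sl[0].start + float((w * rr).sum() / tot)
                    c = sl[1].start + float((w * cc).sum() / tot)
                    cur.append({"onset": f, "r": r, "c": c,
                                "peak": float(vals.max())})
        # merge with open events from the previous frame
        merged: list[dict] = []
        for ev in cur:
            hit = None
            for op in open_events:
                if (ev["r"] - op["r"]) ** 2 + (ev["c"] - op["c"]) ** 2 <= merge_px2:
                    hit = op
                    break
            if hit is not None:
                hit["peak"] = max(hit["peak"], ev["peak"])
                open_events.remove(hit)
                merged.append(hit)
            else:
                merged.append(ev)
        done.extend(open_events)  # not continued on this frame
        open_events = merged
    done.extend(open_events)

    done.sort(key=lambda e: (e["onset"], e["r"], e["c"]))
    ev = pd.DataFrame({
        "event_id": np.arange(len(done)),
        "frame": [e["onset"] for e in done],
        "time_s": [e["onset"] * stack.frame_interval_s for e in done],
        "x_um": [e["c"] * px for e in done],
        "y_um": [e["r"] * px for e in done],
        "peak_dF": [e["peak"] for e in done],
    })
    ev["kind"] = pd.Series([None] * len(ev), dtype=object)
    ev["az_id"] = pd.Series([pd.NA] * len(ev), dtype="Int64")
    return ev


def assign_events(
    events: pd.DataFrame,
    az: pd.DataFrame,
    max_dist_um: float = 0.5,
) -> pd.DataFrame:
    """Assign each event to the nearest AZ centroid within ``max_dist_um``.

    Ties (equal distance within 1e-9 um) break to the lower ``az_id``.
    Events with no AZ in range stay unassigned with a recorded reason.  The
    mapping depends only on geometry: event order is irrelevant.
    """
    if len(az) == 0:
        raise ValueError("AZ table is empty")
    if max_dist_um <= 0:
        raise ValueError("max_dist_um must be positive")
    out = events.copy()
    if len(events) == 0:
        out["az_id"] = pd.Series(dtype="Int64")
        out["assign_reason"] = pd.Series(dtype=object)
        return out
    # order AZs by id so that among exact ties the lower id wins
    az_sorted = az.sort_values("az_id", kind="stable")
    pts = az_sorted[["x_um", "y_um"]].to_numpy()
    ids = az_sorted["az_id"].to_numpy()
    tree = cKDTree(pts)
    q = events[["x_um", "y_um"]].to_numpy()
    k = min(2, len(az_sorted))
    dist, idx = tree.query(q, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    best = idx[:, 0].copy()
    if k == 2:
        tie = np.abs(dist[:, 0] - dist[:, 1]) < 1e-9
        if tie.any():
            lower = np.minimum(ids[idx[tie, 0]], ids[idx[tie, 1]])
            # map back to positions in az_sorted (ids are sorted ascending)
            best[tie] = np.searchsorted(ids, lower)
    assigned = ids[best]
    in_range = dist[:, 0] <= max_dist_um
    out["az_id"] = pd.array(np.where(in_range, assigned, -1), dtype="Int64")
    out.loc[~in_range, "az_id"] = pd.NA
    out["assign_reason"] = np.where(in_range, "nearest", "no AZ in range")
    return out


def unresolvable_fraction(az: pd.DataFrame, limit_um: float = 0.28) -> float:
    """Fraction of AZs with at least one neighbour within ``limit_um``."""
    if limit_um <= 0:
        raise ValueError("limit_um must be positive")
    n = len(az)
    if n < 2:
        return 0.0
    pts = az[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(pts)
    pairs = tree.query_pairs(limit_um, output_type="ndarray")
    if pairs.size == 0:
        return 0.0
    has_close = np.zeros(n, dtype=bool)
    has_close[pairs.ravel()] = True
    return float(has_close.mean())
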
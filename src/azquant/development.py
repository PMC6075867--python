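"""Longitudinal tracking: session matching, birth-dating, maturation, growth.

AZ identity across imaging sessions is recovered geometrically: a consensus
global translation between sessions is estimated from mutual-nearest-
neighbour pairs, then AZs are matched by mutual nearest neighbour within a
distance cap.  Chained correspondences give persistent identities, birth
dates (first appearance; left-censored for AZs already present in session 1),
and the time from PSD emergence to the first ring-positive session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from azquant.containers import SessionSeries


def _mutual_nn(pts_a: np.ndarray, pts_b: np.ndarray, max_dist: float):
    """Indices (ia, ib) of mutual nearest neighbours within ``max_dist``."""
    if len(pts_a) == 0 or len(pts_b) == 0:
        return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    ta, tb = cKDTree(pts_a), cKDTree(pts_b)
    d_ab, j_ab = tb.query(pts_a)            # nearest B for each A
    d_ba, j_ba = ta.query(pts_b)            # nearest A for each B
    ia = np.arange(len(pts_a))
    mutual = (j_ba[j_ab] == ia) & (d_ab <= max_dist)
    return ia[mutual], j_ab[mutual]


def match_sessions(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    max_match_um: float = 1.0,
    coarse_radius_um: float = 5.0,
) -> pd.DataFrame:
    """Match AZs between two sessions of the same field.

    A consensus translation registers session B onto A: the mode of all
    A-to-B displacement vectors within ``coarse_radius_um`` (AZ layouts are
    dense relative to inter-session drift, so nearest-neighbour pairing
    alone mismatches; the true offset shows up as the dominant cluster of
    displacements), refined by the median of the clustered displacements.
    Matching then uses mutual nearest neighbours within ``max_match_um``.
    Unmatched B entries are "new" (births), unmatched A entries are "lost"
    (flagged for QC).

    Returns a correspondence frame with columns ``az_id_a, az_id_b`` plus
    attrs ``shift_um`` (recovered translation), ``new_ids``, ``lost_ids``.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both AZ tables must be nonempty")
    pa = table_a[["x_um", "y_um"]].to_numpy(dtype=float)
    pb = table_b[["x_um", "y_um"]].to_numpy(dtype=float)
    tb = cKDTree(pb)
    neigh = tb.query_ball_point(pa, coarse_radius_um)
    disp = np.concatenate([
        pb[js] - pa[i] for i, js in enumerate(neigh) if js
    ]) if any(neigh) else np.zeros((0, 2))
    if disp.shape[0] < 3:
        raise ValueError("ambiguous registration: fewer than 3 coarse displacement pairs")
    bins = np.arange(-coarse_radius_um, coarse_radius_um + 0.1, 0.1)
    hist, xe, ye = np.histogram2d(disp[:, 0], disp[:, 1], bins=(bins, bins))
    iy, ix = np.unravel_index(np.argmax(hist), hist.shape)
    mode = np.array([(xe[iy] + xe[iy + 1]) / 2, (ye[ix] + ye[ix + 1]) / 2])
    near = disp[np.hypot(*(disp - mode).T) < 0.3]
    if near.shape[0] < 3:
        raise ValueError("ambiguous registration: no consensus displacement cluster")
    shift = np.median(near, axis=0)

    ia, ib = _mutual_nn(pa, pb - shift[None], max_match_um)
    ids_a = table_a["az_id"].to_numpy()
    ids_b = table_b["az_id"].to_numpy()
    corr = pd.DataFrame({"az_id_a": ids_a[ia], "az_id_b": ids_b[ib]})
    corr.attrs["shift_um"] = (float(shift[0]), float(shift[1]))
    corr.attrs["new_ids"] = np.setdiff1d(ids_b, ids_b[ib]).tolist()
    corr.attrs["lost_ids"] = np.setdiff1d(ids_a, ids_a[ia]).tolist()
    return corr


def birthdate(
    series: SessionSeries,
    max_match_um: float = 1.0,
    bridge_gaps: bool = False,
) -> pd.DataFrame:
    """Chain pairwise correspondences into persistent identities.

    Returns a track table with one row per (track, session) observation:
    ``track_id, session, timestamp_days, az_id, birth_day, censored, age_days``.
    ``birth_day`` is the timestamp of first appearance; tracks already
    present in session 0 are left-censored.  An AZ that disappears and is
    not re-matched ends its track ("lost" -- broken chains are reported via
    track termination, never silently bridged unless ``bridge_gaps``).
    """
    n_sessions = len(series)
    corrs = [
        match_sessions(series.tables[i], series.tables[i + 1], max_match_um)
        for i in range(n_sessions - 1)
    ]
    # track bookkeeping: active maps az_id in current session -> track_id
    next_track = 0
    rows = []
    active: dict[int, int] = {}
    pending_gap: dict[int, tuple[int, int]] = {}  # az_id in session i-1 -> (track, gap count)
    for s in range(n_sessions):
        t = series.timestamps_days[s]
        tab = series.tables[s]
        if s == 0:
            for az in tab["az_id"]:
                active[int(az)] = next_track
                rows.append((next_track, s, t, int(az), t, True))
                next_track += 1
            continue
        corr = corrs[s - 1]
        fwd = dict(zip(corr["az_id_a"].astype(int), corr["az_id_b"].astype(int)))
        new_active: dict[int, int] = {}
        for az_a, track in active.items():
            if az_a in fwd:
                new_active[fwd[az_a]] = track
            elif bridge_gaps and az_a not in pending_gap:
                pending_gap[az_a] = (track, s)
        # optional single-gap bridging: az missing in s-1 but matched s-2 -> s
        if bridge_gaps and pending_gap and s >= 2:
            try:
                skip = match_sessions(series.tables[s - 2], tab, max_match_um)
                skip_map = dict(zip(skip["az_id_a"].astype(int), skip["az_id_b"].astype(int)))
            except ValueError:
                skip_map = {}
            for az_old, (track, gap_s) in list(pending_gap.items()):
                if gap_s == s - 0 or s - gap_s > 1:
                    continue
                if az_old in skip_map and skip_map[az_old] not in new_active:
                    new_active[skip_map[az_old]] = track
                    del pending_gap[az_old]
        seen_tracks = {tr: az for az, tr in new_active.items()}
        # births: B-side AZs with no track
        for az in tab["az_id"].astype(int):
            if az not in new_active:
                new_active[az] = next_track
                next_track += 1
        # record one row per present track
        for az, tr in new_active.items():
            rows.append((tr, s, t, az, None, None))
        active = new_active

    df = pd.DataFrame(rows, columns=["track_id", "session", "timestamp_days",
                                     "az_id", "birth_day", "censored"])
    first = df.groupby("track_id").agg(
        first_t=("timestamp_days", "min"), first_s=("session", "min")
    )
    df["birth_day"] = df["track_id"].map(first["first_t"])
    df["censored"] = df["track_id"].map(first["first_s"] == 0)
    df["age_days"] = df["timestamp_days"] - df["birth_day"]
    return df


def maturation_time(
    tracks: pd.DataFrame,
    ring_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Days from PSD emergence to the first ring-positive session.

    ``tracks`` is the :func:`birthdate` output; ``ring_calls`` has columns
    ``session, az_id, has_ring``.  Only uncensored tracks (born during the
    series) are reported; the measurement is interval-censored at the session
    spacing and assigned the first positive session's timestamp.  Tracks
    ringed already at their birth session are flagged (inconsistent with the
    structural >= 2-day floor).

    Returns ``track_id, birth_day, ring_day, days_to_ring, ringed_at_birth``.
    """
    merged = tracks.merge(ring_calls, on=["session", "az_id"], how="left")
    merged["has_ring"] = merged["has_ring"].eq(True)  # missing calls count as no ring
    out = []
    for tr, sub in merged.groupby("track_id"):
        if bool(sub["censored"].iloc[0]):
            continue
        ringed = sub[sub["has_ring"].astype(bool)]
        if len(ringed) == 0:
            continue
        birth = float(sub["birth_day"].iloc[0])
        ring_day = float(ringed["timestamp_days"].min())
        out.append({
            "track_id": tr,
            "birth_day": birth,
            "ring_day": ring_day,
            "days_to_ring": ring_day - birth,
            "ringed_at_birth": bool(ring_day <= birth),
        })
    return pd.DataFrame(out)


def growth_fold(series: SessionSeries, interval_days: float = 1.0) -> pd.DataFrame:
    """AZ-count fold change across each interval, plus the day-1 fraction.

    Returns one row per consecutive session pair whose spacing matches
    ``interval_days`` (within 1e-6), with the count ratio; attrs carry
    ``first_fraction_of_final`` (session-1 count / final count).
    """
    if len(series) < 2:
        raise ValueError("need >= 2 sessions")
    counts = [len(t) for t in series.tables]
    ts = series.timestamps_days
    rows = []
    for i in range(len(counts) - 1):
        dt = ts[i + 1] - ts[i]
        if abs(dt - interval_days) <= 1e-6:
            rows.append({
                "from_day": ts[i], "to_day": ts[i + 1],
                "n_from": counts[i], "n_to": counts[i + 1],
                "fold": counts[i + 1] / counts[i] if counts[i] else np.nan,
            })
    df = pd.DataFrame(rows)
    df.attrs["first_fraction_of_final"] = counts[0] / counts[-1] if counts[-1] else np.nan
    return df


def apposition_ratio(
    psd_table: pd.DataFrame,
    presyn_table: pd.DataFrame,
    max_match_um: float = 0.5,
) -> dict:
    """Ratio of postsynaptic to presynaptic puncta, with apposition flags.

    Matches PSDs to presynaptic puncta by mutual nearest neighbour within
    ``max_match_um`` (no global registration: same field of view).  Returns
    the count ratio and a per-PSD ``apposed`` flag for contingency analyses
    (e.g. ring formation vs presynaptic apposition).
    """
    pp = psd_table[["x_um", "y_um"]].to_numpy(dtype=float)
    qq = presyn_table[["x_um", "y_um"]].to_numpy(dtype=float)
    ip, iq = _mutual_nn(pp, qq, max_match_um)
    apposed = np.zeros(len(psd_table), dtype=bool)
    apposed[ip] = True
    return {
        "ratio": len(psd_table) / len(presyn_table) if len(presyn_table) else np.inf,
        "n_psd": int(len(psd_table)),
        "n_presyn": int(len(presyn_table)),
        "n_apposed": int(apposed.sum()),
        "apposed": pd.DataFrame({
            "az_id": psd_table["az_id"].to_numpy(),
            "apposed": apposed,
        }),
    }
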
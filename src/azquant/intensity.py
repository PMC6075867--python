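"""Per-AZ channel intensities, bright-AZ classification, dF, correlations.

Structural-channel fluorescence is quantified in a small odd-sized square ROI
centred on each AZ's nearest pixel (3x3 by default); functional dF is the
stimulus-epoch minus rest-epoch mean ROI intensity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from azquant.containers import MovieStack


def _roi_slices(row: int, col: int, half: int, shape) -> tuple[slice, slice]:
    return slice(row - half, row + half + 1), slice(col - half, col + half + 1)


def quantify_intensity(
    image: np.ndarray,
    az: pd.DataFrame,
    pixel_size_um: float,
    roi_px: int = 3,
    channel: str = "chan",
) -> pd.DataFrame:
    """Mean/sum fluorescence in an odd square ROI around each AZ.

    AZs within ``roi_px // 2`` of the border are flagged ``border=True`` and
    excluded from the normalization statistics.  ``norm_f`` is per-image
    min-max normalized mean intensity over the non-border AZs.
    """
    if roi_px < 1 or roi_px % 2 == 0:
        raise ValueError("roi_px must be odd and >= 1")
    if len(az) == 0:
        raise ValueError("AZ table is empty")
    img = np.asarray(image, dtype=np.float64)
    half = roi_px // 2
    rows = np.round(az["y_um"].to_numpy() / pixel_size_um).astype(int)
    cols = np.round(az["x_um"].to_numpy() / pixel_size_um).astype(int)
    border = (
        (rows < half) | (cols < half)
        | (rows >= img.shape[0] - half) | (cols >= img.shape[1] - half)
    )
    mean_f = np.full(len(az), np.nan)
    sum_f = np.full(len(az), np.nan)
    for i, (r, c, b) in enumerate(zip(rows, cols, border)):
        if b:
            continue
        rs, cs = _roi_slices(r, c, half, img.shape)
        patch = img[rs, cs]
        mean_f[i] = patch.mean()
        sum_f[i] = patch.sum()
    ok = ~border
    norm = np.full(len(az), np.nan)
    if ok.any():
        lo, hi = np.nanmin(mean_f[ok]), np.nanmax(mean_f[ok])
        norm[ok] = (mean_f[ok] - lo) / (hi - lo) if hi > lo else 0.0
    return pd.DataFrame({
        "az_id": az["az_id"].to_numpy(),
        "channel": channel,
        "mean_f": mean_f,
        "sum_f": sum_f,
        "norm_f": norm,
        "border": border,
    })


def bright_az_classify(table: pd.DataFrame, sd_mult: float = 2.0) -> pd.DataFrame:
    """Flag AZs brighter than mean + ``sd_mult`` x population SD.

    Adds a ``bright`` column; the bright fraction and the bright/rest mean
    fold-difference are stored in ``table.attrs``.
    """
    vals = table["mean_f"].to_numpy(dtype=float)
    ok = ~table["border"].to_numpy() if "border" in table else np.isfinite(vals)
    v = vals[ok & np.isfinite(vals)]
    if v.size < 3:
        raise ValueError("need >= 3 quantified AZs")
    thr = v.mean() + sd_mult * v.std(ddof=0)
    out = table.copy()
    out["bright"] = (vals > thr) & ok & np.isfinite(vals)
    bright = out["bright"].to_numpy()
    rest = ok & ~bright & np.isfinite(vals)
    out.attrs["bright_threshold"] = float(thr)
    out.attrs["bright_fraction"] = float(bright.sum() / ok.sum())
    out.attrs["bright_fold"] = (
        float(vals[bright].mean() / vals[rest].mean())
        if bright.any() and rest.any() and vals[rest].mean() > 0 else np.nan
    )
    return out


def delta_f(
    stack: MovieStack,
    stim_epoch: tuple[int, int],
    rest_epoch: tuple[int, int],
    az: pd.DataFrame,
    roi_px: int = 3,
) -> pd.DataFrame:
    """Stimulus-epoch minus rest-epoch mean ROI intensity per AZ.

    Epochs are half-open frame ranges ``(start, stop)`` and must be disjoint,
    each at least 3 frames.  Means over sustained epochs (rather than
    single-frame peaks) keep the estimate noise-robust.
    """
    s0, s1 = stim_epoch
    r0, r1 = rest_epoch
    if s1 - s0 < 3 or r1 - r0 < 3:
        raise ValueError("each epoch needs >= 3 frames")
    if max(s0, r0) < min(s1, r1):
        raise ValueError("epochs overlap")
    stim_img = stack.data[s0:s1].mean(axis=0)
    rest_img = stack.data[r0:r1].mean(axis=0)
    t_stim = quantify_intensity(stim_img, az, stack.pixel_size_um, roi_px)
    t_rest = quantify_intensity(rest_img, az, stack.pixel_size_um, roi_px)
    return pd.DataFrame({
        "az_id": az["az_id"].to_numpy(),
        "delta_f": t_stim["mean_f"].to_numpy() - t_rest["mean_f"].to_numpy(),
        "f_stim": t_stim["mean_f"].to_numpy(),
        "f_rest": t_rest["mean_f"].to_numpy(),
        "border": t_stim["border"].to_numpy(),
    })


def delta_f_stability(df_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-AZ coefficient of variation of dF across repeated epochs."""
    if len(df_tables) < 2:
        raise ValueError("need >= 2 dF tables")
    merged = df_tables[0][["az_id", "delta_f"]].rename(columns={"delta_f": "df_0"})
    for i, t in enumerate(df_tables[1:], start=1):
        merged = merged.merge(
            t[["az_id", "delta_f"]].rename(columns={"delta_f": f"df_{i}"}), on="az_id"
        )
    vals = merged.filter(like="df_").to_numpy()
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    merged["mean_df"] = mean
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["cov"] = np.where(mean != 0, sd / np.abs(mean), np.nan)
    return merged


def saturation_control(
    df_stim: pd.DataFrame,
    df_iono: pd.DataFrame,
    sensor_limit_ratio: float = 0.8,
) -> dict:
    """Compare stimulus-epoch dF with an ionophore (saturating) epoch.

    Reports the two means, robust dispersion (MAD/median), the mean ratio,
    and flags ``sensor_limited`` when the stimulus mean reaches
    ``sensor_limit_ratio`` of the ionophore mean (indicator saturation would
    then compress genuine between-AZ differences).
    """
    merged = df_stim[["az_id", "delta_f"]].merge(
        df_iono[["az_id", "delta_f"]], on="az_id", suffixes=("_stim", "_iono")
    )
    if len(merged) == 0:
        raise ValueError("no shared AZs")
    a = merged["delta_f_stim"].to_numpy(dtype=float)
    b = merged["delta_f_iono"].to_numpy(dtype=float)

    def robust_cv(v):
        med = np.median(v)
        return float(1.4826 * np.median(np.abs(v - med)) / abs(med)) if med != 0 else np.nan

    ratio = float(a.mean() / b.mean()) if b.mean() != 0 else np.inf
    return {
        "mean_stim": float(a.mean()),
        "mean_iono": float(b.mean()),
        "mean_ratio": ratio,
        "robust_cv_stim": robust_cv(a),
        "robust_cv_iono": robust_cv(b),
        "shift": float(b.mean() - a.mean()),
        "sensor_limited": bool(ratio >= sensor_limit_ratio),
        "n": int(len(merged)),
    }


def correlate(
    x: pd.DataFrame | pd.Series,
    y: pd.DataFrame | pd.Series,
    group: np.ndarray | None = None,
) -> dict:
    """Pearson correlation of two per-AZ measures, per recording and pooled.

    ``x`` and ``y`` are DataFrames with ``az_id`` plus one value column (or
    aligned Series).  ``group`` assigns each AZ to a recording; per-group r
    and R^2 (each group >= 10 AZs), their mean across groups (the headline
    statistic), pooled statistics, and per-group two-tailed p and Fisher-z
    95% CI are returned.
    """
    if isinstance(x, pd.DataFrame):
        val_x = x.columns[-1]
        merged = x[["az_id", val_x]].merge(y, on="az_id")
        val_y = [c for c in merged.columns if c not in ("az_id", val_x)][-1]
        xa = merged[val_x].to_numpy(dtype=float)
        ya = merged[val_y].to_numpy(dtype=float)
    else:
        xa = np.asarray(x, dtype=float)
        ya = np.asarray(y, dtype=float)
    if group is None:
        group = np.zeros(len(xa), dtype=int)
    group = np.asarray(group)

    per_group = []
    for g in pd.unique(group):
        m = group == g
        if m.sum() < 10:
            raise ValueError(f"group {g!r} has {int(m.sum())} AZs; need >= 10")
        gx, gy = xa[m], ya[m]
        if gx.std() == 0 or gy.std() == 0:
            raise ValueError(f"group {g!r} has zero variance")
        r, p = stats.pearsonr(gx, gy)
        z = np.arctanh(np.clip(r, -0.999999, 0.999999))
        se = 1.0 / np.sqrt(m.sum() - 3)
        ci = (float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se)))
        per_group.append({"group": g, "r": float(r), "r_squared": float(r**2),
                          "p_value": float(p), "n": int(m.sum()), "ci95": ci})
    r_pool, p_pool = stats.pearsonr(xa, ya)
    return {
        "per_group": per_group,
        "mean_r": float(np.mean([g["r"] for g in per_group])),
        "mean_r_squared": float(np.mean([g["r_squared"] for g in per_group])),
        "pooled_r": float(r_pool),
        "pooled_r_squared": float(r_pool**2),
        "pooled_p": float(p_pool),
        "n_total": int(len(xa)),
    }
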
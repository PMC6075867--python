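"""Per-AZ release probability estimation, classification, and stability.

Pr at an AZ is the number of evoked events divided by the number of delivered
stimuli.  Events are split into evoked and spontaneous by a fixed
post-stimulus window; AZs are classified high/low/spontaneous-only/silent
with the mean + 2 SD rule over all PSD-defined AZs (silent included).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def split_evoked_spontaneous(
    events: pd.DataFrame,
    stim_times_s,
    window_s: float = 0.3,
) -> pd.DataFrame:
    """Label events evoked/spontaneous by a post-stimulus window.

    Events with onset in ``(t_stim, t_stim + window_s]`` are evoked and tagged
    with that stimulus index; at most one evoked event per (AZ, stimulus) --
    later same-AZ events in the same window are relabelled spontaneous.
    ``window_s`` must not exceed the smallest inter-stimulus interval.
    """
    stim = np.sort(np.asarray(list(stim_times_s), dtype=float))
    out = events.copy()
    out["kind"] = "spontaneous"
    out["stimulus_index"] = np.nan
    if len(out) == 0 or stim.size == 0:
        return out
    if stim.size > 1 and window_s > np.diff(stim).min():
        raise ValueError("window_s exceeds the minimum inter-stimulus interval")
    if window_s <= 0:
        raise ValueError("window_s must be positive")

    t = out["time_s"].to_numpy()
    idx = np.searchsorted(stim, t, side="left") - 1  # last stimulus strictly before t
    valid = idx >= 0
    in_win = np.zeros(len(out), dtype=bool)
    dt = t[valid] - stim[idx[valid]]
    in_win[valid] = (dt > 0) & (dt <= window_s + 1e-9)
    out.loc[in_win, "kind"] = "evoked"
    out.loc[in_win, "stimulus_index"] = idx[in_win].astype(float)

    # one evoked event per (AZ, stimulus): keep the earliest, demote the rest
    if "az_id" in out:
        ev = out[in_win & out["az_id"].notna()]
        if len(ev):
            dup = ev.sort_values("time_s", kind="stable").duplicated(
                subset=["az_id", "stimulus_index"], keep="first"
            )
            demote = dup[dup].index
            out.loc[demote, "kind"] = "spontaneous"
            out.loc[demote, "stimulus_index"] = np.nan
    return out


def compute_pr(
    events: pd.DataFrame,
    az: pd.DataFrame,
    n_stimuli: int,
    duration_s: float,
) -> pd.DataFrame:
    """Per-AZ Pr and spontaneous rate from labelled, assigned events.

    ``pr_hat = n_evoked / n_stimuli``; ``spont_rate_hz = spont_count /
    duration_s``.  Every AZ in the table gets a row; AZs without events score
    zero.  Returns a PrMap with columns ``az_id, n_evoked, n_stimuli, pr_hat,
    spont_count, spont_rate_hz``.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1 (no stimuli delivered: Pr undefined)")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    assigned = events[events["az_id"].notna()] if len(events) else events
    ev_counts = (
        assigned[assigned["kind"] == "evoked"].groupby("az_id").size()
        if len(assigned) else pd.Series(dtype=int)
    )
    sp_counts = (
        assigned[assigned["kind"] == "spontaneous"].groupby("az_id").size()
        if len(assigned) else pd.Series(dtype=int)
    )
    ids = az["az_id"].to_numpy()
    n_ev = pd.Series(ev_counts, dtype=float).reindex(ids).fillna(0).to_numpy()
    n_sp = pd.Series(sp_counts, dtype=float).reindex(ids).fillna(0).to_numpy()
    return pd.DataFrame({
        "az_id": ids,
        "n_evoked": n_ev.astype(int),
        "n_stimuli": n_stimuli,
        "pr_hat": n_ev / n_stimuli,
        "spont_count": n_sp.astype(int),
        "spont_rate_hz": n_sp / duration_s,
    })


def classify_azs(prmap: pd.DataFrame, sd_mult: float = 2.0, ddof: int = 0) -> pd.DataFrame:
    """Mean + ``sd_mult`` * SD classification over all AZs (silent included).

    ``high``: pr_hat strictly above threshold; ``low``: remaining AZs with
    evoked release; ``spont_only``: no evoked but spontaneous events;
    ``silent``: no events at all.  Classes partition the table.  ``ddof=0``
    (population SD) is the default; ``ddof=1`` gives the sample-SD variant.
    """
    if sd_mult <= 0:
        raise ValueError("sd_mult must be positive")
    out = prmap.copy()
    pr = out["pr_hat"].to_numpy(dtype=float)
    sd = pr.std(ddof=ddof)
    thr = pr.mean() + sd_mult * sd
    cls = np.full(len(out), "low", dtype=object)
    cls[(pr > thr) & (sd > 0)] = "high"
    no_ev = out["n_evoked"].to_numpy() == 0
    cls[no_ev & (out["spont_count"].to_numpy() > 0)] = "spont_only"
    cls[no_ev & (out["spont_count"].to_numpy() == 0)] = "silent"
    out["class"] = cls
    out.attrs["class_threshold"] = float(thr)
    out.attrs["sd_mult"] = sd_mult
    return out


def class_fractions(prmap: pd.DataFrame) -> dict[str, float]:
    """Fraction of AZs per class (sums to 1)."""
    frac = prmap["class"].value_counts(normalize=True).to_dict()
    return {c: float(frac.get(c, 0.0)) for c in ("high", "low", "spont_only", "silent")}


def distribution_summary(prmap: pd.DataFrame, bins: int = 40) -> dict:
    """Shape of the Pr distribution: moments, skew, percentiles, histogram.

    Skewness is the adjusted Fisher-Pearson (bias-corrected) coefficient.
    Also returns the Pr vector normalized to its maximum and the empirical
    CDF, the two standard displays for cross-genotype shape comparison.
    """
    pr = prmap["pr_hat"].to_numpy(dtype=float)
    if pr.size < 3:
        raise ValueError("need >= 3 AZs for a distribution summary")
    hist, edges = np.histogram(pr, bins=bins)
    mx = pr.max()
    order = np.sort(pr)
    return {
        "n": int(pr.size),
        "mean": float(pr.mean()),
        "sd": float(pr.std(ddof=1)),
        "sem": float(pr.std(ddof=1) / np.sqrt(pr.size)),
        "skewness": float(stats.skew(pr, bias=False)),
        "percentiles": {p: float(np.percentile(pr, p)) for p in (5, 25, 50, 75, 95)},
        "max": float(mx),
        "hist_counts": hist,
        "hist_edges": edges,
        "normalized_to_max": pr / mx if mx > 0 else pr,
        "ecdf_x": order,
        "ecdf_y": np.arange(1, pr.size + 1) / pr.size,
    }


def attenuation_prediction(true_pr: np.ndarray, n_stimuli: int) -> float:
    """Expected Pearson r between two independent Pr estimates of one
    population: ``Var(p) / (Var(p) + E[p(1-p)] / S)`` (binomial attenuation).
    """
    p = np.asarray(true_pr, dtype=float)
    v = p.var()
    noise = (p * (1 - p)).mean() / n_stimuli
    return float(v / (v + noise)) if v + noise > 0 else 0.0


def session_stability(
    map1: pd.DataFrame,
    map2: pd.DataFrame,
    true_pr: np.ndarray | None = None,
    n_stimuli: int | None = None,
) -> dict:
    """Pearson correlation of per-AZ Pr across two sessions.

    Inner-joins on ``az_id`` (>= 10 shared AZs required).  When ground truth
    and the stimulus count are supplied (synthetic runs), also reports the
    analytic attenuation prediction for r.
    """
    merged = map1[["az_id", "pr_hat"]].merge(
        map2[["az_id", "pr_hat"]], on="az_id", suffixes=("_1", "_2")
    )
    if len(merged) < 10:
        raise ValueError(f"only {len(merged)} shared AZs; need >= 10")
    x = merged["pr_hat_1"].to_numpy()
    y = merged["pr_hat_2"].to_numpy()
    r, p = stats.pearsonr(x, y)
    out = {
        "pearson_r": float(r),
        "r_squared": float(r**2),
        "p_value": float(p),
        "n": int(len(merged)),
        "paired": merged,
    }
    if true_pr is not None and n_stimuli:
        out["r_predicted"] = attenuation_prediction(true_pr, n_stimuli)
    return out
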
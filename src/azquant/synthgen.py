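"""Synthetic ground-truth generator for single-AZ quantal imaging.

Emulates the statistical structure of larval NMJ quantal-imaging data: punctate
AZ layouts, a right-skewed heterogeneous release-probability (Pr) population
with silent and spontaneous-only classes, Bernoulli evoked / Poisson
spontaneous fusion, diffraction-limited flash kernels with exponential decay,
photobleaching, drift and noise, structural channels whose punctum intensity
correlates with Pr, two-channel PSD core+ring morphologies, and multi-day
developmental series with persistent AZ identities.

Default calibration
-------------------
The Pr population is a three-part mixture: silent AZs (14.6%), spontaneous-only
AZs (9.7%, Pr = 0), and active AZs (75.7%) whose Pr is drawn from a
two-component gamma mixture -- a dominant low-Pr mode plus a tight "mature"
high-Pr mode -- capped at ``pr_cap``.  The committed constants (see
``scripts/calibrate_pr_mixture.py``) place the overall population mean at
0.073 and are calibrated at the *measurement* level: when Pr is estimated as
binomial events/stimuli over a 0.3 Hz x 5 min train (~100 stimuli), the mean
+ 2 SD rule flags ~9.9% of AZs as high-Pr, the high/low class-mean ratio is
~6-fold, and the estimate distribution's skewness is ~2.  (Reference
summaries of release heterogeneity are themselves measured through that
protocol, so the calibration criterion applies the same estimator.)  A
single gamma for the active mode cannot satisfy these summaries jointly:
with its mean pinned, its mean+2SD exceedance never rises above ~6.6%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from azquant.containers import MovieStack, SessionSeries, make_az_table

# Committed Pr-mixture calibration (see scripts/calibrate_pr_mixture.py).
ACTIVE_PR_SHAPE = 1.8
ACTIVE_PR_MEAN = 0.0442227
MATURE_PR_SHAPE = 60.0
MATURE_PR_MEAN = 0.355
MATURE_FRAC = 0.168


def stim_train(n_stimuli: int, rate_hz: float, start_s: float = 1.5) -> tuple[float, ...]:
    """Regular stimulus train: ``n_stimuli`` onsets at ``rate_hz``."""
    if n_stimuli < 0 or rate_hz <= 0:
        raise ValueError("need n_stimuli >= 0 and rate_hz > 0")
    return tuple(start_s + k / rate_hz for k in range(n_stimuli))


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the study conditions.

    Geometry is set by the 0.138 um pixel and a ~7.7 Hz frame rate; the
    stimulus paradigm defaults to 0.3 Hz.  Flash and channel parameters are
    chosen so that single-vesicle flashes are comfortably above the noise
    floor after fine Gaussian filtering, as in the source recordings.
    """

    n_az: int = 300
    pixel_size_um: float = 0.138
    frame_interval_s: float = 0.13
    stim_times_s: tuple[float, ...] = field(default_factory=lambda: stim_train(54, 1 / 3.0))
    movie_duration_s: float = 300.0
    # Pr mixture
    silent_frac: float = 0.146
    spont_only_frac: float = 0.097
    active_pr_shape: float = ACTIVE_PR_SHAPE
    active_pr_scale: float = ACTIVE_PR_MEAN / ACTIVE_PR_SHAPE
    mature_pr_shape: float = MATURE_PR_SHAPE
    mature_pr_scale: float = MATURE_PR_MEAN / MATURE_PR_SHAPE
    mature_frac: float = MATURE_FRAC
    pr_cap: float = 0.73
    spont_rate_hz: float = 0.011
    # layout
    min_sep_um: float = 0.6
    close_pair_frac: float = 0.0
    field_margin_um: float = 2.0
    # movie rendering
    baseline: float = 100.0
    baseline_texture_sd: float = 12.0
    baseline_texture_sigma_um: float = 0.7
    flash_amplitude: float = 40.0
    flash_decay_s: float = 0.26
    psf_sigma_um: float = 0.2
    bleach_tau_s: float = 2000.0
    noise_sd: float = 4.0
    drift_px_per_frame: float = 0.0
    # structural channels
    intensity_pr_r: float = 0.61
    channel_mean: float = 60.0
    channel_sd: float = 20.0
    channel_floor: float = 15.0
    channel_noise_sd: float = 3.0
    channel_psf_sigma_um: float = 0.18
    seed: int = 0

    def __post_init__(self):
        for name in ("silent_frac", "spont_only_frac", "close_pair_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.silent_frac + self.spont_only_frac > 1.0:
            raise ValueError("silent_frac + spont_only_frac must be <= 1")
        if not 0.0 < self.pr_cap <= 1.0:
            raise ValueError("pr_cap must be in (0, 1]")
        if self.spont_rate_hz < 0 or self.movie_duration_s < 0:
            raise ValueError("rates and durations must be >= 0")
        if self.n_az < 1:
            raise ValueError("n_az must be >= 1")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(salt)))


# ---------------------------------------------------------------------------
# AZ layout
# ---------------------------------------------------------------------------

def generate_az_layout(
    n_az: int,
    field_size_um: tuple[float, float] | None = None,
    min_sep_um: float = 0.6,
    close_pair_frac: float = 0.0,
    seed: int | np.random.Generator = 0,
    margin_um: float = 2.0,
) -> pd.DataFrame:
    """Random AZ layout with a hard minimum separation.

    Points are dart-thrown with rejection below ``min_sep_um``.  A fraction
    ``close_pair_frac`` of AZs is then deliberately planted closer than
    0.28 um to a partner, mimicking AZ pairs that conventional light
    microscopy cannot resolve.  ``field_size_um`` defaults to a square sized
    for a packing density of 0.25 AZ * min_sep^2 per unit area, which dart
    throwing fills reliably.

    Returns an AZ table with columns ``az_id, x_um, y_um``.
    """
    if n_az < 1:
        raise ValueError("n_az must be >= 1")
    if min_sep_um <= 0:
        raise ValueError("min_sep_um must be positive")
    if not 0.0 <= close_pair_frac < 1.0:
        raise ValueError("close_pair_frac must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_pairs = int(round(close_pair_frac * n_az / 2.0))
    n_base = n_az - n_pairs
    if field_size_um is None:
        side = math.sqrt(max(n_base, 1) * min_sep_um**2 / 0.25)
        field_size_um = (side, side)
    fx, fy = field_size_um
    density = n_base * min_sep_um**2 / (fx * fy)
    if density > 0.55:
        raise ValueError(
            f"field too small: {n_base} points at min separation {min_sep_um} um in "
            f"{fx:.1f} x {fy:.1f} um gives packing density {density:.2f} (> 0.55)"
        )

    # dart throwing on a neighbour grid (cells of side min_sep)
    cell = min_sep_um
    nx, ny = max(1, int(fx / cell)), max(1, int(fy / cell))
    grid: dict[tuple[int, int], list[int]] = {}
    xs = np.empty(n_base)
    ys = np.empty(n_base)
    placed = 0
    max_attempts = 200 * n_base + 1000
    attempts = 0
    while placed < n_base:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_base} points at min separation {min_sep_um} um "
                f"in {fx:.1f} x {fy:.1f} um (density {density:.2f}); enlarge the field"
            )
        x = rng.uniform(0, fx)
        y = rng.uniform(0, fy)
        ci, cj = int(x / cell), int(y / cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    if (xs[k] - x) ** 2 + (ys[k] - y) ** 2 < min_sep_um**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        xs[placed], ys[placed] = x, y
        grid.setdefault((ci, cj), []).append(placed)
        placed += 1

    # plant close partners next to the first n_pairs hosts
    px, py = [], []
    for h in range(n_pairs):
        for _ in range(1000):
            r = rng.uniform(0.15, 0.27)
            th = rng.uniform(0, 2 * np.pi)
            x = xs[h] + r * math.cos(th)
            y = ys[h] + r * math.sin(th)
            if not (0 <= x <= fx and 0 <= y <= fy):
                continue
            d2 = (xs[:placed] - x) ** 2 + (ys[:placed] - y) ** 2
            d2[h] = np.inf  # the host is allowed close
            if d2.min() >= min_sep_um**2:
                px.append(x)
                py.append(y)
                break
        else:
            raise RuntimeError("could not plant a close pair; layout too dense")

    x_all = np.concatenate([xs, np.asarray(px)]) + margin_um
    y_all = np.concatenate([ys, np.asarray(py)]) + margin_um
    tab = make_az_table(x_all, y_all)
    tab.attrs["field_size_um"] = (fx + 2 * margin_um, fy + 2 * margin_um)
    tab.attrs["min_sep_um"] = min_sep_um
    return tab


# ---------------------------------------------------------------------------
# Pr population
# ---------------------------------------------------------------------------

def _draw_capped_gamma(rng, shape, scale, cap, size):
    """Gamma draws resampled above ``cap``; errors if > 5% mass is discarded."""
    from scipy import stats

    if stats.gamma.sf(cap, shape, scale=scale) > 0.05:
        raise ValueError(
            "truncation at pr_cap would discard > 5% of the gamma mass; "
            "calibration invalid for these shape/scale parameters"
        )
    out = rng.gamma(shape, scale, size=size)
    bad = out > cap
    while bad.any():
        out[bad] = rng.gamma(shape, scale, size=int(bad.sum()))
        bad = out > cap
    return out


def sample_pr_population(cfg: SynthConfig, layout: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assign ground-truth class and Pr to each AZ.

    Class counts are stratified (deterministically rounded) so the configured
    fractions hold exactly up to integer granularity; class labels are then
    shuffled over AZ ids.  Active-AZ Pr comes from the calibrated two-gamma
    mixture capped at ``pr_cap``.
    """
    rng = cfg.rng(salt=1)
    if layout is None:
        layout = generate_az_layout(
            cfg.n_az, min_sep_um=cfg.min_sep_um, close_pair_frac=cfg.close_pair_frac,
            seed=cfg.rng(salt=0), margin_um=cfg.field_margin_um,
        )
    tab = layout.copy()
    n = len(tab)
    n_silent = int(round(cfg.silent_frac * n))
    n_spont = int(round(cfg.spont_only_frac * n))
    n_active = n - n_silent - n_spont
    if n_active < 0:
        n_spont = n - n_silent
        n_active = 0

    classes = np.array(
        ["silent"] * n_silent + ["spont_only"] * n_spont + ["active"] * n_active,
        dtype=object,
    )
    rng.shuffle(classes)

    pr = np.zeros(n)
    if n_active:
        n_mature = int(round(cfg.mature_frac * n_active))
        draws = np.concatenate([
            _draw_capped_gamma(rng, cfg.active_pr_shape, cfg.active_pr_scale,
                               cfg.pr_cap, n_active - n_mature),
            _draw_capped_gamma(rng, cfg.mature_pr_shape, cfg.mature_pr_scale,
                               cfg.pr_cap, n_mature),
        ])
        rng.shuffle(draws)
        pr[classes == "active"] = draws

    tab["true_class"] = classes
    tab["true_pr"] = pr
    tab.attrs.update(layout.attrs)
    return tab


# ---------------------------------------------------------------------------
# Event times
# ---------------------------------------------------------------------------

def simulate_event_times(
    az: pd.DataFrame,
    stim_times_s,
    duration_s: float,
    spont_rate_hz: float,
    seed: int | np.random.Generator = 0,
    evoked_latency_s: float = 0.01,
    latency_jitter_s: float = 0.0,
) -> pd.DataFrame:
    """Ground-truth fusion events: Bernoulli evoked + Poisson spontaneous.

    Per stimulus, each active AZ releases with probability ``true_pr``
    (independently across AZs and stimuli; at most one vesicle per AZ per
    stimulus).  Non-silent AZs additionally emit homogeneous-Poisson
    spontaneous events at ``spont_rate_hz`` over the full duration.  Silent
    AZs emit nothing.

    Returns columns ``az_id, time_s, kind, stimulus_index``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stim = np.asarray(list(stim_times_s), dtype=float)
    if duration_s <= 0 and (stim.size or spont_rate_hz > 0):
        raise ValueError("duration_s must be positive")
    if stim.size and (stim.min() < 0 or stim.max() > duration_s):
        raise ValueError("stimulus times must lie within [0, duration]")
    if spont_rate_hz < 0:
        raise ValueError("spont_rate_hz must be >= 0")

    pr = az["true_pr"].to_numpy() if "true_pr" in az else np.zeros(len(az))
    cls = az["true_class"].to_numpy() if "true_class" in az else np.array(["active"] * len(az))
    ids = az["az_id"].to_numpy()

    rows_az, rows_t, rows_kind, rows_stim = [], [], [], []

    if stim.size:
        # (n_stim, n_az) Bernoulli field
        hits = rng.random((stim.size, len(az))) < pr[None, :]
        s_idx, a_idx = np.nonzero(hits)
        t = stim[s_idx] + evoked_latency_s
        if latency_jitter_s > 0:
            t = t + rng.uniform(0, latency_jitter_s, size=t.size)
        rows_az.append(ids[a_idx])
        rows_t.append(t)
        rows_kind.append(np.full(t.size, "evoked", dtype=object))
        rows_stim.append(s_idx.astype(float))

    if spont_rate_hz > 0:
        nonsilent = cls != "silent"
        counts = rng.poisson(spont_rate_hz * duration_s, size=int(nonsilent.sum()))
        total = int(counts.sum())
        if total:
            t = rng.uniform(0, duration_s, size=total)
            a = np.repeat(ids[nonsilent], counts)
            rows_az.append(a)
            rows_t.append(t)
            rows_kind.append(np.full(total, "spontaneous", dtype=object))
            rows_stim.append(np.full(total, np.nan))

    if not rows_az:
        return pd.DataFrame({"az_id": pd.Series(dtype=int),
                             "time_s": pd.Series(dtype=float),
                             "kind": pd.Series(dtype=object),
                             "stimulus_index": pd.Series(dtype=float)})
    ev = pd.DataFrame({
        "az_id": np.concatenate(rows_az),
        "time_s": np.concatenate(rows_t),
        "kind": np.concatenate(rows_kind),
        "stimulus_index": np.concatenate(rows_stim),
    })
    ev = ev.sort_values("time_s", kind="stable").reset_index(drop=True)
    return ev


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def _field_shape(az: pd.DataFrame, cfg: SynthConfig) -> tuple[int, int]:
    fs = az.attrs.get("field_size_um")
    if fs is not None:
        fx, fy = fs
    else:
        fx = az["x_um"].max() + cfg.field_margin_um
        fy = az["y_um"].max() + cfg.field_margin_um
    return int(math.ceil(fy / cfg.pixel_size_um)) + 1, int(math.ceil(fx / cfg.pixel_size_um)) + 1


def _add_gaussian(frame: np.ndarray, row: float, col: float, amp: float, sigma_px: float) -> None:
    """Add ``amp * exp(-r^2 / 2 sigma^2)`` centred at (row, col), in place."""
    half = int(math.ceil(4 * sigma_px))
    r0, r1 = int(math.floor(row)) - half, int(math.floor(row)) + half + 1
    c0, c1 = int(math.floor(col)) - half, int(math.floor(col)) + half + 1
    r0c, r1c = max(r0, 0), min(r1, frame.shape[0])
    c0c, c1c = max(c0, 0), min(c1, frame.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c, dtype=np.float32) - row
    cc = np.arange(c0c, c1c, dtype=np.float32) - col
    g = np.exp(-(rr[:, None] ** 2 + cc[None, :] ** 2) / (2 * sigma_px**2))
    frame[r0c:r1c, c0c:c1c] += (amp * g).astype(frame.dtype, copy=False)


def render_movie(az: pd.DataFrame, events: pd.DataFrame, cfg: SynthConfig) -> MovieStack:
    """Render ground-truth events into a noisy, bleaching, drifting stack.

    Each event contributes an isotropic Gaussian kernel (sd ``psf_sigma_um``)
    with a single-frame rise at the first frame at or after its onset time and
    exponential decay ``flash_decay_s`` thereafter; the kernel peak at onset
    equals ``flash_amplitude``.  The baseline is the configured mean plus a
    static membrane-like texture (smoothed Gaussian field of sd
    ``baseline_texture_sd``), emulating the structured resting fluorescence of
    a membrane-targeted indicator -- which is also what makes translational
    registration well-posed.  The baseline bleaches with time constant
    ``bleach_tau_s``; the whole field (texture and flashes) drifts as a
    Gaussian random walk of per-frame step ``drift_px_per_frame``; i.i.d.
    Gaussian noise of sd ``noise_sd`` is added everywhere.
    """
    if cfg.flash_decay_s < cfg.frame_interval_s:
        warnings.warn("flash_decay_s < frame_interval_s: events may span a single frame")
    rng = cfg.rng(salt=2)
    n_frames = int(round(cfg.movie_duration_s / cfg.frame_interval_s))
    shape = _field_shape(az, cfg)
    px = cfg.pixel_size_um
    sigma_px = cfg.psf_sigma_um / px

    data = np.empty((n_frames, *shape), dtype=np.float32)
    t = np.arange(n_frames, dtype=np.float64) * cfg.frame_interval_s
    if np.isfinite(cfg.bleach_tau_s) and cfg.bleach_tau_s > 0:
        bleach = np.exp(-t / cfg.bleach_tau_s).astype(np.float32)
    else:
        bleach = np.ones(n_frames, dtype=np.float32)

    # static membrane-like texture (same structure every frame, bleaching
    # with the baseline and carried along by the drift path)
    if cfg.baseline_texture_sd > 0:
        raw = rng.normal(0, 1.0, size=shape)
        sig = cfg.baseline_texture_sigma_um / px
        tex = ndimage.gaussian_filter(raw, sig, mode="reflect")
        tex *= cfg.baseline_texture_sd / tex.std()
        texture = tex.astype(np.float32)
    else:
        texture = None

    # drift path (cumulative random walk), in pixels, (dy, dx) per frame
    if cfg.drift_px_per_frame > 0:
        steps = rng.normal(0, cfg.drift_px_per_frame, size=(n_frames, 2))
        steps[0] = 0
        drift = np.cumsum(steps, axis=0)
    else:
        drift = np.zeros((n_frames, 2))

    base_frame = np.full(shape, float(cfg.baseline), dtype=np.float32)
    for f in range(n_frames):
        if texture is None:
            data[f] = cfg.baseline * bleach[f]
        elif drift[f, 0] == 0 and drift[f, 1] == 0:
            np.multiply(base_frame + texture, bleach[f], out=data[f])
        else:
            shifted = ndimage.shift(texture, drift[f], order=1, mode="reflect")
            np.multiply(base_frame + shifted, bleach[f], out=data[f])

    pos = az.set_index("az_id")[["x_um", "y_um"]]
    ev_xy = pos.reindex(events["az_id"].to_numpy()).to_numpy()
    n_decay = max(1, int(math.ceil(cfg.flash_decay_s / cfg.frame_interval_s * 4.6)))  # to 1%
    for (x, y), t0 in zip(ev_xy, events["time_s"].to_numpy()):
        f0 = int(math.ceil(t0 / cfg.frame_interval_s - 1e-9))
        for k in range(n_decay + 1):
            f = f0 + k
            if f < 0 or f >= n_frames:
                continue
            amp = cfg.flash_amplitude * math.exp(-(t[f] - t0) / cfg.flash_decay_s)
            _add_gaussian(data[f], y / px + drift[f, 0], x / px + drift[f, 1], amp, sigma_px)

    if cfg.noise_sd > 0:
        # per-frame draws keep the transient footprint at one frame
        for f in range(n_frames):
            noise = rng.standard_normal(size=shape, dtype=np.float32)
            noise *= cfg.noise_sd
            data[f] += noise

    return MovieStack(
        data=data,
        frame_interval_s=cfg.frame_interval_s,
        pixel_size_um=px,
        stim_times_s=tuple(s for s in cfg.stim_times_s if s <= cfg.movie_duration_s),
        meta={"synthetic": True, "drift_px": drift, "baseline": cfg.baseline,
              "bleach_tau_s": cfg.bleach_tau_s},
    )


# ---------------------------------------------------------------------------
# Structural channels
# ---------------------------------------------------------------------------

def sample_channel_amplitudes(
    az: pd.DataFrame, cfg: SynthConfig, rng: np.random.Generator,
    intensity_pr_r: float | None = None,
) -> np.ndarray:
    """Per-AZ punctum amplitudes with target Pearson correlation to true Pr.

    ``amp = mean + sd * (r * z_pr + sqrt(1 - r^2) * eps)`` with ``z_pr`` the
    standardized Pr vector, which has population Pearson correlation exactly
    ``r`` with Pr.  Amplitudes are floored at ``channel_floor`` (a PSD below
    the detection floor would not define an AZ in the first place).
    """
    r = cfg.intensity_pr_r if intensity_pr_r is None else intensity_pr_r
    if abs(r) > 1.0:
        raise ValueError("|intensity_pr_r| must be <= 1")
    pr = az["true_pr"].to_numpy()
    sd = pr.std()
    z = (pr - pr.mean()) / sd if sd > 0 else np.zeros_like(pr)
    eps = rng.standard_normal(len(az))
    mix = r * z + math.sqrt(1 - r**2) * eps
    amp = cfg.channel_mean + cfg.channel_sd * mix
    return np.maximum(amp, cfg.channel_floor)


def render_channel_image(
    az: pd.DataFrame,
    channel: str,
    cfg: SynthConfig,
    seed: int | np.random.Generator | None = None,
    intensity_pr_r: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one structural channel (Cac/BRP/GluRIIA/GluRIIB analogue).

    One Gaussian punctum per AZ (sd ``channel_psf_sigma_um``) whose amplitude
    correlates with true Pr at ``intensity_pr_r``; additive Gaussian
    background noise of sd ``channel_noise_sd``.  Returns the image and a copy
    of the AZ table with the drawn amplitudes in column
    ``intensity_<channel>``.
    """
    if seed is None:
        rng = cfg.rng(salt=hash(channel) % (2**31))
    elif isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    amps = sample_channel_amplitudes(az, cfg, rng, intensity_pr_r)
    shape = _field_shape(az, cfg)
    img = np.zeros(shape, dtype=np.float32)
    px = cfg.pixel_size_um
    sig = cfg.channel_psf_sigma_um / px
    for (x, y), a in zip(az[["x_um", "y_um"]].to_numpy(), amps):
        _add_gaussian(img, y / px, x / px, a, sig)
    if cfg.channel_noise_sd > 0:
        img += rng.normal(0, cfg.channel_noise_sd, size=shape).astype(np.float32)
    out = az.copy()
    out[f"intensity_{channel}"] = amps
    out.attrs.update(az.attrs)
    return img, out


# ---------------------------------------------------------------------------
# PSD core + ring morphology
# ---------------------------------------------------------------------------

def psd_ring_geometry(ring_outer_diam_um: float, dip_frac: float) -> tuple[float, float]:
    """Solve the annulus radial-Gaussian (peak radius r0, sd sigma).

    Channel B's radial profile is ``exp(-(r - r0)^2 / 2 sigma^2)`` with the
    central value ``B(0) = 1 - dip_frac`` relative to the flank maximum and
    the outer half-maximum crossing at ``ring_outer_diam_um / 2``.
    """
    if not 0.0 <= dip_frac < 1.0:
        raise ValueError("dip_frac must be in [0, 1)")
    if dip_frac == 0.0:
        return 0.0, ring_outer_diam_um / 2.0 / math.sqrt(2 * math.log(2))
    a = math.sqrt(2 * math.log(1.0 / (1.0 - dip_frac)))  # r0 = a * sigma
    b = math.sqrt(2 * math.log(2.0))                     # outer crossing at r0 + b * sigma
    sigma = (ring_outer_diam_um / 2.0) / (a + b)
    return a * sigma, sigma


def render_psd_pair(
    core_diam_um: float,
    ring_outer_diam_um: float,
    dip_frac: float,
    pixel_size_um: float = 0.138,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    amplitude: float = 100.0,
    size_px: int | None = None,
) -> dict:
    """Render a two-channel PSD: filled core (A) + peripheral ring (B).

    Channel A is an isotropic Gaussian of FWHM ``core_diam_um``; channel B is
    an annulus whose radial profile dips at the centre by ``dip_frac`` of the
    flank maximum and whose outer FWHM is ``ring_outer_diam_um``.  Returns a
    dict with ``chan_a``, ``chan_b``, ``center_um`` and the ground truth.
    """
    if ring_outer_diam_um < core_diam_um:
        raise ValueError("ring_outer_diam_um must be >= core_diam_um")
    if min(core_diam_um, ring_outer_diam_um) < 2 * pixel_size_um:
        raise ValueError("unresolvable: diameter below 2 pixels at this pixel size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if size_px is None:
        # wide enough for the ring plus a standard 2.2-um profile window
        size_um = max(2.4 * ring_outer_diam_um, 2.6)
        size_px = int(math.ceil(size_um / pixel_size_um)) | 1
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    r_um = np.hypot(yy - c, xx - c) * pixel_size_um

    sig_a = core_diam_um / (2 * math.sqrt(2 * math.log(2)))
    chan_a = amplitude * np.exp(-(r_um**2) / (2 * sig_a**2))

    r0, sig_b = psd_ring_geometry(ring_outer_diam_um, dip_frac)
    chan_b = amplitude * np.exp(-((r_um - r0) ** 2) / (2 * sig_b**2))

    if noise_sd > 0:
        chan_a = chan_a + rng.normal(0, noise_sd, chan_a.shape)
        chan_b = chan_b + rng.normal(0, noise_sd, chan_b.shape)

    return {
        "chan_a": chan_a.astype(np.float32),
        "chan_b": chan_b.astype(np.float32),
        "center_um": (c * pixel_size_um, c * pixel_size_um),
        "pixel_size_um": pixel_size_um,
        "truth": {
            "core_diam_um": core_diam_um,
            "ring_outer_diam_um": ring_outer_diam_um,
            "dip_frac": dip_frac,
            "ring_radius_um": r0,
        },
    }


# ---------------------------------------------------------------------------
# Development
# ---------------------------------------------------------------------------

#: Structural floor below which a ring can never be expressed (days).
RING_MIN_AGE_DAYS = 2.0
#: Shape of the post-floor gamma delay to ring formation.  Concentrated
#: (sd ~0.3 d at the default 3.2-day mean): segregation onset clusters a
#: little over a day past the 2-day structural floor, with only a small
#: fast tail.
RING_DELAY_SHAPE = 16.0
#: Receptor-field geometry endpoints (um), matching mature 72-h fields.
DIAM_A_NEWBORN, DIAM_A_MATURE, DIAM_A_TAU = 0.40, 0.59, 0.4
DIAM_B_NEWBORN, DIAM_B_MATURE, DIAM_B_TAU = 0.36, 1.01, 0.9
DIP_MAX = 0.35


def _dip_tau(ring_age: float) -> float:
    # dip(age) = DIP_MAX * (1 - exp(-(age - 2)/tau)) crosses 0.10 at ring_age
    return (ring_age - RING_MIN_AGE_DAYS) / math.log(DIP_MAX / (DIP_MAX - 0.10))


def dip_at_age(age_days: np.ndarray, ring_age_days: np.ndarray) -> np.ndarray:
    """Ground-truth central-dip fraction as a function of AZ age."""
    age = np.asarray(age_days, dtype=float)
    ra = np.asarray(ring_age_days, dtype=float)
    tau = (ra - RING_MIN_AGE_DAYS) / math.log(DIP_MAX / (DIP_MAX - 0.10))
    out = np.where(
        age <= RING_MIN_AGE_DAYS, 0.0,
        DIP_MAX * (1.0 - np.exp(-(age - RING_MIN_AGE_DAYS) / np.maximum(tau, 1e-9))),
    )
    return out


def diam_at_age(age_days: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth channel-A / channel-B field diameters vs age (um)."""
    age = np.asarray(age_days, dtype=float)
    da = DIAM_A_MATURE - (DIAM_A_MATURE - DIAM_A_NEWBORN) * np.exp(-age / DIAM_A_TAU)
    db = DIAM_B_MATURE - (DIAM_B_MATURE - DIAM_B_NEWBORN) * np.exp(-age / DIAM_B_TAU)
    return da, db


def simulate_development(
    days: int,
    growth_fold_per_day: float = 1.9,
    maturation_days: float = 3.2,
    activity_factor: float = 1.0,
    cfg: SynthConfig | None = None,
    seed: int | None = None,
    growth_coupling: float = 1.0,
    session_jitter_um: float = 0.05,
    session_offset_um: float = 0.5,
    rab3_like: bool = False,
    rab3_silent_frac: float = 0.5,
) -> SessionSeries:
    """Multi-day AZ birth/maturation series with persistent identities.

    The AZ population grows geometrically at
    ``growth_fold_per_day * activity_factor ** growth_coupling`` per day;
    births are continuous in time with the growth-law density.  Each AZ
    matures along saturating trajectories: Pr rises toward a target drawn from
    the calibrated mixture, receptor-field diameters grow toward the mature
    72-h geometry, and the channel-B central dip starts rising only after a
    structural floor of 2 days, crossing the 10% ring criterion at
    ``2 + Gamma(4, .) / activity_factor`` days of age, with mean
    ``maturation_days`` at ``activity_factor = 1``.

    Sessions are daily snapshots at integer days 0..days-1; AZs are never
    deleted.  Each session applies a global position offset plus per-AZ
    jitter so that cross-session matching is non-trivial.

    Under ``rab3_like``, a fraction of AZs carries no presynaptic channel
    intensity and never releases or matures (its PSD stays ringless), while
    presynaptic intensity concentrates in the remainder.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if growth_fold_per_day < 1:
        raise ValueError("growth_fold_per_day must be >= 1")
    if maturation_days <= RING_MIN_AGE_DAYS:
        raise ValueError(f"maturation_days must exceed {RING_MIN_AGE_DAYS}")
    if activity_factor <= 0:
        raise ValueError("activity_factor must be positive")
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    g = growth_fold_per_day * activity_factor**growth_coupling
    n0 = cfg.n_az
    span = days - 1
    n_final = int(round(n0 * g**span))
    # birth times: initial cohort at t <= 0 (left-censored), then growth-law density
    counts = [n0] + [int(round(n0 * g ** (d + 1))) - int(round(n0 * g**d)) for d in range(span)]
    births = [np.zeros(counts[0])]
    for d in range(span):
        k = counts[d + 1]
        if k <= 0:
            births.append(np.zeros(0))
            continue
        u = rng.uniform(0, 1, size=k)
        if abs(g - 1) < 1e-12:
            bt = d + u
        else:
            # inverse CDF of density ~ g^t on (d, d+1]
            bt = d + np.log1p(u * (g - 1)) / np.log(g)
        births.append(bt)
    birth_t = np.concatenate(births)
    n_total = birth_t.size

    layout = generate_az_layout(
        n_total, min_sep_um=cfg.min_sep_um, seed=rng, margin_um=cfg.field_margin_um,
    )
    # per-AZ maturation parameters
    delay_scale = (maturation_days - RING_MIN_AGE_DAYS) / RING_DELAY_SHAPE
    ring_age = RING_MIN_AGE_DAYS + rng.gamma(RING_DELAY_SHAPE, delay_scale, n_total) / activity_factor
    pr_target = _draw_capped_gamma(
        rng, cfg.active_pr_shape, cfg.active_pr_scale, cfg.pr_cap, n_total
    )
    mature_mask = rng.random(n_total) < cfg.mature_frac
    pr_target[mature_mask] = _draw_capped_gamma(
        rng, cfg.mature_pr_shape, cfg.mature_pr_scale, cfg.pr_cap, int(mature_mask.sum())
    )
    pr_tau = maturation_days / activity_factor

    presyn_silent = np.zeros(n_total, dtype=bool)
    if rab3_like:
        presyn_silent = rng.random(n_total) < rab3_silent_frac

    tables = []
    ts = []
    for d in range(days):
        present = birth_t <= d + 1e-9
        idx = np.nonzero(present)[0]
        age = d - birth_t[idx]
        da, db = diam_at_age(age)
        dip = dip_at_age(age, ring_age[idx])
        pr_now = pr_target[idx] * (1 - np.exp(-age / pr_tau))
        chan = cfg.channel_mean * (0.3 + 0.7 * (1 - np.exp(-age / pr_tau)))
        sil = presyn_silent[idx]
        pr_now = np.where(sil, 0.0, pr_now)
        dip = np.where(sil, 0.0, dip)
        chan = np.where(sil, 0.0, chan * (1 + rab3_silent_frac if rab3_like else 1.0))

        off = rng.normal(0, session_offset_um, size=2)
        jit = rng.normal(0, session_jitter_um, size=(idx.size, 2))
        tab = pd.DataFrame({
            "az_id": idx,
            "x_um": layout["x_um"].to_numpy()[idx] + off[0] + jit[:, 0],
            "y_um": layout["y_um"].to_numpy()[idx] + off[1] + jit[:, 1],
            "true_pr": pr_now,
            "age_days": age,
            "birth_day": birth_t[idx],
            "true_dip_frac": dip,
            "diam_a_um": da,
            "diam_b_um": db,
            "intensity_presyn": chan,
            "presyn_silent": sil,
        })
        tab.attrs["field_size_um"] = layout.attrs.get("field_size_um")
        tab.attrs["session_offset_um"] = tuple(off)
        tables.append(tab)
        ts.append(float(d))

    return SessionSeries(
        timestamps_days=tuple(ts),
        tables=tuple(tables),
        meta={
            "growth_fold_per_day": growth_fold_per_day,
            "activity_factor": activity_factor,
            "maturation_days": maturation_days,
            "ring_age_days": ring_age,
            "birth_t_days": birth_t,
        },
    )
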
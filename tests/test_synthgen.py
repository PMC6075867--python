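"""Generator ground truth: layouts, Pr mixture, event statistics, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from azquant import profiles
from azquant.detect import unresolvable_fraction
from azquant.synthgen import (
    SynthConfig, dip_at_age, generate_az_layout, render_channel_image,
    render_movie, render_psd_pair, sample_channel_amplitudes,
    sample_pr_population, simulate_development, simulate_event_times, stim_train,
)


class TestLayout:
    def test_single_point(self):
        tab = generate_az_layout(1, min_sep_um=0.6, seed=0)
        assert len(tab) == 1
        assert unresolvable_fraction(tab) == 0.0

    def test_min_separation_exhaustive(self):
        tab = generate_az_layout(50, min_sep_um=0.6, close_pair_frac=0.0, seed=3)
        d = pdist(tab[["x_um", "y_um"]].to_numpy())
        assert d.min() >= 0.6 - 1e-9

    def test_planted_close_pairs(self):
        tab = generate_az_layout(300, min_sep_um=0.6, close_pair_frac=0.0245, seed=5)
        assert len(tab) == 300
        frac = unresolvable_fraction(tab, limit_um=0.28)
        # planting granularity: round(0.0245 * 300 / 2) = 4 pairs -> 8/300
        assert frac == pytest.approx(8 / 300, abs=1e-9)

    def test_field_too_small_raises(self):
        with pytest.raises((ValueError, RuntimeError), match="density|field"):
            generate_az_layout(200, field_size_um=(5.0, 5.0), min_sep_um=0.6, seed=0)

    def test_deterministic_under_seed(self):
        a = generate_az_layout(80, min_sep_um=0.6, seed=11)
        b = generate_az_layout(80, min_sep_um=0.6, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestPrPopulation:
    def test_all_silent_degenerate(self):
        cfg = SynthConfig(n_az=50, silent_frac=1.0, spont_only_frac=0.0, seed=1)
        tab = sample_pr_population(cfg)
        assert (tab["true_pr"] == 0).all()
        assert (tab["true_class"] == "silent").all()

    def test_mean_pr_calibration(self):
        cfg = SynthConfig(n_az=2000, seed=2)
        tab = sample_pr_population(cfg)
        sem = tab["true_pr"].std() / np.sqrt(len(tab))
        assert abs(tab["true_pr"].mean() - 0.073) < 3 * sem

    def test_measured_level_high_fraction(self, rng):
        # the mean+2SD rule applied to binomial estimates at the reference
        # protocol (~100 stimuli) flags ~9.9% of AZs
        cfg = SynthConfig(n_az=200_000, seed=3, min_sep_um=0.0)  # layout skipped below
        layout = pd.DataFrame({"az_id": np.arange(cfg.n_az),
                               "x_um": 0.0, "y_um": 0.0})
        tab = sample_pr_population(cfg, layout)
        pr_hat = rng.binomial(100, tab["true_pr"].to_numpy()) / 100
        frac = (pr_hat > pr_hat.mean() + 2 * pr_hat.std()).mean()
        assert 0.085 <= frac <= 0.113

    def test_population_shape(self):
        cfg = SynthConfig(n_az=100_000, seed=4)
        layout = pd.DataFrame({"az_id": np.arange(cfg.n_az), "x_um": 0.0, "y_um": 0.0})
        tab = sample_pr_population(cfg, layout)
        pr = tab["true_pr"].to_numpy()
        assert 1.9 < stats.skew(pr) < 2.6
        assert pr.max() <= cfg.pr_cap
        cls = tab["true_class"].value_counts(normalize=True)
        assert cls["silent"] == pytest.approx(0.146, abs=0.001)
        assert cls["spont_only"] == pytest.approx(0.097, abs=0.001)
        assert (tab.loc[tab["true_class"] != "active", "true_pr"] == 0).all()

    def test_invalid_truncation_rejected(self):
        cfg = SynthConfig(n_az=100, active_pr_scale=0.5, seed=0)  # huge mean, cap bites
        with pytest.raises(ValueError, match="truncation"):
            sample_pr_population(cfg)


class TestEventTimes:
    def _az(self, n, pr, cls="active"):
        return pd.DataFrame({"az_id": np.arange(n), "x_um": 0.0, "y_um": 0.0,
                             "true_pr": pr, "true_class": cls})

    def test_pr_zero_no_evoked(self):
        ev = simulate_event_times(self._az(20, 0.0), stim_train(10, 1 / 3.0),
                                  40.0, 0.0, seed=0)
        assert len(ev) == 0

    def test_pr_one_every_stimulus(self):
        stim = stim_train(54, 1 / 3.0)
        ev = simulate_event_times(self._az(1, 1.0), stim, 170.0, 0.0, seed=0)
        assert len(ev) == 54
        assert (ev["kind"] == "evoked").all()
        assert sorted(ev["stimulus_index"]) == list(range(54))

    def test_poisson_total_count(self):
        az = self._az(1000, 0.0)
        ev = simulate_event_times(az, (), 300.0, 0.011, seed=1)
        lam = 0.011 * 300 * 1000
        assert abs(len(ev) - lam) < 4 * np.sqrt(lam)

    def test_binomial_consistency(self):
        # 1e4 replicates of Binomial(20, 0.3) via independent AZs
        az = self._az(10_000, 0.3)
        stim = stim_train(20, 1 / 3.0)
        ev = simulate_event_times(az, stim, 70.0, 0.0, seed=2)
        counts = ev.groupby("az_id").size().reindex(az["az_id"]).fillna(0).to_numpy()
        n, p, s = len(az), 0.3, 20
        se_mean = np.sqrt(s * p * (1 - p) / n)
        assert abs(counts.mean() - s * p) < 3 * se_mean
        var = counts.var(ddof=1)
        se_var = s * p * (1 - p) * np.sqrt(2 / (n - 1))  # normal approx
        assert abs(var - s * p * (1 - p)) < 3.5 * se_var

    def test_poisson_dispersion(self):
        az = self._az(2000, 0.0)
        ev = simulate_event_times(az, (), 100.0, 0.02, seed=3)
        counts = ev.groupby("az_id").size().reindex(az["az_id"]).fillna(0).to_numpy()
        disp = counts.var(ddof=1) / counts.mean()
        assert 0.9 <= disp <= 1.1

    def test_silent_azs_emit_nothing(self):
        az = self._az(10, 0.0, cls="silent")
        ev = simulate_event_times(az, stim_train(5, 1 / 3.0), 30.0, 0.5, seed=4)
        assert len(ev) == 0


class TestRenderMovie:
    def _quiet_cfg(self, **kw):
        base = dict(n_az=4, stim_times_s=(), movie_duration_s=2.6,
                    noise_sd=0.0, baseline_texture_sd=0.0, bleach_tau_s=np.inf,
                    drift_px_per_frame=0.0, seed=0)
        base.update(kw)
        return SynthConfig(**base)

    def _az_on_grid(self, cfg, x_px=30, y_px=30):
        px = cfg.pixel_size_um
        tab = pd.DataFrame({"az_id": [0], "x_um": [x_px * px], "y_um": [y_px * px],
                            "true_pr": [0.5], "true_class": ["active"]})
        tab.attrs["field_size_um"] = (60 * px, 60 * px)
        return tab

    def test_constant_without_events(self):
        cfg = self._quiet_cfg()
        az = self._az_on_grid(cfg)
        movie = render_movie(az, pd.DataFrame({"az_id": [], "time_s": []}), cfg)
        assert np.allclose(movie.data, cfg.baseline)

    def test_single_event_peak(self):
        cfg = self._quiet_cfg()
        az = self._az_on_grid(cfg)
        ev = pd.DataFrame({"az_id": [0], "time_s": [cfg.frame_interval_s * 5]})
        movie = render_movie(az, ev, cfg)
        assert movie.data[5].max() == pytest.approx(cfg.baseline + cfg.flash_amplitude,
                                                    rel=1e-6)
        assert np.unravel_index(movie.data[5].argmax(), movie.data[5].shape) == (30, 30)

    def test_exponential_decay_closed_form(self):
        cfg = self._quiet_cfg(flash_decay_s=0.26, movie_duration_s=3.9)
        az = self._az_on_grid(cfg)
        t0 = cfg.frame_interval_s * 4
        ev = pd.DataFrame({"az_id": [0], "time_s": [t0]})
        movie = render_movie(az, ev, cfg)
        for k in range(6):
            expected = cfg.flash_amplitude * np.exp(-0.13 * k / 0.26)
            assert movie.data[4 + k, 30, 30] - cfg.baseline == pytest.approx(
                expected, rel=1e-5)

    def test_bit_identical_under_seed(self, small_cfg):
        from azquant.pipeline import simulate_recording
        a = simulate_recording(small_cfg)
        b = simulate_recording(small_cfg)
        assert np.array_equal(a["movie"].data, b["movie"].data)
        pd.testing.assert_frame_equal(a["events"], b["events"])

    def test_short_decay_warns(self):
        cfg = self._quiet_cfg(flash_decay_s=0.05)
        az = self._az_on_grid(cfg)
        with pytest.warns(UserWarning, match="single frame"):
            render_movie(az, pd.DataFrame({"az_id": [], "time_s": []}), cfg)


class TestChannelRendering:
    def _pop(self, n, seed=0):
        cfg = SynthConfig(n_az=n, seed=seed)
        layout = pd.DataFrame({"az_id": np.arange(n),
                               "x_um": np.linspace(2, 50, n), "y_um": 5.0})
        return cfg, sample_pr_population(cfg, layout)

    def test_perfect_correlation_preserves_rank(self):
        cfg, tab = self._pop(400)
        amps = sample_channel_amplitudes(tab, cfg, np.random.default_rng(0),
                                         intensity_pr_r=1.0)
        active = tab["true_pr"] > 0
        assert stats.spearmanr(amps[active], tab["true_pr"][active]).statistic > 1 - 1e-9

    @pytest.mark.parametrize("r_target, lo, hi", [(0.61, 0.56, 0.66), (0.0, -0.1, 0.1)])
    def test_target_correlation_recovered(self, r_target, lo, hi):
        cfg, tab = self._pop(1000, seed=3)
        amps = sample_channel_amplitudes(tab, cfg, np.random.default_rng(1),
                                         intensity_pr_r=r_target)
        r = stats.pearsonr(amps, tab["true_pr"]).statistic
        assert lo <= r <= hi

    def test_extreme_r_rejected(self):
        cfg, tab = self._pop(20)
        with pytest.raises(ValueError, match="intensity_pr_r"):
            sample_channel_amplitudes(tab, cfg, np.random.default_rng(0),
                                      intensity_pr_r=1.5)

    def test_amplitudes_stored_in_table(self):
        cfg, tab = self._pop(50)
        img, out = render_channel_image(tab, "cac", cfg, seed=0)
        assert "intensity_cac" in out.columns
        assert img.ndim == 2 and img.max() > 0


class TestPsdPair:
    def test_no_dip_is_unimodal(self):
        psd = render_psd_pair(0.59, 1.01, dip_frac=0.0, noise_sd=0.0)
        p = profiles.extract_profile(psd["chan_a"], psd["chan_b"], psd["center_um"],
                                     psd["pixel_size_um"])
        half = p.chanB_norm[len(p.chanB_norm) // 2:]
        assert np.all(np.diff(half) <= 1e-9)  # monotone decreasing from centre

    def test_dip_ratio_on_noise_free_image(self):
        psd = render_psd_pair(0.59, 1.01, dip_frac=0.15, noise_sd=0.0)
        p = profiles.detect_ring(profiles.extract_profile(
            psd["chan_a"], psd["chan_b"], psd["center_um"], psd["pixel_size_um"]))
        # central minimum / flank maximum ratio = 0.85 +/- 0.01
        assert (1 - p.dip_frac) == pytest.approx(0.85, abs=0.01)

    def test_degenerate_diameter_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            render_psd_pair(0.1, 0.2, dip_frac=0.1, pixel_size_um=0.138)

    def test_ring_must_contain_core(self):
        with pytest.raises(ValueError, match="ring_outer"):
            render_psd_pair(1.0, 0.5, dip_frac=0.1)


class TestDevelopment:
    def test_constant_count_without_growth(self):
        cfg = SynthConfig(n_az=30, seed=0)
        series = simulate_development(days=4, growth_fold_per_day=1.0, cfg=cfg, seed=0)
        assert [len(t) for t in series.tables] == [30] * 4

    def test_geometric_growth_exact(self):
        cfg = SynthConfig(n_az=25, seed=1)
        series = simulate_development(days=4, growth_fold_per_day=2.0, cfg=cfg, seed=1)
        assert len(series.tables[-1]) == 8 * len(series.tables[0])

    def test_ring_age_distribution(self):
        cfg = SynthConfig(n_az=500, seed=2)
        series = simulate_development(days=2, growth_fold_per_day=1.0,
                                      maturation_days=3.2, cfg=cfg, seed=2)
        ring_age = series.meta["ring_age_days"]
        assert ring_age.min() >= 2.0
        assert ring_age.mean() == pytest.approx(3.2, abs=0.2)

    def test_no_ring_before_two_days(self):
        dip = dip_at_age(np.array([0.5, 1.9, 2.0]), np.array([3.2, 3.2, 3.2]))
        assert (dip == 0).all()

    def test_newborns_weak_and_ringless(self):
        cfg = SynthConfig(n_az=100, seed=3)
        series = simulate_development(days=3, growth_fold_per_day=2.0, cfg=cfg, seed=3)
        last = series.tables[-1]
        newborn = last[last["age_days"] < 1.0]
        assert (newborn["true_pr"] <= 0.14).all()
        assert (newborn["true_dip_frac"] == 0).all()

    def test_rab3_like_regime(self):
        cfg = SynthConfig(n_az=200, seed=4)
        series = simulate_development(days=3, growth_fold_per_day=1.2, cfg=cfg,
                                      seed=4, rab3_like=True, rab3_silent_frac=0.5)
        last = series.tables[-1]
        sil = last["presyn_silent"]
        assert 0.35 < sil.mean() < 0.65
        assert (last.loc[sil, "intensity_presyn"] == 0).all()
        assert (last.loc[sil, "true_dip_frac"] == 0).all()
        assert (last.loc[sil, "true_pr"] == 0).all()
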
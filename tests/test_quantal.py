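"""Pr estimation, evoked/spontaneous splitting, classification, stability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from azquant.quantal import (
    attenuation_prediction, class_fractions, classify_azs, compute_pr,
    distribution_summary, session_stability, split_evoked_spontaneous,
)
from azquant.synthgen import (
    SynthConfig, sample_pr_population, simulate_event_times, stim_train,
)


def _events(rows):
    df = pd.DataFrame(rows)
    for col, default in [("event_id", range(len(df))), ("frame", 0),
                         ("peak_dF", 1.0), ("x_um", 0.0), ("y_um", 0.0)]:
        if col not in df:
            df[col] = default
    return df


def _az(n):
    return pd.DataFrame({"az_id": np.arange(n), "x_um": 0.0, "y_um": 0.0})


def _prmap_from_counts(ev, sp, n_stimuli=54, duration=170.0):
    n = len(ev)
    return pd.DataFrame({
        "az_id": np.arange(n),
        "n_evoked": ev, "n_stimuli": n_stimuli,
        "pr_hat": np.asarray(ev) / n_stimuli,
        "spont_count": sp,
        "spont_rate_hz": np.asarray(sp) / duration,
    })


class TestSplit:
    def test_event_shortly_after_stimulus_is_evoked(self):
        ev = _events([{"az_id": 0, "time_s": 3.05}])
        out = split_evoked_spontaneous(ev, [3.0], window_s=0.3)
        assert out.loc[0, "kind"] == "evoked"
        assert out.loc[0, "stimulus_index"] == 0

    def test_event_between_stimuli_is_spontaneous(self):
        ev = _events([{"az_id": 0, "time_s": 4.6}])  # 1.6 s after a 0.3 Hz stimulus
        out = split_evoked_spontaneous(ev, [3.0, 6.0], window_s=0.3)
        assert out.loc[0, "kind"] == "spontaneous"
        assert np.isnan(out.loc[0, "stimulus_index"])

    def test_at_most_one_evoked_per_az_stimulus(self):
        ev = _events([{"az_id": 5, "time_s": 3.05}, {"az_id": 5, "time_s": 3.15},
                      {"az_id": 6, "time_s": 3.10}])
        out = split_evoked_spontaneous(ev, [3.0], window_s=0.3)
        assert list(out["kind"]) == ["evoked", "spontaneous", "evoked"]

    def test_exhaustive_enumeration_oracle(self):
        # scripted list covering every window/AZ combination
        stim = [2.0, 5.0, 8.0]
        rows, expected = [], []
        for t, az, kind in [
            (1.9, 0, "spontaneous"),   # before any stimulus
            (2.0, 0, "spontaneous"),   # exactly at stimulus: window is open
            (2.01, 0, "evoked"), (2.30, 1, "evoked"),  # in window
            (2.31, 1, "spontaneous"),  # just past window
            (5.25, 1, "evoked"), (5.28, 1, "spontaneous"),  # duplicate demoted
            (8.3, 2, "evoked"), (8.31, 2, "spontaneous"),
        ]:
            rows.append({"az_id": az, "time_s": t})
            expected.append(kind)
        out = split_evoked_spontaneous(_events(rows), stim, window_s=0.3)
        assert list(out["kind"]) == expected

    def test_window_wider_than_isi_rejected(self):
        with pytest.raises(ValueError, match="inter-stimulus"):
            split_evoked_spontaneous(_events([{"az_id": 0, "time_s": 1.0}]),
                                     [1.0, 1.2], window_s=0.3)


class TestComputePr:
    def test_no_events_zero_pr(self):
        prmap = compute_pr(_events([]), _az(3), n_stimuli=100, duration_s=300.0)
        assert (prmap["pr_hat"] == 0).all()
        assert (prmap["spont_rate_hz"] == 0).all()

    def test_direct_division(self):
        ev = _events([{"az_id": 0, "time_s": t, "kind": "evoked"}
                      for t in np.arange(15)])
        prmap = compute_pr(ev, _az(1), n_stimuli=54, duration_s=170.0)
        assert prmap.loc[0, "pr_hat"] == pytest.approx(15 / 54)
        assert prmap.loc[0, "pr_hat"] == pytest.approx(0.2778, abs=1e-4)

    def test_binomial_interval_at_large_s(self):
        az = _az(1).assign(true_pr=0.3, true_class="active")
        stim = stim_train(1000, 1 / 3.0)
        ev = simulate_event_times(az, stim, 3010.0, 0.0, seed=5)
        ev["kind"] = "evoked"
        prmap = compute_pr(ev, az, n_stimuli=1000, duration_s=3010.0)
        # central 99% binomial interval for p=0.3, S=1000
        assert 0.256 <= prmap.loc[0, "pr_hat"] <= 0.344

    def test_zero_stimuli_rejected(self):
        with pytest.raises(ValueError, match="n_stimuli"):
            compute_pr(_events([]), _az(1), n_stimuli=0, duration_s=10.0)

    def test_estimator_consistency(self):
        # median |pr_hat - true_pr| decreases monotonically with stimuli
        cfg = SynthConfig(n_az=500, seed=6)
        az = sample_pr_population(cfg, _az(500))
        errs = []
        for s in (100, 1000, 10000):
            stim = tuple(3.0 * k for k in range(s))
            dur = 3.0 * s + 1
            ev = simulate_event_times(az, stim, dur, 0.0, seed=s)
            ev["kind"] = "evoked"
            prmap = compute_pr(ev, az, n_stimuli=s, duration_s=dur)
            errs.append(np.median(np.abs(prmap["pr_hat"].to_numpy()
                                         - az["true_pr"].to_numpy())))
        assert errs[0] > errs[1] > errs[2]


class TestClassify:
    def test_hand_computed_threshold(self):
        # mean 0.1083, population SD 0.1766 -> threshold 0.4615 -> one high
        prmap = _prmap_from_counts(
            ev=[0, 0, 3, 3, 3, 27], sp=[2, 1, 1, 1, 1, 1], n_stimuli=54)
        prmap["pr_hat"] = [0.0, 0.0, 0.05, 0.05, 0.05, 0.5]
        out = classify_azs(prmap)
        assert out.attrs["class_threshold"] == pytest.approx(0.4615, abs=2e-4)
        assert (out["class"] == "high").sum() == 1
        assert out.loc[5, "class"] == "high"
        # zero-Pr AZs with spontaneous events are spontaneous-only by the rule
        assert list(out.loc[[0, 1], "class"]) == ["spont_only", "spont_only"]
        assert (out.loc[[2, 3, 4], "class"] == "low").all()

    def test_all_equal_no_high(self):
        prmap = _prmap_from_counts(ev=[5, 5, 5, 5], sp=[0, 0, 0, 0])
        out = classify_azs(prmap)
        assert (out["class"] != "high").all()

    def test_partition_property(self, small_recording):
        cfg_stim = len(small_recording["movie"].stim_times_s)
        ev = small_recording["events"].copy()
        ev["kind"] = np.where(ev["stimulus_index"].notna(), "evoked", "spontaneous")
        prmap = compute_pr(ev, small_recording["az"], cfg_stim,
                           small_recording["movie"].duration_s)
        out = classify_azs(prmap)
        fr = class_fractions(out)
        assert sum(fr.values()) == pytest.approx(1.0)
        counts = out["class"].value_counts()
        assert counts.sum() == len(out)

    def test_silent_class_requires_no_events(self):
        prmap = _prmap_from_counts(ev=[0, 2], sp=[0, 0])
        out = classify_azs(prmap)
        assert out.loc[0, "class"] == "silent"
        assert out.loc[1, "class"] == "low"


class TestDistributionSummary:
    def test_symmetric_data_near_zero_skew(self, rng):
        prmap = _prmap_from_counts(ev=np.zeros(10_000, dtype=int), sp=np.zeros(10_000))
        prmap["pr_hat"] = rng.normal(0.5, 0.1, 10_000)
        assert abs(distribution_summary(prmap)["skewness"]) < 0.05

    def test_adjusted_fisher_pearson_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        n = len(x)
        m = x.mean()
        g1 = ((x - m) ** 3).mean() / (((x - m) ** 2).mean()) ** 1.5
        adj = np.sqrt(n * (n - 1)) / (n - 2) * g1
        prmap = _prmap_from_counts(ev=np.zeros(5, dtype=int), sp=np.zeros(5))
        prmap["pr_hat"] = x
        assert distribution_summary(prmap)["skewness"] == pytest.approx(adj, rel=1e-12)

    def test_default_population_skew_band(self, rng):
        cfg = SynthConfig(n_az=20_000, seed=8)
        az = sample_pr_population(cfg, _az(20_000))
        pr_hat = rng.binomial(100, az["true_pr"].to_numpy()) / 100
        prmap = _prmap_from_counts(ev=(pr_hat * 100).astype(int),
                                   sp=np.zeros(20_000), n_stimuli=100)
        s = distribution_summary(prmap)
        assert 1.9 <= s["skewness"] <= 2.6

    def test_contract_of_derived_vectors(self, rng):
        prmap = _prmap_from_counts(ev=rng.integers(0, 20, 50), sp=np.zeros(50))
        s = distribution_summary(prmap)
        assert s["normalized_to_max"].max() == pytest.approx(1.0)
        assert s["ecdf_y"][-1] == 1.0
        assert np.all(np.diff(s["ecdf_x"]) >= 0)


class TestSessionStability:
    def _sim_prmap(self, az, seed, n_stim=54):
        stim = stim_train(n_stim, 1 / 3.0)
        ev = simulate_event_times(az, stim, 3 * n_stim + 10, 0.0, seed=seed)
        ev["kind"] = "evoked"
        return compute_pr(ev, az, n_stim, 3 * n_stim + 10)

    def test_identical_maps_r_one(self):
        az = sample_pr_population(SynthConfig(n_az=200, seed=1), _az(200))
        m = self._sim_prmap(az, seed=1)
        assert session_stability(m, m)["pearson_r"] == pytest.approx(1.0)

    def test_shuffled_identities_destroy_correlation(self, rng):
        az = sample_pr_population(SynthConfig(n_az=1000, seed=2), _az(1000))
        m1 = self._sim_prmap(az, seed=10)
        m2 = self._sim_prmap(az, seed=11)
        m2["az_id"] = rng.permutation(m2["az_id"].to_numpy())
        assert abs(session_stability(m1, m2)["pearson_r"]) < 0.1

    def test_attenuation_prediction_matches_replicates(self):
        # measured between-session r agrees with Var(p)/(Var(p)+E[p(1-p)]/S)
        az = sample_pr_population(SynthConfig(n_az=1500, seed=3), _az(1500))
        pred = attenuation_prediction(az["true_pr"].to_numpy(), 54)
        rs = [session_stability(self._sim_prmap(az, seed=100 + 2 * k),
                                self._sim_prmap(az, seed=101 + 2 * k))["pearson_r"]
              for k in range(30)]
        assert abs(np.mean(rs) - pred) <= 0.05

    def test_too_few_shared_azs_rejected(self):
        m = _prmap_from_counts(ev=[1, 2, 3], sp=[0, 0, 0])
        with pytest.raises(ValueError, match="shared"):
            session_stability(m, m)
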
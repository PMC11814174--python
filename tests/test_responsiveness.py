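"""KDE rate functions, paired tests, BH correction, classification, latency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from popsep import (
    SyntheticConfig,
    TimeWindow,
    bh_adjust,
    classify_neurons,
    firing_rate_function,
    generate_dataset,
    image_responsiveness_test,
    onset_latency,
    summarize_responsiveness,
)
from popsep.responsiveness import DEFAULT_BASELINE, DEFAULT_STIMULUS, _paired_t

from conftest import make_dataset


class TestRateFunction:
    def test_no_spikes_gives_zero_rate(self):
        grid = np.linspace(-300, 400, 701)
        rf = firing_rate_function([np.array([]), np.array([])], grid=grid)
        assert np.all(rf.rate == 0)

    def test_single_spike_peak_height(self):
        """One spike, one trial: peak = 1/(sqrt(2 pi) * 0.010 s) spikes/s."""
        grid = np.linspace(-100, 100, 2001)
        rf = firing_rate_function([np.array([0.0])], bandwidth=10.0, grid=grid)
        peak = 1000.0 / (np.sqrt(2 * np.pi) * 10.0)
        assert rf.rate[np.argmin(np.abs(grid))] == pytest.approx(peak, rel=1e-12)
        assert peak == pytest.approx(39.894, abs=1e-3)

    @given(
        st.lists(
            st.lists(st.floats(-250, 350), max_size=15),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_mass_conservation(self, trials):
        """Integral of the rate equals spikes per trial (1e-3 relative)."""
        arrays = [np.sort(np.unique(np.asarray(t))) for t in trials]
        grid = np.linspace(-400, 500, 1801)  # pads >= 5 bandwidths, 0.5 ms spacing
        rf = firing_rate_function(arrays, bandwidth=10.0, grid=grid)
        per_trial = sum(len(a) for a in arrays) / len(arrays)
        assert rf.integral() == pytest.approx(per_trial, rel=1e-3, abs=1e-6)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            firing_rate_function([np.array([0.0])], grid=np.array([]))


class TestPairedTest:
    def test_matches_textbook_formula(self):
        """p equals the closed-form paired-t computation to 1e-10."""
        base = np.array([2, 3, 2, 3, 2], dtype=float)
        stim = np.array([8, 9, 10, 8, 9], dtype=float)
        diffs = stim - base
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        p_ref = 2 * stats.t.sf(abs(t), 4)
        assert _paired_t(diffs) == pytest.approx(p_ref, abs=1e-10)
        # equal-width windows: rates and counts give the same p
        assert _paired_t(diffs / 0.2) == pytest.approx(p_ref, abs=1e-10)

    def test_zero_difference_convention(self):
        spikes = {
            "c1": [{"nA": [-150.0, 50.0]}, {"nA": [-100.0, 100.0]},
                   {"nA": [-50.0, 150.0]}],
            "d1": [{"nA": []}, {"nA": []}, {"nA": []}],
        }
        ds = make_dataset(spikes, {"c1": "cat", "d1": "dog"})
        # one spike in baseline [-200,0) and one in [0,200) per trial: rate
        # difference identically zero
        p, direction = image_responsiveness_test(
            ds, "nA", "c1", TimeWindow(-200, 200), TimeWindow(0, 200)
        )
        assert p == 1.0 and direction == 0

    def test_detects_synthetic_responder(self):
        """Strong visual response, 19 trials: p < 0.05 in >= 95% of seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                n_neurons=1, images_per_category=1, trials_per_image=19,
                baseline_rate_mean=5.0, baseline_rate_sd=0.0,
                response_gain_mean=10.0, response_gain_sd=0.0,
                category_contrast=0.0, image_idiosyncrasy_sd=0.0,
                latency_mean=80.0, latency_sd=0.0, seed=seed,
            )
            ds = generate_dataset(cfg)
            p, direction = image_responsiveness_test(
                ds, "n000", ds.image_ids[0], DEFAULT_BASELINE, DEFAULT_STIMULUS
            )
            hits += (p < 0.05) and (direction == 1)
        assert hits >= int(0.95 * n_seeds)


class TestBH:
    @staticmethod
    def brute_force_bh(p, alpha):
        """Literal step-up definition, independent of any library."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * alpha / m:
                k_star = k
        reject = np.zeros(m, dtype=bool)
        reject[order[:k_star]] = True
        return reject

    def test_matches_definition_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            alpha = rng.uniform(0.01, 0.2)
            np.testing.assert_array_equal(
                bh_adjust(p, alpha), self.brute_force_bh(p, alpha)
            )

    def test_all_ones_rejects_nothing(self):
        assert not bh_adjust(np.ones(10), 0.05).any()

    def test_single_test_identity(self):
        assert bh_adjust(np.array([0.049]), 0.05).all()
        assert not bh_adjust(np.array([0.051]), 0.05).any()

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(3)
        p = rng.random(30)
        prev = bh_adjust(p, 0.01)
        for alpha in (0.02, 0.05, 0.1, 0.2):
            cur = bh_adjust(p, alpha)
            assert np.all(cur[prev])  # rejection set never shrinks
            prev = cur

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]), 0.05)


class TestClassification:
    def _signal_dataset(self):
        """Neurons engineered to land in each responsiveness class."""
        quiet = [{"nA": [], "nB": [], "nC": [], "nD": []} for _ in range(5)]

        def burst(neurons):
            out = []
            for k in range(5):
                tmap = {"nA": [], "nB": [], "nC": [], "nD": []}
                for n in neurons:
                    tmap[n] = list(np.linspace(20, 330, 12 + k))
                out.append(tmap)
            return out

        spikes = {
            "dogA": burst(["nA", "nC"]),
            "catB": burst(["nB", "nC"]),
            "dogC": quiet,
            "catD": quiet,
        }
        cats = {"dogA": "dog", "catB": "cat", "dogC": "dog", "catD": "cat"}
        return make_dataset(spikes, cats)

    def test_taxonomy(self):
        ds = self._signal_dataset()
        table = classify_neurons(ds, alpha=0.05)
        assert table.classes["nA"] == "only_dog"
        assert table.classes["nB"] == "only_cat"
        assert table.classes["nC"] == "both"
        assert table.classes["nD"] == "none"

    def test_class_counts_partition_neurons(self, small_synthetic):
        _, ds = small_synthetic
        table = classify_neurons(ds)
        assert sum(table.class_counts().values()) == ds.n_neurons

    def test_vectorised_path_matches_per_pair_test(self, small_synthetic):
        _, ds = small_synthetic
        table = classify_neurons(ds)
        rng = np.random.default_rng(0)
        for _ in range(10):
            nid = rng.choice(ds.neuron_ids)
            img = rng.choice(ds.image_ids)
            p, _ = image_responsiveness_test(ds, nid, img)
            assert table.p_values.loc[nid, img] == pytest.approx(p, abs=1e-12)

    def test_null_false_positive_rate_controlled(self):
        """No-signal simulation: responsive fraction <= alpha + 3 SE."""
        cfg = SyntheticConfig(
            n_neurons=60, images_per_category=60, trials_per_image=5,
            baseline_rate_mean=5.0, baseline_rate_sd=1.0,
            response_gain_mean=0.0, response_gain_sd=0.0,
            category_contrast=0.0, image_idiosyncrasy_sd=0.0, seed=8,
        )
        ds = generate_dataset(cfg)
        table = classify_neurons(ds, alpha=0.05)
        frac = table.n_responsive / table.n_neurons
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / table.n_neurons)
        assert frac <= bound


class TestSummaries:
    # per-monkey class counts (only_dog, only_cat, both, none) from the
    # recorded study's responsiveness tables
    X_TEO_PRE = {"only_dog": 3, "only_cat": 1, "both": 84, "none": 5}
    L_TEO_PRE = {"only_dog": 1, "only_cat": 3, "both": 57, "none": 17}
    X_TE_POST = {"only_dog": 8, "only_cat": 5, "both": 45, "none": 77}

    def test_pooled_teo_pre_is_87_percent(self):
        s = summarize_responsiveness([self.X_TEO_PRE, self.L_TEO_PRE])
        assert s["percent_responsive_rounded"] == 87

    def test_single_monkey_percentages(self):
        assert summarize_responsiveness([self.X_TEO_PRE])["percent_responsive_rounded"] == 95
        assert summarize_responsiveness([self.X_TE_POST])["percent_responsive_rounded"] == 43

    def test_all_none_is_zero(self):
        s = summarize_responsiveness([{"only_dog": 0, "only_cat": 0, "both": 0, "none": 9}])
        assert s["percent_responsive"] == 0.0

    def test_empty_pool_flagged(self):
        with pytest.raises(ValueError):
            summarize_responsiveness([])


class TestLatency:
    def _rate_fn(self, latency, rate_hi=60.0, noise_seed=None):
        from popsep.responsiveness import RateFunction

        grid = np.arange(-300.0, 400.0, 1.0)
        rate = np.full_like(grid, 5.0)
        rate[grid >= latency] = rate_hi
        if noise_seed is not None:
            rate += np.random.default_rng(noise_seed).normal(0, 0.5, len(grid))
            rate = np.maximum(rate, 0)
        return RateFunction(grid, rate, 10.0, 10)

    def test_flat_rate_undefined(self):
        rf = self._rate_fn(latency=10_000.0, rate_hi=5.0)
        assert onset_latency(rf).latency is None

    def test_recovers_step_latency(self):
        """Estimate within +-10 ms of the true 80 ms step in >= 90% of seeds."""
        hits = 0
        for seed in range(20):
            est = onset_latency(self._rate_fn(80.0, noise_seed=seed))
            hits += est.latency is not None and abs(est.latency - 80.0) <= 10.0
        assert hits >= 18

    def test_monotone_in_true_latency(self):
        prev = -1.0
        for true_lat in (40.0, 80.0, 120.0, 200.0):
            est = onset_latency(self._rate_fn(true_lat)).latency
            assert est is not None and est >= prev
            prev = est

    def test_neuron_latencies_recover_generative_latency(self):
        from popsep import neuron_latencies

        cfg = SyntheticConfig(
            n_neurons=4, images_per_category=10, trials_per_image=10,
            baseline_rate_mean=5.0, baseline_rate_sd=0.0,
            response_gain_mean=40.0, response_gain_sd=0.0,
            category_contrast=0.0, image_idiosyncrasy_sd=0.0,
            latency_mean=80.0, latency_sd=0.0, seed=14,
        )
        ds = generate_dataset(cfg)
        lat = neuron_latencies(ds)
        assert lat.notna().all()
        # the 10-ms KDE kernel leads a sharp step by a few bandwidths, so
        # threshold crossings sit somewhat before the true 80 ms onset and
        # never after it plus noise
        vals = lat.to_numpy()
        assert np.all((vals >= 80.0 - 45.0) & (vals <= 95.0))

    def test_rule_reported(self):
        est = onset_latency(self._rate_fn(80.0))
        assert est.threshold_rule["threshold_sd"] == 3.0
        assert est.threshold_rule["min_duration_ms"] == 20.0
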
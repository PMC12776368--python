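import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import spikefield as sf
from spikefield import decoders as dec


class TestSpikeCountClassifier:
    def test_two_unit_worked_example(self):
        train_nov = np.array([[4, 4], [4, 2]], dtype=float)
        train_rep = np.array([[2, 0], [0, 2]], dtype=float)
        readout = dec.spike_count_classifier(train_nov, train_rep)
        np.testing.assert_allclose(readout.weights, [0.5, 0.5])
        assert readout.bias == pytest.approx(2.25)
        assert readout.predict(np.array([[3], [3]]))[0] == "novel"
        assert readout.predict(np.array([[1], [1]]))[0] == "repeated"

    def test_boundary_ties_go_to_repeated(self):
        train_nov = np.array([[4, 4], [4, 2]], dtype=float)
        train_rep = np.array([[2, 0], [0, 2]], dtype=float)
        readout = dec.spike_count_classifier(train_nov, train_rep)
        x = np.array([[2.25], [2.25]])  # w.x exactly at the bias
        assert readout.predict(x)[0] == "repeated"

    def test_empty_training_class_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            dec.spike_count_classifier(np.empty((3, 0)), np.ones((3, 2)))

    def test_identical_class_distributions_decode_at_chance(self):
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(100):
            nov = rng.normal(size=(5, 20))
            rep = rng.normal(size=(5, 20))
            readout = dec.spike_count_classifier(nov, rep)
            accs.append(
                dec.classify(readout, rng.normal(size=(5, 50)), rng.normal(size=(5, 50)))
            )
        assert abs(np.mean(accs) - 0.5) < 0.02

    @given(seed=st.integers(0, 10_000))
    def test_equals_population_mean_threshold_rule(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 10)
        nov = rng.normal(1, 1, size=(n, 8))
        rep = rng.normal(0, 1, size=(n, 8))
        test = rng.normal(0.5, 1, size=(n, 30))
        readout = dec.spike_count_classifier(nov, rep)
        labels = readout.predict(test)
        threshold = (nov.mean(axis=1).mean() + rep.mean(axis=1).mean()) / 2.0
        oracle = np.where(test.mean(axis=0) > threshold, "novel", "repeated")
        assert (labels == oracle).all()


class TestFld:
    def test_single_observation_worked_example(self):
        # mu_nov=3, mu_rep=1, var=2 in both classes -> weight (3-1)/2 = 1
        nov = np.array([[3.0 - 1.0, 3.0 + 1.0]])
        rep = np.array([[1.0 - 1.0, 1.0 + 1.0]])
        readout = dec.fld_fit(nov, rep)
        assert readout.weights[0] == pytest.approx(1.0)

    def test_equal_means_give_zero_weight(self):
        nov = np.array([[1.0, 3.0], [0.0, 2.0]])
        rep = np.array([[3.0, 1.0], [1.0, 5.0]])
        readout = dec.fld_fit(nov, rep)
        assert readout.weights[0] == 0.0

    def test_all_zero_variance_raises(self):
        nov = np.ones((2, 3))
        rep = np.zeros((2, 3))
        with pytest.raises(ValueError, match="zero variance"):
            dec.fld_fit(nov, rep)

    def test_matches_brute_force_diagonal_gaussian_discriminant(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(2, 6)
            nov = rng.normal(1, 1, size=(n, 12))
            rep = rng.normal(0, 1, size=(n, 12))
            test = rng.normal(0.5, 1.5, size=(n, 20))
            readout = dec.fld_fit(nov, rep)
            pred = readout.predict(test)
            # oracle: likelihood ratio of two diagonal Gaussians sharing the
            # class-averaged variance
            mu_n, mu_r = nov.mean(axis=1), rep.mean(axis=1)
            sd = np.sqrt(
                (nov.var(axis=1, ddof=1) + rep.var(axis=1, ddof=1)) / 2.0
            )
            llr = stats.norm.logpdf(test.T, mu_n, sd).sum(axis=1) - stats.norm.logpdf(
                test.T, mu_r, sd
            ).sum(axis=1)
            oracle = np.where(llr > 0, "novel", "repeated")
            assert (pred == oracle).all()

    def test_reduces_to_spike_count_rule_under_symmetric_stats(self):
        # equal variances and equal mean differences: both rules order test
        # points identically
        rng = np.random.default_rng(2)
        base = rng.normal(size=4)
        nov = np.column_stack([base + 1 - 0.5, base + 1 + 0.5])
        rep = np.column_stack([base - 0.5, base + 0.5])
        fld = dec.fld_fit(nov, rep)
        scc = dec.spike_count_classifier(nov, rep)
        test = rng.normal(0.5, 2, size=(4, 200)) + base[:, None]
        assert (fld.predict(test) == scc.predict(test)).all()


class TestCrossValidatedDecoding:
    def test_zero_signal_population_decodes_at_chance(self, constant_memorability):
        model = sf.generate_population(
            n_neurons=200, sheet_size=(3.0, 3.0), n_channels=8,
            units_per_channel=2, pooling_radius=2.0, suppression_s0=0.0,
            memorability_gain=0.0, seed=3,
        )
        trials = sf.generate_task_sequence(
            60, (1, 2, 4), memorability_sampler=constant_memorability, seed=4
        )
        session = sf.simulate_responses(model, trials, seed=5)
        pseudo = sf.build_pseudopopulation(
            [session], [session.hga_proxy], (1, 2, 4)
        )
        res = sf.cross_validated_decoding(
            pseudo, population_size=12, n_cv=100, n_subsample=10, seed=6
        )
        assert abs(res.accuracy - 0.5) < 0.06

    def test_signal_population_beats_chance(self, small_pseudo):
        res = sf.cross_validated_decoding(
            small_pseudo, population_size=16, n_cv=60, n_subsample=10, seed=7
        )
        assert res.accuracy > 0.6
        assert res.accuracy == pytest.approx(res.per_iteration.mean())

    def test_small_stratum_failure_names_it(self, small_model):
        trials = sf.generate_task_sequence(10, {1, 2}, seed=8)
        session = sf.simulate_responses(small_model, trials, seed=9)
        pseudo = sf.build_pseudopopulation([session], [session.hga_proxy], {1, 2})
        with pytest.raises(ValueError, match="n_back"):
            sf.cross_validated_decoding(pseudo, population_size=4, n_cv=10,
                                        n_subsample=2, seed=0)

    def test_deterministic_under_seed(self, small_pseudo):
        a = sf.cross_validated_decoding(small_pseudo, population_size=8,
                                        n_cv=40, n_subsample=8, seed=11)
        b = sf.cross_validated_decoding(small_pseudo, population_size=8,
                                        n_cv=40, n_subsample=8, seed=11)
        np.testing.assert_array_equal(a.per_iteration, b.per_iteration)


class TestNeuronDroppingCurve:
    def test_one_result_per_size_and_final_matches_direct_call(self, small_pseudo):
        sizes = (2, 8, 16)
        curve = sf.neuron_dropping_curve(
            small_pseudo, sizes=sizes, n_cv=40, n_subsample=8, seed=12
        )
        assert len(curve) == 3
        direct = sf.cross_validated_decoding(
            small_pseudo, population_size=16, n_cv=40, n_subsample=8,
            seed=12 + 7919 * 2,
        )
        np.testing.assert_array_equal(curve[-1].per_iteration, direct.per_iteration)

    def test_accuracy_grows_with_population_on_signal(self, small_pseudo):
        curve = sf.neuron_dropping_curve(
            small_pseudo, sizes=(1, 4, 16), n_cv=60, n_subsample=10, seed=13
        )
        accs = [r.accuracy for r in curve]
        assert accs[0] < accs[-1]


class TestPowerLaw:
    def test_noiseless_parameters_recovered_and_inverted(self):
        x = np.array([1, 5, 25, 100, 400], dtype=float)
        y = 0.02 * x**0.5 + 0.5
        fit = sf.fit_power_law(x, y)
        assert fit.a == pytest.approx(0.02, rel=1e-4)
        assert fit.b == pytest.approx(0.5, rel=1e-4)
        assert fit.c == pytest.approx(0.5, rel=1e-4)
        assert fit.n_at(0.75) == pytest.approx(156.25, rel=1e-3)
        assert fit.sse < 1e-12

    def test_constant_curve_never_reaches_target(self):
        x = np.array([1, 2, 4, 8], dtype=float)
        fit = sf.fit_power_law(x, np.full(4, 0.6))
        assert fit.n_at(0.75) is None

    def test_fewer_than_four_points_raises(self):
        with pytest.raises(ValueError):
            sf.fit_power_law([1, 2, 3], [0.5, 0.6, 0.7])


class TestEfficiencyRatio:
    def test_identical_curves_give_one(self):
        x = np.array([1, 4, 16, 64], dtype=float)
        y = 0.05 * x**0.4 + 0.5
        fit = sf.fit_power_law(x, y)
        assert sf.efficiency_ratio(fit, fit) == pytest.approx(1.0)

    def test_four_fold_shifted_curve_gives_exactly_four(self):
        x = np.array([1, 4, 16, 64, 256], dtype=float)
        f = lambda z: 0.03 * z**0.45 + 0.48
        spike_fit = sf.fit_power_law(x, f(x))
        hga_fit = sf.fit_power_law(x, f(4 * x))
        assert sf.efficiency_ratio(spike_fit, hga_fit) == pytest.approx(4.0, rel=1e-3)

    def test_unattained_target_raises(self):
        x = np.array([1, 2, 4, 8], dtype=float)
        flat = sf.fit_power_law(x, np.full(4, 0.6))
        good = sf.fit_power_law(x, 0.1 * x**0.5 + 0.5)
        with pytest.raises(ValueError, match="not attained"):
            sf.efficiency_ratio(good, flat)


class TestPredictionQuality:
    behavior = {1: 0.9, 2: 0.8, 4: 0.7}

    def _benchmark(self):
        vals = np.array(list(self.behavior.values()))
        return np.mean((vals - 0.5) ** 2)

    def test_perfect_prediction_scores_one(self):
        assert sf.prediction_quality(0.0, self.behavior) == pytest.approx(1.0)

    def test_benchmark_level_scores_zero(self):
        assert sf.prediction_quality(self._benchmark(), self.behavior) == pytest.approx(0.0)

    def test_twice_benchmark_scores_minus_one(self):
        assert sf.prediction_quality(2 * self._benchmark(), self.behavior) == pytest.approx(-1.0)

    def test_flat_50_percent_behavior_is_degenerate(self):
        with pytest.raises(ValueError, match="undefined"):
            sf.prediction_quality(0.1, {1: 0.5, 2: 0.5})


class TestRescaleToBehavior:
    def _projections(self, slopes, sd, sizes, n=400, seed=0):
        rng = np.random.default_rng(seed)
        return {
            s: {c: slopes[c] * s + rng.normal(0, sd, n) for c in slopes}
            for s in sizes
        }

    def test_self_consistent_behavior_recovers_measured_size(self):
        slopes = {"novel": 0.05, 1: -0.06, 4: -0.03, 16: -0.01}
        sizes = [10, 20]
        proj = self._projections(slopes, sd=1.0, sizes=sizes)
        # behavior := the model's own Gaussian performance at size 20,
        # computed from the same estimates the rescaler uses
        s_arr = np.array(sizes, dtype=float)
        est_slopes = {
            c: (s_arr @ np.array([proj[s][c].mean() for s in sizes]))
            / (s_arr @ s_arr)
            for c in slopes
        }
        est_sd = np.mean([proj[20][c].std(ddof=1) for c in slopes])
        behavior = {
            c: dec.gaussian_performance(
                est_slopes[c] * 20, est_sd, "novel" if c == "novel" else "repeated"
            )
            for c in slopes
        }
        pred = sf.rescale_to_behavior(proj, behavior, size_grid=[5, 10, 20, 40])
        assert pred.chosen_population_size == 20
        assert pred.mse_neural == pytest.approx(0.0, abs=1e-20)
        assert pred.pq == pytest.approx(1.0)

    def test_rank_order_preserved_by_rescaling(self):
        slopes = {"novel": 0.04, 1: -0.07, 2: -0.05, 8: -0.02, 32: -0.005}
        proj = self._projections(slopes, sd=0.8, sizes=[8, 16], seed=1)
        behavior = {c: 0.7 for c in slopes}
        pred = sf.rescale_to_behavior(proj, behavior, size_grid=[2, 10, 30])
        # predictions at any two candidate sizes share the same ranking
        ranks = []
        for cand in (2.0, 30.0):
            perf = {
                c: dec.gaussian_performance(
                    pred.mean_slopes[c] * cand, pred.sd_plateau,
                    "novel" if c == "novel" else "repeated",
                )
                for c in slopes
            }
            ranks.append(stats.rankdata([perf[c] for c in slopes]))
        np.testing.assert_array_equal(ranks[0], ranks[1])

    def test_empty_size_grid_raises(self):
        proj = self._projections({"novel": 0.1, 1: -0.1}, 1.0, [4, 8])
        with pytest.raises(ValueError, match="size_grid"):
            sf.rescale_to_behavior(proj, {"novel": 0.8, 1: 0.7}, [])


class TestRsa:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(3)
        mat = sf.rsa_matrix(rng.normal(size=(20, 15)))
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)

    def test_zero_variance_rows_dropped_but_matrix_valid(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 8))
        x[3] = 7.0
        mat = sf.rsa_matrix(x)
        assert mat.shape == (8, 8)
        assert np.isfinite(mat).all()

    def test_too_few_usable_observations_raise(self):
        with pytest.raises(ValueError, match="nonzero variance"):
            sf.rsa_matrix(np.ones((3, 5)))

    def test_within_category_exceeds_between_on_category_simulation(self):
        model = sf.generate_population(
            n_neurons=200, sheet_size=(3.0, 3.0), n_channels=4,
            units_per_channel=4, pooling_radius=2.0,
            categories=("a", "b", "c", "d", "e"), clustering_length=0.0,
            tuning_strength=1.0, suppression_s0=0.0, memorability_gain=0.0,
            seed=5,
        )
        from spikefield.task import CategorySpec

        trials = sf.generate_task_sequence(
            60, (1, 2, 4),
            category_spec=CategorySpec(categories=("a", "b", "c", "d", "e"),
                                       n_blocks=5),
            seed=6,
        )
        session = sf.simulate_responses(model, trials, seed=7)
        nov = trials[trials["exposure"] == "novel"]
        responses = session.spike_counts[:, nov.index.to_numpy()].astype(float)
        labels = nov["category"].to_numpy()
        mat = sf.rsa_matrix(responses)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert mat[same & off].mean() > mat[~same].mean()


class TestPrototypeDecoder:
    def _patterns(self, n_obs=12, per_cat=4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        protos = rng.normal(size=(n_obs, 5))
        responses, labels = [], []
        for c in range(5):
            for _ in range(per_cat):
                responses.append(protos[:, c] + noise * rng.standard_normal(n_obs))
                labels.append(c)
        return np.column_stack(responses), np.array(labels)

    def test_noiseless_distinct_patterns_decode_perfectly(self):
        responses, labels = self._patterns()
        assert sf.prototype_decoder(responses, labels, n_cv=50, seed=1) == 1.0

    def test_permuted_labels_decode_at_chance(self):
        responses, labels = self._patterns(per_cat=10, noise=0.3, seed=2)
        rng = np.random.default_rng(3)
        accs = [
            sf.prototype_decoder(responses, rng.permutation(labels),
                                 n_cv=150, seed=4 + i)
            for i in range(5)
        ]
        assert abs(np.mean(accs) - 0.2) < 0.08

    def test_exact_prototype_match_is_assigned_its_category(self):
        responses, labels = self._patterns(noise=0.0, seed=5)
        # the held-out image equals the prototype of its own category exactly
        acc = sf.prototype_decoder(responses, labels, n_cv=20, seed=6)
        assert acc == 1.0

    def test_category_with_one_image_is_named(self):
        responses, labels = self._patterns()
        labels = labels.copy()
        labels[labels == 4] = 3
        labels[0] = 4  # category 4 now has a single image
        responses = responses
        with pytest.raises(ValueError, match="4"):
            sf.prototype_decoder(responses, labels, n_cv=5, seed=7)

    def test_nearest_centroid_agrees_on_easy_problems(self):
        responses, labels = self._patterns(noise=0.05, seed=8)
        a = sf.prototype_decoder(responses, labels, n_cv=100, seed=9)
        b = sf.nearest_centroid_decoder(responses, labels, n_cv=100, seed=9)
        assert a > 0.9 and b > 0.9
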
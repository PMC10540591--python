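"""Decoders, the repeated-split protocol, and its scoring rules."""

import numpy as np
import pytest
from scipy.stats import norm

import cortdecode as cd
from cortdecode.decoding import DecodingResult, ExperimentConfig
from cortdecode.surface import FeatureMatrix


def _samples(data, labels, groups=None):
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    return FeatureMatrix(
        data=data,
        feature_ids=np.arange(data.shape[1]),
        labels=np.asarray(labels),
        groups=np.arange(len(labels)) if groups is None else np.asarray(groups),
    )


def _separable(n_per_class=8, levels=(1, 2, 3, 4, 5, 6, 7, 8), noise=0.0, seed=0):
    """Each level at its own constant feature vector (optionally noisy)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, lv in enumerate(levels):
        base = np.zeros(len(levels))
        base[i] = 10.0
        for _ in range(n_per_class):
            rows.append(base + noise * rng.standard_normal(len(levels)))
            labels.append(lv)
    return _samples(np.array(rows), labels)


class TestScores:
    def test_rmse_examples(self):
        assert cd.rmse([1, 2], [1, 2]) == 0.0
        assert cd.rmse([1, 8], [8, 1]) == 7.0
        assert np.isclose(cd.rmse([2, 4], [1, 2]), np.sqrt(2.5))
        with pytest.raises(ValueError):
            cd.rmse([], [])

    def test_accuracy_examples(self):
        assert cd.accuracy([1, 2], [1, 2]) == 1.0
        assert cd.accuracy([1, 1, 1, 1], [1, 2, 1, 2]) == 0.5
        # SVR-style prediction 4.5 rounds half away from zero -> 5
        assert cd.accuracy([4.5], [5]) == 1.0
        assert cd.accuracy([4.49], [5]) == 0.0
        # rounding clips to the 1..8 scale
        assert cd.accuracy([8.4], [8]) == 1.0
        with pytest.raises(ValueError):
            cd.accuracy([], [])


class TestSplit:
    def test_fraction_of_reports(self):
        fm = _samples(np.zeros(20), np.tile([1, 2], 10), groups=np.repeat(np.arange(10), 2))
        train, test = cd.split_by_report(fm, 0.2, seed=0)
        test_groups = np.unique(np.asarray(fm.groups)[test])
        assert len(test_groups) == 2
        assert len(train) + len(test) == 20

    def test_reports_never_straddle_the_split(self, small_samples):
        for seed in range(5):
            train, test = cd.split_by_report(small_samples, 0.2, seed)
            tg = set(np.asarray(small_samples.groups)[train])
            sg = set(np.asarray(small_samples.groups)[test])
            assert tg.isdisjoint(sg)
            assert len(train) + len(test) == small_samples.n_samples

    def test_seeds_give_distinct_partitions(self, small_samples):
        seen = set()
        for seed in range(100):
            _, test = cd.split_by_report(small_samples, 0.2, seed)
            seen.add(tuple(test.tolist()))
        assert len(seen) >= 95

    def test_deterministic_per_seed(self, small_samples):
        a = cd.split_by_report(small_samples, 0.2, 7)
        b = cd.split_by_report(small_samples, 0.2, 7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_singleton_class_stays_in_training_with_warning(self):
        labels = [1] * 10 + [8]
        fm = _samples(np.zeros(11), labels, groups=np.arange(11))
        with pytest.warns(UserWarning, match="single report"):
            train, test = cd.split_by_report(fm, 0.2, seed=0)
        assert 10 in train  # the lone level-8 report


class TestTrainDecoder:
    @pytest.mark.parametrize("kind", ["svm", "svr", "mlp"])
    def test_separable_classes_reach_perfect_training_accuracy(self, kind):
        fm = _separable(levels=(2, 6), n_per_class=6)
        cfg = ExperimentConfig(model_kind=kind)
        dec = cd.train_decoder(fm, cfg, seed=0)
        pred = dec.predict(fm.data)
        assert cd.accuracy(pred, fm.labels) == 1.0

    def test_svr_tracks_label_equal_feature(self):
        """SVR on a feature equal to the label: near-zero held-out RMSE."""
        rng = np.random.default_rng(0)
        y = np.tile(np.arange(1, 9), 12)
        x = np.c_[y + 0.001 * rng.standard_normal(len(y))]
        train = _samples(x[:64], y[:64])
        test = _samples(x[64:], y[64:])
        dec = cd.train_decoder(train, ExperimentConfig(model_kind="svr"), seed=0)
        assert cd.rmse(dec.predict(test.data), test.labels) <= 0.1

    def test_svr_predictions_clipped_to_scale(self):
        y = np.tile([1, 8], 10)
        x = np.c_[np.tile([-50.0, 50.0], 10)]
        dec = cd.train_decoder(_samples(x, y), ExperimentConfig(model_kind="svr"), seed=0)
        p = dec.predict(np.array([[500.0], [-500.0]]))
        assert p.max() <= 8.0 and p.min() >= 1.0

    @pytest.mark.parametrize("kind", ["svm", "svr", "mlp"])
    def test_same_seed_same_predictions(self, kind):
        fm = _separable(noise=1.0, seed=3)
        cfg = ExperimentConfig(model_kind=kind)
        p1 = cd.train_decoder(fm, cfg, seed=5).predict(fm.data)
        p2 = cd.train_decoder(fm, cfg, seed=5).predict(fm.data)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        fm = _samples(np.zeros(6), np.full(6, 3))
        with pytest.raises(ValueError, match="single class"):
            cd.train_decoder(fm, ExperimentConfig(), seed=0)


class TestRunExperiment:
    def test_iteration_count_contract(self):
        fm = _separable(n_per_class=6, levels=(1, 4, 8))
        cfg = ExperimentConfig(model_kind="svm", n_iterations=25, base_seed=0)
        res = cd.run_experiment(fm, cfg)
        assert len(res.rmse_per_iter) == 25
        assert len(res.accuracy_per_iter) == 25
        assert np.all(res.rmse_per_iter >= 0)
        assert np.all(res.rmse_per_iter <= 7.0)  # bounded label scale

    def test_perfectly_separable_data_scores_perfectly(self):
        fm = _separable(n_per_class=10)
        cfg = ExperimentConfig(model_kind="svm", n_iterations=5, base_seed=0)
        res = cd.run_experiment(fm, cfg)
        assert res.mean_rmse == 0.0
        assert res.mean_accuracy == 1.0

    def test_signal_strength_never_hurts(self):
        """Stronger effect amplitude does not increase mean RMSE (sign
        test over generator seeds)."""
        import cortdecode.pipeline as pl
        from cortdecode.simulate import SimulationParams

        wins = 0
        for seed in range(5):
            rmses = []
            for amp in (0.0, 0.05):
                mesh, sim = cd.simulate_subject(
                    1, 8.0, 1, 2,
                    params=SimulationParams(seed=seed, effect_amplitude=amp),
                    seed=seed,
                )
                fm = pl.extract_block_samples(
                    sim.runs, mesh, sim.schedule, fwhm_mm=4.0, k_base=42, block_size=5
                )
                cfg = ExperimentConfig(model_kind="svm", n_iterations=3, base_seed=seed)
                rmses.append(cd.run_experiment(fm, cfg).mean_rmse)
            wins += rmses[1] <= rmses[0]
        assert wins >= 4

    def test_group_splitting_is_more_conservative_than_frame_splitting(
        self, small_samples
    ):
        """On autocorrelated data, samples of one report are near-duplicates:
        splitting frames instead of reports leaks and flatters the RMSE."""
        cfg = ExperimentConfig(model_kind="svm", n_iterations=5, base_seed=0)
        grouped = cd.run_experiment(small_samples, cfg).mean_rmse

        rng = np.random.default_rng(0)
        leaky = []
        for i in range(5):
            order = rng.permutation(small_samples.n_samples)
            test = order[: small_samples.n_samples // 5]
            train = order[small_samples.n_samples // 5:]
            dec = cd.train_decoder(small_samples.subset_samples(train), cfg, seed=i)
            pred = dec.predict(small_samples.data[test])
            leaky.append(cd.rmse(pred, np.asarray(small_samples.labels)[test]))
        assert grouped >= np.mean(leaky)


class TestOptimizeFeatureCount:
    def test_single_candidate_returned(self):
        fm = _separable(n_per_class=6, levels=(1, 5, 8))
        cfg = ExperimentConfig(model_kind="svm", n_iterations=3, base_seed=0)
        best, results = cd.optimize_feature_count(fm, cfg, candidates=(3,))
        assert best == 3
        assert set(results) == {3}

    def test_informative_subset_wins(self):
        """Signal concentrated in the first feature: small K beats all-K."""
        rng = np.random.default_rng(1)
        y = np.tile(np.arange(1, 9), 10)
        informative = y + 0.05 * rng.standard_normal(len(y))
        noise = 30.0 * rng.standard_normal((len(y), 30))
        fm = _samples(np.c_[informative, noise], y)
        cfg = ExperimentConfig(model_kind="svm", n_iterations=5, base_seed=0)
        best, results = cd.optimize_feature_count(fm, cfg, candidates=(1, 31))
        assert len(results) == 2
        assert best == 1
        assert results[1].mean_rmse < results[31].mean_rmse

    def test_candidate_exceeding_features_rejected(self):
        fm = _separable(n_per_class=4, levels=(1, 8))
        with pytest.raises(ValueError, match="exceeds"):
            cd.optimize_feature_count(fm, ExperimentConfig(), candidates=(999,))


class TestCompareConditions:
    def _result(self, rmses):
        rmses = np.asarray(rmses, dtype=float)
        return DecodingResult(
            rmse_per_iter=rmses,
            accuracy_per_iter=np.zeros_like(rmses),
            predictions=[], true_labels=[], config=ExperimentConfig(),
        )

    def test_identical_results_give_p_one(self):
        a = self._result(np.linspace(0.4, 0.8, 25))
        assert cd.compare_conditions(a, a).p_value == 1.0
        assert cd.compare_conditions(a, a).direction == "tie"

    def test_constant_shift_matches_normal_approximation_oracle(self):
        """B = A + 1 for n=25: all differences tie in rank; hand-computed
        normal approximation with tie correction (no continuity term)."""
        # binary-exact values so a + 1.0 subtracts back to exactly -1.0
        a = self._result(0.5 + np.arange(25) / 128.0)
        b = self._result(a.rmse_per_iter + 1.0)
        out = cd.compare_conditions(a, b)
        n = 25
        mu = n * (n + 1) / 4
        sigma2 = n * (n + 1) * (2 * n + 1) / 24 - (n**3 - n) / 48
        z = (0 - mu) / np.sqrt(sigma2)
        expect = 2 * norm.cdf(z)
        assert np.isclose(out.p_value, expect, rtol=1e-6)
        assert out.direction == "A<B"

    def test_swapping_flips_direction_keeps_p(self):
        rng = np.random.default_rng(2)
        a = self._result(0.5 + 0.1 * rng.standard_normal(25))
        b = self._result(a.rmse_per_iter + 0.05 + 0.02 * rng.standard_normal(25))
        ab = cd.compare_conditions(a, b)
        ba = cd.compare_conditions(b, a)
        assert np.isclose(ab.p_value, ba.p_value)
        assert {ab.direction, ba.direction} == {"A<B", "A>B"}

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            cd.compare_conditions(self._result([1.0]), self._result([1.0, 2.0]))
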
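import numpy as np
import pytest

from vtlocate import (
    ErrorSummary,
    IntegralVector,
    LabeledSample,
    bootstrap_evaluate,
    compare_projectors,
    evaluate,
    iqr_outliers,
    make_forward_model,
    simulate_dataset,
    split_train_test,
)
from vtlocate.model import RankDeficientWarning


class TestSplit:
    def test_clinical_protocol_sizes(self):
        train, test = split_train_test(1012, 0.8, seed=0)
        assert len(train) == 810 and len(test) == 202

    @pytest.mark.parametrize(
        "n,frac,expected", [(10, 0.8, (8, 2)), (5, 0.5, (3, 2)), (1012, 0.8, (810, 202))]
    )
    def test_round_half_up_sizes(self, n, frac, expected):
        train, test = split_train_test(n, frac, seed=1)
        assert (len(train), len(test)) == expected

    def test_partition_disjoint_and_exhaustive(self):
        train, test = split_train_test(97, 0.8, seed=5)
        union = np.concatenate([train, test])
        assert len(np.intersect1d(train, test)) == 0
        np.testing.assert_array_equal(np.sort(union), np.arange(97))

    def test_too_small_refused(self):
        with pytest.raises(ValueError):
            split_train_test(1, 0.8, seed=0)


class TestEvaluate:
    def test_noiseless_data_gives_zero_error(self, noiseless_dataset, default_mesh):
        train = noiseless_dataset.samples[:100]
        test = noiseless_dataset.samples[100:]
        with pytest.warns(RankDeficientWarning):
            for projector in ("knn", "sa"):
                errors, summ = evaluate(train, test, default_mesh, projector)
                assert summ.gmean == 0.0
                np.testing.assert_array_equal(errors, 0.0)

    def test_summary_self_consistent_with_raw_errors(self, default_dataset, default_mesh):
        train = default_dataset.samples[:800]
        test = default_dataset.samples[800:]
        errors, summ = evaluate(train, test, default_mesh, "knn")
        assert summ.gmean == pytest.approx(np.mean(errors))
        assert summ.gsd == pytest.approx(np.std(errors, ddof=1))
        assert summ.gmedian == pytest.approx(np.median(errors))
        assert summ.pctl5 == pytest.approx(np.percentile(errors, 5))
        assert summ.pctl95 == pytest.approx(np.percentile(errors, 95))
        assert summ.pctl5 <= summ.gmedian <= summ.pctl95
        assert summ.n == len(test)

    def test_matches_independent_pipeline_recomputation(self, default_dataset, default_mesh):
        """End-to-end oracle: rebuild the fit/predict/project/measure chain
        from primitive numpy operations and compare summaries."""
        train = default_dataset.samples[:810]
        test = default_dataset.samples[810:]
        errors, _ = evaluate(train, test, default_mesh, "knn", "geodesic")

        X = np.column_stack(
            [np.ones(len(train)), [s.integrals.values for s in train]]
        )
        Y = np.array([s.target for s in train])
        W, *_ = np.linalg.lstsq(X, Y, rcond=None)
        expected = []
        cc = default_mesh.cavity_center
        for s in test:
            p = W[0] + s.integrals.values @ W[1:]
            d2 = ((default_mesh.centroids - p) ** 2).sum(axis=1)
            est = int(np.argmin(d2))
            va = default_mesh.centroids[est] - cc
            vb = default_mesh.centroid_of(s.true_element) - cc
            ra, rb = np.linalg.norm(va), np.linalg.norm(vb)
            cos = np.clip(va @ vb / (ra * rb), -1, 1)
            expected.append((ra + rb) / 2 * np.arccos(cos))
        np.testing.assert_allclose(errors, expected, rtol=1e-10, atol=1e-6)

    def test_forced_single_error(self, default_mesh):
        """One test sample whose integrals come from a different element
        than its label produces exactly that geodesic distance."""
        model = make_forward_model(seed=2, noise_sd=0, jitter_sd=0, scatter_sd=0)
        ds = simulate_dataset(default_mesh, model, 120, seed=2)
        wrong = LabeledSample(ds.samples[0].integrals, true_element=99)
        from vtlocate import geodesic_distance

        with pytest.warns(RankDeficientWarning):
            errors, summ = evaluate(
                ds.samples[1:], [wrong], default_mesh, "knn"
            )
        d = geodesic_distance(default_mesh, ds.samples[0].true_element, 99)
        assert summ.gmean == pytest.approx(d)
        assert summ.gsd == 0.0
        assert summ.n == 1

    def test_overlapping_sets_warn(self, default_dataset, default_mesh):
        s = default_dataset.samples[:50]
        with pytest.warns(UserWarning, match="overlap"):
            evaluate(s, s[:10], default_mesh, "knn")


class TestBootstrap:
    def test_reproducible_given_seed(self, default_mesh):
        model = make_forward_model(seed=4)
        ds = simulate_dataset(default_mesh, model, 80, seed=4)
        a = bootstrap_evaluate(ds.samples, default_mesh, n_trials=20, seed=11)
        b = bootstrap_evaluate(ds.samples, default_mesh, n_trials=20, seed=11)
        assert a.trials.equals(b.trials)
        assert a.table.equals(b.table)

    def test_mean_oob_fraction_near_1_over_e(self, default_mesh):
        model = make_forward_model(seed=6)
        ds = simulate_dataset(default_mesh, model, 100, seed=6)
        res = bootstrap_evaluate(ds.samples, default_mesh, n_trials=200, seed=3)
        expected = 100 * (1 - 1 / 100) ** 100  # 36.6
        # binomial-ish SE of the per-trial OOB count, 3 SE band
        se = np.sqrt(100 * 0.37 * 0.63) / np.sqrt(200)
        assert abs(res.mean_oob_size - expected) < 3 * max(se, 1.0)

    def test_noiseless_bootstrap_all_zero(self, default_mesh):
        model = make_forward_model(seed=5, noise_sd=0, jitter_sd=0, scatter_sd=0)
        ds = simulate_dataset(default_mesh, model, 60, seed=5)
        with pytest.warns(RankDeficientWarning):
            res = bootstrap_evaluate(ds.samples, default_mesh, n_trials=10, seed=0)
        assert (res.trials["gmean"] == 0).all()

    def test_small_n_refused(self, default_mesh):
        model = make_forward_model(seed=5)
        ds = simulate_dataset(default_mesh, model, 5, seed=5)
        with pytest.raises(ValueError):
            bootstrap_evaluate(ds.samples, default_mesh, n_trials=5, seed=0)

    def test_noise_ladder_does_not_reduce_error(self, default_mesh):
        """Common-random-numbers noise ladder: more integral noise never
        shrinks the median per-trial mean error."""
        medians = []
        for noise in (0.0, 8.0, 20.0):
            model = make_forward_model(seed=8, noise_sd=noise, scatter_sd=4.0)
            ds = simulate_dataset(default_mesh, model, 300, seed=8)
            res = bootstrap_evaluate(
                ds.samples, default_mesh, n_trials=30, seed=8
            )
            medians.append(res.trials["gmean"].median())
        assert medians[0] <= medians[1] <= medians[2]


class TestComparison:
    def test_identical_errors_degenerate(self):
        e = np.array([1.0, 2, 3, 4, 5, 6])
        res = compare_projectors(e, e)
        assert res.degenerate and res.p_value == 1.0 and res.mean_diff == 0.0

    def test_unit_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(2, 20, 50)
        res = compare_projectors(a, a + 1.0)
        assert res.p_value < 1e-3
        assert res.mean_diff == pytest.approx(-1.0)
        assert res.mean_diff_ci[0] <= -1.0 <= res.mean_diff_ci[1]

    def test_length_mismatch_and_short_input_refused(self):
        with pytest.raises(ValueError):
            compare_projectors(np.ones(5), np.ones(6))
        with pytest.raises(ValueError):
            compare_projectors(np.ones(3), np.ones(3))


class TestIqrOutliers:
    def test_textbook_example(self):
        flags, fences = iqr_outliers(np.array([1.0, 2, 3, 4, 100]))
        np.testing.assert_array_equal(flags, [False] * 4 + [True])
        q1, q3 = np.percentile([1, 2, 3, 4, 100], [25, 75])
        assert fences == (q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1))

    def test_constant_sequence_no_outliers(self):
        flags, _ = iqr_outliers(np.full(10, 3.0))
        assert not flags.any()

    def test_affine_invariance_of_flags(self):
        rng = np.random.default_rng(12)
        v = rng.normal(0, 1, 60)
        v[:3] += 15
        f0, _ = iqr_outliers(v)
        f1, _ = iqr_outliers(4.0 * v - 7.0)
        np.testing.assert_array_equal(f0, f1)

    def test_fewer_than_four_refused(self):
        with pytest.raises(ValueError):
            iqr_outliers(np.array([1.0, 2, 3]))
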
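import numpy as np
import pytest

from breedtrace import (
    ThresholdRule,
    apply_threshold,
    assignment_summary,
    fit_cda,
    predict,
)
from breedtrace.datatypes import GenotypeError

from conftest import make_dataset
from oracles import bayes_posteriors


def gaussian_classes(rng, means, n_per_class, cov=None):
    """Sample labelled Gaussian data with a shared covariance."""
    p = len(means[0])
    cov = np.eye(p) if cov is None else cov
    xs, labels = [], []
    for k, mu in enumerate(means):
        xs.append(rng.multivariate_normal(mu, cov, size=n_per_class))
        labels += [f"c{k}"] * n_per_class
    return np.vstack(xs), labels


class TestFitCDA:
    def test_univariate_decision_boundary_at_midpoint(self):
        rng = np.random.default_rng(0)
        x, labels = gaussian_classes(rng, [[0.0], [4.0]], 400)
        model = fit_cda(x, labels, priors="equal")
        post = predict(model, np.array([[2.0], [1.9], [2.1]])).posteriors
        # at the midpoint the posterior splits by the *estimated* means;
        # check the boundary is near 2 by bracketing
        assert post[1, 0] > 0.5 > post[2, 0]
        assert post[0, 0] == pytest.approx(0.5, abs=0.05)

    def test_canonical_axes_match_direct_eigendecomposition(self):
        rng = np.random.default_rng(1)
        x, labels = gaussian_classes(
            rng, [[0, 0], [6, 0], [0, 6]], 100
        )
        model = fit_cda(x, labels)
        assert model.canonical_axes.shape == (2, 2)
        assert model.canonical_eigenvalues[0] >= model.canonical_eigenvalues[1] > 0
        # independent oracle: eig of inv(SW) @ SB
        sw = model.pooled_within_covariance
        lab = np.array(labels)
        grand = x.mean(axis=0)
        sb = np.zeros((2, 2))
        for cls in sorted(set(labels)):
            rows = x[lab == cls]
            d = rows.mean(axis=0) - grand
            sb += rows.shape[0] * np.outer(d, d)
        sb /= len(set(labels)) - 1
        eigval = np.sort(np.linalg.eigvals(np.linalg.inv(sw) @ sb).real)[::-1]
        assert np.allclose(model.canonical_eigenvalues, eigval, rtol=1e-8)

    def test_constant_column_raises_unless_ridge(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        labels = ["a", "a", "b", "b"]
        with pytest.raises(ValueError, match="ridge"):
            fit_cda(x, labels)
        model = fit_cda(x, labels, ridge=1e-6)
        assert np.isfinite(model.pooled_within_covariance).all()

    def test_class_with_single_member_rejected(self):
        x = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="member"):
            fit_cda(x, ["a", "a", "b"])

    def test_missing_genotypes_rejected(self, tiny_two_pop):
        with pytest.raises(GenotypeError, match="missing"):
            fit_cda(tiny_two_pop)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        x, labels = gaussian_classes(rng, [[0, 0], [3, 1]], 50)
        perm = rng.permutation(len(labels))
        m1 = fit_cda(x, labels)
        m2 = fit_cda(x[perm], [labels[i] for i in perm])
        assert np.allclose(m1.class_means, m2.class_means)
        assert np.allclose(
            m1.pooled_within_covariance, m2.pooled_within_covariance
        )
        assert np.allclose(
            np.abs(m1.canonical_axes), np.abs(m2.canonical_axes), atol=1e-8
        )

    def test_matches_sklearn_lda_posteriors(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(3)
        x, labels = gaussian_classes(rng, [[0, 0, 0], [2, 1, 0], [0, 2, 2]], 40)
        model = fit_cda(x, labels)
        ours = predict(model, x).posteriors
        lda = sklearn.LinearDiscriminantAnalysis(solver="svd")
        lda.fit(x, labels)
        # sklearn uses 1/(n-c) pooled covariance as well
        assert np.allclose(ours, lda.predict_proba(x), atol=1e-6)


class TestPredict:
    def test_class_mean_gets_top_posterior(self):
        rng = np.random.default_rng(4)
        x, labels = gaussian_classes(rng, [[0, 0], [5, 5]], 100)
        model = fit_cda(x, labels, priors="equal")
        res = predict(model, model.class_means)
        assert res.predicted == ["c0", "c1"]
        assert (res.max_posterior > 0.99).all()

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(5)
        x, labels = gaussian_classes(rng, [[0, 0], [1, 2], [3, 0]], 30)
        res = predict(fit_cda(x, labels), x)
        assert np.allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_dense_bayes_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            means = rng.normal(size=(5, 20))
            x, labels = gaussian_classes(rng, means, 50)
            model = fit_cda(x, labels)
            test = rng.normal(size=(30, 20)) + means[rng.integers(5, size=30)]
            ours = predict(model, test).posteriors
            oracle = bayes_posteriors(
                test, model.class_means, model.pooled_within_covariance,
                model.priors,
            )
            assert np.max(np.abs(ours - oracle)) < 1e-10

    def test_equidistant_tie_breaks_lexicographically(self):
        model = fit_cda(
            np.array([[0.0], [0.2], [3.8], [4.0]]), ["b", "b", "a", "a"],
            priors="equal",
        )
        res = predict(model, np.array([[2.0]]))
        assert res.posteriors[0] == pytest.approx([0.5, 0.5], abs=1e-12)
        assert res.predicted == ["a"]

    def test_dimension_mismatch_rejected(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0], [4.0, 4.0], [5.0, 5.0]])
        model = fit_cda(x, ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="variables"):
            predict(model, np.array([[1.0]]))

    def test_separability_limit_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(7)
        rates = []
        for sep in (0.5, 2.0, 8.0):
            x, labels = gaussian_classes(
                rng, [[0, 0], [sep, 0], [0, sep]], 60
            )
            res = predict(fit_cda(x, labels), x)
            rates.append(np.mean([p == t for p, t in zip(res.predicted, labels)]))
        assert rates == sorted(rates)
        assert rates[-1] == 1.0


class TestThreshold:
    def make_result(self, max_posts, predicted):
        from breedtrace.breed_assignment import AssignmentResult

        classes = sorted(set(predicted) | {"HY", "NS"})
        n, c = len(predicted), len(classes)
        post = np.full((n, c), 0.0)
        for i, (mp, pred) in enumerate(zip(max_posts, predicted)):
            k = classes.index(pred)
            post[i, k] = mp
            rest = (1 - mp) / (c - 1)
            post[i, [j for j in range(c) if j != k]] = rest
        return AssignmentResult(
            sample_ids=[f"s{i}" for i in range(n)],
            classes=classes,
            posteriors=post,
            predicted=list(predicted),
            max_posterior=np.array(max_posts),
        )

    def test_confident_call_kept(self):
        res = apply_threshold(self.make_result([0.70], ["NS"]))
        assert res.thresholded == ["NS"]

    def test_low_confidence_reassigned_to_hybrid(self):
        res = apply_threshold(self.make_result([0.5493], ["NS"]))
        assert res.thresholded == ["HY"]

    def test_tau_to_zero_limit_keeps_all(self):
        res = apply_threshold(
            self.make_result([0.34, 0.51], ["NS", "DU"]),
            ThresholdRule(tau=1e-9),
        )
        assert res.thresholded == res.predicted

    def test_monotone_in_tau(self):
        mps = list(np.linspace(0.3, 0.99, 20))
        preds = ["NS"] * 20
        kept_counts = []
        for tau in (0.4, 0.65, 0.9):
            res = apply_threshold(self.make_result(mps, preds), ThresholdRule(tau=tau))
            kept_counts.append(sum(t != "HY" for t in res.thresholded))
        assert kept_counts == sorted(kept_counts, reverse=True)

    def test_predicted_hybrids_unchanged(self):
        res = apply_threshold(self.make_result([0.4], ["HY"]))
        assert res.thresholded == ["HY"]

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            ThresholdRule(tau=1.0)


class TestAssignmentSummary:
    def test_all_correct(self):
        rng = np.random.default_rng(8)
        x, labels = gaussian_classes(rng, [[0, 0], [9, 9]], 40)
        res = predict(fit_cda(x, labels), x)
        summ = assignment_summary(res, labels)
        assert summ.overall_rate == 1.0
        assert (summ.table.wrong_destinations == "").all()

    def test_rate_recomputed_from_counts(self):
        # 284 correct of 300 -> 94.7%
        from breedtrace.breed_assignment import AssignmentResult

        n = 300
        truth = ["NS"] * n
        predicted = ["NS"] * 284 + ["WB"] * 16
        post = np.tile([0.9, 0.1], (n, 1))
        res = AssignmentResult(
            sample_ids=[f"s{i}" for i in range(n)],
            classes=["NS", "WB"],
            posteriors=post,
            predicted=predicted,
            max_posterior=post.max(axis=1),
        )
        summ = assignment_summary(res, truth)
        assert summ.overall_rate == pytest.approx(284 / 300)
        assert round(100 * summ.overall_rate, 1) == 94.7
        assert summ.table.loc["NS", "wrong_destinations"].startswith("WB")

    def test_empty_cohort_rejected(self):
        rng = np.random.default_rng(9)
        x, labels = gaussian_classes(rng, [[0], [4]], 10)
        res = predict(fit_cda(x, labels), x)
        with pytest.raises(GenotypeError):
            assignment_summary(
                type(res)(
                    sample_ids=[], classes=res.classes,
                    posteriors=np.empty((0, 2)), predicted=[],
                    max_posterior=np.empty(0),
                ),
                [],
            )

    def test_truth_length_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        x, labels = gaussian_classes(rng, [[0], [4]], 10)
        res = predict(fit_cda(x, labels), x)
        with pytest.raises(ValueError):
            assignment_summary(res, labels[:-1])
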
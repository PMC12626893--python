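import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from helixcharge import (
    CompositionLDA,
    SyntheticConfig,
    aa_frequencies,
    accuracy,
    composition_matrix,
    generate,
    split_fit_evaluate,
    stratified_split,
)
from helixcharge.io import STANDARD_AA


class TestFrequencies:
    def test_two_residue_segment(self):
        cv = aa_frequencies("KKRR")
        assert cv.freq[STANDARD_AA.index("K")] == 0.5
        assert cv.freq[STANDARD_AA.index("R")] == 0.5
        assert cv.freq.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_four_residues(self):
        cv = aa_frequencies("MKDE")
        for a in "MKDE":
            assert cv.freq[STANDARD_AA.index(a)] == 0.25

    def test_x_and_gaps_excluded_everywhere(self):
        cv = aa_frequencies("MXK-")
        assert cv.n_res == 2
        assert cv.freq[STANDARD_AA.index("M")] == 0.5

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            aa_frequencies("XX--")


class TestSplit:
    def test_thirty_percent_per_class(self):
        y = np.repeat(["a", "b", "c"], 100)
        train, test = stratified_split(y, 0.3, seed=1)
        for cls in "abc":
            assert (y[train] == cls).sum() == 30
        assert len(set(train) & set(test)) == 0
        assert len(train) + len(test) == 300

    def test_deterministic(self):
        y = np.repeat(["a", "b"], 20)
        s1 = stratified_split(y, 0.3, seed=7)
        s2 = stratified_split(y, 0.3, seed=7)
        assert np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])

    def test_rounding_rule(self):
        y = np.array(["a"] * 10 + ["b"] * 7)
        train, _ = stratified_split(y, 0.3, seed=0)
        assert (y[train] == "a").sum() == 3  # round(3.0)
        assert (y[train] == "b").sum() == 2  # round(2.1)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="single member"):
            stratified_split(np.array(["a", "a", "b"]), 0.3, seed=0)


class TestFit:
    def test_two_class_closed_form_direction(self):
        # isotropic unit covariance, means (0,0) and (1,0): the discriminant
        # direction is Sigma^-1 (mu2 - mu1), i.e. the first axis
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (500, 2)), rng.normal(0, 1, (500, 2)) + [1, 0]])
        y = np.repeat([0, 1], 500)
        model = CompositionLDA(ridge=1e-9).fit(X, y)
        w = model.scalings_[:, 0]
        assert abs(w[0]) / np.linalg.norm(w) > 0.97

    def test_label_permutation_flips_axes_only_in_sign(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(1, 1, (100, 3))])
        y = np.repeat([0, 1], 100)
        w1 = CompositionLDA().fit(X, y).scalings_[:, 0]
        w2 = CompositionLDA().fit(X, 1 - y).scalings_[:, 0]
        assert np.allclose(np.abs(w1), np.abs(w2), atol=1e-8)

    def test_identical_distributions_near_zero_eigenvalue(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (4000, 5))
        y = np.repeat([0, 1], 2000)
        model = CompositionLDA().fit(X, y)
        assert model.eigenvalues_[0] < 0.01

    def test_singular_covariance_needs_ridge(self):
        rng = np.random.default_rng(3)
        # compositional rows (sum to one) make S_W singular
        X = rng.dirichlet(np.ones(5), size=60)
        y = np.repeat([0, 1, 2], 20)
        with pytest.raises(ValueError, match="ridge"):
            CompositionLDA(ridge=0.0).fit(X, y)
        CompositionLDA(ridge=1e-6).fit(X, y)  # and the ridge fixes it

    def test_axes_sw_orthogonal(self, default_dataset):
        ids, X = composition_matrix({k: v[0] for k, v in default_dataset.segments.items()})
        y = np.array([default_dataset.families[i] for i in ids])
        m = CompositionLDA().fit(X, y)
        gram = m.scalings_.T @ m.covariance_ @ m.scalings_
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_fisher_ratio_maximized_over_random_directions(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (200, 6)), rng.normal(0.8, 1, (200, 6))])
        y = np.repeat([0, 1], 200)
        model = CompositionLDA(ridge=1e-9).fit(X, y)

        mu = [X[y == k].mean(axis=0) for k in (0, 1)]
        Sw = sum((X[y == k] - mu[k]).T @ (X[y == k] - mu[k]) for k in (0, 1))
        d = mu[1] - mu[0]

        def fisher(w):
            return float((w @ d) ** 2 / (w @ Sw @ w))

        best = fisher(model.scalings_[:, 0])
        dirs = rng.normal(size=(1000, 6))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert all(fisher(w) <= best + 1e-6 for w in dirs)


class TestClassify:
    def test_training_accuracy_on_separated_classes(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (50, 4)), rng.normal(3, 0.1, (50, 4))])
        y = np.repeat(["lo", "hi"], 50)
        model = CompositionLDA().fit(X, y)
        assert model.score(X, y) == 1.0

    def test_chance_level_on_identical_distributions(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (3000, 4))
        y = rng.choice(["a", "b"], size=3000, p=[0.6, 0.4])  # max prior 0.6
        model = CompositionLDA().fit(X[:1000], y[:1000])
        acc = model.score(X[1000:], y[1000:])
        assert abs(acc - 0.6) < 0.05

    def test_shuffled_labels_score_at_majority_frequency(self, default_dataset):
        ids, X = composition_matrix({k: v[0] for k, v in default_dataset.segments.items()})
        rng = np.random.default_rng(7)
        y = rng.permutation(np.array([default_dataset.families[i] for i in ids]))
        res = split_fit_evaluate(X, y, seed=7)
        majority = max(np.bincount(np.unique(y, return_inverse=True)[1])) / len(y)
        assert abs(res["accuracy_heldout"] - majority) < 0.08

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(1, 1, (100, 4))])
        y = np.repeat([0, 1], 100)
        model = CompositionLDA().fit(X, y)
        shifted = CompositionLDA().fit(X + 5.0, y)
        assert np.array_equal(model.predict(X), shifted.predict(X + 5.0))

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 4))
        y = np.repeat([0, 1], 20)
        model = CompositionLDA().fit(X, y)
        with pytest.raises(ValueError, match="features"):
            model.predict(rng.normal(size=(5, 3)))

    def test_accuracy_function(self):
        assert accuracy(["a", "b", "a"], ["a", "b", "b"]) == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            accuracy(["a"], ["a", "b"])


class TestContributions:
    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (400, 5))
        y = np.repeat([0, 1], 200)
        X[y == 1, 2] += 3.0
        c = CompositionLDA().fit(X, y).feature_contributions()
        assert np.argmax(c) == 2 and c[2] > 2 * np.max(np.delete(c, 2))

    def test_equal_class_means_near_zero(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (4000, 4))
        y = np.repeat([0, 1], 2000)
        c = CompositionLDA().fit(X, y).feature_contributions()
        # leading eigenvalue is ~0, shares are ill-defined but loadings stay bounded
        assert np.all(c >= 0)

    def test_charged_residues_lead_on_composition_shift(self):
        # composition-shift mode concentrates the signal in D/E/K/R
        ds = generate(SyntheticConfig(seed=5, couple_to_trait=False))
        ids, X = composition_matrix({k: v[0] for k, v in ds.segments.items()})
        y = np.array([ds.families[i] for i in ids])
        c = CompositionLDA().fit(X, y).feature_contributions()
        top4 = {STANDARD_AA[i] for i in np.argsort(c)[::-1][:4]}
        assert {"D", "E", "K", "R"} == top4


class TestSklearnCrossCheck:
    def test_agreement_with_reference_implementation(self, default_dataset):
        ids, X = composition_matrix({k: v[0] for k, v in default_dataset.segments.items()})
        y = np.array([default_dataset.families[i] for i in ids])
        ours = CompositionLDA().fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        assert np.mean(ours.predict(X) == ref.predict(X)) >= 0.99
        r = np.corrcoef(ours.transform(X)[:, 0], ref.transform(X)[:, 0])[0, 1]
        assert abs(r) > 0.999

    def test_sklearn_estimator_protocol(self):
        model = CompositionLDA(ridge=1e-5)
        assert model.get_params() == {"ridge": 1e-5, "n_components": None}
        model.set_params(ridge=1e-4)
        assert model.get_params()["ridge"] == 1e-4
        from sklearn.model_selection import cross_val_score

        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(3, 1, (60, 3))])
        y = np.repeat([0, 1], 60)
        scores = cross_val_score(CompositionLDA(), X, y, cv=3)
        assert scores.mean() > 0.95
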
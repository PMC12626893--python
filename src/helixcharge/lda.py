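"""Linear discriminant analysis of amino-acid composition, from scratch.

The classifier that separates paralogue families by the residue make-up of
their N-terminal helices. Implemented as a scikit-learn estimator
(``fit`` / ``predict`` / ``transform``, ``get_params`` / ``set_params``) so it
composes with sklearn pipelines and model selection; sklearn's own LDA is
used only as an independent cross-check in the test suite.

Compositional frequency vectors sum to one and are therefore collinear, so
the pooled within-class covariance receives a small ridge on its diagonal
(surfaced as ``ridge``, default 1e-6) rather than being regularized silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import STANDARD_AA


@dataclass
class CompositionVector:
    """Amino-acid frequencies of a residue segment (X and gaps uncounted)."""

    freq: np.ndarray  # length 20, order STANDARD_AA
    n_res: int


def aa_frequencies(segment: str) -> CompositionVector:
    """Frequencies over the 20 standard residues; gaps and X are excluded
    from numerator and denominator alike."""
    counts = np.zeros(20)
    index = {a: i for i, a in enumerate(STANDARD_AA)}
    n = 0
    for c in segment:
        i = index.get(c)
        if i is not None:
            counts[i] += 1
            n += 1
    if n == 0:
        raise ValueError("segment has no countable residues")
    return CompositionVector(freq=counts / n, n_res=n)


def composition_matrix(segments: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Stack per-sequence composition vectors into an (n, 20) matrix."""
    ids = list(segments)
    X = np.vstack([aa_frequencies(segments[sid]).freq for sid in ids])
    return ids, X


def stratified_split(
    labels: np.ndarray | list, train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test split.

    Per class, round(n_k * train_frac) training members (at least 1 train and
    1 test member per class). Classes of size 1 are an error.
    """
    if not (0 < train_frac < 1):
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has a single member; cannot split")
        n_train = int(round(idx.size * train_frac))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


class CompositionLDA(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Linear discriminant analysis with a ridge-regularized pooled covariance.

    Parameters
    ----------
    ridge : float
        Value added to the diagonal of the pooled within-class covariance.
        Must be > 0 for compositional features (they are collinear).
    n_components : int or None
        Number of discriminant axes to keep; capped at min(K - 1, p).

    Attributes
    ----------
    classes_ : (K,) array of class labels.
    means_ : (K, p) class mean vectors.
    covariance_ : (p, p) pooled within-class covariance plus ridge.
    scalings_ : (p, n_components) discriminant axes, unit Euclidean norm,
        S_W-orthogonal, ordered by non-increasing eigenvalue.
    eigenvalues_ : discriminant eigenvalues (between/within variance ratios).
    priors_ : empirical class priors.
    """

    def __init__(self, ridge: float = 1e-6, n_components: int | None = None):
        self.ridge = ridge
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in sample count")
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least two classes")
        n, p = X.shape
        counts = np.bincount(y_idx, minlength=classes.size)
        if np.any(counts < 2):
            small = classes[counts < 2][0]
            raise ValueError(f"class {small!r} has fewer than 2 samples")

        means = np.vstack([X[y_idx == k].mean(axis=0) for k in range(classes.size)])
        priors = counts / n

        # pooled within-class covariance (ML pooling over n) + ridge
        Sw = np.zeros((p, p))
        for k in range(classes.size):
            diff = X[y_idx == k] - means[k]
            Sw += diff.T @ diff
        Sw /= n
        if self.ridge <= 0:
            cond = np.linalg.cond(Sw)
            if not np.isfinite(cond) or cond > 1e12:
                raise ValueError(
                    "pooled within-class covariance is singular; compositional "
                    "features are collinear — set ridge > 0"
                )
        Sw_r = Sw + self.ridge * np.eye(p)

        # prior-weighted between-class scatter of the means
        grand = priors @ means
        centered = means - grand
        Sb = (centered.T * priors) @ centered

        eigvals, eigvecs = linalg.eigh(Sb, Sw_r)
        order = np.argsort(eigvals)[::-1]
        max_axes = min(classes.size - 1, p)
        if self.n_components is not None:
            max_axes = min(max_axes, self.n_components)
        eigvals = np.clip(eigvals[order][:max_axes], 0.0, None)
        W = eigvecs[:, order][:, :max_axes]
        W = W / np.linalg.norm(W, axis=0, keepdims=True)

        self.classes_ = classes
        self.means_ = means
        self.covariance_ = Sw_r
        self.scalings_ = W
        self.eigenvalues_ = eigvals
        self.priors_ = priors
        self.n_features_in_ = p
        # cache for the Gaussian discriminant: Sigma^-1 mu_k and constants
        self._sigma_inv_means = np.linalg.solve(Sw_r, means.T).T
        self._const = (
            -0.5 * np.einsum("kp,kp->k", means, self._sigma_inv_means)
            + np.log(priors)
        )
        return self

    def decision_function(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        return X @ self._sigma_inv_means.T + self._const

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def transform(self, X):
        """Project onto the discriminant axes (for ordination plots)."""
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        return X @ self.scalings_

    def score(self, X, y):
        return accuracy(self.predict(X), np.asarray(y))

    def feature_contributions(self) -> np.ndarray:
        """Per-feature contribution: the norm of the feature's loadings across
        the retained axes, each axis weighted by its eigenvalue share."""
        check_is_fitted(self, "classes_")
        total = self.eigenvalues_.sum()
        share = (
            self.eigenvalues_ / total
            if total > 0
            else np.zeros_like(self.eigenvalues_)
        )
        return np.sqrt((self.scalings_**2 * share) @ np.ones(len(share)))


def accuracy(pred, truth) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return float(np.mean(pred == truth))


def fit_lda(X, y, ridge: float = 1e-6) -> CompositionLDA:
    """Functional wrapper over :class:`CompositionLDA`."""
    return CompositionLDA(ridge=ridge).fit(X, y)


def split_fit_evaluate(
    X,
    y,
    *,
    train_frac: float = 0.3,
    seed: int = 20240131,
    ridge: float = 1e-6,
) -> dict:
    """Stratified split, fit on the training fraction, report held-out and
    resubstitution accuracy (both, because which one a published "~95%"
    refers to is rarely stated)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    train, test = stratified_split(y, train_frac, seed)
    model = CompositionLDA(ridge=ridge).fit(X[train], y[train])
    return {
        "model": model,
        "train_idx": train,
        "test_idx": test,
        "accuracy_heldout": accuracy(model.predict(X[test]), y[test]),
        "accuracy_resubstitution": accuracy(model.predict(X[train]), y[train]),
    }
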
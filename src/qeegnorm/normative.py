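"""Normative reference space: robust scaling + sparse PCA.

The reference (typically developing) cohort defines a low-dimensional
space of spectro-spatial EEG features.  Each feature is centered on the
reference median and scaled by the reference interquartile range; the
scaled reference matrix is decomposed with an l1-penalized (sparse) PCA
so each component loads on a subset of features.  Patient cohorts are
scaled with the *reference* parameters and projected onto the same
loadings — the space is fitted on reference rows only.

Because sparse components are not exactly orthogonal, explained variance
uses the adjusted-variance convention: component scores are sequentially
orthogonalized (QR) and each component is credited only with the
variance not already explained by earlier ones.
"""

from __future__ import annotations

import json
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import SparsePCA
from sklearn.utils.validation import check_is_fitted


class RobustFeatureScaler(BaseEstimator, TransformerMixin):
    """Median/IQR scaler fitted on reference rows only.

    After ``transform`` the reference matrix has per-feature median 0 and
    IQR 1; any other cohort is scaled with the reference parameters.
    """

    def fit(self, X, y=None):
        X = self._as_array(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 reference rows to fit the scaler")
        self.median_ = np.median(X, axis=0)
        q75, q25 = np.percentile(X, [75, 25], axis=0)
        self.iqr_ = q75 - q25
        bad = np.nonzero(self.iqr_ == 0)[0]
        if bad.size:
            name = self.feature_names_in_[bad[0]] if hasattr(self, "feature_names_in_") else bad[0]
            raise ValueError(f"feature {name!r} has zero interquartile range")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "median_")
        X = self._as_array(X)
        return (X - self.median_) / self.iqr_

    def _as_array(self, X):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


class NormativeSpace(BaseEstimator, TransformerMixin):
    """Sparse-PCA decomposition of the scaled reference cohort.

    Parameters
    ----------
    n_components : int, default 5
    sparsity : float, default 1.5
        The l1 penalty weight of the elastic-net sparse-PCA formulation.
        At 1.5 the loadings are qualitatively sparse (roughly a third to
        two thirds of entries exactly zero on realistic cohorts); at 0
        the solution coincides with classical PCA.
    ridge_alpha : float, default 0.01
        Small l2 term stabilizing the score regression.
    random_state : int, default 0
        Seed for the alternating-minimization solver.

    Attributes
    ----------
    components_ : ndarray (n_components, n_features)
        Sparse loading vectors, ordered by explained variance, each
        sign-fixed so its largest-magnitude loading is positive.
    explained_variance_ratio_ : ndarray (n_components,)
        Adjusted-variance fractions (nonincreasing).
    """

    def __init__(self, n_components=5, sparsity=1.5, ridge_alpha=0.01,
                 max_iter=2000, tol=1e-8, random_state=0):
        self.n_components = n_components
        self.sparsity = sparsity
        self.ridge_alpha = ridge_alpha
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = self._validate(X)
        n, p = X.shape
        if p >= n:
            raise ValueError(
                f"{p} features but only {n} reference subjects; stable "
                "covariance estimation requires more subjects than features"
            )
        if not 1 <= self.n_components <= p:
            raise ValueError("n_components must be in [1, n_features]")
        model = SparsePCA(
            n_components=self.n_components,
            alpha=self.sparsity,
            ridge_alpha=self.ridge_alpha,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
            method="lars",
        )
        model.fit(X)
        V = model.components_.copy()  # (k, p)
        # normalize each loading vector (harmless for alpha=0 PCA limit)
        norms = np.linalg.norm(V, axis=1)
        if np.any(norms == 0):
            raise ValueError("sparse PCA produced an all-zero component; lower sparsity")
        V /= norms[:, None]
        # order components by individual projected variance, then credit
        # shared variance sequentially (adjusted variance, QR convention)
        scores = X @ V.T
        order = np.argsort(-np.var(scores, axis=0, ddof=1))
        V = V[order]
        adj = _adjusted_variance(X, V)
        # sign convention: largest-|loading| entry positive
        for k in range(V.shape[0]):
            j = np.argmax(np.abs(V[k]))
            if V[k, j] < 0:
                V[k] *= -1
        self.components_ = V
        total = np.sum(np.var(X, axis=0, ddof=1))
        self.explained_variance_ = adj
        self.explained_variance_ratio_ = adj / total
        self.n_features_in_ = p
        self.n_samples_fit_ = n
        return self

    def transform(self, X):
        """Project (already scaled) rows onto all components."""
        check_is_fitted(self, "components_")
        X = self._validate(X)
        return X @ self.components_.T

    def project_pair(self, X, pair: tuple[int, int]) -> np.ndarray:
        """2-D scores of rows on a distinct pair of components (0-based)."""
        i, j = pair
        if i == j:
            raise ValueError("pair indices must be distinct")
        scores = self.transform(X)
        k = scores.shape[1]
        if not (0 <= i < k and 0 <= j < k):
            raise ValueError(f"pair {pair} outside the {k} fitted components")
        return scores[:, [i, j]]

    def component_pairs(self) -> list[tuple[int, int]]:
        """All distinct component pairs (10 pairs for 5 components)."""
        check_is_fitted(self, "components_")
        return list(combinations(range(self.components_.shape[0]), 2))

    def sparsity_fraction(self) -> float:
        """Fraction of exactly-zero loadings across all components."""
        check_is_fitted(self, "components_")
        return float(np.mean(self.components_ == 0))

    def _validate(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        return X


def _adjusted_variance(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Sequential (QR-orthogonalized) variance credited to each component."""
    scores = X @ V.T
    q, r = np.linalg.qr(scores)
    return np.diag(r) ** 2 / (X.shape[0] - 1)


def fit_normative_space(
    reference_features: pd.DataFrame | np.ndarray,
    n_components: int = 5,
    sparsity: float = 1.5,
    random_state: int = 0,
) -> tuple[RobustFeatureScaler, NormativeSpace]:
    """Convenience: fit scaler + sparse PCA on the reference cohort."""
    scaler = RobustFeatureScaler().fit(reference_features)
    space = NormativeSpace(
        n_components=n_components, sparsity=sparsity, random_state=random_state
    ).fit(scaler.transform(reference_features))
    return scaler, space


def save_space(path, scaler: RobustFeatureScaler, space: NormativeSpace) -> None:
    """Serialize the fitted scaler and space as JSON."""
    payload = {
        "scaler": {"median": scaler.median_.tolist(), "iqr": scaler.iqr_.tolist()},
        "components": space.components_.tolist(),
        "explained_variance_ratio": space.explained_variance_ratio_.tolist(),
        "config": {
            "n_components": space.n_components,
            "sparsity": space.sparsity,
            "random_state": space.random_state,
        },
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def load_space(path) -> tuple[RobustFeatureScaler, NormativeSpace]:
    with open(path) as f:
        payload = json.load(f)
    scaler = RobustFeatureScaler()
    scaler.median_ = np.asarray(payload["scaler"]["median"])
    scaler.iqr_ = np.asarray(payload["scaler"]["iqr"])
    scaler.n_features_in_ = len(scaler.median_)
    cfg = payload["config"]
    space = NormativeSpace(**cfg)
    space.components_ = np.asarray(payload["components"])
    space.explained_variance_ratio_ = np.asarray(payload["explained_variance_ratio"])
    space.n_features_in_ = space.components_.shape[1]
    return scaler, space
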
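"""Min-max scaling and PCA feeding the distance/probability classifiers.

The pipeline scales every feature to [0, 1] using the training range, then
projects onto the leading principal components of the scaled training
matrix. The PCA-routed classifiers (SVM, ANN, KNN, GNB) consume the
component scores; the tree ensembles (RF, XGB) consume the raw features.

Component signs are fixed so that each component's largest-magnitude
loading is positive, making loadings reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import MinMaxScaler


__all__ = ["Preprocessor", "fit_apply_minmax", "fit_pca", "transform"]


def fit_apply_minmax(train: np.ndarray, apply_to: np.ndarray) -> np.ndarray:
    """Scale ``apply_to`` with min/max learned from ``train``.

    Constant training columns map to 0; out-of-range values clip to [0, 1].
    """
    train = np.asarray(train, dtype=float)
    apply_to = np.asarray(apply_to, dtype=float)
    if train.size == 0:
        raise ValueError("training matrix is empty")
    if train.ndim != 2 or apply_to.ndim != 2 or train.shape[1] != apply_to.shape[1]:
        raise ValueError(
            f"column count mismatch: train {train.shape} vs apply {apply_to.shape}"
        )
    scaler = MinMaxScaler(clip=True).fit(train)
    return scaler.transform(apply_to)


@dataclass
class Preprocessor:
    """Fitted min-max ranges plus the PCA basis of the scaled training data.

    ``n_components_`` is the smallest count whose cumulative explained
    variance reaches ``variance_target`` (default 0.99) unless a fixed
    component count is requested.
    """

    feature_min: np.ndarray = field(default=None, repr=False)
    feature_max: np.ndarray = field(default=None, repr=False)
    pca_mean: np.ndarray = field(default=None, repr=False)
    loadings: np.ndarray = field(default=None, repr=False)  # (n_features, n_features)
    explained_variance_ratio: np.ndarray = field(default=None, repr=False)
    n_components_: int = 0
    variance_target: float = 0.99

    # -- fitting -----------------------------------------------------------
    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        *,
        variance_target: float = 0.99,
        n_components: int | None = None,
    ) -> "Preprocessor":
        """Fit min-max ranges and PCA on a raw (unscaled) feature matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        pre = cls(variance_target=variance_target)
        pre.feature_min = X.min(axis=0)
        pre.feature_max = X.max(axis=0)
        scaled = pre.apply_minmax(X)
        pre._fit_pca(scaled, variance_target, n_components)
        return pre

    def _fit_pca(
        self, scaled: np.ndarray, variance_target: float, n_components: int | None
    ) -> None:
        if not (0.0 < variance_target <= 1.0):
            raise ValueError(f"variance_target must lie in (0, 1], got {variance_target}")
        pca = PCA(n_components=min(scaled.shape), svd_solver="full").fit(scaled)
        comps = pca.components_.copy()
        # sign convention: largest-magnitude loading of each component positive
        for i in range(comps.shape[0]):
            j = int(np.argmax(np.abs(comps[i])))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.pca_mean = pca.mean_
        self.loadings = comps
        self.explained_variance_ratio = pca.explained_variance_ratio_
        if n_components is not None:
            if not (1 <= n_components <= comps.shape[0]):
                raise ValueError(f"n_components out of range: {n_components}")
            self.n_components_ = int(n_components)
        else:
            cum = np.cumsum(self.explained_variance_ratio)
            self.n_components_ = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
            self.n_components_ = min(self.n_components_, comps.shape[0])

    # -- application -------------------------------------------------------
    def apply_minmax(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_min.size:
            raise ValueError(
                f"expected {self.feature_min.size} columns, got {X.shape}"
            )
        span = self.feature_max - self.feature_min
        span = np.where(span == 0, 1.0, span)
        return np.clip((X - self.feature_min) / span, 0.0, 1.0)

    def pca_scores(self, scaled: np.ndarray) -> np.ndarray:
        """Project min-max-scaled rows onto the retained components."""
        scaled = np.asarray(scaled, dtype=float)
        if scaled.ndim != 2 or scaled.shape[1] != self.loadings.shape[1]:
            raise ValueError(f"expected {self.loadings.shape[1]} columns, got {scaled.shape}")
        centered = scaled - self.pca_mean
        return centered @ self.loadings[: self.n_components_].T

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Raw features -> min-max scaling -> retained PCA scores."""
        return self.pca_scores(self.apply_minmax(X))


def fit_pca(scaled: np.ndarray, variance_target: float = 0.99) -> Preprocessor:
    """Fit PCA on an already min-max-scaled matrix.

    Returns a Preprocessor whose min-max step is the identity on [0, 1]
    (useful when scaling was done separately with :func:`fit_apply_minmax`).
    """
    scaled = np.asarray(scaled, dtype=float)
    if scaled.ndim != 2 or scaled.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if scaled.shape[1] < 1:
        raise ValueError("need at least one feature column")
    pre = Preprocessor(variance_target=variance_target)
    pre.feature_min = np.zeros(scaled.shape[1])
    pre.feature_max = np.ones(scaled.shape[1])
    pre._fit_pca(scaled, variance_target, None)
    return pre


def transform(pre: Preprocessor, features: np.ndarray) -> np.ndarray:
    """Project raw feature rows into the retained PCA score space."""
    return pre.transform(features)
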
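"""Correlation (or covariance) PCA of the comparative dataset.

The pipeline is deliberately literal: columns of Z are centered, Pearson's
correlation over the centered columns gives X (J x J), eigendecomposition of
X gives the loading matrix V, and *taxon scores* are the product of the
centered (not standardized) Z with V.  Per-component inertia is the sum of
squared taxon scores in that component's column; the "80% components" are
the shortest leading prefix of components reaching 80% of total inertia.

With ``score_scaling="centered"`` (the default) the per-component inertia
therefore differs from the eigenvalues of X — the fidelity of the score
definition wins over textbook correlation PCA, where scores would be
computed from standardized columns (``score_scaling="standardized"``).
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


def center_columns(Z: np.ndarray) -> np.ndarray:
    """Remove each column's mean.  Requires at least 2 rows."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError(f"expected a 2-D matrix with >= 2 rows, got shape {Z.shape}")
    return Z - Z.mean(axis=0, keepdims=True)


def correlation_matrix(centered_Z: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix X (J x J) of the centered columns.

    Every column must have nonzero variance and J must be >= 2; degenerate
    columns are expected to have been filtered (and logged) by the caller.
    """
    Zc = np.asarray(centered_Z, dtype=float)
    if Zc.shape[1] < 2:
        raise ValueError("need at least 2 non-degenerate columns for correlation PCA")
    sd = Zc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance column(s) {bad.tolist()}: filter first")
    X = np.corrcoef(Zc, rowvar=False)
    return np.clip((X + X.T) / 2.0, -1.0, 1.0)


def eigendecompose(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending, negatives clamped to 0) and eigenvectors of a
    symmetric matrix, with a deterministic sign convention: each
    eigenvector's largest-magnitude element is positive."""
    X = np.asarray(X, dtype=float)
    if not np.allclose(X, X.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    vals, vecs = np.linalg.eigh(X)
    order = np.argsort(-vals, kind="stable")
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    flip = vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])] < 0
    vecs[:, flip] *= -1.0
    return vals, vecs


def taxon_scores(centered_Z: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Score matrix (I x J): the centered Z rotated into component space."""
    return np.asarray(centered_Z, dtype=float) @ np.asarray(V, dtype=float)


def component_selection(inertia: np.ndarray, threshold: float = 0.80) -> np.ndarray:
    """Indices of the shortest leading component prefix whose cumulative
    inertia share reaches `threshold` (components are already in descending
    inertia order)."""
    inertia = np.asarray(inertia, dtype=float)
    if np.any(inertia < 0):
        raise ValueError("inertia must be non-negative")
    total = inertia.sum()
    if total == 0:
        return np.arange(0)
    cum = np.cumsum(inertia) / total
    n = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return np.arange(min(n, len(inertia)))


def contributions(scores: np.ndarray, inertia: np.ndarray) -> np.ndarray:
    """contribution[i, l] = scores[i, l]**2 / inertia[l]; zero-inertia
    components give all-zero columns."""
    scores = np.asarray(scores, dtype=float)
    inertia = np.asarray(inertia, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = scores**2 / inertia[np.newaxis, :]
    C[:, inertia == 0] = 0.0
    return C


class CorrelationPCA(TransformerMixin, BaseEstimator):
    """PCA of a genera x windows bias matrix, correlation or covariance mode.

    Parameters
    ----------
    mode : {"correlation", "covariance"}
        Matrix eigendecomposed: Pearson correlation of the centered columns,
        or their sample covariance.  Correlation mode drops zero-variance
        columns (reported in ``dropped_columns_``); covariance mode keeps
        them.
    score_scaling : {"centered", "standardized"}
        Whether taxon scores multiply the merely centered Z (default) or the
        column-standardized Z into V.
    threshold : float
        Cumulative inertia share defining the leading component set
        (default 0.80).

    Attributes
    ----------
    eigenvalues_ : ndarray of shape (J',)
    loadings_ : ndarray of shape (J', J')
        Eigenvector matrix V; rows = retained windows, columns = components.
    scores_ : ndarray of shape (I, J')
        Taxon scores.
    inertia_, pct_inertia_ : ndarray of shape (J',)
    components_80_ : ndarray
        Indices of the leading components reaching `threshold`.
    contributions_ : ndarray of shape (I, J')
    kept_columns_, dropped_columns_ : ndarray
        Indices into the input columns.
    """

    def __init__(
        self,
        mode: str = "correlation",
        score_scaling: str = "centered",
        threshold: float = 0.80,
    ):
        self.mode = mode
        self.score_scaling = score_scaling
        self.threshold = threshold

    def fit(self, Z, y=None):
        if self.mode not in ("correlation", "covariance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.score_scaling not in ("centered", "standardized"):
            raise ValueError(f"unknown score_scaling {self.score_scaling!r}")
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2:
            raise ValueError("Z must be 2-D (genera x windows)")
        if Z.shape[0] < 2 or Z.shape[1] < 2:
            raise ValueError(f"Z must be at least 2 x 2, got {Z.shape}")
        self.n_features_in_ = Z.shape[1]
        self.mean_ = Z.mean(axis=0)
        Zc = Z - self.mean_
        sd = Zc.std(axis=0, ddof=1)

        if self.mode == "correlation":
            keep = sd > 0
            if not np.any(keep):
                raise ValueError("all columns are constant; correlation PCA undefined")
            if keep.sum() < 2:
                raise ValueError(
                    "fewer than 2 non-degenerate columns after filtering"
                )
            if not np.all(keep):
                logger.warning(
                    "dropping %d zero-variance (degenerate) column(s): %s",
                    (~keep).sum(), np.flatnonzero(~keep).tolist(),
                )
            self.kept_columns_ = np.flatnonzero(keep)
            self.dropped_columns_ = np.flatnonzero(~keep)
            X = correlation_matrix(Zc[:, keep])
        else:
            self.kept_columns_ = np.arange(Z.shape[1])
            self.dropped_columns_ = np.arange(0)
            X = np.cov(Zc, rowvar=False, ddof=1)

        self.eigenvalues_, self.loadings_ = eigendecompose(X)
        self.std_ = sd[self.kept_columns_]
        basis = Zc[:, self.kept_columns_]
        if self.score_scaling == "standardized":
            basis = basis / self.std_
        self.scores_ = taxon_scores(basis, self.loadings_)
        self.inertia_ = (self.scores_**2).sum(axis=0)
        total = self.inertia_.sum()
        self.pct_inertia_ = (
            100.0 * self.inertia_ / total if total > 0 else np.zeros_like(self.inertia_)
        )
        self.components_80_ = component_selection(self.inertia_, self.threshold)
        self.contributions_ = contributions(self.scores_, self.inertia_)
        return self

    def transform(self, Z):
        """Project new genus rows into the fitted component space."""
        Z = np.asarray(Z, dtype=float)
        basis = (Z - self.mean_)[:, self.kept_columns_]
        if self.score_scaling == "standardized":
            basis = basis / self.std_
        return basis @ self.loadings_

    # convenient views used by clustering and reports ----------------------

    def loadings_80(self) -> np.ndarray:
        """L1: loadings restricted to the 80% components (J' x m)."""
        return self.loadings_[:, self.components_80_]

    def loadings_first_second(self) -> np.ndarray:
        """L2: loadings on the first and second components."""
        return self.loadings_[:, : min(2, self.loadings_.shape[1])]

    def scores_80(self) -> np.ndarray:
        """T1: taxon scores restricted to the 80% components."""
        return self.scores_[:, self.components_80_]

    def scores_first_second(self) -> np.ndarray:
        """T2: taxon scores on the first and second components."""
        return self.scores_[:, : min(2, self.scores_.shape[1])]


def covariance_mode(Z: np.ndarray, **kwargs) -> CorrelationPCA:
    """Fit the identical pipeline with the covariance matrix replacing X."""
    return CorrelationPCA(mode="covariance", **kwargs).fit(Z)
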
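"""Two-class linear discriminant analysis with a pooled covariance.

Self-contained Gaussian equal-covariance classifier used as the scorer
inside the genetic-algorithm feature search. The pooled within-class
covariance is ``sum_k (n_k - 1) S_k / (n - 2)``; the discriminant score of
class k at x is

    delta_k(x) = x' Sigma^-1 mu_k - mu_k' Sigma^-1 mu_k / 2 + log pi_k

and posteriors follow by softmax over the two scores. A deterministic ridge
``eps * trace(Sigma) / p`` is added to the diagonal when the condition
number exceeds 1e8, so collinear marker subsets (which a feature search
will inevitably propose) degrade gracefully instead of failing.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["PooledLDA", "lda_fit", "lda_predict"]


class PooledLDA(BaseEstimator, ClassifierMixin):
    """Two-class LDA with empirical (default) or uniform priors.

    Parameters
    ----------
    priors : "empirical", "uniform", or array of two class priors.
        Empirical priors reproduce the strongly asymmetric
        sensitivity/specificity behaviour expected under class imbalance.
    ridge_eps : scale of the diagonal ridge applied when the pooled
        covariance is ill-conditioned (condition number > ``cond_max``).
    """

    def __init__(self, priors="empirical", ridge_eps: float = 1e-6,
                 cond_max: float = 1e8):
        self.priors = priors
        self.ridge_eps = ridge_eps
        self.cond_max = cond_max

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) != 2:
            raise ValueError(f"exactly 2 classes required, got {len(classes)}")
        n, p = X.shape
        counts = np.bincount(y_idx, minlength=2)
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")

        means = np.vstack([X[y_idx == k].mean(axis=0) for k in range(2)])
        pooled = np.zeros((p, p))
        for k in range(2):
            d = X[y_idx == k] - means[k]
            pooled += d.T @ d
        pooled /= n - 2

        if isinstance(self.priors, str):
            if self.priors == "empirical":
                priors = counts / n
            elif self.priors == "uniform":
                priors = np.array([0.5, 0.5])
            else:
                raise ValueError(f"unknown priors {self.priors!r}")
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.shape != (2,) or abs(priors.sum() - 1) > 1e-9:
                raise ValueError("priors must be two values summing to 1")

        cov = pooled.copy()
        ridge_used = 0.0
        if np.linalg.cond(cov) > self.cond_max:
            ridge_used = self.ridge_eps * np.trace(cov) / p
            cov = cov + ridge_used * np.eye(p)
        try:
            precision = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            ridge_used = self.ridge_eps * max(np.trace(cov) / p, 1.0)
            cov = cov + ridge_used * np.eye(p)
            try:
                precision = np.linalg.inv(cov)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "pooled covariance singular even after ridge") from exc

        self.classes_ = classes
        self.means_ = means
        self.covariance_ = cov
        self.precision_ = precision
        self.priors_ = priors
        self.ridge_used_ = ridge_used
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        """Per-class discriminant scores delta_k(x), shape (n, 2).

        Ties are broken toward ``classes_[0]`` (argmax takes the first
        maximum), which is documented behaviour.
        """
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape}"
            )
        scores = np.empty((len(X), 2))
        for k in range(2):
            a = self.precision_ @ self.means_[k]
            scores[:, k] = (
                X @ a - 0.5 * self.means_[k] @ a + np.log(self.priors_[k])
            )
        return scores

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def predict_proba(self, X):
        scores = self.decision_function(X)
        scores -= scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "classes_")
        return json.dumps(
            {
                "classes": self.classes_.tolist(),
                "means": self.means_.tolist(),
                "covariance": self.covariance_.tolist(),
                "priors": self.priors_.tolist(),
                "ridge_used": self.ridge_used_,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "PooledLDA":
        d = json.loads(payload)
        model = cls()
        model.classes_ = np.asarray(d["classes"])
        model.means_ = np.asarray(d["means"], dtype=float)
        model.covariance_ = np.asarray(d["covariance"], dtype=float)
        model.precision_ = np.linalg.inv(model.covariance_)
        model.priors_ = np.asarray(d["priors"], dtype=float)
        model.ridge_used_ = float(d["ridge_used"])
        model.n_features_in_ = model.means_.shape[1]
        return model


def lda_fit(X, y, priors="empirical", ridge_eps: float = 1e-6) -> PooledLDA:
    """Fit a two-class pooled-covariance LDA (functional wrapper)."""
    return PooledLDA(priors=priors, ridge_eps=ridge_eps).fit(X, y)


def lda_predict(model: PooledLDA, X):
    """Return (labels, posterior probabilities) for ``X``."""
    return model.predict(X), model.predict_proba(X)
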
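"""Input-scaling primitives: auto-scaling and diagonal (Omega) scaling.

Diagonal scaling multiplies every predictor column j by a non-negative
factor lambda_j (``X_scaled = X @ diag(lambda)``).  Scaling every column by
one common positive constant leaves centered PLS predictions unchanged;
non-uniform factors change the solution — that differential influence is
the premise of input-scaling variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["ScalingMatrix", "AutoScaler", "auto_scale", "apply_scaling"]


@dataclass
class ScalingMatrix:
    """Non-negative per-column factors with their provenance."""

    factors: np.ndarray
    provenance: str = "identity"  # vip_total | mcuve_reliability | identity | autoscale

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float).ravel()
        if not np.isfinite(self.factors).all():
            raise ValueError("scaling factors must be finite")
        if (self.factors < 0).any():
            raise ValueError("scaling factors must be non-negative")

    def __len__(self) -> int:
        return len(self.factors)


class AutoScaler(BaseEstimator, TransformerMixin):
    """Column-wise standardisation: center by the mean, divide by the
    sample standard deviation (ddof=1)."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.means_ = X.mean(axis=0)
        self.scales_ = X.std(axis=0, ddof=1)
        zero = np.nonzero(self.scales_ == 0.0)[0]
        if zero.size:
            raise ValueError(
                f"zero-variance columns cannot be auto-scaled: {zero.tolist()}"
            )
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.means_) / self.scales_

    def inverse_transform(self, X):
        return np.asarray(X, dtype=float) * self.scales_ + self.means_


def auto_scale(X):
    """Auto-scale X; returns the scaled matrix and the fitted scaler."""
    scaler = AutoScaler().fit(X)
    return scaler.transform(X), scaler


def apply_scaling(X, omega) -> np.ndarray:
    """Column-wise multiplication by the diagonal scaling factors."""
    factors = omega.factors if isinstance(omega, ScalingMatrix) else None
    if factors is None:
        factors = ScalingMatrix(np.asarray(omega)).factors  # validates
    X = np.asarray(X, dtype=float)
    if X.shape[1] != factors.shape[0]:
        raise ValueError(
            f"factor length {factors.shape[0]} != column count {X.shape[1]}"
        )
    return X * factors
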
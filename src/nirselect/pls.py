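"""NIPALS partial least squares regression and the OPLS decomposition.

Single-response PLSR is fitted with the NIPALS algorithm: components are
extracted one at a time by alternating weight/score updates with deflation
of the predictor matrix.  For a single response the inner loop is closed
form (the starting score ``u`` is the current response residual), so every
component converges in one iteration.

The OPLS variant splits predictor variation into a response-predictive
block and a response-orthogonal block: before the predictive components
are extracted, directions of X-variation that are uncorrelated with ``y``
are removed into the orthogonal block (orthogonal weight
``w_o = p - (w'p) w``, normalised, followed by deflation).  Per-component
explained sums of squares of X and y are recorded for both blocks; they
feed the OPLS-VIP scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DegenerateComponentError, DimensionError

__all__ = ["NIPALSPLS", "OPLS", "fit_plsr", "fit_opls"]

# Relative threshold below which a deflated X block or a weight vector is
# considered numerically zero.
_ZERO_RTOL = 1e-12


@dataclass
class _NipalsBlocks:
    weights: np.ndarray  # (m, l), unit-norm columns
    scores: np.ndarray  # (n, l), mutually orthogonal
    loadings: np.ndarray  # (m, l)
    y_loadings: np.ndarray  # (l,)
    u_path: np.ndarray  # (n, l) response residual entering each component
    ssx: np.ndarray  # (l,) explained SS of X per component
    ssy: np.ndarray  # (l,) explained SS of y per component
    x_residual: np.ndarray  # (n, m)
    y_residual: np.ndarray  # (n,)
    n_iter: np.ndarray  # (l,) inner iterations per component


def _nipals_single_y(Xc: np.ndarray, yc: np.ndarray, n_components: int) -> _NipalsBlocks:
    """Run single-y NIPALS on centered data.

    Stops early (with a warning) when the deflated X is numerically zero;
    raises :class:`DegenerateComponentError` when a weight vector has zero
    norm while X still carries variation.
    """
    n, m = Xc.shape
    K = n_components
    W = np.empty((m, K))
    V = np.empty((n, K))
    P = np.empty((m, K))
    q = np.empty(K)
    U = np.empty((n, K))
    ssx = np.empty(K)
    ssy = np.empty(K)

    X = Xc.copy()
    u = yc.copy()
    x_scale = np.linalg.norm(Xc)
    extracted = 0
    for g in range(K):
        if np.linalg.norm(X) <= _ZERO_RTOL * max(x_scale, 1.0):
            warnings.warn(
                f"predictor matrix exhausted after {g} components; "
                f"requested {K}",
                stacklevel=2,
            )
            break
        w = X.T @ u
        w_norm = np.linalg.norm(w)
        if w_norm <= _ZERO_RTOL * max(x_scale * np.linalg.norm(u), 1e-300):
            raise DegenerateComponentError(g)
        w /= w_norm
        v = X @ w
        vv = v @ v
        if vv <= 0.0:
            raise DegenerateComponentError(g)
        p = (X.T @ v) / vv
        qg = (u @ v) / vv
        U[:, g] = u
        X -= np.outer(v, p)
        u = u - qg * v
        W[:, g] = w
        V[:, g] = v
        P[:, g] = p
        q[g] = qg
        ssx[g] = vv * (p @ p)
        ssy[g] = qg * qg * vv
        extracted = g + 1

    k = extracted
    return _NipalsBlocks(
        weights=W[:, :k],
        scores=V[:, :k],
        loadings=P[:, :k],
        y_loadings=q[:k],
        u_path=U[:, :k],
        ssx=ssx[:k],
        ssy=ssy[:k],
        x_residual=X,
        y_residual=u,
        n_iter=np.ones(k, dtype=int),
    )


def _coef_path(blocks: _NipalsBlocks) -> np.ndarray:
    """Regression vectors for every nested component count.

    ``b_k = W_k (P_k' W_k)^{-1} q_k`` — column ``k-1`` of the result is the
    coefficient vector of the k-component model.
    """
    W, P, q = blocks.weights, blocks.loadings, blocks.y_loadings
    k = W.shape[1]
    R = P.T @ W
    path = np.empty((W.shape[0], k))
    for j in range(1, k + 1):
        a = np.linalg.solve(R[:j, :j], q[:j])
        path[:, j - 1] = W[:, :j] @ a
    return path


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise DimensionError("X must be a 2-D array")
    if X.shape[0] != y.shape[0]:
        raise DimensionError(
            f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
        )
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite with no missing values")
    return X, y


class NIPALSPLS(BaseEstimator, RegressorMixin):
    """Single-response PLSR fitted by NIPALS.

    Parameters
    ----------
    n_components : int
        Number of latent components to extract. Must satisfy
        ``1 <= n_components <= min(n - 1, m)``.

    Attributes
    ----------
    x_weights_ : ndarray of shape (m, l)
        Unit-norm weight vectors ``w_g``.
    x_scores_ : ndarray of shape (n, l)
        Mutually orthogonal score vectors ``v_g``.
    x_loadings_ : ndarray of shape (m, l)
        Loadings ``p_g``.
    y_loadings_ : ndarray of shape (l,)
        Response loadings ``q_g`` (for a single response these coincide
        with the inner-relation and mixed coefficients).
    coef_ : ndarray of shape (m,)
        The PLSR regression vector of the full l-component model, on
        centered data.
    coef_path_ : ndarray of shape (m, l)
        Regression vector for every nested component count.
    ssx_per_component_, ssy_per_component_ : ndarray of shape (l,)
        Explained sum of squares of X and y per component.
    x_residual_, y_residual_ : ndarray
        Deflation residuals E and the response residual.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        n, m = X.shape
        if not 1 <= self.n_components <= min(n - 1, m):
            raise ValueError(
                f"n_components={self.n_components} outside [1, min(n-1, m)]"
                f" = [1, {min(n - 1, m)}]"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        blocks = self._blocks_ = _nipals_single_y(Xc, yc, self.n_components)
        self.n_components_ = blocks.weights.shape[1]
        self.x_weights_ = blocks.weights
        self.x_scores_ = blocks.scores
        self.x_loadings_ = blocks.loadings
        self.y_loadings_ = blocks.y_loadings
        self.inner_coefficients_ = blocks.y_loadings.copy()
        self.mixed_coefficients_ = blocks.y_loadings.copy()
        self.ssx_per_component_ = blocks.ssx
        self.ssy_per_component_ = blocks.ssy
        self.x_residual_ = blocks.x_residual
        self.y_residual_ = blocks.y_residual
        self.n_iter_ = blocks.n_iter
        self.coef_path_ = _coef_path(blocks)
        self.coef_ = self.coef_path_[:, -1]
        return self

    def predict(self, X, n_components: int | None = None):
        """Predict the response: centered X times the regression vector
        plus the response offset.  ``n_components`` selects a nested
        sub-model from the coefficient path."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean_.shape[0]:
            raise DimensionError(
                f"X has {X.shape[1]} columns, model expects "
                f"{self.x_mean_.shape[0]}"
            )
        if n_components is None:
            b = self.coef_
        else:
            if not 1 <= n_components <= self.n_components_:
                raise ValueError("n_components outside fitted range")
            b = self.coef_path_[:, n_components - 1]
        return (X - self.x_mean_) @ b + self.y_mean_

    def regression_vector(self, form: str = "standard") -> np.ndarray:
        """The regression vector ``b`` on centered data.

        ``form="standard"`` returns ``W (P'W)^{-1} q``.  ``form="direct"``
        evaluates the equivalent score-space expression
        ``X'U (V'X X'U)^{-1} V'y`` with U the matrix of response residuals
        entering each component; both agree to numerical precision and the
        standard form is the production path.
        """
        if form == "standard":
            return self.coef_.copy()
        if form != "direct":
            raise ValueError(f"unknown form {form!r}")
        blocks = self._blocks_
        Xc = blocks.scores @ blocks.loadings.T + blocks.x_residual
        yc = (blocks.scores * blocks.y_loadings).sum(axis=1) + blocks.y_residual
        U, V = blocks.u_path, blocks.scores
        XtU = Xc.T @ U
        middle = V.T @ Xc @ XtU
        return XtU @ np.linalg.solve(middle, V.T @ yc)

    def to_dict(self) -> dict:
        """JSON-ready layout; all matrices row-major nested lists."""
        return {
            "kind": "nipals_pls",
            "n_components": int(self.n_components_),
            "x_weights": self.x_weights_.tolist(),
            "x_scores": self.x_scores_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coef": self.coef_.tolist(),
            "coef_path": self.coef_path_.tolist(),
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "ssx_per_component": self.ssx_per_component_.tolist(),
            "ssy_per_component": self.ssy_per_component_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NIPALSPLS":
        if payload.get("kind") != "nipals_pls":
            raise ValueError("payload is not a serialized NIPALSPLS model")
        model = cls(n_components=payload["n_components"])
        model.n_components_ = payload["n_components"]
        model.x_weights_ = np.asarray(payload["x_weights"])
        model.x_scores_ = np.asarray(payload["x_scores"])
        model.x_loadings_ = np.asarray(payload["x_loadings"])
        model.y_loadings_ = np.asarray(payload["y_loadings"])
        model.coef_ = np.asarray(payload["coef"])
        model.coef_path_ = np.asarray(payload["coef_path"])
        model.x_mean_ = np.asarray(payload["x_mean"])
        model.y_mean_ = float(payload["y_mean"])
        model.ssx_per_component_ = np.asarray(payload["ssx_per_component"])
        model.ssy_per_component_ = np.asarray(payload["ssy_per_component"])
        return model


class OPLS(BaseEstimator, RegressorMixin):
    """Orthogonal projections to latent structures for a single response.

    ``n_orthogonal`` y-orthogonal components are removed from X first;
    ``n_predictive`` ordinary NIPALS components are then fitted on the
    filtered matrix.  With ``n_orthogonal=0`` the predictive block is
    identical to :class:`NIPALSPLS`.

    Attributes
    ----------
    predictive_ : NIPALSPLS
        The predictive block, fitted on the orthogonal-filtered matrix.
    orthogonal_weights_, orthogonal_scores_, orthogonal_loadings_ : ndarray
        W_o (m, l_o), T_o (n, l_o), P_o (m, l_o).
    ssx_predictive_, ssy_predictive_ : ndarray of shape (l,)
    ssx_orthogonal_, ssy_orthogonal_ : ndarray of shape (l_o,)
        Per-component explained sums of squares (SSY of orthogonal
        components is zero up to rounding, by construction).
    ssx_cum_, ssy_cum_ : float
        Cumulative explained SS over all components of both blocks.
    """

    def __init__(self, n_predictive: int = 1, n_orthogonal: int = 1):
        self.n_predictive = n_predictive
        self.n_orthogonal = n_orthogonal

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        n, m = X.shape
        if self.n_predictive < 1 or self.n_orthogonal < 0:
            raise ValueError("need n_predictive >= 1 and n_orthogonal >= 0")
        if self.n_predictive + self.n_orthogonal > min(n - 1, m):
            raise ValueError(
                "n_predictive + n_orthogonal exceeds min(n - 1, m)"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        Xf = Xc.copy()
        s = Xf.T @ yc
        s_norm = np.linalg.norm(s)
        if s_norm <= 0.0:
            raise DegenerateComponentError(0, "X carries no covariance with y")
        w = s / s_norm

        Wo, To, Po, ssx_o, ssy_o = [], [], [], [], []
        for go in range(self.n_orthogonal):
            t = Xf @ w
            tt = t @ t
            p = (Xf.T @ t) / tt
            w_o = p - (w @ p) * w
            norm_o = np.linalg.norm(w_o)
            if norm_o <= _ZERO_RTOL * max(np.linalg.norm(p), 1e-300):
                warnings.warn(
                    f"no orthogonal variation left after {go} components; "
                    f"requested {self.n_orthogonal}",
                    stacklevel=2,
                )
                break
            w_o /= norm_o
            t_o = Xf @ w_o
            tt_o = t_o @ t_o
            if tt_o <= 0.0:
                warnings.warn(
                    f"degenerate orthogonal component {go}; stopping",
                    stacklevel=2,
                )
                break
            p_o = (Xf.T @ t_o) / tt_o
            Xf -= np.outer(t_o, p_o)
            q_o = (yc @ t_o) / tt_o
            Wo.append(w_o)
            To.append(t_o)
            Po.append(p_o)
            ssx_o.append(tt_o * (p_o @ p_o))
            ssy_o.append(q_o * q_o * tt_o)  # ~0 by construction

        lo = len(Wo)
        self.n_orthogonal_ = lo
        self.orthogonal_weights_ = (
            np.column_stack(Wo) if lo else np.empty((m, 0))
        )
        self.orthogonal_scores_ = (
            np.column_stack(To) if lo else np.empty((n, 0))
        )
        self.orthogonal_loadings_ = (
            np.column_stack(Po) if lo else np.empty((m, 0))
        )
        self.ssx_orthogonal_ = np.asarray(ssx_o)
        self.ssy_orthogonal_ = np.asarray(ssy_o)

        pred = NIPALSPLS(n_components=self.n_predictive)
        pred.fit(Xf + self.x_mean_, yc + self.y_mean_)
        self.predictive_ = pred
        self.n_predictive_ = pred.n_components_
        self.ssx_predictive_ = pred.ssx_per_component_
        self.ssy_predictive_ = pred.ssy_per_component_
        self.ssx_cum_ = float(
            self.ssx_predictive_.sum() + self.ssx_orthogonal_.sum()
        )
        self.ssy_cum_ = float(
            self.ssy_predictive_.sum() + self.ssy_orthogonal_.sum()
        )
        return self

    def _filter(self, X):
        """Remove the fitted orthogonal components from new data."""
        Xc = np.asarray(X, dtype=float) - self.x_mean_
        for go in range(self.n_orthogonal_):
            t_o = Xc @ self.orthogonal_weights_[:, go]
            Xc -= np.outer(t_o, self.orthogonal_loadings_[:, go])
        return Xc + self.x_mean_

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean_.shape[0]:
            raise DimensionError(
                f"X has {X.shape[1]} columns, model expects "
                f"{self.x_mean_.shape[0]}"
            )
        return self.predictive_.predict(self._filter(X))


def fit_plsr(X, y, n_components: int) -> NIPALSPLS:
    """Thin functional wrapper over :class:`NIPALSPLS`."""
    return NIPALSPLS(n_components=n_components).fit(X, y)


def fit_opls(X, y, n_predictive: int, n_orthogonal: int) -> OPLS:
    """Thin functional wrapper over :class:`OPLS`."""
    return OPLS(n_predictive=n_predictive, n_orthogonal=n_orthogonal).fit(X, y)
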
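"""Monte-Carlo uninformative variable elimination (MCUVE).

Artificial noise columns (uniform values scaled to a negligible amplitude,
the classical UVE convention) are appended to the predictor matrix; ``r``
PLS sub-models are fitted on random subsamples; and every column's
reliability is the mean of its sub-model coefficients divided by their
standard deviation (``ddof=1``),

    c_j = mean(b_j) / sd(b_j).

Reliability is scale-invariant, so the tiny noise amplitude does not bias
the artificial reliabilities.  Two cut-offs on the artificial block are
provided:

* classical: ``max_j |c_artif,j|`` — real variables with ``|c_j|`` below it
  are flagged uninformative;
* robust: ``median(c_artif) + k * MAD(c_artif)`` where ``k`` is a one-sided
  normal tolerance factor covering a proportion ``gamma`` with confidence
  ``1 - alpha`` over ``r`` repetitions.  Classification under the robust
  rule uses the signed reliability ``c_j > cutoff``.

The MAD is scaled by 1.4826 by default so median + k*MAD mimics
mean + k*sd under Gaussian reliabilities; the raw MAD is available via
``mad_scale="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import InvalidConfigurationError
from .pls import _nipals_single_y

__all__ = [
    "MCUVE",
    "MCUVEResult",
    "ToleranceParams",
    "augment_noise",
    "mc_reliability",
    "classical_cutoff",
    "tolerance_k",
    "robust_cutoff",
]

_MAD_NORMAL = 1.4826022185056018  # 1 / norm.ppf(0.75)


@dataclass
class ToleranceParams:
    """One-sided normal tolerance factor k and its intermediates.

    k = (z_gamma + sqrt(z_gamma^2 - a*b)) / a with
    a = 1 - z_alpha^2 / (2 (r-1)) and b = z_gamma^2 - z_alpha^2 / r.
    """

    gamma: float
    alpha: float
    r: int
    k_factor: float
    a_const: float
    b_const: float


@dataclass
class MCUVEResult:
    """Per-variable reliabilities and the active cut-off."""

    reliability: np.ndarray  # real variables
    reliability_artificial: np.ndarray
    coefficient_matrix: np.ndarray  # r x (m + noise columns)
    mean_coefficients: np.ndarray
    coefficient_sd: np.ndarray
    cutoff_value: float
    cutoff_kind: str  # classical | robust
    selected_mask: np.ndarray
    tolerance: ToleranceParams | None = None
    degenerate_mask: np.ndarray | None = None


def augment_noise(
    X: np.ndarray,
    n_columns: int | None = None,
    amplitude: float = 1e-10,
    rng: np.random.Generator | int | None = None,
):
    """Append uniform(0,1) noise columns scaled by ``amplitude``.

    Returns the augmented matrix and the indices of the artificial columns.
    """
    if amplitude <= 0:
        raise InvalidConfigurationError("noise amplitude must be > 0")
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    k = m if n_columns is None else int(n_columns)
    rng = np.random.default_rng(rng)
    noise = rng.uniform(0.0, 1.0, size=(n, k)) * amplitude
    return np.hstack([X, noise]), np.arange(m, m + k)


def _reliability_from_coefficients(B: np.ndarray):
    """c_j = mean/sd per column; sd==0 columns are flagged degenerate and
    reported as maximally reliable (infinite c)."""
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    c = np.empty_like(mean)
    ok = ~degenerate
    c[ok] = mean[ok] / sd[ok]
    c[degenerate] = np.where(mean[degenerate] >= 0, np.inf, -np.inf)
    return c, mean, sd, degenerate


def mc_reliability(
    X_aug: np.ndarray,
    y: np.ndarray,
    noise_index: np.ndarray,
    n_resamples: int = 500,
    subsample_fraction: float = 0.8,
    n_components: int = 2,
    rng: np.random.Generator | int | None = None,
) -> MCUVEResult:
    """Reliability coefficients from ``n_resamples`` PLS sub-models.

    No cut-off is attached yet (``cutoff_kind="none"``); use
    :func:`classical_cutoff` / :func:`robust_cutoff` or the :class:`MCUVE`
    estimator.
    """
    X_aug = np.asarray(X_aug, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m_tot = X_aug.shape
    if n_resamples < 2:
        raise InvalidConfigurationError("n_resamples must be >= 2")
    if not 0.0 < subsample_fraction < 1.0:
        raise InvalidConfigurationError("subsample_fraction must be in (0, 1)")
    n_sub = max(int(round(subsample_fraction * n)), 2)
    if n_sub < n_components + 1:
        raise InvalidConfigurationError(
            f"subsample size {n_sub} too small for {n_components} components"
        )
    rng = np.random.default_rng(rng)
    B = np.empty((n_resamples, m_tot))
    for i in range(n_resamples):
        idx = rng.choice(n, size=n_sub, replace=False)
        Xi = X_aug[idx]
        yi = y[idx]
        Xc = Xi - Xi.mean(axis=0)
        yc = yi - yi.mean()
        blocks = _nipals_single_y(Xc, yc, n_components)
        W, P, q = blocks.weights, blocks.loadings, blocks.y_loadings
        B[i] = W @ np.linalg.solve(P.T @ W, q)

    c, mean, sd, degenerate = _reliability_from_coefficients(B)
    real = np.ones(m_tot, dtype=bool)
    real[noise_index] = False
    return MCUVEResult(
        reliability=c[real],
        reliability_artificial=c[noise_index],
        coefficient_matrix=B,
        mean_coefficients=mean,
        coefficient_sd=sd,
        cutoff_value=np.nan,
        cutoff_kind="none",
        selected_mask=np.ones(int(real.sum()), dtype=bool),
        degenerate_mask=degenerate,
    )


def classical_cutoff(result: MCUVEResult) -> float:
    """Classical UVE cut-off: the maximum absolute artificial reliability.

    Updates the result in place: real variables with ``|c_j|`` below the
    cut-off are deselected.
    """
    c_artif = np.asarray(result.reliability_artificial, dtype=float)
    if c_artif.size == 0:
        raise InvalidConfigurationError("no artificial reliabilities")
    cutoff = float(np.max(np.abs(c_artif)))
    result.cutoff_value = cutoff
    result.cutoff_kind = "classical"
    result.selected_mask = np.abs(result.reliability) >= cutoff
    return cutoff


def tolerance_k(gamma: float, alpha: float, r: int) -> ToleranceParams:
    """One-sided normal tolerance factor (closed-form approximation).

    ``gamma`` is the population proportion to cover, ``alpha`` the error
    level (confidence ``1 - alpha``) and ``r`` the repetition count.
    """
    if not 0.0 < gamma < 1.0 or not 0.0 < alpha < 1.0:
        raise InvalidConfigurationError("gamma and alpha must lie in (0, 1)")
    if r < 3:
        raise InvalidConfigurationError("r must be >= 3")
    z_g = stats.norm.ppf(gamma)
    z_a = stats.norm.ppf(1.0 - alpha)
    a = 1.0 - z_a**2 / (2.0 * (r - 1))
    b = z_g**2 - z_a**2 / r
    if a <= 0.0:
        raise InvalidConfigurationError(
            f"a = 1 - z_alpha^2/(2(r-1)) = {a:.4g} <= 0; increase r"
        )
    disc = z_g**2 - a * b
    if disc < 0.0:
        raise InvalidConfigurationError(
            f"negative discriminant z_gamma^2 - a*b = {disc:.4g}"
        )
    k = (z_g + np.sqrt(disc)) / a
    return ToleranceParams(
        gamma=gamma, alpha=alpha, r=r, k_factor=float(k),
        a_const=float(a), b_const=float(b),
    )


def mad(values: np.ndarray, scale: str = "normal") -> float:
    """Median absolute deviation; ``scale="normal"`` applies the 1.4826
    consistency factor, ``"raw"`` does not."""
    values = np.asarray(values, dtype=float)
    raw = float(np.median(np.abs(values - np.median(values))))
    if scale == "normal":
        return raw * _MAD_NORMAL
    if scale == "raw":
        return raw
    raise ValueError(f"unknown MAD scale {scale!r}")


def robust_cutoff(
    result: MCUVEResult,
    tol: ToleranceParams,
    mad_scale: str = "normal",
) -> float:
    """Robust tolerance-interval cut-off: median + k * MAD of the
    artificial reliabilities.

    Updates the result in place: real variables are selected when their
    signed reliability exceeds the cut-off.
    """
    c_artif = np.asarray(result.reliability_artificial, dtype=float)
    if c_artif.size < 3:
        raise InvalidConfigurationError(
            "robust cut-off needs at least 3 artificial reliabilities"
        )
    cutoff = float(np.median(c_artif) + tol.k_factor * mad(c_artif, mad_scale))
    result.cutoff_value = cutoff
    result.cutoff_kind = "robust"
    result.tolerance = tol
    result.selected_mask = result.reliability > cutoff
    return cutoff


class MCUVE(BaseEstimator):
    """MCUVE reliability estimator with classical or robust cut-off.

    Parameters
    ----------
    n_components : int
        PLS components per sub-model (typically the CV-selected count on
        the full data).
    n_resamples : int, default 500
        Number of Monte-Carlo subsamples ``r``.
    subsample_fraction : float, default 0.8
        Fraction of samples drawn (without replacement) per sub-model.
    noise_column_count : int or None
        Artificial columns appended; ``None`` means one per real variable.
    noise_amplitude : float, default 1e-10
        Scale of the appended uniform noise.
    cutoff : {"robust", "classical"}
    gamma, alpha : float
        Tolerance-interval proportion and error level for the robust rule.
    mad_scale : {"normal", "raw"}
    """

    def __init__(
        self,
        n_components: int = 2,
        n_resamples: int = 500,
        subsample_fraction: float = 0.8,
        noise_column_count: int | None = None,
        noise_amplitude: float = 1e-10,
        cutoff: str = "robust",
        gamma: float = 0.95,
        alpha: float = 0.05,
        mad_scale: str = "normal",
        random_state=None,
    ):
        self.n_components = n_components
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.noise_column_count = noise_column_count
        self.noise_amplitude = noise_amplitude
        self.cutoff = cutoff
        self.gamma = gamma
        self.alpha = alpha
        self.mad_scale = mad_scale
        self.random_state = random_state

    def fit(self, X, y):
        if self.cutoff not in ("robust", "classical"):
            raise ValueError(f"unknown cutoff kind {self.cutoff!r}")
        rng = np.random.default_rng(self.random_state)
        X_aug, noise_index = augment_noise(
            X, self.noise_column_count, self.noise_amplitude, rng
        )
        result = mc_reliability(
            X_aug,
            y,
            noise_index,
            n_resamples=self.n_resamples,
            subsample_fraction=self.subsample_fraction,
            n_components=self.n_components,
            rng=rng,
        )
        if self.cutoff == "classical":
            classical_cutoff(result)
        else:
            tol = tolerance_k(self.gamma, self.alpha, self.n_resamples)
            robust_cutoff(result, tol, self.mad_scale)
        self.result_ = result
        self.reliability_ = result.reliability
        self.reliability_artificial_ = result.reliability_artificial
        self.cutoff_ = result.cutoff_value
        self.selected_mask_ = result.selected_mask
        self.noise_index_ = noise_index
        return self

    def to_frame(self, wavelengths=None):
        """Reliability table: variable, c_j, artificial flag, cutoff,
        selected."""
        import pandas as pd

        res = self.result_
        n_real = res.reliability.size
        labels = (
            np.arange(n_real) if wavelengths is None else np.asarray(wavelengths)
        )
        return pd.DataFrame(
            {
                "variable": np.concatenate(
                    [labels.astype(object),
                     [f"artificial_{i}" for i in range(res.reliability_artificial.size)]]
                ),
                "reliability": np.concatenate(
                    [res.reliability, res.reliability_artificial]
                ),
                "artificial": np.concatenate(
                    [np.zeros(n_real, bool),
                     np.ones(res.reliability_artificial.size, bool)]
                ),
                "cutoff": res.cutoff_value,
                "selected": np.concatenate(
                    [res.selected_mask,
                     np.zeros(res.reliability_artificial.size, bool)]
                ),
            }
        )
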
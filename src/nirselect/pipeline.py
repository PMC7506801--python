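"""The mod-VIP-MCUVE pipeline and the comparator calibration methods.

The pipeline combines a filter step with a wrapper step to build the final
diagonal input-scaling matrix:

1. fit an OPLS model on the raw predictors and use the total OPLS-VIP
   score of every column as the initial scaling factor,
   ``X1 = X @ diag(VIP_total)``;
2. run MCUVE on the scaled matrix — append artificial noise columns, fit
   PLS sub-models on random subsamples, compute reliability coefficients
   c_j, and set the robust tolerance-interval cut-off
   ``median(c_artif) + k * MAD(c_artif)``;
3. rescale with the reliability magnitudes, ``X2 = X1 @ diag(|c_j|)``
   (cumulative by default; ``step3="from_raw"`` rescales the raw X
   instead), and fit the final PLSR with a CV-selected component count.

Relevant wavelengths end up with large combined factors and dominate the
PLS solution; irrelevant ones are downweighted towards zero without hard
deletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .mcuve import MCUVE
from .model_selection import CVSpec, cross_validate, evaluate
from .pls import NIPALSPLS
from .scaling import AutoScaler, apply_scaling
from .vip import classical_vip, classify_by_vip, opls_vip
from .pls import OPLS

__all__ = ["ModVIPMCUVE", "ComparatorResult", "run_comparator", "COMPARATOR_METHODS"]

COMPARATOR_METHODS = ("plsr", "vip", "mcuve", "mod-vip-mcuve")


class ModVIPMCUVE(BaseEstimator, RegressorMixin):
    """Three-step robust input-scaling PLSR estimator.

    Parameters
    ----------
    n_predictive, n_orthogonal : int
        OPLS component counts for the step-1 VIP-total score.  The default
        (one predictive component, the single-y OPLS convention, plus three
        orthogonal components) lets the total score see several dimensions
        of response-orthogonal predictor variation, as is typical of
        spectral data; the score is insensitive to additional orthogonal
        components.
    n_resamples, subsample_fraction, noise_amplitude : MCUVE settings.
    gamma, alpha : float
        Robust cut-off tolerance-interval proportion and error level.
    mad_scale : {"normal", "raw"}
    step3 : {"cumulative", "from_raw"}
        Whether step 3 rescales the step-1 output (default) or the raw X.
    cv : CVSpec or None
        Protocol for component selection (both for the MCUVE sub-model
        count and the final model).
    submodel_components : int or None
        PLS components per MCUVE sub-model; ``None`` selects them by CV on
        the step-1 scaled matrix.
    """

    def __init__(
        self,
        n_predictive: int = 1,
        n_orthogonal: int = 3,
        n_resamples: int = 500,
        subsample_fraction: float = 0.8,
        noise_column_count: int | None = None,
        noise_amplitude: float = 1e-10,
        gamma: float = 0.95,
        alpha: float = 0.05,
        mad_scale: str = "normal",
        step3: str = "cumulative",
        cv: CVSpec | None = None,
        submodel_components: int | None = None,
        random_state=None,
    ):
        self.n_predictive = n_predictive
        self.n_orthogonal = n_orthogonal
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.noise_column_count = noise_column_count
        self.noise_amplitude = noise_amplitude
        self.gamma = gamma
        self.alpha = alpha
        self.mad_scale = mad_scale
        self.step3 = step3
        self.cv = cv
        self.submodel_components = submodel_components
        self.random_state = random_state

    def fit(self, X, y):
        if self.step3 not in ("cumulative", "from_raw"):
            raise ValueError(f"unknown step3 mode {self.step3!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        cv = self.cv or CVSpec()
        rng = np.random.default_rng(self.random_state)

        # Step 1: OPLS-VIP total score as initial scaling factors.
        opls = OPLS(
            n_predictive=self.n_predictive, n_orthogonal=self.n_orthogonal
        ).fit(X, y)
        vip = opls_vip(opls, variant="total")
        step1_factors = vip.scores
        X1 = apply_scaling(X, step1_factors)

        # Step 2: modified MCUVE on the scaled matrix, robust cut-off.
        if self.submodel_components is None:
            cv1 = cross_validate(X1, y, cv)
            n_sub = cv1.selected_components
        else:
            n_sub = self.submodel_components
        mcuve = MCUVE(
            n_components=n_sub,
            n_resamples=self.n_resamples,
            subsample_fraction=self.subsample_fraction,
            noise_column_count=self.noise_column_count,
            noise_amplitude=self.noise_amplitude,
            cutoff="robust",
            gamma=self.gamma,
            alpha=self.alpha,
            mad_scale=self.mad_scale,
            random_state=rng,
        ).fit(X1, y)

        # Step 3: reliability magnitudes as the final factors (Omega must
        # be non-negative while reliabilities are signed).
        step2_factors = np.abs(mcuve.reliability_)
        if self.step3 == "cumulative":
            combined = step1_factors * step2_factors
            X2 = apply_scaling(X1, step2_factors)
        else:
            combined = step2_factors
            X2 = apply_scaling(X, step2_factors)
        if not np.any(combined > 0):
            raise ValueError(
                "all scaling factors are zero; every variable fell below "
                "the cut-off — review gamma/alpha or the data"
            )

        cv_result = cross_validate(X2, y, cv)
        n_final = cv_result.selected_components
        model = NIPALSPLS(n_components=n_final).fit(X2, y)

        self.opls_ = opls
        self.vip_scores_ = vip
        self.step1_factors_ = step1_factors
        self.mcuve_ = mcuve
        self.cutoff_ = mcuve.cutoff_
        self.scaling_factors_ = combined
        self.cv_result_ = cv_result
        self.n_components_ = n_final
        self.model_ = model
        self.cv_metrics_ = evaluate(
            y, cv_result.selected_predictions, n_components=n_final
        )
        self.refit_metrics_ = evaluate(
            y, model.predict(X2), n_components=n_final
        )
        self.selection_report_ = pd.DataFrame(
            {
                "vip_total": step1_factors,
                "reliability": mcuve.reliability_,
                "cutoff": mcuve.cutoff_,
                "above_cutoff": mcuve.selected_mask_,
                "factor": combined,
            }
        )
        return self

    def predict(self, X):
        X2 = apply_scaling(np.asarray(X, dtype=float), self.scaling_factors_)
        return self.model_.predict(X2)


@dataclass
class ComparatorResult:
    """One benchmark method's fit under the shared CV protocol.

    ``metrics`` is an alias for the basis requested from
    :func:`run_comparator`; both bases are always retained:
    ``metrics_cv`` evaluates the pooled out-of-fold predictions, while
    ``metrics_refit`` evaluates the final model refitted on all samples at
    the CV-selected component count.
    """

    model: object
    metrics: "object"
    metrics_cv: "object"
    metrics_refit: "object"
    cv_result: object
    factors: np.ndarray | None


def _cv_metrics(X, y, cv: CVSpec):
    """CV curve, selected count, final fit and metrics on both bases."""
    cv_result = cross_validate(X, y, cv)
    k = cv_result.selected_components
    model = NIPALSPLS(n_components=k).fit(X, y)
    metrics_cv = evaluate(y, cv_result.selected_predictions, n_components=k)
    metrics_refit = evaluate(y, model.predict(X), n_components=k)
    return model, metrics_cv, metrics_refit, cv_result


def run_comparator(
    X,
    y,
    method: str,
    cv: CVSpec | None = None,
    random_state=None,
    hard_selection: bool = False,
    metric_basis: str = "cv",
    **pipeline_params,
) -> ComparatorResult:
    """Fit one of the benchmark calibration methods under a shared CV
    protocol.

    * ``plsr`` — auto-scaled classical PLSR;
    * ``vip`` — PLSR on X scaled by the classical VIP scores;
    * ``mcuve`` — PLSR on X scaled by classical-MCUVE reliability
      magnitudes (classical max|c_artif| cut-off);
    * ``mod-vip-mcuve`` — the full three-step pipeline.

    ``hard_selection=True`` zeroes the factors of variables below the
    method's cut (VIP score <= 1, reliability below the cut-off) instead of
    merely downweighting them.  ``metric_basis`` picks which evaluation the
    ``metrics`` alias points to ("cv" or "refit"); both are returned.
    """
    if metric_basis not in ("cv", "refit"):
        raise ValueError(f"unknown metric basis {metric_basis!r}")
    cv = cv or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    if method == "plsr":
        Xs = AutoScaler().fit_transform(X)
        model, m_cv, m_refit, cv_result = _cv_metrics(Xs, y, cv)
        factors = None
    elif method == "vip":
        base_cv = cross_validate(X, y, cv)
        base = NIPALSPLS(n_components=base_cv.selected_components).fit(X, y)
        scores = classical_vip(base).scores
        factors = scores.copy()
        if hard_selection:
            labels, _ = classify_by_vip(scores)
            factors[labels != "relevant"] = 0.0
        model, m_cv, m_refit, cv_result = _cv_metrics(
            apply_scaling(X, factors), y, cv
        )
    elif method == "mcuve":
        base_cv = cross_validate(X, y, cv)
        mc = MCUVE(
            n_components=base_cv.selected_components,
            n_resamples=pipeline_params.get("n_resamples", 500),
            subsample_fraction=pipeline_params.get("subsample_fraction", 0.8),
            noise_column_count=pipeline_params.get("noise_column_count"),
            noise_amplitude=pipeline_params.get("noise_amplitude", 1e-10),
            cutoff="classical",
            random_state=random_state,
        ).fit(X, y)
        factors = np.abs(mc.reliability_)
        if hard_selection:
            factors[~mc.selected_mask_] = 0.0
        model, m_cv, m_refit, cv_result = _cv_metrics(
            apply_scaling(X, factors), y, cv
        )
    elif method == "mod-vip-mcuve":
        est = ModVIPMCUVE(
            cv=cv, random_state=random_state, **pipeline_params
        ).fit(X, y)
        model = est
        m_cv, m_refit = est.cv_metrics_, est.refit_metrics_
        cv_result = est.cv_result_
        factors = est.scaling_factors_
    else:
        raise ValueError(
            f"unknown method {method!r}; expected one of {COMPARATOR_METHODS}"
        )

    return ComparatorResult(
        model=model,
        metrics=m_cv if metric_basis == "cv" else m_refit,
        metrics_cv=m_cv,
        metrics_refit=m_refit,
        cv_result=cv_result,
        factors=factors,
    )
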
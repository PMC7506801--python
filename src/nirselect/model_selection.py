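"""Cross-validation for the number of PLS components and calibration metrics.

The RMSEP curve is computed from pooled out-of-fold predictions for every
nested component count (NIPALS models are nested, so one fit per fold covers
the whole curve).  Two selection outputs are reported:

* ``abs_minimum`` — the component count with the lowest RMSEP (smallest
  count on ties);
* ``one_se`` — the smallest count whose RMSEP is within one standard error
  (across folds) of the absolute minimum; a parsimony rule that guards
  against overfitting the RMSEP curve.

Metrics follow multivariate-calibration conventions: RMSE is the root mean
squared residual, R^2 the squared Pearson correlation between reference and
predicted values, RPD the standard deviation of the reference divided by
the RMSE, and SE the bias-corrected standard deviation of the residuals
(standard error of prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .pls import NIPALSPLS

__all__ = ["CVSpec", "CVResult", "EvaluationMetrics", "cross_validate", "evaluate"]


@dataclass
class CVSpec:
    """Cross-validation protocol.

    ``max_components`` is an upper bound; it is reduced when a fold's
    training set cannot support it.  ``n_folds=n`` gives leave-one-out.
    """

    n_folds: int = 10
    max_components: int = 15
    selection_rule: str = "one_se"  # or "abs_minimum"
    seed: int | None = None

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if self.selection_rule not in ("one_se", "abs_minimum"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")


@dataclass
class CVResult:
    rmsep_by_components: np.ndarray  # (K,)
    rmsep_se_by_components: np.ndarray  # (K,)
    selected_components: int
    abs_minimum_components: int
    predictions: np.ndarray  # (n, K) out-of-fold predictions
    fold_assignment: np.ndarray = field(default=None)

    @property
    def selected_predictions(self) -> np.ndarray:
        return self.predictions[:, self.selected_components - 1]


def cross_validate(X, y, cv: CVSpec | None = None, scale_factors=None) -> CVResult:
    """RMSEP curve and component selection by k-fold cross-validation.

    ``scale_factors``, when given, are non-negative per-column factors
    applied to X before fitting (inside every fold identically, since the
    factors are fixed inputs to the protocol).
    """
    cv = cv or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if scale_factors is not None:
        X = X * np.asarray(scale_factors, dtype=float)
    n, m = X.shape
    if cv.n_folds > n:
        raise ValueError(f"n_folds={cv.n_folds} exceeds n={n}")

    kf = KFold(
        n_splits=cv.n_folds,
        shuffle=True,
        random_state=None if cv.seed is None else int(cv.seed) % (2**31),
    )
    splits = list(kf.split(X))
    min_train = min(len(tr) for tr, _ in splits)
    K = min(cv.max_components, min_train - 1, m)
    if K < 1:
        raise ValueError("folds too small to fit even one component")

    preds = np.empty((n, K))
    fold_rmsep = np.empty((len(splits), K))
    fold_of = np.empty(n, dtype=int)
    K_eff = K
    for f, (tr, te) in enumerate(splits):
        model = NIPALSPLS(n_components=K).fit(X[tr], y[tr])
        K_eff = min(K_eff, model.n_components_)
        Xc = X[te] - model.x_mean_
        p = Xc @ model.coef_path_ + model.y_mean_  # (n_te, k_fold)
        if p.shape[1] < K:  # component extraction stopped early: pad
            p = np.hstack([p, np.repeat(p[:, -1:], K - p.shape[1], axis=1)])
        preds[te] = p
        fold_rmsep[f] = np.sqrt(((p - y[te, None]) ** 2).mean(axis=0))
        fold_of[te] = f
    preds = preds[:, :K_eff]
    fold_rmsep = fold_rmsep[:, :K_eff]

    rmsep = np.sqrt(((preds - y[:, None]) ** 2).mean(axis=0))
    se = fold_rmsep.std(axis=0, ddof=1) / np.sqrt(len(splits))
    abs_min = int(np.argmin(rmsep)) + 1
    if cv.selection_rule == "abs_minimum":
        selected = abs_min
    else:
        threshold = rmsep[abs_min - 1] + se[abs_min - 1]
        selected = int(np.nonzero(rmsep <= threshold)[0][0]) + 1
    return CVResult(
        rmsep_by_components=rmsep,
        rmsep_se_by_components=se,
        selected_components=selected,
        abs_minimum_components=abs_min,
        predictions=preds,
        fold_assignment=fold_of,
    )


@dataclass
class EvaluationMetrics:
    rmse: float
    r2: float
    rpd: float
    se: float
    n_components: int | None = None

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "r2": self.r2,
            "rpd": self.rpd,
            "se": self.se,
            "n_components": self.n_components,
        }


def evaluate(reference, predicted, n_components: int | None = None) -> EvaluationMetrics:
    """RMSE, squared-correlation R^2, RPD and SE of a prediction set."""
    reference = np.asarray(reference, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if reference.shape != predicted.shape:
        raise ValueError("reference and predicted must have equal length")
    n = reference.size
    if n < 2:
        raise ValueError("need at least 2 values")
    sd_ref = reference.std(ddof=1)
    if sd_ref == 0.0:
        raise ValueError("reference has zero variance; R2 and RPD undefined")
    residuals = reference - predicted
    rmse = float(np.sqrt((residuals**2).mean()))
    if predicted.std() == 0.0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(reference, predicted)[0, 1] ** 2)
    rpd = float(np.inf) if rmse == 0.0 else float(sd_ref / rmse)
    se = float(residuals.std(ddof=1))
    return EvaluationMetrics(rmse=rmse, r2=r2, rpd=rpd, se=se, n_components=n_components)
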
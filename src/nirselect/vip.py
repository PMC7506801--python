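"""Variable importance in projection (VIP) scores.

Two families are provided:

* the classical PLS VIP, ``VIP_j = sqrt(m * sum_g(v_gj^2 SSY_g) / sum_g SSY_g)``
  with ``v_g`` the unit-norm weight vectors — mean-square normalised so that
  ``sum_j VIP_j^2 = m``;
* the OPLS-VIP scores, which weight squared normalised weights by the
  explained sums of squares of both X and y, separately over the predictive
  and orthogonal blocks.  The predictive score averages the SSX- and
  SSY-weighted terms with factor ``m/2``; the orthogonal score uses
  ``m_o/2``; the total score combines all four sums with factor ``M/2``.

The printed definition of the effective counts ``m``, ``m_o`` and ``M`` is
circular, so this implementation uses the documented fallback: ``m`` is the
number of predictors, ``m_o`` equals ``m`` when at least one orthogonal
component exists and 0 otherwise, and ``M = m + m_o``.  With no orthogonal
components the total score therefore reduces exactly to the predictive one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import UndefinedScoreError
from .pls import NIPALSPLS, OPLS

__all__ = ["VIPScores", "classical_vip", "opls_vip", "classify_by_vip"]

_LABELS = ("relevant", "intermediate", "irrelevant")


@dataclass
class VIPScores:
    """Per-variable importance scores of one variant."""

    scores: np.ndarray
    variant: str  # classical | pred | ortho | total
    component_counts: tuple[int, int]  # (l, l_o)
    effective_variable_counts: dict = field(default_factory=dict)  # m, m_o, M

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self, wavelengths=None) -> pd.DataFrame:
        labels, _ = classify_by_vip(self)
        return pd.DataFrame(
            {
                "wavelength": (
                    np.arange(len(self.scores))
                    if wavelengths is None
                    else np.asarray(wavelengths)
                ),
                "score": self.scores,
                "variant": self.variant,
                "label": labels,
            }
        )


def classical_vip(model: NIPALSPLS) -> VIPScores:
    """Classical VIP scores of a fitted PLS model."""
    W = model.x_weights_
    ssy = model.ssy_per_component_
    total = ssy.sum()
    if total <= 0.0:
        raise UndefinedScoreError("total explained SSY is zero")
    m = W.shape[0]
    vip_sq = m * ((W**2) @ ssy) / total
    return VIPScores(
        scores=np.sqrt(vip_sq),
        variant="classical",
        component_counts=(model.n_components_, 0),
        effective_variable_counts={"m": m, "m_o": 0, "M": m},
    )


def opls_vip(model: OPLS, variant: str = "total") -> VIPScores:
    """OPLS-VIP score of the requested variant (pred, ortho or total)."""
    if variant not in ("pred", "ortho", "total"):
        raise ValueError(f"unknown OPLS-VIP variant {variant!r}")
    if model.ssx_cum_ <= 0.0 or model.ssy_cum_ <= 0.0:
        raise UndefinedScoreError("cumulative explained SSX or SSY is zero")
    lo = model.n_orthogonal_
    if variant == "ortho" and lo < 1:
        raise UndefinedScoreError(
            "orthogonal variant requires at least one orthogonal component"
        )
    m = model.predictive_.x_weights_.shape[0]
    m_o = m if lo >= 1 else 0
    M = m + m_o

    Wp2 = model.predictive_.x_weights_ ** 2
    sx_pred = Wp2 @ (model.ssx_predictive_ / model.ssx_cum_)
    sy_pred = Wp2 @ (model.ssy_predictive_ / model.ssy_cum_)
    if lo >= 1:
        Wo2 = model.orthogonal_weights_ ** 2
        sx_orth = Wo2 @ (model.ssx_orthogonal_ / model.ssx_cum_)
        sy_orth = Wo2 @ (model.ssy_orthogonal_ / model.ssy_cum_)
    else:
        sx_orth = np.zeros(m)
        sy_orth = np.zeros(m)

    if variant == "pred":
        scores = (m / 2.0) * (sx_pred + sy_pred)
    elif variant == "ortho":
        scores = (m_o / 2.0) * (sx_orth + sy_orth)
    else:
        scores = (M / 2.0) * (sx_pred + sx_orth + sy_pred + sy_orth)
    return VIPScores(
        scores=scores,
        variant=variant,
        component_counts=(model.n_predictive_, lo),
        effective_variable_counts={"m": m, "m_o": m_o, "M": M},
    )


def classify_by_vip(
    scores: VIPScores | np.ndarray,
    relevant_threshold: float = 1.0,
    irrelevant_threshold: float = 0.5,
):
    """Three-way relevance labels from VIP scores.

    Thresholds are strict: score > 1 is relevant, score < 0.5 irrelevant,
    scores in [0.5, 1] intermediate.  Returns the label array and the count
    per label.
    """
    if irrelevant_threshold > relevant_threshold:
        raise ValueError("irrelevant_threshold must be <= relevant_threshold")
    values = scores.scores if isinstance(scores, VIPScores) else np.asarray(scores)
    labels = np.full(values.shape, "intermediate", dtype=object)
    labels[values > relevant_threshold] = "relevant"
    labels[values < irrelevant_threshold] = "irrelevant"
    counts = {lab: int((labels == lab).sum()) for lab in _LABELS}
    return labels, counts
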
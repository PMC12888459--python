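"""Multi-criteria indicator weighting and composite efficacy scoring.

Combines a subjective weighting (analytic hierarchy process, AHP: principal
eigenvector of a positive reciprocal pairwise-comparison matrix with Saaty's
consistency ratio) with an objective one (entropy weight method, EWM:
information divergence of each indicator across alternatives), and applies
the resulting weights as a linear composite score over a positively oriented
efficacy panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import EfficacyPanel, ValidationError

__all__ = ["WeightScheme", "AHPResult", "ahp_weights", "ewm_weights",
           "combine_weights", "composite_score", "SAATY_RI"]

logger = logging.getLogger(__name__)

# Saaty random-consistency index by matrix order.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
            7: 1.32, 8: 1.41, 9: 1.45}


@dataclass
class WeightScheme:
    """Per-indicator weights summing to one."""

    weights: pd.Series
    provenance: str = "supplied"  # AHP | EWM | combined | supplied

    def __post_init__(self) -> None:
        self.weights = self.weights.astype(float)
        if (self.weights < 0).any():
            raise ValidationError("negative weights")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(f"weights sum to {total}, expected 1")
        if self.weights.index.has_duplicates:
            raise ValidationError("duplicate indicator ids in weights")

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.weights.index)

    @classmethod
    def from_values(cls, values, indicator_ids=None, provenance="supplied",
                    normalize=False) -> "WeightScheme":
        w = pd.Series(np.asarray(values, float), index=indicator_ids)
        if normalize:
            w = w / w.sum()
        return cls(weights=w, provenance=provenance)


@dataclass
class AHPResult:
    """Fitted pairwise-comparison weighting with consistency diagnostics."""

    weights: WeightScheme
    lambda_max: float
    consistency_ratio: float
    matrix: np.ndarray


def _check_reciprocal(a: np.ndarray) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] < 2:
        raise ValidationError("comparison matrix must be square with n >= 2")
    if (a <= 0).any():
        raise ValidationError("comparison matrix must be strictly positive")
    if not np.allclose(np.diag(a), 1.0, atol=1e-9):
        raise ValidationError("comparison matrix diagonal must be 1")
    if not np.allclose(a * a.T, 1.0, rtol=1e-6):
        raise ValidationError("matrix is not reciprocal (a_ij != 1/a_ji)")


def ahp_weights(matrix, indicator_ids=None, tol: float = 1e-12,
                max_iter: int = 10_000) -> AHPResult:
    """Principal-eigenvector weights of a positive reciprocal matrix.

    Power iteration to ``tol``; the consistency ratio is
    ``[(λmax − n) / (n − 1)] / RI(n)`` with Saaty's random index.  A ratio at
    or above 0.1 signals inconsistent judgements and is logged as a warning.
    """
    if isinstance(matrix, pd.DataFrame):
        indicator_ids = indicator_ids or list(matrix.columns)
        matrix = matrix.to_numpy(float)
    a = np.asarray(matrix, dtype=float)
    _check_reciprocal(a)
    n = a.shape[0]

    v = np.full(n, 1.0 / n)
    lam = float("nan")
    for _ in range(max_iter):
        av = a @ v
        v_new = av / av.sum()
        lam = float(av.sum())  # since v sums to 1, sum(Av) estimates λmax
        if np.abs(v_new - v).max() < tol:
            v = v_new
            break
        v = v_new
    # refresh λmax with a Rayleigh-style estimate at the converged vector
    lam = float(np.mean((a @ v) / v))

    ci = (lam - n) / (n - 1)
    ri = SAATY_RI.get(n)
    if ri is None:
        raise ValidationError(f"no random-consistency index for n={n}")
    cr = 0.0 if ri == 0 else ci / ri
    cr = max(cr, 0.0)
    if cr >= 0.1:
        logger.warning("AHP consistency ratio %.3f >= 0.1: judgements "
                       "are inconsistent", cr)
    scheme = WeightScheme.from_values(v, indicator_ids, provenance="AHP",
                                      normalize=True)
    return AHPResult(weights=scheme, lambda_max=lam, consistency_ratio=cr,
                     matrix=a)


def ewm_weights(panel: EfficacyPanel) -> WeightScheme:
    """Entropy weights across groups for a positively oriented panel.

    Per indicator: min-max normalize across groups, convert to shares
    ``p_ij``, entropy ``e_j = −(1/ln n) Σ p ln p`` (with ``0·ln 0 := 0``),
    divergence ``d_j = 1 − e_j``, weights ``d_j / Σ d``.  Constant indicators
    carry zero divergence and receive weight zero.
    """
    if panel.values.shape[0] < 2:
        raise ValidationError("EWM needs at least 2 groups")
    if not panel.orientation.all():
        raise ValidationError("EWM expects all indicators positively oriented")
    x = panel.values.to_numpy(float)
    n = x.shape[0]
    rng_ = x.max(axis=0) - x.min(axis=0)
    d = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if rng_[j] == 0:
            continue  # constant column: zero divergence
        xp = (x[:, j] - x[:, j].min()) / rng_[j]
        total = xp.sum()
        p = xp / total
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e = -plogp.sum() / np.log(n)
        d[j] = 1.0 - e
    if d.sum() == 0:
        raise ValidationError("all indicators constant: entropy weights undefined")
    return WeightScheme.from_values(d / d.sum(), list(panel.values.columns),
                                    provenance="EWM")


def combine_weights(w_ahp: WeightScheme, w_ewm: WeightScheme,
                    method: str = "multiplicative") -> WeightScheme:
    """Merge subjective and objective weights over identical indicator sets.

    ``multiplicative`` (default): ``w_j ∝ a_j·b_j``; ``arithmetic_mean``:
    ``w_j = (a_j + b_j)/2``.  Output renormalized to sum one.
    """
    if set(w_ahp.indicator_ids) != set(w_ewm.indicator_ids):
        raise ValidationError("indicator sets differ between weight schemes")
    a = w_ahp.weights
    b = w_ewm.weights.reindex(a.index)
    if method == "multiplicative":
        w = a * b
        if w.sum() == 0:
            raise ValidationError("all products zero; combined weights undefined")
    elif method == "arithmetic_mean":
        w = (a + b) / 2.0
    else:
        raise ValueError(f"unknown combination method {method!r}")
    return WeightScheme.from_values(w / w.sum(), list(a.index),
                                    provenance="combined")


def composite_score(panel: EfficacyPanel, scheme: WeightScheme) -> pd.Series:
    """Weighted sum of positively oriented indicators per group.

    Returns scores in descending order (best formulation first); no further
    rescaling is applied, so with indicators on a percent scale the score is
    itself percent-like.
    """
    missing = [i for i in scheme.indicator_ids if i not in panel.values.columns]
    if missing:
        raise ValidationError(f"panel lacks indicators {missing}")
    values = panel.values[scheme.indicator_ids]
    scores = values.mul(scheme.weights, axis=1).sum(axis=1)
    scores.name = "composite_score"
    return scores.sort_values(ascending=False, kind="stable")
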
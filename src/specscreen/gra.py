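"""Grey relational analysis (Deng formulation).

Measures how closely each peak subsequence tracks a pharmacodynamic parent
sequence.  The relational coefficient at point ``k`` for subsequence ``i`` is

    ε_i(k) = (Δmin + ρ·Δmax) / (Δ_oi(k) + ρ·Δmax)

where ``Δ_oi(k) = |parent(k) − x_i(k)|`` and the extremes Δmin/Δmax are taken
globally over all subsequences and points of one parent.  The grey relational
degree (GRD) of a subsequence is the mean of its coefficients; ρ is the
distinguishing coefficient, conventionally 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import ValidationError

__all__ = ["GRAResult", "gray_relational", "grd_screen"]


def _normalize(seq: np.ndarray, mode: str) -> np.ndarray:
    """Optional per-sequence rescaling applied before differencing."""
    if mode == "none":
        return seq
    if mode == "minmax":
        rng = seq.max() - seq.min()
        return (seq - seq.min()) / rng if rng > 0 else np.zeros_like(seq)
    if mode == "mean":
        m = seq.mean()
        if m == 0:
            raise ValidationError("mean normalization undefined for zero-mean sequence")
        return seq / m
    if mode == "initial":
        if seq[0] == 0:
            raise ValidationError("initial-value normalization undefined: first value 0")
        return seq / seq[0]
    raise ValueError(f"unknown normalization {mode!r}")


@dataclass
class GRAResult:
    """Coefficients and degrees of one grey relational run."""

    parent_id: str
    rho: float
    coefficients: pd.DataFrame  # subsequences × points
    grd: pd.Series              # per subsequence, original order
    delta_min: float
    delta_max: float

    @property
    def ranking(self) -> pd.Series:
        """GRD in descending order; ties broken by subsequence id."""
        df = self.grd.rename("grd").to_frame()
        df["_id"] = df.index
        df = df.sort_values(["grd", "_id"], ascending=[False, True], kind="stable")
        return df["grd"]


def gray_relational(parent, subsequences: pd.DataFrame, rho: float = 0.5,
                    normalization: str = "none",
                    parent_id: str = "parent") -> GRAResult:
    """Grey relational coefficients and degrees of peak rows vs one indicator.

    Parameters
    ----------
    parent
        Indicator sequence over observations (Series or 1-D array).
    subsequences
        Peaks × observations matrix, typically already standardized upstream.
    rho
        Distinguishing coefficient in (0, 1].
    normalization
        ``none`` (default: sequences used as supplied), or classic GRA
        preprocessing applied per sequence: ``minmax``, ``mean``, ``initial``.
    """
    if not 0 < rho <= 1:
        raise ValidationError(f"rho must be in (0, 1], got {rho}")
    p = np.asarray(parent, dtype=float).ravel()
    if isinstance(parent, pd.Series) and parent.name:
        parent_id = str(parent.name)
    x = subsequences.to_numpy(float)
    if x.shape[1] != p.size:
        raise ValidationError(
            f"length mismatch: parent has {p.size} points, "
            f"subsequences have {x.shape[1]}"
        )
    if p.size < 2:
        raise ValidationError("sequences need at least 2 points")

    p = _normalize(p, normalization)
    if normalization != "none":
        x = np.apply_along_axis(_normalize, 1, x, normalization)

    delta = np.abs(p[None, :] - x)          # subsequences × points
    dmin = float(delta.min())
    dmax = float(delta.max())
    if dmax == 0:  # every subsequence identical to parent
        eps = np.ones_like(delta)
    else:
        eps = (dmin + rho * dmax) / (delta + rho * dmax)
    coefficients = pd.DataFrame(eps, index=subsequences.index,
                                columns=subsequences.columns)
    grd = pd.Series(eps.mean(axis=1), index=subsequences.index, name="grd")
    return GRAResult(parent_id=parent_id, rho=rho, coefficients=coefficients,
                     grd=grd, delta_min=dmin, delta_max=dmax)


def grd_screen(result: GRAResult, threshold: float = 0.8, k: int = 5) -> list[str]:
    """Subsequence ids with GRD strictly above ``threshold``, top ``k`` by GRD.

    Ties at the cutoff are broken toward the lexicographically lower id.
    """
    ranked = result.ranking
    survivors = ranked[ranked > threshold]
    return list(survivors.index[:k])
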
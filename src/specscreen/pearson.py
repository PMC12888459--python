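"""Peak-by-indicator Pearson correlation screening."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import PeakTable, ValidationError

__all__ = ["CorrelationResult", "pearson_screen"]


@dataclass
class CorrelationResult:
    """Per-peak correlation against one indicator."""

    indicator_id: str
    table: pd.DataFrame  # columns r, p, abs_r, rank; index peak ids
    n: int
    top: list[str]       # top-k peak ids by ranking rule


def pearson_screen(peaks, efficacy, k: int = 5,
                   signed: bool = False) -> CorrelationResult:
    """Correlate every peak row with one indicator sequence and rank.

    Parameters
    ----------
    peaks
        :class:`PeakTable` (typically standardized) or peaks × observations
        DataFrame.
    efficacy
        Indicator values over the same observations (Series or 1-D array).
    k
        Number of top-ranked peaks to return.
    signed
        Rank by signed ``r`` descending instead of ``|r|`` descending.
        Default ranks by magnitude: a constituent whose abundance tracks the
        outcome inversely is as informative for screening as a direct tracker.

    The two-sided p-value comes from ``t = r·√((n−2)/(1−r²))`` against the
    t(n−2) reference.  Constant peak rows have undefined ``r`` and are skipped
    with a warning; ties in the ranking are broken by peak id.
    """
    x = peaks.areas if isinstance(peaks, PeakTable) else peaks
    y = np.asarray(efficacy, dtype=float).ravel()
    indicator_id = str(getattr(efficacy, "name", None) or "indicator")
    if x.shape[1] != y.size:
        raise ValidationError("observation count mismatch between peaks and indicator")
    n = y.size
    if n < 3:
        raise ValidationError("Pearson screening needs at least 3 observations")
    if np.std(y) == 0:
        raise ValidationError("indicator is constant; correlation undefined")

    xv = x.to_numpy(float)
    sd = xv.std(axis=1)
    constant = sd == 0
    if constant.any():
        skipped = [p for p, c in zip(x.index, constant) if c]
        warnings.warn(f"constant peaks skipped: {skipped}", stacklevel=2)
    if constant.all():
        warnings.warn("all peaks constant; empty ranking", stacklevel=2)
        empty = pd.DataFrame(columns=["r", "p", "abs_r", "rank"])
        return CorrelationResult(indicator_id, empty, n, [])

    xc = xv - xv.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)

    table = pd.DataFrame({"r": r, "p": p, "abs_r": np.abs(r)}, index=x.index)
    table = table[~constant]
    key = "r" if signed else "abs_r"
    table["_id"] = table.index
    table = table.sort_values([key, "_id"], ascending=[False, True],
                              kind="stable").drop(columns="_id")
    table["rank"] = np.arange(1, len(table) + 1)
    return CorrelationResult(indicator_id=indicator_id, table=table, n=n,
                             top=list(table.index[:k]))
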
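"""Pharmacodynamic scoring and preprocessing.

Implements the weighted histology lung-injury score, the inhibition-rate
positive transformation that re-orients every indicator so that larger is
better, and the relative standard deviation used in chromatographic method
validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import EfficacyPanel, ValidationError

__all__ = ["FieldScore", "lung_injury_score", "inhibition_rate",
           "positive_transform", "rsd"]

# Weighting of the five histology parameters per high-power field:
# A neutrophils in alveolar space, B neutrophils in interstitial space,
# C hyaline membranes, D proteinaceous debris, E alveolar septal thickening.
_FIELD_WEIGHTS = (20, 14, 7, 7, 2)


@dataclass(frozen=True)
class FieldScore:
    """Histology grades (0–2) for one microscope field."""

    A: int
    B: int
    C: int
    D: int
    E: int

    def __post_init__(self) -> None:
        for name in "ABCDE":
            g = getattr(self, name)
            if g not in (0, 1, 2):
                raise ValueError(f"grade {name}={g!r} outside {{0, 1, 2}}")


def lung_injury_score(fields: Iterable[FieldScore]) -> float:
    """Weighted lung-injury score over scored fields, on the [0, 1] scale.

    Each field contributes 20·A + 14·B + 7·C + 7·D + 2·E points, and the sum
    is divided by (number of fields × 100), so a field with every grade at
    its maximum contributes exactly 1.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("at least one scored field required")
    total = sum(
        sum(w * g for w, g in zip(_FIELD_WEIGHTS, (f.A, f.B, f.C, f.D, f.E)))
        for f in fields
    )
    return total / (len(fields) * 100.0)


def inhibition_rate(model_value: float, treatment_value: float) -> float:
    """Percent reduction of an indicator relative to the untreated model group.

    ``(model − treatment) / model × 100``; negative when treatment worsens
    the indicator.
    """
    if model_value == 0:
        raise ZeroDivisionError("model group value is zero; rate undefined")
    return (model_value - treatment_value) / model_value * 100.0


def positive_transform(raw: EfficacyPanel, model_group: str) -> EfficacyPanel:
    """Replace every indicator by its inhibition rate vs the model group.

    The model-group row is removed from the output and every indicator is
    flagged higher-is-better.
    """
    if model_group not in raw.values.index:
        raise KeyError(f"model group {model_group!r} not in panel")
    model = raw.values.loc[model_group]
    if (model == 0).any():
        zero = list(model.index[model == 0])
        raise ZeroDivisionError(f"model group has zero values for {zero}")
    treated = raw.values.drop(index=model_group)
    rates = (model - treated) / model * 100.0
    orientation = pd.Series(True, index=raw.values.columns)
    return EfficacyPanel(values=rates, orientation=orientation)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (percent), sample sd over mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("RSD needs at least 2 replicate values")
    mean = x.mean()
    if mean == 0:
        raise ZeroDivisionError("mean of replicates is zero; RSD undefined")
    return x.std(ddof=1) / mean * 100.0
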
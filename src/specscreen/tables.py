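"""Core data containers and I/O for fingerprint peak tables and efficacy panels.

The two central objects are :class:`PeakTable` (chromatographic characteristic
peaks × observations, where an observation is either a formulation group mean
or an individual sample) and :class:`EfficacyPanel` (groups × pharmacodynamic
indicators).  Both wrap pandas DataFrames and validate their invariants on
construction.

Packaged fixtures carry the published reference tables for a two-herb
decoction study: 57 characteristic peaks (A1–A40 at 254 nm, B1–B17 at 440 nm)
across four raw/processed formulation groups PW1–PW4, the positively
transformed pharmacodynamic panel with its composite ratings, the printed
multi-criteria weights, the three-method consensus sets, and the network
centrality table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "EfficacyPanel",
    "CompoundAnnotation",
    "ValidationError",
    "load_peak_table",
    "load_efficacy_panel",
    "write_peak_table",
    "write_efficacy_panel",
    "standardize_peaks",
    "load_fixture",
    "FIXTURE_NAMES",
]


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass
class PeakTable:
    """Peaks × observations abundance matrix with per-peak metadata.

    Parameters
    ----------
    areas
        Nonnegative matrix, rows indexed by unique peak ids (e.g. ``"A11"``),
        columns by observation labels (group or sample names).
    area_sd
        Optional matrix of the same shape holding standard deviations, used
        for group-mean tables published as ``mean ± sd``.
    meta
        Optional per-peak metadata (retention time ``rt_min``, ``compound``
        name, source ``herb`` in {``SR``, ``GF``}, ``wavelength_nm``),
        indexed like ``areas``.
    """

    areas: pd.DataFrame
    area_sd: pd.DataFrame | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.areas = self.areas.astype(float)
        if self.areas.index.has_duplicates:
            dupes = self.areas.index[self.areas.index.duplicated()].unique()
            raise ValidationError(f"duplicate peak ids: {list(dupes)}")
        if self.areas.isna().any().any():
            raise ValidationError("missing values in areas are not allowed")
        if (self.areas.to_numpy() < 0).any():
            raise ValidationError("negative peak areas")
        if self.area_sd is not None:
            self.area_sd = self.area_sd.astype(float)
            if self.area_sd.shape != self.areas.shape:
                raise ValidationError("area_sd shape differs from areas")
            if (self.area_sd.to_numpy() < 0).any():
                raise ValidationError("negative area standard deviations")
        if self.meta is not None and not self.meta.index.equals(self.areas.index):
            self.meta = self.meta.reindex(self.areas.index)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def observations(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def herb_map(self) -> pd.Series | None:
        """Source herb per peak, when metadata carries a ``herb`` column."""
        if self.meta is not None and "herb" in self.meta.columns:
            return self.meta["herb"]
        return None

    def select_peaks(self, peak_ids: Iterable[str]) -> "PeakTable":
        ids = list(peak_ids)
        missing = [p for p in ids if p not in self.areas.index]
        if missing:
            raise KeyError(f"unknown peak ids: {missing}")
        return PeakTable(
            areas=self.areas.loc[ids],
            area_sd=None if self.area_sd is None else self.area_sd.loc[ids],
            meta=None if self.meta is None else self.meta.loc[ids],
        )


@dataclass
class EfficacyPanel:
    """Groups × pharmacodynamic indicators with per-indicator orientation.

    ``orientation`` flags whether larger values mean better outcome; after the
    inhibition-rate positive transformation every indicator is
    higher-is-better.
    """

    values: pd.DataFrame
    orientation: pd.Series | None = None  # True = higher is better

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate indicator ids")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate group ids")
        if self.orientation is None:
            self.orientation = pd.Series(True, index=self.values.columns)
        else:
            self.orientation = self.orientation.reindex(self.values.columns)
            if self.orientation.isna().any():
                raise ValidationError("orientation missing for some indicators")
            self.orientation = self.orientation.astype(bool)

    @property
    def group_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)

    def indicator(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise KeyError(f"unknown indicator {name!r}")
        return self.values[name]

    def select_indicators(self, indicator_ids: Iterable[str]) -> "EfficacyPanel":
        ids = list(indicator_ids)
        return EfficacyPanel(self.values[ids], self.orientation[ids])


@dataclass(frozen=True)
class CompoundAnnotation:
    """Identity card for one characteristic peak."""

    peak_id: str
    compound: str
    herb: str
    lung_tissue_detected: bool = False


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_PM_RE = re.compile(r"^\s*([0-9.,eE+-]+)\s*±\s*([0-9.,eE+-]+)\s*$")


def _parse_number(text: str) -> float:
    return float(str(text).replace(",", ""))


def load_peak_table(path: str | Path, dialect: str = "samples") -> PeakTable:
    """Read a peak table from CSV/TSV.

    ``samples`` dialect: plain numeric matrix, first column peak ids, header
    row observation labels.  ``group_means`` dialect: cells either
    ``"mean ± sd"`` strings or paired ``<group>_mean`` / ``<group>_sd``
    columns; non-numeric trailing columns (``compound``, ``herb``, ...) are
    collected into metadata.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique()
        raise ValidationError(f"duplicate peak ids in {path.name}: {list(dupes)}")

    if dialect == "samples":
        try:
            areas = raw.apply(lambda col: col.map(_parse_number))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric cell in {path.name}: {exc}") from exc
        return PeakTable(areas=areas)

    if dialect != "group_means":
        raise ValueError(f"unknown dialect {dialect!r}")

    mean_cols = [c for c in raw.columns if c.endswith("_mean")]
    if mean_cols:  # paired-column encoding
        groups = [c[: -len("_mean")] for c in mean_cols]
        areas = pd.DataFrame(
            {g: raw[f"{g}_mean"].map(_parse_number) for g in groups}, index=raw.index
        )
        sd = pd.DataFrame(
            {
                g: raw[f"{g}_sd"].map(_parse_number)
                for g in groups
                if f"{g}_sd" in raw.columns
            },
            index=raw.index,
        )
        area_sd = sd if sd.shape[1] == len(groups) else None
        meta_cols = [
            c
            for c in raw.columns
            if not (c.endswith("_mean") or c.endswith("_sd"))
        ]
        meta = raw[meta_cols].copy() if meta_cols else None
        if meta is not None and "rt_min" in meta.columns:
            meta["rt_min"] = meta["rt_min"].map(_parse_number)
        return PeakTable(areas=areas, area_sd=area_sd, meta=meta)

    # "mean ± sd" cell encoding
    means, sds = {}, {}
    meta_cols: dict[str, pd.Series] = {}
    for col in raw.columns:
        sample = raw[col].dropna().astype(str)
        if sample.str.contains("±").all() and len(sample):
            m = sample.str.extract(_PM_RE)
            if m.isna().any().any():
                bad = sample[m.isna().any(axis=1)].index.tolist()
                raise ValidationError(f"unparseable mean ± sd cells at {bad}")
            means[col] = m[0].map(_parse_number).reindex(raw.index)
            sds[col] = m[1].map(_parse_number).reindex(raw.index)
        else:
            meta_cols[col] = raw[col]
    if not means:
        raise ValidationError("no 'mean ± sd' columns found")
    areas = pd.DataFrame(means, index=raw.index)
    if areas.isna().any().any():
        raise ValidationError("ragged rows: some groups missing values")
    return PeakTable(
        areas=areas,
        area_sd=pd.DataFrame(sds, index=raw.index),
        meta=pd.DataFrame(meta_cols) if meta_cols else None,
    )


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write areas (and sd, metadata when present) to CSV, round-trip safe."""
    path = Path(path)
    if table.area_sd is None and table.meta is None:
        df = table.areas.copy()
        df.index.name = df.index.name or "peak_id"
        df.to_csv(path)  # pandas default repr round-trips floats exactly
        return
    parts = {}
    for g in table.areas.columns:
        parts[f"{g}_mean"] = table.areas[g]
        if table.area_sd is not None:
            parts[f"{g}_sd"] = table.area_sd[g]
    df = pd.DataFrame(parts)
    if table.meta is not None:
        df = pd.concat([df, table.meta], axis=1)
    df.index.name = "peak_id"
    df.to_csv(path)


def load_efficacy_panel(path: str | Path) -> EfficacyPanel:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    values = pd.read_csv(path, sep=sep, index_col=0)
    return EfficacyPanel(values=values)


def write_efficacy_panel(panel: EfficacyPanel, path: str | Path) -> None:
    df = panel.values.copy()
    df.index.name = df.index.name or "group"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def standardize_peaks(table: PeakTable) -> PeakTable:
    """Z-score every peak row to zero mean and unit sample sd (n−1 denominator).

    Constant rows (zero variance) map to all-zero with a warning; they carry
    no between-observation information.
    """
    if table.areas.shape[1] < 2:
        raise ValidationError("standardization needs at least 2 observations")
    x = table.areas.to_numpy(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        ids = [p for p, c in zip(table.peak_ids, constant) if c]
        warnings.warn(
            f"constant peak rows standardized to zero: {ids}", stacklevel=2
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[constant, :] = 0.0
    zdf = pd.DataFrame(z, index=table.areas.index, columns=table.areas.columns)
    # z-scores are signed; bypass the nonnegativity check via direct construction
    out = PeakTable.__new__(PeakTable)
    out.areas = zdf
    out.area_sd = None
    out.meta = None if table.meta is None else table.meta.copy()
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "table3": "table3_peak_areas.csv",
    "table6": "table6_efficacy.csv",
    "table8": "table8_consensus.csv",
    "table9": "table9_centrality.csv",
    "weights": "ahp_ewm_weights.csv",
}

FIXTURE_NAMES = (
    "table3",
    "table6",
    "table8",
    "table9",
    "weights",
    "herb_map",
    "herb_map_network",
)


def _fixture_path(filename: str) -> Path:
    return Path(str(resources.files("specscreen") / "fixtures" / filename))


def load_fixture(name: str):
    """Return a packaged reference table by short name.

    ``table3``  → :class:`PeakTable` of 57 peak group means ± sd (PW1–PW4);
    ``table6``  → :class:`EfficacyPanel`, positively transformed, including the
    ``Overall rating`` column;
    ``table8``  → dict mapping each indicator to its ordered consensus peak list;
    ``table9``  → DataFrame of published per-compound network centralities;
    ``weights`` → pandas Series of the published seven indicator weights;
    ``herb_map`` → Series peak id → source herb from the chemistry table;
    ``herb_map_network`` → alternate map from the network table's Source column.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    if name == "table3":
        return load_peak_table(_fixture_path(_FIXTURE_FILES["table3"]), "group_means")
    if name == "table6":
        return load_efficacy_panel(_fixture_path(_FIXTURE_FILES["table6"]))
    if name == "table8":
        df = pd.read_csv(_fixture_path(_FIXTURE_FILES["table8"]))
        sets: dict[str, list[str]] = {}
        for indicator, sub in df.groupby("indicator", sort=False):
            sets[indicator] = list(sub["peak_id"])
        return sets
    if name == "table9":
        return pd.read_csv(
            _fixture_path(_FIXTURE_FILES["table9"]), index_col="peak_id"
        )
    if name == "weights":
        df = pd.read_csv(_fixture_path(_FIXTURE_FILES["weights"]), index_col="indicator")
        return df["weight"]
    if name == "herb_map":
        table3 = load_fixture("table3")
        return table3.meta["herb"].copy()
    if name == "herb_map_network":
        return load_fixture("table9")["herb"].copy()
    raise AssertionError("unreachable")
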
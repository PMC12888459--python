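"""Synthetic fingerprint–efficacy datasets with planted ground truth.

The generator emulates the structure of a multi-formulation fingerprint
study: strictly positive, right-skewed peak abundances (log-normal group
means, log-normal replicate noise at a fixed coefficient of variation) and
pharmacodynamic indicators that are noisy linear combinations of a planted
subset of "active" peaks on the standardized scale, mapped onto a positive
inhibition-rate-like scale.  Every run is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import EfficacyPanel, PeakTable, ValidationError

__all__ = ["SimConfig", "SimTruth", "RecoveryReport", "simulate_dataset",
           "group_mean_table", "recovery_report"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults describe a mid-sized calibration study: 12 formulation groups
    with 6 replicate injections, 50 characteristic peaks of which 5 drive
    efficacy with unit effect size on the standardized scale, 10 % replicate
    coefficient of variation, and indicator noise of 0.25 sd relative to
    unit-variance standardized abundances.  ``effect_offset``/``effect_scale``
    map the latent linear effect onto a percent-like inhibition-rate scale.
    """

    n_groups: int = 12
    n_replicates: int = 6
    n_peaks: int = 50
    n_active: int = 5
    n_indicators: int = 7
    beta: tuple[float, ...] | None = None  # None → +1 per active peak
    cv: float = 0.1
    noise_sd: float = 0.25
    log_mean: float = 10.0
    log_sd: float = 0.5
    effect_offset: float = 50.0
    effect_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active > self.n_peaks:
            raise ValidationError("n_active exceeds n_peaks")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if min(self.n_groups, self.n_replicates, self.n_peaks,
               self.n_indicators) < 1:
            raise ValidationError("dimensions must be positive")
        if self.beta is not None and len(self.beta) != self.n_active:
            raise ValidationError("beta length must equal n_active")


@dataclass
class SimTruth:
    """Planted ground truth of one simulated dataset."""

    config: SimConfig
    active_ids: list[str]
    beta: np.ndarray
    group_means: pd.DataFrame        # peaks × groups, noiseless group level
    noiseless_efficacy: pd.DataFrame  # groups × indicators, before noise
    replicate_groups: pd.Series       # sample label → group label


def _peak_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def simulate_dataset(cfg: SimConfig) -> tuple[PeakTable, EfficacyPanel, SimTruth]:
    """Draw one dataset: replicate-level peak areas, group-level efficacy, truth.

    Group-level peak means are iid log-normal; replicates scatter around the
    group mean multiplicatively at coefficient of variation ``cfg.cv``.  Each
    indicator is ``offset + scale·(Σ_active β_j z_gj + ε)`` with ``z`` the
    per-peak standardized group means and ``ε ~ N(0, noise_sd)``.
    """
    rng = np.random.default_rng(cfg.seed)
    peaks = _peak_ids(cfg.n_peaks)
    gw = len(str(cfg.n_groups))
    groups = [f"G{g + 1:0{gw}d}" for g in range(cfg.n_groups)]

    # group-level means, log-normal baseline
    log_means = rng.normal(cfg.log_mean, cfg.log_sd,
                           size=(cfg.n_peaks, cfg.n_groups))
    group_means = np.exp(log_means)

    # replicates: multiplicative log-normal noise with the requested CV
    sigma_rep = np.sqrt(np.log1p(cfg.cv ** 2))
    rep_labels, rep_groups, columns = [], [], []
    areas = np.empty((cfg.n_peaks, cfg.n_groups * cfg.n_replicates))
    col = 0
    for g, gname in enumerate(groups):
        for r in range(cfg.n_replicates):
            noise = rng.normal(0.0, sigma_rep, size=cfg.n_peaks)
            # mean-preserving multiplicative noise
            areas[:, col] = group_means[:, g] * np.exp(noise - sigma_rep ** 2 / 2)
            label = f"{gname}:r{r + 1}"
            columns.append(label)
            rep_labels.append(label)
            rep_groups.append(gname)
            col += 1

    # planted actives and latent standardized signal
    active_idx = rng.choice(cfg.n_peaks, size=cfg.n_active, replace=False)
    active_idx.sort()
    beta = (np.ones(cfg.n_active) if cfg.beta is None
            else np.asarray(cfg.beta, float))
    z = ((group_means - group_means.mean(axis=1, keepdims=True))
         / group_means.std(axis=1, ddof=1, keepdims=True))
    signal = beta @ z[active_idx]  # per group

    ind_ids = [f"I{i + 1}" for i in range(cfg.n_indicators)]
    eff = np.empty((cfg.n_groups, cfg.n_indicators))
    for i in range(cfg.n_indicators):
        eps = rng.normal(0.0, cfg.noise_sd, size=cfg.n_groups)
        eff[:, i] = cfg.effect_offset + cfg.effect_scale * (signal + eps)

    table = PeakTable(
        areas=pd.DataFrame(areas, index=pd.Index(peaks, name="peak_id"),
                           columns=columns)
    )
    panel = EfficacyPanel(
        values=pd.DataFrame(eff, index=pd.Index(groups, name="group"),
                            columns=ind_ids)
    )
    noiseless = pd.DataFrame(
        cfg.effect_offset + cfg.effect_scale * np.tile(signal[:, None],
                                                       cfg.n_indicators),
        index=panel.values.index, columns=ind_ids,
    )
    truth = SimTruth(
        config=cfg,
        active_ids=[peaks[i] for i in active_idx],
        beta=beta,
        group_means=pd.DataFrame(group_means,
                                 index=pd.Index(peaks, name="peak_id"),
                                 columns=groups),
        noiseless_efficacy=noiseless,
        replicate_groups=pd.Series(rep_groups, index=rep_labels, name="group"),
    )
    return table, panel, truth


def group_mean_table(table: PeakTable, groups: pd.Series) -> PeakTable:
    """Average replicate observations into group-level columns.

    ``groups`` maps each observation label to its group; column order follows
    first appearance.
    """
    groups = pd.Series(groups)
    missing = [c for c in table.observations if c not in groups.index]
    if missing:
        raise ValidationError(f"observations without group assignment: {missing}")
    order = pd.unique(groups.loc[table.observations])
    means = table.areas.T.groupby(groups, sort=False).mean().T[order]
    return PeakTable(areas=means, meta=table.meta)


@dataclass(frozen=True)
class RecoveryReport:
    """Sensitivity/precision of a screened list against planted actives."""

    sensitivity: float
    precision: float
    n_hit: int
    n_active: int
    n_screened: int


def recovery_report(truth: SimTruth, screened) -> RecoveryReport:
    """Score a screened compound list against the planted active set.

    Sensitivity = |screened ∩ active| / |active|; precision =
    |screened ∩ active| / |screened|.  Empty-over-empty cases score 1;
    other zero denominators are reported as NaN.
    """
    active = set(truth.active_ids)
    found = set(screened)
    hit = len(active & found)
    if active:
        sensitivity = hit / len(active)
    else:
        sensitivity = 1.0 if not found else float("nan")
    if found:
        precision = hit / len(found)
    else:
        precision = 1.0 if not active else float("nan")
    return RecoveryReport(sensitivity=sensitivity, precision=precision,
                          n_hit=hit, n_active=len(active),
                          n_screened=len(found))
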
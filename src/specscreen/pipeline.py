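"""End-to-end orchestration: standardize → score → screen → consensus → network.

The library entry point is :func:`run_pipeline`, which consumes a
:class:`RunConfig`, executes every stage, writes CSV/JSON/GraphML artifacts
into an output directory and returns an in-memory :class:`PipelineResult`
together with a JSON manifest sufficient to re-run the identical analysis.
:func:`screen_all` is the reusable core that applies the three correlation
engines per indicator and intersects them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gra import gray_relational
from .network import (ConsensusNetwork, ConsensusTable, MethodRules,
                      build_network, intersect_sets, median_filter,
                      method_sets, union_dedup, write_graphml, write_sif)
from .opls import fit_opls, vip
from .pearson import pearson_screen
from .pharmacodynamics import positive_transform
from .simulate import (RecoveryReport, SimConfig, group_mean_table,
                       recovery_report, simulate_dataset)
from .tables import (EfficacyPanel, PeakTable, ValidationError, load_fixture,
                     load_efficacy_panel, load_peak_table, standardize_peaks)
from .weighting import WeightScheme, composite_score, ewm_weights

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "StageError", "screen_all",
           "run_pipeline"]

OVERALL = "Overall rating"


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline settings; every threshold has the documented default.

    Inputs resolve in this order: ``simulate`` (generate synthetically),
    explicit ``peaks_path``/``efficacy_path``, or the packaged reference
    fixtures.  ``model_group`` triggers the inhibition-rate positive
    transformation; leave ``None`` when the panel is already positively
    transformed.  ``weight_source`` is ``supplied`` (packaged published
    weights or ``weights_path``) or ``ewm`` (entropy weights computed from
    the panel).
    """

    peaks_path: str | None = None
    efficacy_path: str | None = None
    weights_path: str | None = None
    use_fixtures: bool = True
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    model_group: str | None = None
    weight_source: str = "supplied"     # supplied | ewm
    pearson_top_k: int = 5
    grd_threshold: float = 0.8
    gra_top_k: int = 10
    vip_threshold: float = 1.0
    rho: float = 0.5
    gra_parent: str = "standardized"    # standardized | raw
    n_orth: int = 1
    folds: int = 7
    n_perm: int = 200
    k_of_3: int = 2
    include_overall: bool = True
    seed: int = 0
    out_dir: str | None = None

    @property
    def rules(self) -> MethodRules:
        return MethodRules(pearson_top_k=self.pearson_top_k,
                           grd_threshold=self.grd_threshold,
                           gra_top_k=self.gra_top_k,
                           vip_threshold=self.vip_threshold)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    peaks: PeakTable
    peaks_standardized: PeakTable
    panel: EfficacyPanel
    weights: WeightScheme | None
    scores: pd.Series | None
    screen_tables: dict[str, pd.DataFrame]
    consensus: ConsensusTable
    union: pd.Series
    network: ConsensusNetwork
    flagged: list[str]
    recovery: RecoveryReport | None
    manifest: dict


def _zscore(y: pd.Series) -> pd.Series:
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValidationError(f"indicator {y.name!r} is constant")
    return (y - y.mean()) / sd


def screen_all(peaks_std: PeakTable, panel: EfficacyPanel,
               rules: MethodRules = MethodRules(), rho: float = 0.5,
               gra_parent: str = "standardized",
               n_orth: int = 1) -> tuple[ConsensusTable, dict[str, pd.DataFrame]]:
    """Run Pearson, GRA and OPLS-VIP per indicator and intersect.

    ``peaks_std`` must be standardized (z-scored rows); the GRA parent is the
    indicator z-scored to the same scale by default (``gra_parent="raw"``
    feeds the indicator as supplied).  Returns the consensus table plus one
    tidy per-indicator DataFrame of r, GRD and VIP per peak for audit.
    """
    X = peaks_std.areas.T  # observations × peaks, the regression layout
    per_indicator: dict[str, dict[str, list[str]]] = {}
    detail: dict[str, pd.DataFrame] = {}
    for ind in panel.indicator_ids:
        y = panel.indicator(ind)
        pe = pearson_screen(peaks_std, y, k=rules.pearson_top_k)
        parent = _zscore(y) if gra_parent == "standardized" else y
        gr = gray_relational(parent, peaks_std.areas, rho=rho, parent_id=ind)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_opls(X, y, n_orth=n_orth)
        vips = vip(model)
        per_indicator[ind] = method_sets(pe, gr, vips, rules)
        detail[ind] = pd.DataFrame({
            "r": pe.table["r"].reindex(peaks_std.peak_ids),
            "p": pe.table["p"].reindex(peaks_std.peak_ids),
            "grd": gr.grd,
            "vip": vips.reindex(peaks_std.peak_ids),
        })
    return intersect_sets(per_indicator), detail


def _load_inputs(cfg: RunConfig):
    truth = None
    if cfg.simulate:
        sim_cfg = cfg.sim
        if sim_cfg.seed != cfg.seed:
            sim_cfg = SimConfig(**{**asdict(sim_cfg), "seed": cfg.seed})
        table, panel, truth = simulate_dataset(sim_cfg)
        peaks = group_mean_table(table, truth.replicate_groups)
        return peaks, panel, truth
    if cfg.peaks_path or cfg.efficacy_path:
        if not (cfg.peaks_path and cfg.efficacy_path):
            raise ValidationError("both peaks_path and efficacy_path are required")
        dialect = "group_means" if "mean" in Path(cfg.peaks_path).read_text(
            encoding="utf-8").splitlines()[0] else "samples"
        peaks = load_peak_table(cfg.peaks_path, dialect=dialect)
        panel = load_efficacy_panel(cfg.efficacy_path)
        return peaks, panel, None
    if cfg.use_fixtures:
        return load_fixture("table3"), load_fixture("table6"), None
    raise ValidationError("no inputs: set simulate, paths, or use_fixtures")


def _resolve_weights(cfg: RunConfig, panel: EfficacyPanel) -> WeightScheme:
    source = cfg.weight_source
    if source == "supplied" and cfg.weights_path is None and cfg.simulate:
        # packaged weights name the published indicators; synthetic panels
        # get objective entropy weights instead
        logger.info("simulate run without weights_path: using entropy weights")
        source = "ewm"
    if source == "supplied":
        if cfg.weights_path:
            w = pd.read_csv(cfg.weights_path, index_col=0).iloc[:, 0]
        else:
            w = load_fixture("weights")
        return WeightScheme(weights=w, provenance="supplied")
    if source == "ewm":
        indicators = [i for i in panel.indicator_ids if i != OVERALL]
        return ewm_weights(panel.select_indicators(indicators))
    raise ValidationError(f"unknown weight_source {source!r}")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full screening pipeline and write artifacts.

    Stages: load (or simulate) → standardize peaks → positive transform (when
    a model group is named) → composite score (appended as the
    overall-rating pseudo-indicator) → three screens per indicator →
    consensus intersection and union → herb/compound/indicator network →
    median centrality filter → recovery report (synthetic runs).  Failures
    raise :class:`StageError` naming the stage; partial artifact files keep a
    ``.partial`` suffix.
    """
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            if out:
                for f in out.glob("*"):
                    if f.suffix != ".partial" and f.is_file():
                        f.rename(f.with_suffix(f.suffix + ".partial"))
            raise StageError(name, exc) from exc

    peaks, panel, truth = _stage("load", lambda: _load_inputs(cfg))
    peaks_std = _stage("standardize", lambda: standardize_peaks(peaks))
    if cfg.model_group is not None:
        panel = _stage("positive_transform",
                       lambda: positive_transform(panel, cfg.model_group))

    indicators = [i for i in panel.indicator_ids if i != OVERALL]
    work_panel = panel.select_indicators(indicators)

    weights = scores = None
    if cfg.include_overall:
        weights = _stage("weights", lambda: _resolve_weights(cfg, work_panel))
        scores = _stage("composite_score",
                        lambda: composite_score(work_panel, weights))
        values = work_panel.values.copy()
        values[OVERALL] = scores.reindex(values.index)
        work_panel = EfficacyPanel(values=values)

    consensus, detail = _stage(
        "screen",
        lambda: screen_all(peaks_std, work_panel, rules=cfg.rules, rho=cfg.rho,
                           gra_parent=cfg.gra_parent, n_orth=cfg.n_orth),
    )
    union = _stage("consensus", lambda: union_dedup(consensus))
    herb_map = (peaks.herb_map if peaks.herb_map is not None
                else pd.Series("unknown", index=peaks.peak_ids))
    network = _stage("network",
                     lambda: build_network(consensus, herb_map,
                                           include_overall=cfg.include_overall))
    flagged = _stage("median_filter",
                     lambda: median_filter(network.centralities,
                                           k_of_3=cfg.k_of_3))
    recovery = recovery_report(truth, list(union.index)) if truth else None

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (asdict(v) if isinstance(v, SimConfig) else v)
                   for k, v in asdict(cfg).items()},
        "stages": {
            "n_peaks": len(peaks.peak_ids),
            "n_observations": len(peaks.observations),
            "n_indicators": len(work_panel.indicator_ids),
            "composite_scores": (None if scores is None
                                 else {k: round(float(v), 6)
                                       for k, v in scores.items()}),
            "consensus_sizes": {k: len(v) for k, v in consensus.sets.items()},
            "union_size": int(len(union)),
            "n_flagged": len(flagged),
        },
        "recovery": None if recovery is None else asdict(recovery),
    }

    if out:
        def _write():
            peaks_std.areas.to_csv(out / "peaks_standardized.csv",
                                   float_format="%.12g")
            work_panel.values.to_csv(out / "efficacy_panel.csv",
                                     float_format="%.12g")
            long = pd.concat(
                [df.assign(indicator=ind) for ind, df in detail.items()]
            ).rename_axis("peak_id").reset_index()
            long.to_csv(out / "screen_detail.csv", index=False,
                        float_format="%.10g")
            rows = [(ind, p) for ind, ps in consensus.sets.items() for p in ps]
            pd.DataFrame(rows, columns=["indicator", "peak_id"]).to_csv(
                out / "consensus_sets.csv", index=False)
            union.rename_axis("peak_id").to_csv(out / "union_compounds.csv")
            network.centralities.assign(
                flagged=[p in flagged for p in network.centralities.index]
            ).to_csv(out / "centralities.csv", float_format="%.10g")
            write_graphml(network, out / "network.graphml")
            write_sif(network, out / "network.sif")
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, ensure_ascii=False),
                encoding="utf-8")
        _stage("write_artifacts", _write)

    return PipelineResult(peaks=peaks, peaks_standardized=peaks_std,
                          panel=work_panel, weights=weights, scores=scores,
                          screen_tables=detail, consensus=consensus,
                          union=union, network=network, flagged=flagged,
                          recovery=recovery, manifest=manifest)
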
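"""End-to-end orchestration: simulate -> preprocess -> twin -> evaluate -> compare.

A single :class:`RunConfig` drives the whole pipeline; one master seed fans
out deterministically to per-stage seeds so stages stay independent and any
run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fixtures import CohortSpec, CohortBundle, generate_cohort
from .preprocess import apply_exclusions, build_analytical, AttritionReport
from .sifter import preset, sift, dslo, TwinTable
from .copula import get_synthesizer
from .metrics import (quality_report, diagnostic_report, privacy_report,
                      utility_report, QualityReport, DiagnosticReport,
                      PrivacyReport, UtilityReport)
from .compare import (fit_outcome_model, compare_models, univariate_comparison,
                      ModelComparison)

__all__ = ["RunConfig", "RunManifest", "EvaluationReport", "run",
           "render_summary", "make_twin", "DS_METHODS"]

DS_METHODS = {"ds_small": "small", "ds_medium": "medium", "ds_large": "large"}


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    cohort_spec: CohortSpec | None = None
    input_dir: str | None = None
    methods: tuple[str, ...] = ("ds_small", "ds_medium", "ds_large",
                                "gaussian_copula")
    seed: int = 0
    utility_targets: tuple[str, ...] = ("gender", "avg_aeb_day")
    sensitive_cols: tuple[str, ...] = ("gender", "marital", "ethnicity")
    key_cols: tuple[str, ...] = ("age", "gender", "race", "marital")
    output_dir: str | None = None
    fit_models: bool = True

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one twin method is required")
        if self.cohort_spec is None and self.input_dir is None:
            self.cohort_spec = CohortSpec()


@dataclass
class EvaluationReport:
    """All scores for one twin vs. the original."""

    method: str
    quality: QualityReport
    diagnostic: DiagnosticReport
    privacy: PrivacyReport
    utility: UtilityReport
    model_comparison: ModelComparison | None = None

    def to_dict(self) -> dict:
        out = {"method": self.method,
               "quality": self.quality.to_dict(),
               "diagnostic": self.diagnostic.to_dict(),
               "privacy": self.privacy.to_dict(),
               "utility": self.utility.to_dict()}
        if self.model_comparison is not None:
            out["model_comparison"] = self.model_comparison.to_dict()
        return out


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seeds: dict[str, int]
    attrition: AttritionReport | None
    timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)


def _stage_seeds(master: int, methods: tuple[str, ...]) -> dict[str, int]:
    """Deterministic fan-out of one master seed to named stage seeds."""
    rng = np.random.default_rng(master)
    names = ["simulate"] + [f"twin:{m}" for m in methods] + ["evaluate"]
    return {name: int(rng.integers(2 ** 31)) for name in names}


def make_twin(method: str, analytical: pd.DataFrame, events: pd.DataFrame,
              seed: int) -> TwinTable:
    """Produce one digital twin of the analytical table.

    Sifter methods obfuscate the table cross-sectionally and run the
    longitudinal obfuscator over the event stream, re-deriving the AEB
    aggregates from the obfuscated events.  Registered synthesizers (e.g.
    the Gaussian copula) are fitted on the analytical table — the AEB
    aggregates are synthesized directly as columns — and sampled at the
    original size.
    """
    if method in DS_METHODS:
        level = DS_METHODS[method]
        twin = sift(analytical, preset(level, seed=seed))
        if len(events):
            ev = dslo(events, level, seed=seed)
            dur = (ev["end"] - ev["start"]).dt.total_seconds()
            agg = ev.assign(dur=dur).groupby("subject_id").agg(
                sum_aeb=("kcal", "sum"), sum_seconds=("dur", "sum"))
            data = twin.data.set_index("subject_id")
            idx = data.index.intersection(agg.index)
            data.loc[idx, "sum_aeb"] = agg.loc[idx, "sum_aeb"]
            data.loc[idx, "sum_seconds"] = agg.loc[idx, "sum_seconds"]
            sec = data["sum_seconds"].astype(float)
            data["avg_aeb_day"] = np.where(
                sec > 0, data["sum_aeb"].astype(float) / (sec / 86400.0), 0.0)
            twin.data = data.reset_index()
        return twin
    synth = get_synthesizer(method)
    synth.fit(analytical)
    twin = synth.sample(len(analytical), seed=seed)
    twin.method = method
    return twin


def _restrict_fit(fit, covariates: list[str]):
    """View of a ModelFit limited to a covariate subset (for comparison)."""
    import copy
    out = copy.deepcopy(fit)
    out.covariates = list(covariates)
    keep = ["const"] + list(covariates) if "const" in fit.params.index else list(covariates)
    out.params = fit.params[keep]
    out.bse = fit.bse[keep]
    out.pvalues = fit.pvalues[keep]
    out.conf_int = fit.conf_int.loc[keep]
    return out


def evaluate_twin(method: str, analytical: pd.DataFrame, twin: TwinTable,
                  config: RunConfig, seed: int,
                  original_fit=None) -> EvaluationReport:
    qual = quality_report(analytical, twin.data)
    diag = diagnostic_report(analytical, twin.data)
    priv = privacy_report(analytical, twin.data, seed=seed,
                          key_cols=list(config.key_cols),
                          sensitive_cols=list(config.sensitive_cols))
    util = utility_report(analytical, twin.data,
                          target_cols=list(config.utility_targets), seed=seed)
    comparison = None
    if config.fit_models and original_fit is not None:
        twin_fit = fit_outcome_model(twin.data)
        if set(twin_fit.covariates) != set(original_fit.covariates):
            # aliased-column drops can differ between fits (e.g. a rare
            # diagnosis flag constant in one table); compare on the shared set
            shared = [c for c in original_fit.covariates
                      if c in set(twin_fit.covariates)]
            original_fit = _restrict_fit(original_fit, shared)
            twin_fit = _restrict_fit(twin_fit, shared)
        comparison = compare_models(original_fit, twin_fit)
    return EvaluationReport(method=method, quality=qual, diagnostic=diag,
                            privacy=priv, utility=util,
                            model_comparison=comparison)


def run(config: RunConfig) -> tuple[RunManifest, dict[str, EvaluationReport]]:
    """Execute the full pipeline; returns the manifest and per-method reports."""
    seeds = _stage_seeds(config.seed, config.methods)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if config.input_dir:
        bundle = CohortBundle.from_csv(config.input_dir)
    else:
        spec = config.cohort_spec
        spec.seed = seeds["simulate"]
        bundle = generate_cohort(spec)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clean, attrition = apply_exclusions(bundle)
    analytical = build_analytical(clean)
    timings["preprocess"] = time.perf_counter() - t0

    original_fit = fit_outcome_model(analytical) if config.fit_models else None

    reports: dict[str, EvaluationReport] = {}
    twins: dict[str, pd.DataFrame] = {}
    for method in config.methods:
        t0 = time.perf_counter()
        twin = make_twin(method, analytical, clean.events, seeds[f"twin:{method}"])
        reports[method] = evaluate_twin(method, analytical, twin, config,
                                        seeds["evaluate"], original_fit)
        twins[method] = twin.data
        timings[method] = time.perf_counter() - t0
        if out_dir:
            path = out_dir / f"twin_{method}.csv"
            twin.data.to_csv(path, index=False)
            (out_dir / f"twin_{method}.provenance.json").write_text(
                json.dumps(twin.provenance(), indent=2, default=str))
            (out_dir / f"report_{method}.json").write_text(
                json.dumps(reports[method].to_dict(), indent=2, default=str))
            outputs[f"twin_{method}"] = str(path)

    summary = render_summary(reports)
    univariate = univariate_comparison(analytical, twins)
    if out_dir:
        analytical.to_csv(out_dir / "analytical.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        univariate.to_csv(out_dir / "univariate_comparison.csv", index=False)
        for method, rep in reports.items():
            rep.quality.pair_trends.to_csv(out_dir / f"pair_trends_{method}.csv")
        attrition.to_json(out_dir / "attrition.json")
        outputs.update(summary=str(out_dir / "summary.csv"),
                       univariate=str(out_dir / "univariate_comparison.csv"),
                       attrition=str(out_dir / "attrition.json"))

    manifest = RunManifest(
        config={**{k: v for k, v in asdict(config).items() if k != "cohort_spec"},
                "cohort_spec": asdict(config.cohort_spec) if config.cohort_spec else None},
        version=__version__, stage_seeds=seeds, attrition=attrition,
        timings=timings, outputs=outputs)
    if out_dir:
        (out_dir / "manifest.json").write_text(
            json.dumps({**asdict(manifest)}, indent=2, default=str))
    return manifest, reports


def render_summary(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """One row per method mirroring the quality/diagnostic/privacy/utility tables."""
    if not reports:
        raise ValueError("at least one report is required")
    rows = []
    for method, rep in reports.items():
        row = {
            "method": method,
            "quality": rep.quality.quality_overall,
            "column_shapes": rep.quality.shapes_overall,
            "column_pair_trends": rep.quality.trends_overall,
            "diagnostic": rep.diagnostic.diagnostic_overall,
            "data_validity": rep.diagnostic.validity_overall,
            "data_structure": rep.diagnostic.structure_score,
            "overall_privacy": rep.privacy.overall_privacy,
        }
        for target, entry in rep.utility.targets.items():
            row[f"utility_{target}"] = entry["overall"]
        if rep.model_comparison is not None:
            row["mean_ci_overlap"] = rep.model_comparison.mean_overlap
            row["median_abs_std_diff"] = rep.model_comparison.median_abs_std_diff
        rows.append(row)
    return pd.DataFrame(rows)
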
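"""End-to-end orchestration: survey -> index -> categories -> inequality -> variance.

Stage order: load or simulate microdata; code indicators; aggregate weighted
community prevalences; Cronbach's alpha; one-factor extraction and scoring;
k selection and ordinal GCCS labels; risk-gradient table with concentration
indices; three-model random-intercept ladder.  Every intermediate is written
as plain CSV/JSON so each stage is independently auditable; a failing stage
halts the run with the stage name, leaving earlier outputs plus a
``FAILED_<stage>`` marker in the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .clustering import select_k
from .factor import fit_one_factor, score_communities
from .indicators import code_indicators, community_prevalence, describe_communities
from .inequality import risk_gradient_table
from .multilevel import model_ladder
from .reliability import cronbach_alpha
from .synthetic import SyntheticConfig, generate_survey, write_survey

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("gcci")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    output_dir: str | Path = "gcci_output"
    input_csv: str | Path | None = None  # None => simulate
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int | None = None  # overrides synthetic.seed when set
    use_weights: bool = True
    dv_subsample: bool = True  # False: treat all rows as violence-eligible
    k_range: list[int] = field(default_factory=lambda: [3, 4, 5])
    outcomes: list[str] = field(default_factory=lambda: ["multiparity"])
    multilevel_outcome: str = "multiparity"
    quad_points: int = 12
    recode_indicators: bool = True
    stop_after: str | None = None  # "clustering" / "inequality" for partial runs


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from a YAML key-value file."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    syn = SyntheticConfig(**raw.pop("synthetic", {}))
    known = PipelineConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(synthetic=syn, **raw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages; return the summary dict also written to summary.json."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    stage = "setup"
    try:
        stage = "data"
        if config.input_csv is None:
            syn = config.synthetic
            if config.seed is not None:
                syn = SyntheticConfig(**{**syn.__dict__, "seed": config.seed})
            log.info("simulating survey (seed=%d)", syn.seed)
            data = generate_survey(syn)
            write_survey(data, out / "survey.csv", syn)
            summary["seed"] = syn.seed
        else:
            log.info("loading %s", config.input_csv)
            data = pd.read_csv(config.input_csv)
        if not config.dv_subsample:
            data = data.copy()
            data["dv_flag"] = True
            data["dv_weight"] = data["survey_weight"]
        summary["n_respondents"] = int(len(data))

        stage = "indicators"
        if config.recode_indicators:
            data = code_indicators(data)
        cp = community_prevalence(data, use_weights=config.use_weights)
        cp.to_frame().to_csv(out / "prevalence.csv", index=False)
        describe_communities(cp).to_csv(out / "prevalence_summary.csv")
        summary["n_communities"] = int(cp.community_id.size)

        stage = "reliability"
        rep = cronbach_alpha(cp.prevalence, item_names=list(cp.to_frame().columns[1:6]))
        rep.to_frame().to_csv(out / "alpha.csv")
        summary["cronbach_alpha"] = rep.alpha
        flagged = rep.items_raising_alpha()
        if flagged:
            log.info("items whose deletion raises alpha (retained): %s", flagged)
            summary["alpha_raising_items"] = flagged

        stage = "factor"
        model = fit_one_factor(cp)
        model.to_json(out / "factor_model.json")
        scores = score_communities(model, cp)
        scores.to_frame().to_csv(out / "gcci_scores.csv", index=False)
        summary["proportion_of_variance"] = model.proportion_of_variance
        summary["loadings"] = dict(zip(model.item_names, model.loadings))
        summary["gcci_sd"] = float(scores.score.std(ddof=1))
        summary["gcci_range"] = [float(scores.score.min()), float(scores.score.max())]

        stage = "clustering"
        gccs = select_k(scores.score, scores.community_id, config.k_range)
        gccs.to_frame().to_csv(out / "gccs.csv", index=False)
        gccs.diagnostics_frame().to_csv(out / "ch_diagnostics.csv", index=False)
        summary["selected_k"] = gccs.selected_k
        summary["cluster_sizes"] = gccs.cluster_sizes.tolist()
        summary["cluster_means"] = gccs.cluster_means.tolist()
        if config.stop_after == "clustering":
            return _finish(out, summary)

        stage = "inequality"
        table, ci = risk_gradient_table(data, gccs, config.outcomes)
        table.to_csv(out / "risk_gradient.csv")
        summary["concentration_index"] = {
            name: res.corrected_ci for name, res in ci.items()
        }
        if config.stop_after == "inequality":
            return _finish(out, summary)

        stage = "multilevel"
        ladder = model_ladder(
            data, gccs, outcome=config.multilevel_outcome, quad_points=config.quad_points
        )
        ladder.summary_frame().to_csv(out / "model_ladder.csv")
        for name, fit in ladder.fits.items():
            fit.to_frame().to_csv(out / f"{name}_coefficients.csv")
        summary["level2_variance"] = {
            name: fit.sigma2_u for name, fit in ladder.fits.items()
        }
        summary["icc_percent"] = {
            name: 100 * d.icc for name, d in ladder.decomposition.items()
        }
        summary["pcv_percent_model3_vs_model2"] = ladder.decomposition[
            "model3_gccs"
        ].pcv
        summary["lr_test_model2_vs_model3"] = {
            "statistic": ladder.lr_stat,
            "df": ladder.lr_df,
            "p_value": ladder.lr_pvalue,
        }

        stage = "summary"
        return _finish(out, summary)
    except Exception as err:
        (out / f"FAILED_{stage}").write_text(f"{type(err).__name__}: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _finish(out: Path, summary: dict[str, Any]) -> dict[str, Any]:
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
    )
    return summary
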
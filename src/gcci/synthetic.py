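"""Synthetic survey generator with a latent community restrictiveness factor.

Emulates the design of a DHS-style family health survey: ~47 strata
("communities"), ~20,000 ever-married women of reproductive age, a
half-household domestic-violence (DV) module subsample with its own weights,
five correlated community-clustered binary context indicators, and a
multiparity outcome (five or more children) with a community random intercept.

The data-generating model is a one-factor model on the logit scale.  Each
community j carries a latent restrictiveness factor ``eta_j ~ N(0, 1)``;
indicator k for a woman in community j is
``Bernoulli(expit(a_k + b_k * eta_j))``.  The outcome adds individual
covariate effects, a context effect proportional to ``eta_j`` and an
independent residual community intercept ``e_j ~ N(0, sd^2)``, so the share
of level-2 outcome variance explainable by the context factor has a known
truth (``c^2 / (c^2 + sd^2)`` for context effect c).

Default calibration targets community-prevalence means of roughly
(0.21, 0.22, 0.17, 0.11, 0.36) for the five indicators and a total latent
level-2 outcome variance of ``0.46^2 + 0.46^2 ~= 0.42``, split evenly
between the explainable and residual parts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .indicators import INDICATORS

__all__ = ["SyntheticConfig", "generate_survey", "write_survey"]

# Raw-response vocabulary used when expanding coded indicators back into
# questionnaire-style columns (see indicators.code_indicators).
DECISION_COLUMNS = (
    "decides_earnings",
    "decides_healthcare",
    "decides_purchases",
    "decides_visits",
)
BEATING_COLUMNS = (
    "beating_justified_going_out",
    "beating_justified_neglects_children",
    "beating_justified_argues",
    "beating_justified_refuses_sex",
    "beating_justified_burns_food",
)
VIOLENCE_COLUMNS = ("violence_pushed", "violence_slapped", "violence_kicked")
EDUCATION_BELOW_SECONDARY = ("none", "primary", "preparatory")
EDUCATION_SECONDARY_PLUS = ("secondary", "upper_intermediate", "university", "postgraduate")

_DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age_centered": float(np.log(1.14)),
    "education_secondary": float(np.log(0.84)),
    "education_university": float(np.log(0.57)),
    "wealth_2": float(np.log(0.81)),
    "wealth_3": float(np.log(0.62)),
    "wealth_4": float(np.log(0.50)),
    "wealth_5": float(np.log(0.41)),
    "early_married": float(np.log(2.81)),
    "child_death": float(np.log(4.99)),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey generator.

    ``indicator_intercepts`` and ``indicator_loadings`` are on the logit
    scale, ordered as :data:`gcci.indicators.INDICATORS`.  The defaults were
    calibrated once by numerical integration so that
    ``E[expit(a_k + b_k * Z)]`` matches the target community-prevalence
    means; they are study conditions, not tuning knobs.
    """

    n_communities: int = 47
    n_per_community: int | Sequence[int] = 435
    indicator_intercepts: Sequence[float] = (-1.579, -1.361, -1.780, -2.138, -0.738)
    indicator_loadings: Sequence[float] = (1.0, 0.6, 0.8, 0.35, 1.2)
    indicator_noise_sd: float = 0.0
    outcome_intercept: float = -2.479
    outcome_covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    outcome_context_effect: float = 0.46
    outcome_residual_community_sd: float = 0.46
    dv_subsample_fraction: float = 0.5
    seed: int = 20210

    def community_sizes(self) -> np.ndarray:
        if np.isscalar(self.n_per_community):
            return np.full(self.n_communities, int(self.n_per_community))
        sizes = np.asarray(self.n_per_community, dtype=int)
        if sizes.size != self.n_communities:
            raise ValueError(
                f"n_per_community has {sizes.size} entries for "
                f"{self.n_communities} communities"
            )
        return sizes

    def validate(self) -> None:
        if self.n_communities < 2:
            raise ValueError("need at least 2 communities")
        sizes = self.community_sizes()
        if (sizes < 1).any():
            raise ValueError("every community needs at least 1 respondent")
        if not 0.0 <= self.dv_subsample_fraction <= 1.0:
            raise ValueError("dv_subsample_fraction must lie in [0, 1]")
        vec = np.concatenate(
            [
                np.asarray(self.indicator_intercepts, float),
                np.asarray(self.indicator_loadings, float),
                [
                    self.outcome_intercept,
                    self.outcome_context_effect,
                    self.outcome_residual_community_sd,
                    self.indicator_noise_sd,
                ],
                np.asarray(list(self.outcome_covariate_effects.values()), float),
            ]
        )
        if not np.all(np.isfinite(vec)):
            raise ValueError("all generator parameters must be finite")
        if len(self.indicator_intercepts) != 5 or len(self.indicator_loadings) != 5:
            raise ValueError("five indicator intercepts and loadings are required")
        if np.any(np.asarray(self.indicator_loadings, float) < 0):
            raise ValueError("indicator loadings must be nonnegative")
        if self.outcome_residual_community_sd < 0 or self.indicator_noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def _expand_raw_responses(df: pd.DataFrame, rng: np.random.Generator) -> None:
    """Fill questionnaire-style raw columns consistent with coded indicators.

    The raw columns are redundant with the coded 0/1 indicators by
    construction; they exist so the coding rules can be exercised end to end.
    """
    n = len(df)
    cm = df["child_marriage"].to_numpy(bool)
    df["age_at_first_cohabitation"] = np.where(
        cm, rng.integers(13, 18, n), rng.integers(18, 36, n)
    )

    # Decision participation: "respondent"/"jointly" count as taking part.
    nodec = df["no_decision_power"].to_numpy(bool)
    n_participate = np.where(nodec, 0, rng.integers(1, 5, n))
    order = np.argsort(rng.random((n, 4)), axis=1)
    take_part = order < n_participate[:, None]
    for c, col in enumerate(DECISION_COLUMNS):
        vals = np.where(
            take_part[:, c],
            rng.choice(["respondent", "jointly"], n),
            rng.choice(["husband", "other"], n, p=[0.9, 0.1]),
        )
        df[col] = vals

    just = df["beating_justifiable"].to_numpy(bool)
    n_reasons = np.where(just, rng.integers(1, 6, n), 0)
    order = np.argsort(rng.random((n, 5)), axis=1)
    endorse = order < n_reasons[:, None]
    for c, col in enumerate(BEATING_COLUMNS):
        df[col] = endorse[:, c].astype(int)

    # Violence acts: frequency strings; missing outside the DV subsample.
    dv = df["dv_flag"].to_numpy(bool)
    v12 = df["violence_12m"].to_numpy()
    recent = dv & (v12 == 1)
    n_acts = np.where(recent, rng.integers(1, len(VIOLENCE_COLUMNS) + 1, n), 0)
    order = np.argsort(rng.random((n, len(VIOLENCE_COLUMNS))), axis=1)
    hit = order < n_acts[:, None]
    for c, col in enumerate(VIOLENCE_COLUMNS):
        vals = np.where(
            hit[:, c],
            rng.choice(["often", "sometimes"], n, p=[0.3, 0.7]),
            rng.choice(["never", "not_in_past_12m"], n, p=[0.8, 0.2]),
        )
        df[col] = pd.Series(vals, index=df.index).where(dv, other=pd.NA)

    lowed = df["low_education"].to_numpy(bool)
    df["education_level"] = np.where(
        lowed,
        rng.choice(EDUCATION_BELOW_SECONDARY, n, p=[0.35, 0.35, 0.3]),
        rng.choice(EDUCATION_SECONDARY_PLUS, n, p=[0.55, 0.1, 0.3, 0.05]),
    )


def generate_survey(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic ever-married-women survey as a DataFrame.

    One row per respondent.  Columns: identifiers and weights
    (``respondent_id``, ``community_id``, ``survey_weight``, ``dv_flag``,
    ``dv_weight``), covariates (``age``, ``wealth_quintile``,
    ``education_level``, ``child_death``, ``pregnancy_loss``), raw
    questionnaire responses, the five coded indicators (ordered as
    :data:`INDICATORS`; the violence indicator is missing outside the DV
    subsample), the ``multiparity`` outcome, and the generating truth
    ``eta_true`` (the community latent factor, for recovery tests).

    Deterministic: identical config (including seed) gives an identical
    frame.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = config.community_sizes()
    J = config.n_communities
    n = int(sizes.sum())
    community = np.repeat(np.arange(1, J + 1), sizes)

    eta = rng.standard_normal(J)
    resid = rng.standard_normal(J) * config.outcome_residual_community_sd

    a = np.asarray(config.indicator_intercepts, float)
    b = np.asarray(config.indicator_loadings, float)
    if config.indicator_noise_sd > 0:
        ind_noise = rng.standard_normal((J, 5)) * config.indicator_noise_sd
    else:
        ind_noise = np.zeros((J, 5))
    p_ind = expit(a[None, :] + b[None, :] * eta[:, None] + ind_noise)  # (J, 5)
    ind_draws = rng.random((n, 5)) < p_ind[community - 1]

    df = pd.DataFrame(
        {
            "respondent_id": np.arange(1, n + 1),
            "community_id": community,
            "survey_weight": rng.gamma(20.0, 1 / 20.0, n),
        }
    )
    for k, name in enumerate(INDICATORS):
        df[name] = ind_draws[:, k].astype(int)

    # DV subsample: a fixed fraction of each community, inflated weights.
    dv_flag = np.zeros(n, bool)
    offset = 0
    for sz in sizes:
        m = int(round(sz * config.dv_subsample_fraction))
        pick = rng.choice(sz, size=m, replace=False)
        dv_flag[offset + pick] = True
        offset += sz
    df["dv_flag"] = dv_flag
    if config.dv_subsample_fraction > 0:
        df["dv_weight"] = np.where(
            dv_flag, df["survey_weight"] / config.dv_subsample_fraction, np.nan
        )
    else:
        df["dv_weight"] = np.nan
    df["violence_12m"] = df["violence_12m"].where(dv_flag, other=np.nan)

    # Covariates, independent of the latent factor by default.
    df["age"] = rng.integers(15, 50, n)
    df["wealth_quintile"] = rng.integers(1, 6, n)
    df["child_death"] = (rng.random(n) < 0.05).astype(int)
    df["pregnancy_loss"] = (rng.random(n) < 0.15).astype(int)

    _expand_raw_responses(df, rng)

    edu = df["education_level"].to_numpy()
    effects = dict(config.outcome_covariate_effects)
    lp = np.full(n, config.outcome_intercept)
    lp += effects.get("age_centered", 0.0) * (df["age"] - df["age"].mean()).to_numpy()
    lp += effects.get("education_secondary", 0.0) * np.isin(
        edu, ["secondary", "upper_intermediate"]
    )
    lp += effects.get("education_university", 0.0) * np.isin(
        edu, ["university", "postgraduate"]
    )
    for q in (2, 3, 4, 5):
        lp += effects.get(f"wealth_{q}", 0.0) * (df["wealth_quintile"] == q).to_numpy()
    lp += effects.get("early_married", 0.0) * df["child_marriage"].to_numpy()
    lp += effects.get("child_death", 0.0) * df["child_death"].to_numpy()
    lp += config.outcome_context_effect * eta[community - 1]
    lp += resid[community - 1]
    df["multiparity"] = (rng.random(n) < expit(lp)).astype(int)

    df["eta_true"] = eta[community - 1]
    return df


def write_survey(df: pd.DataFrame, path: str | Path, config: SyntheticConfig | None = None) -> None:
    """Write the survey as CSV with a sidecar metadata JSON (seed, config)."""
    path = Path(path)
    df.to_csv(path, index=False)
    if config is not None:
        meta = asdict(config)
        meta["n_rows"] = int(len(df))
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
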
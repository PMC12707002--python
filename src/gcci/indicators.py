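"""Indicator coding and weighted community-level aggregation.

The five restrictive-context indicators, in canonical column order:

1. ``child_marriage`` — started living with first husband before age 18.
2. ``no_decision_power`` — takes part (alone or jointly) in none of four
   household decisions (husband's earnings, own health care, major
   purchases, family visits).
3. ``beating_justifiable`` — endorses wife-beating for at least one of five
   named reasons.
4. ``violence_12m`` — reports at least one physical-violence act by the
   husband in the past 12 months (often or sometimes).  Asked only of the
   domestic-violence (DV) module subsample; missing elsewhere by design.
5. ``low_education`` — highest school level attended below secondary.

A "community" is whatever grouping key the data supplies (here, the
sampling stratum: the urban or rural segment of a governorate); the code
treats it as opaque.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "CommunityPrevalence",
    "code_indicators",
    "community_prevalence",
    "describe_communities",
]

INDICATORS = (
    "child_marriage",
    "no_decision_power",
    "beating_justifiable",
    "violence_12m",
    "low_education",
)

_DECISION_COLUMNS = (
    "decides_earnings",
    "decides_healthcare",
    "decides_purchases",
    "decides_visits",
)
_BEATING_PREFIX = "beating_justified_"
_VIOLENCE_PREFIX = "violence_"
_PARTICIPATES = {"respondent", "jointly"}
_RECENT = {"often", "sometimes"}
_BELOW_SECONDARY = {"none", "primary", "preparatory"}


@dataclass
class CommunityPrevalence:
    """Communities x indicators prevalence matrix with per-community counts.

    ``prevalence`` is a (J, 5) array with columns ordered as
    :data:`INDICATORS`; the violence column is computed only from DV-flagged
    rows using the DV weight.
    """

    community_id: np.ndarray  # (J,)
    prevalence: np.ndarray  # (J, K) in [0, 1]
    n_respondents: np.ndarray  # (J,)
    n_dv: np.ndarray  # (J,)
    indicator_names: tuple = INDICATORS

    def __post_init__(self) -> None:
        self.community_id = np.asarray(self.community_id)
        self.prevalence = np.asarray(self.prevalence, float)
        J = self.community_id.size
        if J < 2:
            raise ValueError("need at least 2 communities")
        if self.prevalence.shape != (J, len(self.indicator_names)):
            raise ValueError("prevalence matrix shape mismatch")
        if ((self.prevalence < 0) | (self.prevalence > 1)).any():
            raise ValueError("prevalences must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.prevalence, columns=list(self.indicator_names))
        out.insert(0, "community_id", self.community_id)
        out["n_respondents"] = self.n_respondents
        out["n_dv"] = self.n_dv
        return out


def _require(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"missing raw response column(s): {missing}")


def code_indicators(raw: pd.DataFrame) -> pd.DataFrame:
    """Apply the coding rules to raw questionnaire responses.

    Returns a copy of ``raw`` with the five indicator columns (re)computed.
    The violence indicator is coded only for rows with ``dv_flag`` true and
    set to missing elsewhere; a missing violence response inside the DV
    subsample is an error, as is any other missing raw field.
    """
    df = raw.copy()
    _require(df, ["age_at_first_cohabitation", "education_level", "dv_flag"])
    _require(df, list(_DECISION_COLUMNS))

    beating_cols = [c for c in df.columns if c.startswith(_BEATING_PREFIX)]
    if not beating_cols:
        raise KeyError(f"missing raw response column(s): ['{_BEATING_PREFIX}*']")
    violence_cols = [
        c
        for c in df.columns
        if c.startswith(_VIOLENCE_PREFIX) and c != "violence_12m"
    ]
    if not violence_cols:
        raise KeyError(f"missing raw response column(s): ['{_VIOLENCE_PREFIX}*']")

    strict = ["age_at_first_cohabitation", "education_level", *_DECISION_COLUMNS, *beating_cols]
    for col in strict:
        if df[col].isna().any():
            raise ValueError(f"missing values in raw field {col!r}")

    df["child_marriage"] = (df["age_at_first_cohabitation"] < 18).astype(int)

    participates = sum(
        df[c].isin(_PARTICIPATES).astype(int) for c in _DECISION_COLUMNS
    )
    df["no_decision_power"] = (participates == 0).astype(int)

    df["beating_justifiable"] = (
        df[beating_cols].astype(float).sum(axis=1) > 0
    ).astype(int)

    dv = df["dv_flag"].astype(bool)
    if df.loc[dv, violence_cols].isna().any().any():
        raise ValueError("missing violence responses inside the DV subsample")
    any_recent = df[violence_cols].isin(_RECENT).any(axis=1)
    df["violence_12m"] = np.where(dv, any_recent.astype(float), np.nan)

    df["low_education"] = df["education_level"].isin(_BELOW_SECONDARY).astype(int)
    return df


def community_prevalence(
    data: pd.DataFrame, use_weights: bool = True
) -> CommunityPrevalence:
    """Aggregate weighted indicator prevalences per community.

    The violence indicator averages DV-flagged rows with ``dv_weight``; the
    other four use ``survey_weight`` over all rows.  With
    ``use_weights=False`` plain means are used (oracle mode).  A community
    with no DV-subsample rows is an error.
    """
    _require(data, ["community_id", *INDICATORS, "dv_flag"])
    if use_weights:
        _require(data, ["survey_weight", "dv_weight"])
        if (data["survey_weight"] <= 0).any():
            raise ValueError("survey weights must be strictly positive")

    ids = np.unique(data["community_id"].to_numpy())
    dv = data["dv_flag"].astype(bool)
    no_dv = sorted(set(ids) - set(data.loc[dv, "community_id"].unique()))
    if no_dv:
        raise ValueError(f"communities without DV-subsample rows: {no_dv}")

    J = ids.size
    prev = np.empty((J, len(INDICATORS)))
    n_resp = np.empty(J, int)
    n_dv = np.empty(J, int)
    for j, cid in enumerate(ids):
        grp = data[data["community_id"] == cid]
        grp_dv = grp[grp["dv_flag"].astype(bool)]
        n_resp[j] = len(grp)
        n_dv[j] = len(grp_dv)
        for k, name in enumerate(INDICATORS):
            sub = grp_dv if name == "violence_12m" else grp
            y = sub[name].to_numpy(float)
            if use_weights:
                w = sub["dv_weight" if name == "violence_12m" else "survey_weight"]
                w = w.to_numpy(float)
                prev[j, k] = np.average(y, weights=w)
            else:
                prev[j, k] = y.mean()
    return CommunityPrevalence(ids, prev, n_resp, n_dv)


def describe_communities(cp: CommunityPrevalence) -> pd.DataFrame:
    """Mean / SD (n-1) / min / max of each indicator across communities."""
    P = cp.prevalence
    return pd.DataFrame(
        {
            "mean": P.mean(axis=0),
            "std": P.std(axis=0, ddof=1),
            "min": P.min(axis=0),
            "max": P.max(axis=0),
        },
        index=list(cp.indicator_names),
    )
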
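"""Wagstaff concentration index of binary risks across ordered communities.

The concentration index adapts the Gini coefficient to an ordinal social
gradient: individuals are ranked by their community's restrictiveness
category, each group receiving the fractional rank

    R_g = (cumulative population share below group g) + (share of g) / 2,

and the index is ``CI = (2 / mu) * Cov_w(y, R)`` with mu the weighted mean
of the outcome.  For a binary outcome the index is normalized by
``1 - mu`` (the bounded-outcome correction) so its range is [-1, 1].

Rank direction: groups are ordered least -> most restrictive (rank 0 -> 1),
so a risk concentrated in restrictive communities yields a POSITIVE index.
Set ``restrictive_high_rank=False`` to reverse, which exactly negates the
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import GCCSAssignment

__all__ = [
    "RankedGroups",
    "CIResult",
    "fractional_rank",
    "wagstaff_ci",
    "risk_gradient_table",
]


@dataclass
class RankedGroups:
    """Fractional ranks shared by all members of each ordered group."""

    group_order: list  # ascending restrictiveness
    shares: np.ndarray  # population (weight) shares, sum 1
    rank_per_group: np.ndarray  # midpoint fractional ranks
    rank: np.ndarray  # per individual
    group_index: np.ndarray  # per individual, position in group_order


@dataclass
class CIResult:
    outcome: str
    mu: float
    raw_ci: float
    corrected_ci: float
    group_prevalence: pd.Series  # weighted prevalence per ordered group


def fractional_rank(
    groups: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series,
    group_order: list,
) -> RankedGroups:
    """Midpoint fractional ranks for individuals grouped by ordinal labels."""
    g = np.asarray(groups)
    w = np.asarray(weights, float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    unseen = set(np.unique(g)) - set(group_order)
    if unseen:
        raise ValueError(f"individuals with labels outside group order: {sorted(map(str, unseen))}")

    shares = np.empty(len(group_order))
    for i, lab in enumerate(group_order):
        shares[i] = w[g == lab].sum()
    if np.any(shares == 0):
        empty = [str(l) for l, s in zip(group_order, shares) if s == 0]
        raise ValueError(f"empty group(s): {empty}")
    shares /= shares.sum()
    below = np.concatenate([[0.0], np.cumsum(shares)[:-1]])
    rank_per_group = below + shares / 2

    idx = np.empty(g.size, int)
    for i, lab in enumerate(group_order):
        idx[g == lab] = i
    return RankedGroups(
        group_order=list(group_order),
        shares=shares,
        rank_per_group=rank_per_group,
        rank=rank_per_group[idx],
        group_index=idx,
    )


def wagstaff_ci(
    y: np.ndarray | pd.Series,
    ranks: RankedGroups,
    weights: np.ndarray | pd.Series,
    binary_correction: bool = True,
    outcome: str = "outcome",
) -> CIResult:
    """Concentration index ``(2/mu) * Cov_w(y, R)`` with optional correction.

    The weighted covariance centers both arguments at their weighted means
    and normalizes by the total weight.  mu must lie strictly inside (0, 1)
    for a binary outcome; at the boundary the index is undefined.
    """
    yv = np.asarray(y, float)
    w = np.asarray(weights, float)
    R = ranks.rank
    wsum = w.sum()
    mu = float(np.dot(w, yv) / wsum)
    if not 0.0 < mu < 1.0:
        raise ValueError(f"outcome mean {mu} outside (0, 1); index undefined")
    rbar = np.dot(w, R) / wsum
    cov = float(np.dot(w, (yv - mu) * (R - rbar)) / wsum)
    raw = 2.0 / mu * cov
    corrected = raw / (1.0 - mu) if binary_correction else raw

    prev = pd.Series(
        [
            np.average(yv[ranks.group_index == i], weights=w[ranks.group_index == i])
            for i in range(len(ranks.group_order))
        ],
        index=[str(l) for l in ranks.group_order],
        name=outcome,
    )
    return CIResult(
        outcome=outcome,
        mu=mu,
        raw_ci=raw,
        corrected_ci=float(corrected),
        group_prevalence=prev,
    )


def risk_gradient_table(
    data: pd.DataFrame,
    gccs: GCCSAssignment,
    outcomes: list[str],
    weight_col: str = "survey_weight",
    restrictive_high_rank: bool = True,
) -> tuple[pd.DataFrame, dict[str, CIResult]]:
    """Per-category weighted risk prevalences (%) and corrected CI per outcome.

    Rows are outcomes, columns the ordered category labels plus the
    corrected concentration index.
    """
    label_map = dict(zip(gccs.community_id, gccs.label_per_community))
    labels = data["community_id"].map(label_map)
    if labels.isna().any():
        missing = sorted(data.loc[labels.isna(), "community_id"].unique())
        raise ValueError(f"communities without a GCCS label: {missing}")
    order = list(gccs.labels) if restrictive_high_rank else list(gccs.labels)[::-1]
    ranks = fractional_rank(labels.to_numpy(), data[weight_col], order)

    results: dict[str, CIResult] = {}
    rows = []
    for name in outcomes:
        col = data[name]
        vals = set(col.dropna().unique())
        if not vals <= {0, 1, True, False}:
            raise ValueError(f"outcome {name!r} is not binary")
        res = wagstaff_ci(col, ranks, data[weight_col], outcome=name)
        results[name] = res
        row = {str(l): 100 * res.group_prevalence[str(l)] for l in gccs.labels}
        row["wagstaff_ci"] = res.corrected_ci
        rows.append(pd.Series(row, name=name))
    return pd.DataFrame(rows), results
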
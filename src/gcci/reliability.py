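"""Cronbach's alpha item analysis for the community prevalence columns.

Raw (covariance-based) alpha with n-1 denominators, reported in the classic
item-analysis layout: per-item sign, item-test and item-rest correlations,
the average interitem covariance among the remaining items, and alpha if
the item is deleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AlphaReport", "cronbach_alpha"]


@dataclass
class AlphaReport:
    alpha: float
    item_names: list[str]
    sign: np.ndarray  # +1 / -1 per item
    item_test_corr: np.ndarray
    item_rest_corr: np.ndarray
    avg_interitem_cov: np.ndarray  # among the OTHER K-1 items
    alpha_if_deleted: np.ndarray
    overall_avg_interitem_cov: float

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "sign": np.where(self.sign > 0, "+", "-"),
                "item_test_corr": self.item_test_corr,
                "item_rest_corr": self.item_rest_corr,
                "avg_interitem_cov": self.avg_interitem_cov,
                "alpha": self.alpha_if_deleted,
            },
            index=self.item_names,
        )
        out.loc["test_scale"] = [
            "",
            np.nan,
            np.nan,
            self.overall_avg_interitem_cov,
            self.alpha,
        ]
        return out

    def items_raising_alpha(self) -> list[str]:
        """Items whose deletion would increase alpha (flagged, never dropped)."""
        return [
            n
            for n, a in zip(self.item_names, self.alpha_if_deleted)
            if a > self.alpha
        ]


def _raw_alpha(cov: np.ndarray) -> float:
    k = cov.shape[0]
    return k / (k - 1) * (1.0 - np.trace(cov) / cov.sum())


def cronbach_alpha(
    items: np.ndarray | pd.DataFrame, item_names: list[str] | None = None
) -> AlphaReport:
    """Cronbach's alpha and item statistics for a J x K item matrix.

    alpha = K/(K-1) * (1 - sum(var_k) / var(total score)).  Requires K >= 2
    items, J >= 3 observations and no constant column (correlations with a
    constant are undefined).
    """
    if isinstance(items, pd.DataFrame):
        item_names = item_names or list(items.columns)
        X = items.to_numpy(float)
    else:
        X = np.asarray(items, float)
        item_names = item_names or [f"item_{k + 1}" for k in range(X.shape[1])]
    J, K = X.shape
    if K < 2:
        raise ValueError("need at least 2 items")
    if J < 3:
        raise ValueError("need at least 3 observations")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [item_names[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant item column(s): {bad}")

    cov = np.cov(X, rowvar=False, ddof=1)
    alpha = _raw_alpha(cov)
    total = X.sum(axis=1)

    item_test = np.empty(K)
    item_rest = np.empty(K)
    avg_cov = np.empty(K)
    alpha_del = np.empty(K)
    off = cov - np.diag(np.diag(cov))
    for k in range(K):
        item_test[k] = np.corrcoef(X[:, k], total)[0, 1]
        item_rest[k] = np.corrcoef(X[:, k], total - X[:, k])[0, 1]
        rest = np.delete(np.arange(K), k)
        if len(rest) < 2:  # alpha of a single remaining item is undefined
            avg_cov[k] = np.nan
            alpha_del[k] = np.nan
            continue
        sub = off[np.ix_(rest, rest)]
        avg_cov[k] = sub.sum() / (len(rest) * (len(rest) - 1))
        alpha_del[k] = _raw_alpha(cov[np.ix_(rest, rest)])

    return AlphaReport(
        alpha=float(alpha),
        item_names=list(item_names),
        sign=np.where(item_test >= 0, 1, -1),
        item_test_corr=item_test,
        item_rest_corr=item_rest,
        avg_interitem_cov=avg_cov,
        alpha_if_deleted=alpha_del,
        overall_avg_interitem_cov=float(off.sum() / (K * (K - 1))),
    )
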
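"""One-factor principal-factor extraction and regression (Thomson) scoring.

The index is the leading principal factor of the communities x indicators
prevalence correlation matrix, extracted with squared multiple correlations
(SMC) as communalities — the classic non-iterated principal-axis method.
Regression scoring coefficients are ``R^{-1} @ loadings``; the resulting
community scores have mean 0 and variance at most 1 by construction.

Orthogonal rotation of a single factor is the identity, so "rotated" and
unrotated loadings coincide; no rotation step exists.

The proportion of variance explained is reported relative to the sum of the
POSITIVE eigenvalues of the reduced (SMC-diagonal) correlation matrix, the
common principal-factor convention.  Relative to the number of items it
would be much smaller; the convention is stated here because the two are
easily confused.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .indicators import CommunityPrevalence

__all__ = ["FactorModel", "GCCIScores", "fit_one_factor", "score_communities"]


@dataclass
class FactorModel:
    """One-factor principal-factor solution on a correlation matrix."""

    item_names: list[str]
    corr: np.ndarray  # (K, K)
    smc: np.ndarray  # initial communalities
    eigenvalues: np.ndarray  # of the reduced matrix, descending
    loadings: np.ndarray  # (K,)
    uniqueness: np.ndarray  # 1 - loading^2
    scoring: np.ndarray  # regression scoring coefficients
    proportion_of_variance: float
    col_means: np.ndarray = field(repr=False, default=None)
    col_sds: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loading": self.loadings,
                "uniqueness": self.uniqueness,
                "scoring": self.scoring,
            },
            index=self.item_names,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "item_names": self.item_names,
            "loadings": self.loadings.tolist(),
            "uniqueness": self.uniqueness.tolist(),
            "scoring": self.scoring.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "proportion_of_variance": self.proportion_of_variance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class GCCIScores:
    community_id: np.ndarray
    score: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"community_id": self.community_id, "gcci": self.score})


def fit_one_factor(cp: CommunityPrevalence, iterate: bool = False) -> FactorModel:
    """Fit the one-factor principal-factor model to community prevalences.

    Steps: standardize columns (n-1 SDs); form the correlation matrix R;
    replace its diagonal with the SMCs ``1 - 1/diag(R^{-1})``;
    eigen-decompose; keep the leading eigenpair; sign the loadings so their
    sum is positive (restrictiveness-positive convention).  Warns if any
    loading magnitude falls below 0.3, the usual salience threshold; items
    are never dropped automatically.

    With ``iterate=True`` the communalities are refined to convergence
    (replacing the diagonal with the squared loadings and re-solving), which
    removes the downward bias of SMC initial communalities on strongly
    loading items; the default reports the classic non-iterated solution.
    """
    P = cp.prevalence
    J, K = P.shape
    if J <= K:
        raise ValueError(f"need more communities ({J}) than indicators ({K})")
    sds = P.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant prevalence column; correlation undefined")
    R = np.corrcoef(P, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular correlation matrix") from err

    smc = 1.0 - 1.0 / np.diag(Rinv)
    comm = smc.copy()
    for _ in range(200 if iterate else 1):
        reduced = R.copy()
        np.fill_diagonal(reduced, comm)
        eigvals, eigvecs = np.linalg.eigh(reduced)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        lam1 = eigvals[0]
        if lam1 <= 1e-12:
            raise ValueError(
                "degenerate factor solution: no positive leading eigenvalue"
            )
        loadings = np.sqrt(lam1) * eigvecs[:, 0]
        new_comm = np.clip(loadings**2, 0.0, 1.0 - 1e-6)
        if np.max(np.abs(new_comm - comm)) < 1e-8:
            comm = new_comm
            break
        comm = new_comm
    if loadings.sum() < 0:
        loadings = -loadings
    uniqueness = 1.0 - loadings**2
    pos = eigvals[eigvals > 0]
    prop = float(lam1 / pos.sum())
    scoring = Rinv @ loadings

    low = np.abs(loadings) < 0.3
    if low.any():
        names = [n for n, flag in zip(cp.indicator_names, low) if flag]
        warnings.warn(f"factor loadings below 0.3: {names}", stacklevel=2)

    return FactorModel(
        item_names=list(cp.indicator_names),
        corr=R,
        smc=smc,
        eigenvalues=eigvals,
        loadings=loadings,
        uniqueness=uniqueness,
        scoring=scoring,
        proportion_of_variance=prop,
        col_means=P.mean(axis=0),
        col_sds=sds,
    )


def score_communities(model: FactorModel, cp: CommunityPrevalence) -> GCCIScores:
    """Regression factor scores: ``score_j = sum_k scoring_k * z_jk``.

    ``z`` standardizes the prevalence columns with the means/SDs stored in
    the fitted model, so scoring the fitting data yields mean-zero scores.
    """
    P = cp.prevalence
    if P.shape[1] != len(model.item_names):
        raise ValueError("indicator-set mismatch between model and data")
    Z = (P - model.col_means) / model.col_sds
    return GCCIScores(cp.community_id, Z @ model.scoring)
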
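"""Flight-style distinctiveness and its relation to wing-leg divergence.

Binary flight-style tables are filtered (species scored for fewer than two
styles are dropped as under-documented), Gower-standardized and embedded by
principal coordinates; distinctiveness is the rooted squared Mahalanobis
distance of a species' retained ordination scores from the pooled centroid,
``M_flight = sqrt((x - mu)' Sigma^-1 (x - mu))``.  Two ordinary
least-squares models then probe the ecology of divergence per developmental
subset: the quadratic ``M_flight ~ delta + delta^2`` and the allometric
``log10(mass) ~ delta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FlightDistinctiveness",
    "EcologyModelFit",
    "filter_flight",
    "flight_distance",
    "pcoa",
    "mahalanobis_mflight",
    "flight_distinctiveness",
    "fit_ecology_models",
]


@dataclass
class FlightDistinctiveness:
    """Retained ordination scores and Mahalanobis distinctiveness per species."""

    scores: pd.DataFrame  # species x retained axes
    centroid: np.ndarray
    covariance: np.ndarray  # ML (1/n) convention
    d2: pd.Series
    m_flight: pd.Series


@dataclass
class EcologyModelFit:
    """OLS fit summary of one ecological model in one developmental subset."""

    formula: str  # "quadratic" | "linear"
    coefficients: pd.Series
    pvalues: pd.Series
    adj_r2: float
    n: int


def filter_flight(table: pd.DataFrame) -> pd.DataFrame:
    """Keep species scored present for at least two styles.

    Constant-zero style columns (after row filtering) carry no information
    and are dropped with a warning.
    """
    if not table.isin([0, 1]).all().all():
        raise ValueError("flight-style table must be binary")
    kept = table.loc[table.sum(axis=1) >= 2].copy()
    if len(kept) < 5:
        raise ValueError(
            f"only {len(kept)} species scored for 2+ styles; too few to analyse"
        )
    dead = kept.columns[kept.sum(axis=0) == 0]
    if len(dead):
        warnings.warn(f"dropping constant-zero style columns: {list(dead)}")
        kept = kept.drop(columns=list(dead))
    return kept


def flight_distance(table: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances of Gower (range-standardized) style scores.

    For binary columns the Gower transform is the identity, so the distance
    between two species is the square root of their mismatch count.
    """
    X = table.to_numpy(dtype=float)
    rng_ = X.max(axis=0) - X.min(axis=0)
    rng_[rng_ == 0] = 1.0
    D = squareform(pdist(X / rng_, metric="euclidean"))
    return pd.DataFrame(D, index=table.index, columns=table.index)


def pcoa(D: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Classical scaling, truncated to axes explaining > ``threshold``.

    Axis shares are eigenvalues over the sum of positive eigenvalues;
    scores are centred at the origin by construction.
    """
    M = D.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or np.abs(M - M.T).max() > 1e-10:
        raise ValueError("distance matrix must be square and symmetric")
    if np.abs(np.diag(M)).max() > 1e-10:
        raise ValueError("distance matrix must have a zero diagonal")
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M**2) @ J
    evals, evecs = np.linalg.eigh(B)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    share = np.zeros_like(evals)
    share[pos] = evals[pos] / evals[pos].sum()
    keep = share > threshold
    if not keep.any():
        raise ValueError(f"no axis explains more than {threshold:.0%} of variance")
    scores = evecs[:, keep] * np.sqrt(evals[keep])
    cols = [f"pco{k + 1}" for k in range(keep.sum())]
    out = pd.DataFrame(scores, index=D.index, columns=cols)
    out.attrs["proportion_explained"] = share[keep]
    return out


def mahalanobis_mflight(scores: pd.DataFrame) -> FlightDistinctiveness:
    """Squared Mahalanobis distance from the pooled centroid, then rooted.

    The covariance uses the ML (1/n) convention, so the mean of the squared
    distances equals the number of retained axes.
    """
    X = scores.to_numpy(dtype=float)
    n, k = X.shape
    if n < k + 2:
        raise ValueError("need at least axes + 2 species for Mahalanobis distances")
    mu = X.mean(axis=0)
    Xc = X - mu
    cov = (Xc.T @ Xc) / n
    try:
        sol = np.linalg.solve(cov, Xc.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular score covariance; retain fewer ordination axes"
        ) from exc
    d2 = pd.Series(np.einsum("ij,ji->i", Xc, sol), index=scores.index, name="D2")
    return FlightDistinctiveness(
        scores=scores,
        centroid=mu,
        covariance=cov,
        d2=d2,
        m_flight=np.sqrt(d2).rename("m_flight"),
    )


def flight_distinctiveness(
    table: pd.DataFrame, threshold: float = 0.05
) -> FlightDistinctiveness:
    """filter -> Gower/Euclidean -> PCoA -> rooted Mahalanobis, pooled."""
    kept = filter_flight(table)
    D = flight_distance(kept)
    scores = pcoa(D, threshold=threshold)
    return mahalanobis_mflight(scores)


def fit_ecology_models(
    response: pd.Series, delta: pd.Series, formula: str = "quadratic"
) -> EcologyModelFit:
    """OLS fit of distinctiveness or log-mass on the divergence score.

    ``quadratic``: ``y ~ c + b1*delta + b2*delta^2``; ``linear``:
    ``y ~ c + b*delta``.  Aligned on the intersection of the two indexes.
    """
    common = response.index.intersection(delta.index)
    y = response.loc[common].to_numpy(dtype=float)
    d = delta.loc[common].to_numpy(dtype=float)
    if len(common) <= 4:
        raise ValueError("too few species for a stable model fit")
    if formula == "quadratic":
        X = np.column_stack([np.ones_like(d), d, d**2])
        names = ["const", "delta", "delta2"]
    elif formula == "linear":
        X = np.column_stack([np.ones_like(d), d])
        names = ["const", "delta"]
    else:
        raise ValueError(f"unknown formula {formula!r}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant divergence scores?)")
    fit = sm.OLS(y, X).fit()
    return EcologyModelFit(
        formula=formula,
        coefficients=pd.Series(fit.params, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        adj_r2=float(fit.rsquared_adj),
        n=len(common),
    )
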
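"""Concordance/divergence axes from the phylogenetic wing-leg cross-covariance.

The evolutionary (Brownian-rate) covariance of the six allometric residuals
is estimated on the tree; the 3x3 wing-by-leg cross block is decomposed by
SVD.  Its first singular triplet (u1, v1) — the leading *salience* — defines
the concordance axis ``g = (u1 | v1)``: the joint direction along which wing
and leg residuals evolve together.  Rotating the block-score plane by pi/2
gives the divergence axis ``d = (u1 | -v1)``, a wing-versus-leg size
trade-off.  Projecting each species' residual vector on the unit divergence
axis yields its divergence score (positive = disproportionately long wings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .allometry import AllometricResiduals
from .trees import AncestryMatrix, phylo_mean

__all__ = [
    "EvolutionaryCovariance",
    "AxisPair",
    "DivergenceScores",
    "evolutionary_covariance",
    "leading_salience",
    "build_axes",
    "project_divergence",
    "divergence_pipeline",
]


@dataclass
class EvolutionaryCovariance:
    """Brownian-rate covariance of residuals and its wing-leg cross block."""

    sigma_evo: np.ndarray  # 6x6, log10(mm)^2 / Myr scale
    cross_block: np.ndarray  # 3x3 wing rows x leg columns
    singular_values: np.ndarray
    u1: np.ndarray
    v1: np.ndarray
    share: float


@dataclass
class AxisPair:
    """Concordance axis g and divergence axis d over the 6-D residual space.

    Both have norm sqrt(2) (each block is a unit vector) and are exactly
    orthogonal; the wing block of d is positive so that positive scores mean
    disproportionately long wings.
    """

    g: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        for v in (self.g, self.d):
            if v.shape != (6,):
                raise ValueError("axes must be 6-vectors")
            if abs(linalg.norm(v) - np.sqrt(2.0)) > 1e-8:
                raise ValueError("axis blocks must be unit vectors")
        if abs(self.g @ self.d) > 1e-8:
            raise ValueError("axes must be orthogonal")

    @property
    def d_unit(self) -> np.ndarray:
        return self.d / np.sqrt(2.0)


@dataclass
class DivergenceScores:
    """Per-species divergence scores (log10 mm) and deviations from the mean."""

    scores: pd.Series
    mean: float
    deviation: pd.Series  # sqrt|score - mean|


def evolutionary_covariance(
    A: AncestryMatrix, R: AllometricResiduals | pd.DataFrame
) -> EvolutionaryCovariance:
    """Evolutionary covariance ``(R - 1 a')' C^-1 (R - 1 a') / (n - 1)``.

    ``a`` is the per-column phylogenetic mean, so the estimate is the ML-type
    Brownian rate matrix of the residual process (per Myr on the tree's
    branch-length scale).
    """
    Rdf = R.residuals if isinstance(R, AllometricResiduals) else R
    if list(Rdf.index) != list(A.tips):
        raise ValueError("residual rows must match the ancestry matrix tips")
    X = Rdf.to_numpy(dtype=float)
    a = phylo_mean(A, X)
    Xc = X - a
    CiXc = A.solve(Xc)
    sigma = (Xc.T @ CiXc) / (A.n - 1)
    cross = sigma[:3, 3:]
    if cross.any():
        u1, v1, s, share = leading_salience(cross)
    else:  # degenerate inputs: no wing-leg covariance to decompose
        u1 = v1 = s = None
        share = 0.0
    return EvolutionaryCovariance(
        sigma_evo=sigma,
        cross_block=cross,
        singular_values=s,
        u1=u1,
        v1=v1,
        share=share,
    )


def leading_salience(cross_block: np.ndarray):
    """First singular triplet of the wing-by-leg cross-covariance.

    Returns ``(u1, v1, singular_values, share)`` where
    ``share = s1^2 / sum(s^2)`` measures how dominant the leading salience
    is.  Signs are chosen so the joint loading sum is positive (concordant
    growth reads as positive).
    """
    B = np.asarray(cross_block, dtype=float)
    if B.shape != (3, 3):
        raise ValueError("cross block must be 3x3")
    if not B.any():
        raise ValueError("cross-covariance block is identically zero")
    U, s, Vt = linalg.svd(B)
    u1, v1 = U[:, 0], Vt[0]
    if u1.sum() + v1.sum() < 0:
        u1, v1 = -u1, -v1
    share = float(s[0] ** 2 / np.sum(s**2))
    return u1, v1, s, share


def build_axes(u1: np.ndarray, v1: np.ndarray) -> AxisPair:
    """Concordance ``g = (u1 | v1)`` and its pi/2 rotation ``d = (u1 | -v1)``.

    The rotation is within the plane spanned by the pure-wing and pure-leg
    unit directions ``(u1 | 0)`` and ``(0 | v1)``, so g and d are exactly
    orthogonal by construction.
    """
    u1 = np.asarray(u1, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    for v in (u1, v1):
        if v.shape != (3,) or abs(linalg.norm(v) - 1.0) > 1e-8:
            raise ValueError("u1 and v1 must be unit 3-vectors")
    g = np.concatenate([u1, v1])
    d = np.concatenate([u1, -v1])
    if d[:3].sum() < 0:
        d = -d
    return AxisPair(g=g, d=d)


def project_divergence(
    R: AllometricResiduals | pd.DataFrame,
    axes: AxisPair,
    center: str = "arithmetic",
    A: AncestryMatrix | None = None,
) -> DivergenceScores:
    """Species divergence scores: residual projections on the unit d axis.

    ``center`` selects how the reference mean score is computed: the
    default arithmetic mean over included species, or the phylogenetic
    (GLS) mean when ``center='phylogenetic'`` and an ancestry matrix is
    supplied.
    """
    Rdf = R.residuals if isinstance(R, AllometricResiduals) else R
    scores = pd.Series(
        Rdf.to_numpy(dtype=float) @ axes.d_unit, index=Rdf.index, name="delta"
    )
    if center == "arithmetic":
        mean = float(scores.mean())
    elif center == "phylogenetic":
        if A is None:
            raise ValueError("phylogenetic centering requires an ancestry matrix")
        mean = float(phylo_mean(A, scores.loc[A.tips].to_numpy()))
    else:
        raise ValueError(f"unknown center {center!r}")
    deviation = np.sqrt((scores - mean).abs()).rename("deviation")
    return DivergenceScores(scores=scores, mean=mean, deviation=deviation)


def divergence_pipeline(
    A: AncestryMatrix, R: AllometricResiduals
) -> tuple[EvolutionaryCovariance, AxisPair, DivergenceScores]:
    """Covariance -> axes -> scores in one call (the common path)."""
    evo = evolutionary_covariance(A, R)
    axes = build_axes(evo.u1, evo.v1)
    scores = project_divergence(R, axes)
    return evo, axes, scores
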
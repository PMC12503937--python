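"""Phylogenetic allometric correction of limb bone lengths.

Bird masses span four orders of magnitude, and scale-dependent variation in
bone proportions can mask the subtler patterns of correlated evolution this
package studies.  Each log10 bone length is therefore regressed on log10
body mass by generalized least squares under a Brownian motion error
structure (error covariance proportional to the shared-ancestry matrix
``C``), and all downstream analyses consume the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .simulate import BONES
from .trees import AncestryMatrix

__all__ = ["AllometricResiduals", "fit_allometry", "WING_BONES", "LEG_BONES"]

WING_BONES = BONES[:3]
LEG_BONES = BONES[3:]


@dataclass
class AllometricResiduals:
    """Residual log10 bone lengths after removing mass scaling.

    ``residuals`` is species x 6 (log10 mm), column order fixed as
    (humerus, radius, carpometacarpus, femur, tibiotarsus, tarsometatarsus);
    the first three columns form the wing block, the last three the leg
    block.  The GLS normal equations force the C-inverse-weighted mean of
    every residual column to zero.
    """

    residuals: pd.DataFrame
    slopes: pd.Series
    intercepts: pd.Series

    @property
    def species(self) -> list[str]:
        return list(self.residuals.index)

    @property
    def wing(self) -> pd.DataFrame:
        return self.residuals[list(WING_BONES)]

    @property
    def leg(self) -> pd.DataFrame:
        return self.residuals[list(LEG_BONES)]

    def values(self) -> np.ndarray:
        return self.residuals.to_numpy()


def fit_allometry(A: AncestryMatrix, traits: pd.DataFrame) -> AllometricResiduals:
    """Six univariate GLS fits of log10 length on log10 mass.

    Per bone ``j``: ``beta_j = (X' C^-1 X)^-1 X' C^-1 y_j`` with
    ``X = [1, log10 mass]``; the residual is ``y_j - X beta_j``.  Species
    order follows the ancestry matrix.
    """
    trait_species = set(traits.index)
    tree_species = set(A.tips)
    if trait_species != tree_species:
        only_tree = sorted(tree_species - trait_species)
        only_traits = sorted(trait_species - tree_species)
        raise ValueError(
            "species mismatch between tree and traits: "
            f"only in tree {only_tree[:10]}, only in traits {only_traits[:10]}"
        )
    df = traits.loc[A.tips]
    lengths = df[list(BONES)].to_numpy(dtype=float)
    mass = df["mass_g"].to_numpy(dtype=float)
    if np.any(lengths <= 0) or np.any(mass <= 0):
        raise ValueError("bone lengths and masses must be strictly positive")

    Y = np.log10(lengths)
    X = np.column_stack([np.ones(A.n), np.log10(mass)])
    factor = A.cho_factor()
    CiX = linalg.cho_solve(factor, X)
    XtCiX = X.T @ CiX
    if np.linalg.cond(XtCiX) > 1e12:
        raise ValueError("design is singular (constant body mass?)")
    beta = np.linalg.solve(XtCiX, CiX.T @ Y)  # 2 x 6
    resid = Y - X @ beta

    residuals = pd.DataFrame(resid, index=df.index, columns=list(BONES))
    return AllometricResiduals(
        residuals=residuals,
        slopes=pd.Series(beta[1], index=list(BONES), name="slope"),
        intercepts=pd.Series(beta[0], index=list(BONES), name="intercept"),
    )
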
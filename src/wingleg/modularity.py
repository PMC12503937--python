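"""Developmental-subset modularity tests.

Asks whether evolutionary correlations between wing and leg residuals are
weaker in altricial than in precocial lineages.  Each developmental subset
is whitened on its own pruned tree (removing phylogenetic self-correlation),
bone-pair Pearson correlations are compared with a one-tailed two-sample
Fisher-Z test, and phylogenetic effective sample sizes are substituted for
the raw subset sizes.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import AllometricResiduals
from .simulate import BONES
from .trees import AncestryMatrix, Phylogeny, effective_n, prune_to, vcv, whitening

__all__ = [
    "whiten_residuals",
    "pairwise_rho",
    "fisher_z_test",
    "modularity_report",
]


def whiten_residuals(A_subset: AncestryMatrix, R_subset: pd.DataFrame) -> pd.DataFrame:
    """Project residuals onto the scaled eigenvectors of the subset tree.

    The transformed rows are uncorrelated across species (W C W' = I), so
    column correlations can be treated parametrically.
    """
    if list(R_subset.index) != list(A_subset.tips):
        raise ValueError("residual rows must match the subset ancestry matrix")
    if A_subset.n < 4:
        raise ValueError("subset too small for correlation analysis (< 4 species)")
    Wt = whitening(A_subset)
    return pd.DataFrame(
        Wt.apply(R_subset.to_numpy()), index=R_subset.index, columns=R_subset.columns
    )


def pairwise_rho(Rt: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pearson correlation for every bone pair (diagonal = 1).

    Zero-variance columns yield NaN entries and a warning rather than a
    silent zero.
    """
    X = np.asarray(Rt, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 rows for pairwise correlations")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance column(s); correlations undefined there")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    R[np.ix_(sd == 0, np.arange(X.shape[1]))] = np.nan
    R[np.ix_(np.arange(X.shape[1]), sd == 0)] = np.nan
    cols = list(Rt.columns) if isinstance(Rt, pd.DataFrame) else list(range(X.shape[1]))
    return pd.DataFrame(R, index=cols, columns=cols)


def fisher_z_test(
    rho_a: float, rho_p: float, n_a_eff: float, n_p_eff: float
) -> tuple[float, float]:
    """One-tailed two-sample Fisher-Z comparison of correlations.

    ``z = (atanh(rho_a) - atanh(rho_p)) / sqrt(1/(n_a-3) + 1/(n_p-3))``;
    the returned p-value is the lower tail, small when the altricial
    correlation is weaker than the precocial one.
    """
    if n_a_eff <= 3 or n_p_eff <= 3:
        raise ValueError("effective sample sizes must exceed 3")
    if abs(rho_a) >= 1 or abs(rho_p) >= 1:
        raise ValueError("|rho| = 1 has an infinite Fisher transform")
    z = (np.arctanh(rho_a) - np.arctanh(rho_p)) / np.sqrt(
        1.0 / (n_a_eff - 3.0) + 1.0 / (n_p_eff - 3.0)
    )
    return float(z), float(stats.norm.cdf(z))


def modularity_report(
    residuals: AllometricResiduals,
    traits: pd.DataFrame,
    phy: Phylogeny,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All 15 bone-pair correlation comparisons between developmental subsets.

    Global allometric residuals are subset by the binary developmental
    class, each subset is whitened on its own pruned tree, and each pair is
    tested one-tailed for a weaker altricial correlation (uncorrected
    significance flags at ``alpha``).
    """
    from .tables import dev_binary

    dev = traits["dev_class"].map(dev_binary)
    groups = {}
    for name in ("altricial", "precocial"):
        members = [s for s in residuals.species if dev.get(s) == name]
        if len(members) < 4:
            raise ValueError(f"{name} subset has fewer than 4 species")
        sub_tree = prune_to(phy, members)
        A_sub = vcv(sub_tree)
        Rt = whiten_residuals(A_sub, residuals.residuals.loc[A_sub.tips])
        groups[name] = {
            "rho": pairwise_rho(Rt),
            "n_eff": effective_n(A_sub),
            "n": len(members),
        }

    rows = []
    for bone_i, bone_j in itertools.combinations(BONES, 2):
        ra = groups["altricial"]["rho"].loc[bone_i, bone_j]
        rp = groups["precocial"]["rho"].loc[bone_i, bone_j]
        z, p = fisher_z_test(
            ra, rp, groups["altricial"]["n_eff"], groups["precocial"]["n_eff"]
        )
        rows.append(
            {
                "bone_i": bone_i,
                "bone_j": bone_j,
                "rho_altricial": ra,
                "rho_precocial": rp,
                "n_eff_a": groups["altricial"]["n_eff"],
                "n_eff_p": groups["precocial"]["n_eff"],
                "z": z,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
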
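"""Compositional analysis of internal wing proportions.

The three wing bones are closed to proportions ``p = (hum, rad, cmc)``
summing to one, analysed in centred log-ratio (clr) coordinates, and
summarized by the two non-trivial principal components of the clr
covariance (the third eigenvalue vanishes by closure).  Ternary coordinates
support Fig.-style occupancy maps, the Brachial Index (humerus/radius, the
radius standing in for the ulna whose length it matches) reads out
stylopod-zeugopod trade-offs, and the ancestral composition is the
phylogenetic mean taken in clr space and closed back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.composition import clr, closure

from .axes import DivergenceScores
from .trees import AncestryMatrix, phylo_mean

__all__ = [
    "WingComposition",
    "wing_proportions",
    "clr_pca",
    "ternary_xy",
    "ancestral_composition",
    "deviation_overlay",
    "brachial_index",
]

WING_PARTS = ("humerus_mm", "radius_mm", "carpometacarpus_mm")


@dataclass
class WingComposition:
    """Closed wing proportions with clr PCA scores and ternary coordinates."""

    proportions: pd.DataFrame  # species x (p_hum, p_rad, p_cmc)
    clr_coords: pd.DataFrame
    pc_scores: pd.DataFrame  # PC1, PC2
    pc_axes: np.ndarray  # 2 x 3 clr loadings
    eigenvalues: np.ndarray
    ternary: pd.DataFrame  # x, y
    brachial_index: pd.Series


def wing_proportions(traits: pd.DataFrame) -> pd.DataFrame:
    """Wing bone lengths closed to unit-sum proportions."""
    L = traits[list(WING_PARTS)].to_numpy(dtype=float)
    if np.any(L <= 0):
        raise ValueError("wing bone lengths must be strictly positive")
    p = closure(L)
    return pd.DataFrame(p, index=traits.index, columns=["p_hum", "p_rad", "p_cmc"])


def brachial_index(traits: pd.DataFrame) -> pd.Series:
    """Humerus length over radius length (radius as the ulna proxy)."""
    bi = traits["humerus_mm"] / traits["radius_mm"]
    return bi.rename("brachial_index")


def clr_pca(proportions: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Principal components of the centred log-ratio covariance.

    Returns ``(scores, axes, eigenvalues)`` with two non-trivial axes; PC2
    is oriented so positive scores track a higher Brachial Index
    (humeralized wings).
    """
    if len(proportions) < 4:
        raise ValueError("need at least 4 species for a compositional PCA")
    Z = clr(proportions.to_numpy(dtype=float))
    Zc = Z - Z.mean(axis=0)
    if np.allclose(Zc, 0):
        raise ValueError("all compositions identical; PCA undefined")
    cov = (Zc.T @ Zc) / (len(Z) - 1)
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    axes = evecs[:, :2].T  # rows = PC1, PC2 loadings over (hum, rad, cmc)
    scores = Zc @ axes.T
    # orient PC2 with the Brachial Index contrast clr(hum) - clr(rad)
    bi_contrast = Z[:, 0] - Z[:, 1]
    if np.corrcoef(scores[:, 1], bi_contrast)[0, 1] < 0:
        axes[1] = -axes[1]
        scores[:, 1] = -scores[:, 1]
    score_df = pd.DataFrame(scores, index=proportions.index, columns=["PC1", "PC2"])
    return score_df, axes, evals


def ternary_xy(p: np.ndarray | pd.DataFrame) -> pd.DataFrame | np.ndarray:
    """Unit-triangle coordinates, vertex order (humerus, radius, carpometacarpus).

    ``x = p_rad + p_cmc / 2``, ``y = p_cmc * sqrt(3) / 2``: the humerus
    vertex sits at the origin, radius at (1, 0), carpometacarpus at the apex.
    """
    arr = np.asarray(p, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 3:
        raise ValueError("compositions must have 3 parts")
    if np.abs(arr.sum(axis=1) - 1).max() > 1e-9:
        raise ValueError("compositions must sum to 1")
    x = arr[:, 1] + arr[:, 2] / 2.0
    y = arr[:, 2] * np.sqrt(3.0) / 2.0
    out = np.column_stack([x, y])
    if isinstance(p, pd.DataFrame):
        return pd.DataFrame(out, index=p.index, columns=["x", "y"])
    return out[0] if single else out


def ancestral_composition(A: AncestryMatrix, proportions: pd.DataFrame) -> np.ndarray:
    """Phylogenetic mean in clr space, closed back to a composition.

    On a star tree this is the (closed) geometric mean composition.
    """
    P = proportions.loc[A.tips]
    Z = clr(P.to_numpy(dtype=float))
    z_hat = phylo_mean(A, Z)
    return closure(np.exp(z_hat))


def build_wing_composition(
    traits: pd.DataFrame, scores: DivergenceScores | None = None
) -> WingComposition:
    """Assemble the full compositional summary for a trait table."""
    props = wing_proportions(traits)
    pc_scores, axes, evals = clr_pca(props)
    return WingComposition(
        proportions=props,
        clr_coords=pd.DataFrame(
            clr(props.to_numpy(dtype=float)),
            index=props.index,
            columns=["clr_hum", "clr_rad", "clr_cmc"],
        ),
        pc_scores=pc_scores,
        pc_axes=axes,
        eigenvalues=evals,
        ternary=ternary_xy(props),
        brachial_index=brachial_index(traits),
    )


def deviation_overlay(
    scores: DivergenceScores,
    comp: WingComposition,
    grouping: pd.Series | None = None,
) -> pd.DataFrame:
    """Join PC scores, ternary coordinates and divergence deviations.

    ``grouping`` maps species to a developmental class or clade label; empty
    groups are skipped with a warning, unknown species raise.  The result
    feeds plotting layers and per-group PC2-range summaries.
    """
    import warnings

    common = comp.pc_scores.index.intersection(scores.scores.index)
    if len(common) == 0:
        raise ValueError("no shared species between scores and compositions")
    out = pd.DataFrame(
        {
            "PC1": comp.pc_scores.loc[common, "PC1"],
            "PC2": comp.pc_scores.loc[common, "PC2"],
            "x": comp.ternary.loc[common, "x"],
            "y": comp.ternary.loc[common, "y"],
            "deviation": scores.deviation.loc[common],
            "brachial_index": comp.brachial_index.loc[common],
        }
    )
    if grouping is not None:
        unknown = sorted(set(grouping.index) - set(common))
        if unknown:
            raise KeyError(f"grouping names unknown species: {unknown[:10]}")
        out["group"] = grouping.reindex(common)
        for g, sub in out.groupby("group", dropna=False):
            if sub.empty:
                warnings.warn(f"empty group {g!r} skipped")
    else:
        out["group"] = "all"
    return out


def pc2_range_by_group(overlay: pd.DataFrame) -> pd.DataFrame:
    """Per-group PC2 span summary (who explores the Brachial-Index axis)."""
    return (
        overlay.groupby("group")["PC2"]
        .agg(["min", "max", "count"])
        .assign(range=lambda d: d["max"] - d["min"])
    )


def deviation_pc2_association(overlay: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between |PC2| and the divergence deviation."""
    rho, p = stats.spearmanr(overlay["PC2"].abs(), overlay["deviation"])
    return float(rho), float(p)
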
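"""Replicated simulation experiments used for validation and reporting.

Each experiment regenerates data under the study conditions, runs the
relevant slice of the pipeline from scratch, and returns per-replicate
metrics; callers summarize (typically by medians).  All randomness is
driven by a single integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ecology as eco
from .allometry import fit_allometry
from .axes import divergence_pipeline
from .modularity import modularity_report
from .rates import fit_bm_single, fit_bm_two_rate, likelihood_ratio_test
from .regimes import PRECOCIAL, regime_path_lengths, simulate_regimes
from .simulate import GeneratorConfig, make_dataset, simulate_tree
from .tables import dev_binary
from .trees import vcv

__all__ = [
    "two_rate_recovery",
    "default_dataset_metrics",
    "null_lrt_calibration",
    "modularity_null_type_one",
]

_MOD = 2**31 - 1


def _derive(seed: int, k: int) -> int:
    return int((seed * 1000003 + k * 7919 + 1) % _MOD)


def two_rate_recovery(
    n_reps: int = 50,
    n_tips: int = 600,
    sigma2_a: float = 3.7e-4,
    sigma2_p: float = 2.0e-4,
    mk_rate: float = 0.01,
    tree_height: float = 80.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Simulate divergence scores under the two-regime Brownian model on the
    true regime painting and refit by maximum likelihood.

    Per replicate: a fresh pure-birth tree, a fresh equal-rates regime
    history, scores drawn from N(0, s2_a B_a + s2_p B_p), then single- and
    two-rate fits and the 1-df LRT.
    """
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(_derive(seed, 3 * rep + 2))
        phy = simulate_tree(n_tips, _derive(seed, 3 * rep), tree_height)
        rmap = simulate_regimes(phy, mk_rate, PRECOCIAL, _derive(seed, 3 * rep + 1))
        paths = regime_path_lengths(rmap, phy)
        V = sigma2_a * paths.B_altricial + sigma2_p * paths.B_precocial
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n_tips))
        y = L @ rng.standard_normal(n_tips)
        single = fit_bm_single(y, vcv(phy))
        two = fit_bm_two_rate(y, paths)
        lam, p = likelihood_ratio_test(single, two)
        rows.append(
            {
                "sigma2_altricial": two.sigma2_altricial,
                "sigma2_precocial": two.sigma2_precocial,
                "lrt_lambda": lam,
                "lrt_p": p,
            }
        )
    return pd.DataFrame(rows)


def default_dataset_metrics(n_reps: int = 50, seed: int = 1) -> pd.DataFrame:
    """Full-pipeline metrics on default synthetic studies.

    Per replicate: salience share of the wing-leg cross-covariance, the
    altricial mass ~ score adjusted R^2, and the altricial quadratic
    M_flight ~ score adjusted R^2.
    """
    rows = []
    for rep in range(n_reps):
        cfg = GeneratorConfig(seed=_derive(seed, 100 + rep))
        ds = make_dataset(cfg)
        A = vcv(ds.phylogeny)
        resid = fit_allometry(A, ds.traits)
        evo, axes, scores = divergence_pipeline(A, resid)
        dev = ds.traits["dev_class"].map(dev_binary)
        alt = dev.index[dev == "altricial"]

        mass_fit = eco.fit_ecology_models(
            np.log10(ds.traits.loc[alt, "mass_g"]), scores.scores, "linear"
        )
        fd = eco.flight_distinctiveness(ds.flight_styles)
        flight_fit = eco.fit_ecology_models(
            fd.m_flight.loc[fd.m_flight.index.intersection(alt)],
            scores.scores,
            "quadratic",
        )
        rows.append(
            {
                "salience_share": evo.share,
                "mass_adj_r2": mass_fit.adj_r2,
                "flight_adj_r2": flight_fit.adj_r2,
                "n_altricial": len(alt),
            }
        )
    return pd.DataFrame(rows)


def null_lrt_calibration(
    n_reps: int = 200, n_tips: int = 600, sigma2: float = 2.7e-4, seed: int = 1
) -> pd.DataFrame:
    """LRT p-values when the data truly evolve at a single rate.

    Scores are drawn under one Brownian rate on the tree; the two-rate model
    is fit on an (independent) simulated regime painting, so its extra
    parameter is pure overfitting and p should be uniform.
    """
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(_derive(seed, 5 * rep + 4))
        phy = simulate_tree(n_tips, _derive(seed, 5 * rep + 2), 80.0)
        rmap = simulate_regimes(phy, 0.01, PRECOCIAL, _derive(seed, 5 * rep + 3))
        paths = regime_path_lengths(rmap, phy)
        A = vcv(phy)
        L = np.linalg.cholesky(sigma2 * A.C + 1e-12 * np.eye(n_tips))
        y = L @ rng.standard_normal(n_tips)
        single = fit_bm_single(y, A)
        two = fit_bm_two_rate(y, paths)
        _, p = likelihood_ratio_test(single, two)
        rows.append({"lrt_p": p})
    return pd.DataFrame(rows)


def modularity_null_type_one(n_reps: int = 200, seed: int = 1) -> np.ndarray:
    """Fisher-Z p-values for every bone pair under the modularity null.

    The generator is run with equal divergence variances in the two regimes
    (and the ecological couplings off), so no pair should differ between
    developmental subsets beyond chance.
    """
    ps = []
    for rep in range(n_reps):
        cfg = GeneratorConfig(
            seed=_derive(seed, 200 + rep),
            divergence_variance_altricial=2.0e-4,
            divergence_variance_precocial=2.0e-4,
            mass_coupling=0.0,
            flight_coupling=0.0,
        )
        ds = make_dataset(cfg)
        A = vcv(ds.phylogeny)
        resid = fit_allometry(A, ds.traits)
        grid = modularity_report(resid, ds.traits, ds.phylogeny)
        ps.extend(grid["p"].tolist())
    return np.asarray(ps)
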
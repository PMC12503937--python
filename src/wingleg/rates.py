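"""Regime-dependent Brownian rate inference for the divergence score.

The chain of inference: fit the equal-rates (ER) Markov model to binary
developmental tip states; draw stochastic character maps conditioned on the
tips (backward pruning / forward sampling, with exact within-branch path
sampling by uniformization); split shared path lengths by regime; and fit
single-rate versus two-rate Brownian motion models of the divergence score
by maximum likelihood, compared with a 1-df likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .regimes import (
    ALTRICIAL,
    PRECOCIAL,
    STATES,
    RegimeMap,
    RegimePathLengths,
    regime_path_lengths,
)
from .trees import AncestryMatrix, Phylogeny, phylo_mean, vcv

__all__ = [
    "MkFit",
    "RateFit",
    "fit_mk_er",
    "sample_simmap",
    "regime_path_lengths",
    "fit_bm_single",
    "fit_bm_two_rate",
    "likelihood_ratio_test",
    "ancestral_scores",
]

_IDX = {ALTRICIAL: 0, PRECOCIAL: 1}


@dataclass
class MkFit:
    """ML fit of the two-state equal-rates Markov model."""

    q: float
    loglik: float
    root_prior: str = "fixed_precocial"


@dataclass
class RateFit:
    """ML Brownian rate fit of a univariate trait on a (regime-split) tree."""

    model: str  # "single" | "two_rate"
    sigma2: float | None
    sigma2_altricial: float | None
    sigma2_precocial: float | None
    mu: float
    loglik: float
    n_params: int


def _transition_matrix(q: float, t: float) -> np.ndarray:
    """ER 2-state transition probabilities: (1 +/- exp(-2qt)) / 2."""
    e = np.exp(-2.0 * q * t)
    same = 0.5 * (1.0 + e)
    diff = 0.5 * (1.0 - e)
    return np.array([[same, diff], [diff, same]])


def _tip_state_vector(phy: Phylogeny, tip_states) -> dict[int, int]:
    states = dict(tip_states)
    out = {}
    for nid in phy.tip_ids:
        label = phy.tip_label(nid)
        if label not in states:
            raise ValueError(f"no state for tip {label}")
        s = states[label]
        if s not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {s!r}")
        out[int(nid)] = _IDX[s]
    return out


def _pruning(phy: Phylogeny, tip_idx: dict[int, int], q: float):
    """Conditional likelihoods L[node, state] of the data below each node,
    with per-node log scaling factors to avoid underflow."""
    n = phy.n_nodes
    L = np.zeros((n, 2))
    logscale = np.zeros(n)
    for nid in phy.postorder():
        if phy.is_tip(nid):
            L[nid, tip_idx[nid]] = 1.0
            continue
        vals = np.ones(2)
        for c in phy.children[nid]:
            P = _transition_matrix(q, float(phy.edge_length[c]))
            vals = vals * (P @ L[c])
            logscale[nid] += logscale[c]
        m = vals.max()
        if m <= 0:
            return None, None  # impossible data at this rate
        L[nid] = vals / m
        logscale[nid] += np.log(m)
    return L, logscale


def _mk_loglik(phy, tip_idx, q, root_prior):
    L, logscale = _pruning(phy, tip_idx, q)
    if L is None:
        return -np.inf
    if root_prior == "fixed_precocial":
        lik = L[0, _IDX[PRECOCIAL]]
    elif root_prior == "stationary":
        lik = 0.5 * L[0].sum()
    else:
        raise ValueError(f"unknown root prior {root_prior!r}")
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale[0])


def fit_mk_er(
    phy: Phylogeny, tip_states, root_prior: str = "fixed_precocial"
) -> MkFit:
    """ML transition rate of the equal-rates model by bounded 1-D search.

    With all tips in the root state the boundary estimate ``q = 0`` is
    reported (no change needed, log-likelihood 0 under the fixed root).
    """
    tip_idx = _tip_state_vector(phy, tip_states)
    observed = set(tip_idx.values())
    root_idx = _IDX[PRECOCIAL]
    if observed == {root_idx} and root_prior == "fixed_precocial":
        return MkFit(q=0.0, loglik=0.0, root_prior=root_prior)

    mean_edge = float(phy.edge_length[1:].mean())
    q_max = 50.0 / max(mean_edge, 1e-9)

    def neg(q):
        return -_mk_loglik(phy, tip_idx, q, root_prior)

    # the likelihood can have a narrow basin against a high-rate plateau:
    # coarse log-spaced scan first, then a bounded local refinement
    grid = np.geomspace(1e-6 / mean_edge, q_max, 80)
    vals = [neg(q) for q in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    q_hat = float(res.x)
    ll = -float(res.fun)
    ll0 = _mk_loglik(phy, tip_idx, 0.0, root_prior)
    if ll0 >= ll:  # boundary optimum
        return MkFit(q=0.0, loglik=float(ll0), root_prior=root_prior)
    return MkFit(q=q_hat, loglik=ll, root_prior=root_prior)


def _sample_path(i: int, j: int, t: float, q: float, rng) -> list[tuple[str, float]]:
    """Exact ER path conditioned on endpoints, by uniformization.

    With uniformization rate q the auxiliary jump chain is the pure state
    flip, so the number of virtual jumps N given endpoints is Poisson(qt)
    restricted to even (i == j) or odd parity, and every jump is real.
    """
    if t <= 0:
        return []
    if q <= 0:
        if i != j:
            raise ValueError("endpoint change impossible at rate 0")
        return [(STATES[i], t)]
    lam = q * t
    # number of flips N: Poisson(lam) restricted to the endpoint parity
    parity = 0 if i == j else 1
    if parity == 0:
        norm = 0.5 * (1.0 + np.exp(-2.0 * lam))
    else:
        norm = 0.5 * (1.0 - np.exp(-2.0 * lam))
    u = rng.random() * norm
    n = parity
    term = np.exp(-lam) * (lam if parity else 1.0)
    acc = term
    while acc < u and n < 100000:
        n += 2
        term *= lam * lam / ((n - 1) * n)
        acc += term
    jumps = np.sort(rng.random(n)) * t if n else np.array([])
    segs: list[tuple[str, float]] = []
    state, last = i, 0.0
    for tj in jumps:
        segs.append((STATES[state], float(tj - last)))
        state = 1 - state
        last = float(tj)
    segs.append((STATES[state], float(t - last)))
    if state != j:
        raise AssertionError("parity bookkeeping failed")
    return segs


def sample_simmap(
    phy: Phylogeny,
    tip_states,
    mk: MkFit,
    n_maps: int = 1,
    seed: int | np.random.Generator = 0,
) -> list[RegimeMap]:
    """Stochastic character maps conditioned on the observed tip states.

    Node states are drawn from their conditional distributions (backward
    pruning, forward sampling; root fixed precocial under the default
    prior), then each branch history is filled in by uniformization.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be at least 1")
    tip_idx = _tip_state_vector(phy, tip_states)
    if mk.q == 0 and len(set(tip_idx.values())) > 1:
        raise ValueError("tip states differ but the fitted rate is 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L, _ = _pruning(phy, tip_idx, mk.q)
    if L is None:
        raise ValueError("data impossible under the fitted model")

    maps = []
    root_idx = _IDX[PRECOCIAL]
    for _ in range(n_maps):
        node_state = np.zeros(phy.n_nodes, dtype=int)
        if mk.root_prior == "fixed_precocial":
            if L[0, root_idx] <= 0:
                raise ValueError("tip states impossible under a precocial root")
            node_state[0] = root_idx
        else:
            w = 0.5 * L[0]
            node_state[0] = int(rng.random() * w.sum() > w[0])
        segments: list[list[tuple[str, float]]] = [[] for _ in range(phy.n_nodes)]
        stem = float(phy.edge_length[0])
        if stem > 0:
            segments[0] = [(STATES[node_state[0]], stem)]
        for nid in range(1, phy.n_nodes):
            p_state = node_state[phy.parent[nid]]
            t = float(phy.edge_length[nid])
            P = _transition_matrix(mk.q, t)
            w = P[p_state] * L[nid]
            node_state[nid] = int(rng.random() * w.sum() > w[0])
            segments[nid] = _sample_path(p_state, node_state[nid], t, mk.q, rng)
        maps.append(
            RegimeMap(phy=phy, segments=segments, root_state=STATES[node_state[0]])
        )
    return maps


def _gaussian_loglik(y: np.ndarray, V: np.ndarray):
    """Profile-mu Gaussian tree likelihood pieces for covariance V.

    Returns (mu_hat, qform/n, logdet V); the ML scale estimate divides the
    GLS quadratic form by n.
    """
    n = len(y)
    cf = linalg.cho_factor(V)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ones = np.ones(n)
    Vi1 = linalg.cho_solve(cf, ones)
    mu = float((Vi1 @ y) / (ones @ Vi1))
    r = y - mu
    q = float(r @ linalg.cho_solve(cf, r))
    return mu, q / n, logdet


def fit_bm_single(y: np.ndarray | pd.Series, A: AncestryMatrix) -> RateFit:
    """Single-rate Brownian fit: ``sigma2 = (y - mu)' C^-1 (y - mu) / n`` (ML)."""
    yv = np.asarray(y.loc[A.tips] if isinstance(y, pd.Series) else y, dtype=float)
    if len(yv) != A.n:
        raise ValueError("y length does not match the ancestry matrix")
    n = len(yv)
    mu, s2, logdet = _gaussian_loglik(yv, A.C)
    if s2 <= 0:
        # constant data: degenerate likelihood, report the boundary
        return RateFit("single", 0.0, None, None, mu, np.inf, 2)
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return RateFit("single", float(s2), None, None, mu, float(ll), 2)


def fit_bm_two_rate(
    y: np.ndarray | pd.Series, paths: RegimePathLengths
) -> RateFit:
    """Two-rate Brownian fit with ``V = s2_a B_a + s2_p B_p``.

    The overall scale is profiled out analytically, leaving a bounded 1-D
    search over the log rate ratio; the root value is profiled by GLS at
    every step.  Reduces to the single-rate fit when one regime's path
    matrix vanishes.
    """
    yv = np.asarray(
        y.loc[paths.tips] if isinstance(y, pd.Series) else y, dtype=float
    )
    B_a, B_p = paths.B_altricial, paths.B_precocial
    n = len(yv)
    if B_a.shape != (n, n):
        raise ValueError("y length does not match path matrices")
    ridge = 1e-10 * max(paths.height, 1.0) * np.eye(n)

    def pieces(log_ratio):
        V0 = B_a + np.exp(log_ratio) * B_p
        try:
            return _gaussian_loglik(yv, V0)
        except linalg.LinAlgError:
            try:  # near-PSD: ridge only when the clean factorization fails
                return _gaussian_loglik(yv, V0 + ridge)
            except linalg.LinAlgError:
                return None

    def neg(log_ratio):
        out = pieces(log_ratio)
        if out is None or out[1] <= 0:
            return 1e12  # penalized: non-PSD or degenerate
        _, s2, logdet = out
        return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

    # multi-start around the equal-rates point
    best = None
    for x0 in (-4.0, 0.0, 4.0):
        res = optimize.minimize_scalar(
            neg,
            bounds=(x0 - 6.0, x0 + 6.0),
            method="bounded",
            options={"xatol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    log_ratio = float(best.x)
    mu, s2_a, _ = pieces(log_ratio)
    s2_p = s2_a * float(np.exp(log_ratio))
    ll = -float(best.fun)
    return RateFit("two_rate", None, float(s2_a), float(s2_p), mu, ll, 3)


def likelihood_ratio_test(fit0: RateFit, fit1: RateFit) -> tuple[float, float]:
    """1-df chi-square LRT of the two-rate against the single-rate model."""
    df = fit1.n_params - fit0.n_params
    if df != 1:
        raise ValueError("models must differ by exactly one parameter")
    if fit1.loglik < fit0.loglik - 1e-4:
        raise ValueError(
            "two-rate likelihood below single-rate: optimizer failure "
            f"({fit1.loglik:.6f} < {fit0.loglik:.6f})"
        )
    lam = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    return lam, float(stats.chi2.sf(lam, df=1))


def ancestral_scores(phy: Phylogeny, y: np.ndarray | pd.Series) -> pd.DataFrame:
    """BLUP ancestral values at internal nodes under single-rate Brownian motion.

    The root takes the phylogenetic mean; each internal node the Gaussian
    conditional expectation given the tips (the Brownian rate cancels).
    Returns a node table with depths for phenogram plotting.
    """
    A = vcv(phy)
    yv = np.asarray(y.loc[A.tips] if isinstance(y, pd.Series) else y, dtype=float)
    mu = phylo_mean(A, yv)
    resid = A.solve(yv - mu)

    tip_pos = {int(t): k for k, t in enumerate(phy.tip_ids)}
    # representative tip below each node, for cross-covariance lookups
    rep = np.zeros(phy.n_nodes, dtype=int)
    below: dict[int, list[int]] = {}
    for nid in phy.postorder():
        if phy.is_tip(nid):
            below[nid] = [nid]
        else:
            below[nid] = [t for c in phy.children[nid] for t in below[c]]
        rep[nid] = below[nid][0]

    rows = []
    for nid in range(phy.n_nodes):
        if phy.is_tip(nid):
            rows.append(
                {
                    "node": nid,
                    "depth": float(phy.depth[nid]),
                    "estimate": float(yv[tip_pos[nid]]),
                    "is_tip": True,
                    "label": phy.tip_label(nid),
                }
            )
            continue
        cvec = A.C[tip_pos[rep[nid]]].copy()
        under = [tip_pos[t] for t in below[nid]]
        cvec[under] = phy.depth[nid]
        est = mu + float(cvec @ resid)
        rows.append(
            {
                "node": nid,
                "depth": float(phy.depth[nid]),
                "estimate": est,
                "is_tip": False,
                "label": "",
            }
        )
    return pd.DataFrame(rows).set_index("node")
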
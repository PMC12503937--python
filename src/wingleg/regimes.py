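"""Regime histories (altricial/precocial paintings) along a phylogeny.

A :class:`RegimeMap` stores, for every branch, an ordered list of
``(state, duration)`` segments — the same structure a stochastic character
map carries.  Maps are produced either by forward simulation under the
equal-rates Markov model (:func:`simulate_regimes`) or by conditional
sampling given tip states (``rates.sample_simmap``), and are consumed by
the two-regime Brownian model through :func:`regime_path_lengths`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import AncestryMatrix, Phylogeny, vcv

__all__ = [
    "ALTRICIAL",
    "PRECOCIAL",
    "STATES",
    "RegimeMap",
    "simulate_regimes",
    "regime_path_lengths",
    "RegimePathLengths",
]

ALTRICIAL = "altricial"
PRECOCIAL = "precocial"
STATES = (ALTRICIAL, PRECOCIAL)
_STATE_INDEX = {ALTRICIAL: 0, PRECOCIAL: 1}


@dataclass
class RegimeMap:
    """Piecewise-constant state history over every branch of a tree.

    ``segments[node_id]`` covers the edge above that node, ordered from the
    rootward end to the node; durations sum to the branch length and
    adjacent segments differ in state.  ``segments[0]`` covers the stem
    (usually empty).
    """

    phy: Phylogeny
    segments: list[list[tuple[str, float]]]
    root_state: str = PRECOCIAL

    def __post_init__(self):
        if len(self.segments) != self.phy.n_nodes:
            raise ValueError("one segment list per node required")
        for nid in range(self.phy.n_nodes):
            total = sum(d for _, d in self.segments[nid])
            if abs(total - self.phy.edge_length[nid]) > 1e-9 * max(
                1.0, self.phy.edge_length[nid]
            ):
                raise ValueError(f"segment durations do not sum to branch {nid}")
            for (s1, _), (s2, _) in zip(self.segments[nid], self.segments[nid][1:]):
                if s1 == s2:
                    raise ValueError("adjacent segments share a state")

    def node_state(self, node_id: int) -> str:
        """State at the tipward end of the edge above ``node_id``."""
        segs = self.segments[node_id]
        if segs:
            return segs[-1][0]
        if node_id == 0:
            return self.root_state
        return self.node_state(self.phy.parent[node_id])

    @property
    def tip_states(self) -> dict[str, str]:
        return {
            self.phy.tip_label(i): self.node_state(i) for i in self.phy.tip_ids
        }

    def n_transitions(self) -> int:
        total = 0
        for nid in range(self.phy.n_nodes):
            segs = self.segments[nid]
            extra = len(segs) - 1 if segs else 0
            total += max(extra, 0)
            # a change may also occur between parent's last state and this
            # edge's first state only if bookkeeping were inconsistent; the
            # constructors always start an edge in the parent's end state,
            # so transitions are exactly the within-edge state changes.
        return total

    def time_in_state(self, state: str) -> np.ndarray:
        """Cumulative time spent in ``state`` from the root to each node."""
        phy = self.phy
        cum = np.zeros(phy.n_nodes)
        for nid in range(phy.n_nodes):
            here = sum(d for s, d in self.segments[nid] if s == state)
            if nid == 0:
                cum[nid] = here
            else:
                cum[nid] = cum[phy.parent[nid]] + here
        return cum

    def to_table(self):
        """Serializable per-segment table (branch = child node id)."""
        import pandas as pd

        rows = []
        for nid in range(self.phy.n_nodes):
            for k, (state, dur) in enumerate(self.segments[nid]):
                rows.append(
                    {
                        "branch": nid,
                        "parent": int(self.phy.parent[nid]),
                        "segment": k,
                        "state": state,
                        "duration": dur,
                    }
                )
        return pd.DataFrame(rows)


def _evolve_edge(start: str, length: float, q: float, rng) -> list[tuple[str, float]]:
    """Forward-simulate a 2-state symmetric Markov path along one edge."""
    if length <= 0:
        return []
    segs: list[tuple[str, float]] = []
    state = start
    remaining = length
    while True:
        if q <= 0:
            segs.append((state, remaining))
            break
        wait = rng.exponential(1.0 / q)
        if wait >= remaining:
            segs.append((state, remaining))
            break
        segs.append((state, wait))
        remaining -= wait
        state = STATES[1 - _STATE_INDEX[state]]
    return segs


def simulate_regimes(
    phy: Phylogeny,
    q: float,
    root_state: str = PRECOCIAL,
    seed: int | np.random.Generator = 0,
) -> RegimeMap:
    """Simulate an equal-rates two-state history over the whole tree.

    Waiting times between state flips are exponential with rate ``q``
    (transitions per Myr); the root starts in ``root_state`` (ancestral
    precociality by default).
    """
    if q < 0:
        raise ValueError("q must be nonnegative")
    if root_state not in STATES:
        raise ValueError(f"unknown state {root_state!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    segments: list[list[tuple[str, float]]] = [[] for _ in range(phy.n_nodes)]
    end_state = [root_state] * phy.n_nodes
    for nid in range(phy.n_nodes):
        start = root_state if nid == 0 else end_state[phy.parent[nid]]
        segs = _evolve_edge(start, float(phy.edge_length[nid]), q, rng)
        segments[nid] = segs
        end_state[nid] = segs[-1][0] if segs else start
    return RegimeMap(phy=phy, segments=segments, root_state=root_state)


@dataclass
class RegimePathLengths:
    """Decomposition of the ancestry matrix by regime: ``B_a + B_p = C``."""

    B_altricial: np.ndarray
    B_precocial: np.ndarray
    tips: list[str] = field(default_factory=list)
    height: float = 0.0


def regime_path_lengths(rmap: RegimeMap, phy: Phylogeny | None = None) -> RegimePathLengths:
    """Split shared root-path lengths by the time spent in each regime.

    ``B_k[i, j]`` is the time spent in state ``k`` along the shared
    root-to-MRCA(i, j) path, so that ``B_a + B_p`` recovers the ancestry
    matrix exactly.
    """
    phy = phy or rmap.phy
    cum_a = rmap.time_in_state(ALTRICIAL)
    B_a = phy.mrca_fill(cum_a)
    C = vcv(phy)
    B_p = C.C - B_a
    return RegimePathLengths(
        B_altricial=B_a, B_precocial=B_p, tips=list(phy.tips), height=phy.height
    )
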
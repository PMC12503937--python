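"""Shared fixtures: small reference trees and a reusable synthetic study."""

import numpy as np
import pytest

import wingleg as wl


@pytest.fixture(scope="session")
def two_tip():
    return wl.parse_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip():
    # C = [[2,1,0],[1,2,0],[0,0,2]]
    return wl.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def medium_dataset():
    """One mid-sized default-condition synthetic study with pipeline products.

    Session-scoped: several modules reuse the same realization for recovery
    and association checks.
    """
    cfg = wl.GeneratorConfig(n_tips=300, seed=11)
    ds = wl.make_dataset(cfg)
    A = wl.vcv(ds.phylogeny)
    resid = wl.fit_allometry(A, ds.traits)
    evo, axes, scores = wl.divergence_pipeline(A, resid)
    return {
        "dataset": ds,
        "A": A,
        "residuals": resid,
        "evo": evo,
        "axes": axes,
        "scores": scores,
    }


@pytest.fixture(scope="session")
def yule20():
    return wl.simulate_tree(20, seed=5, tree_height=50.0)


def brute_force_vcv(phy):
    """Independent oracle: per-pair MRCA depth by explicit path intersection."""
    n = phy.n_tips
    paths = []
    for t in phy.tip_ids:
        path = []
        node = int(t)
        while node != -1:
            path.append(node)
            node = int(phy.parent[node])
        paths.append(set(path))
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = paths[i] & paths[j]
            mrca = max(shared, key=lambda nid: phy.depth[nid])
            C[i, j] = phy.depth[mrca]
    return C
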
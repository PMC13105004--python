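"""Shared test utilities: independent oracles and small synthetic instances.

The enumeration likelihood here is deliberately naive (explicit sum over all
internal-node state assignments, transition probabilities from scipy's expm)
so it shares no code path with the pruning engine it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

import karyotempo as kt


def enumeration_loglik(tree, counts, Q, space, root_mode="uniform", root_state=None):
    """Brute-force likelihood: sum over every assignment of internal states."""
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    root = nodes[-1]
    count_of = dict(zip(counts["species"], counts["haploid_n"]))
    S = space.size
    P = {}
    for n in nodes:
        if n is not root:
            t = n.edge.length or 0.0
            if t not in P:
                P[t] = expm(Q * t)

    # conditional likelihood of the data given each root state, by enumeration
    L_root = np.zeros(S)
    others = [n for n in internal if n is not root]
    for root_idx in range(S):
        total = 0.0
        for assignment in itertools.product(range(S), repeat=len(others)):
            state = {id(n): s for n, s in zip(others, assignment)}
            state[id(root)] = root_idx
            prob = 1.0
            for n in nodes:
                if n is root:
                    continue
                t = n.edge.length or 0.0
                parent_s = state[id(n.parent_node)]
                if n.is_leaf():
                    child_s = space.index(int(count_of[n.taxon.label]))
                else:
                    child_s = state[id(n)]
                prob *= P[t][parent_s, child_s]
                if prob == 0.0:
                    break
            total += prob
        L_root[root_idx] = total

    if root_mode == "uniform":
        lik = L_root.mean()
    elif root_mode == "fitzjohn":
        lik = float(np.dot(L_root, L_root) / L_root.sum())
    else:
        lik = L_root[space.index(root_state)]
    return np.log(lik)


def random_instance(rng, max_tips=5, max_states=6):
    """A random small tree + counts + rates for oracle comparisons."""
    n_tips = int(rng.integers(3, max_tips + 1))
    tree = kt.simulate_yule_tree(n_tips, seed=int(rng.integers(2**31 - 1)))
    n_max = int(rng.integers(4, max_states + 1))
    space = kt.StateSpace(1, n_max)
    params = kt.RateParams(
        gain=float(rng.exponential(0.7)),
        loss=float(rng.exponential(0.7)),
        poly=float(rng.exponential(0.3)),
        demi=float(rng.exponential(0.3)),
    )
    import pandas as pd

    counts = pd.DataFrame(
        {
            "species": tree.tip_labels,
            "haploid_n": rng.integers(1, n_max + 1, size=n_tips),
        }
    )
    return tree, counts, space, params


def make_clade(n_tips, params, root_state, seed, n_max=None):
    """Simulate one clade (unit-depth tree + counts) under known rates."""
    tree = kt.simulate_yule_tree(n_tips, seed=seed)
    space = kt.StateSpace(1, n_max or 2 * root_state + 8)
    counts, _ = kt.simulate_counts(tree, space, params, root_state, seed + 1)
    return tree, counts, space
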
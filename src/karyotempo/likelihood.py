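"""Pruning (post-order) likelihood of karyotypes on a tree under the CTMC.

The likelihood of tip counts is computed by Felsenstein's pruning algorithm:
conditional likelihood vectors flow from tips to root, each internal node
taking the elementwise product over children of ``P(t_child) @ child_vector``.
Per-node rescaling to a maximum of 1 (with accumulated log scalers) prevents
underflow on large trees.

Root treatment is configurable: FitzJohn weighting (root-state prior
proportional to each state's conditional likelihood at the root), a uniform
prior over states, or a fixed root state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import RateParams, StateSpace, build_rate_matrix, transition_matrices
from .trees import TimeTree

__all__ = [
    "RootPolicy",
    "tip_partials",
    "log_likelihood",
    "LikelihoodEngine",
]


@dataclass(frozen=True)
class RootPolicy:
    """Root-state treatment: ``fitzjohn`` (default), ``uniform`` or ``fixed``."""

    mode: str = "fitzjohn"
    state: int | None = None  # haploid count, required for mode="fixed"

    def __post_init__(self) -> None:
        if self.mode not in {"fitzjohn", "uniform", "fixed"}:
            raise ValueError(f"unknown root policy {self.mode!r}")
        if self.mode == "fixed" and self.state is None:
            raise ValueError("fixed root policy requires a state")


def tip_partials(
    karyotypes: pd.DataFrame,
    space: StateSpace,
    tree: TimeTree,
) -> dict[str, np.ndarray]:
    """Per-tip conditional likelihood vectors over the state space.

    Observed tips get one-hot vectors; tips flagged ambiguous on the tree get
    all-ones vectors (no information). A count outside the state space is an
    error naming the species.
    """
    counts = dict(zip(karyotypes["species"], karyotypes["haploid_n"]))
    partials: dict[str, np.ndarray] = {}
    for label in tree.tip_labels:
        if label in tree.ambiguous_tips or label not in counts:
            if label not in tree.ambiguous_tips and label not in counts:
                raise KeyError(
                    f"tip {label!r} has no karyotype and is not flagged ambiguous; "
                    "run match_tree_data first"
                )
            partials[label] = np.ones(space.size)
        else:
            n = int(counts[label])
            if not (space.n_min <= n <= space.n_max):
                raise ValueError(
                    f"species {label!r} has count {n} outside state space "
                    f"[{space.n_min}, {space.n_max}]"
                )
            vec = np.zeros(space.size)
            vec[space.index(n)] = 1.0
            partials[label] = vec
    return partials


class LikelihoodEngine:
    """Caches the tree traversal so repeated likelihood calls are cheap.

    Branch lengths are deduplicated: one transition matrix is computed per
    distinct length per call, which is exactly equivalent to per-branch
    computation. The engine is the workhorse behind MCMC and ML fitting.
    """

    def __init__(
        self,
        tree: TimeTree,
        karyotypes: pd.DataFrame,
        space: StateSpace,
        root: RootPolicy = RootPolicy(),
    ) -> None:
        self.space = space
        self.root_policy = root
        partials = tip_partials(karyotypes, space, tree)

        nodes = list(tree.tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        lengths = []
        for n in nodes[:-1]:  # root last in postorder; its edge is ignored
            lengths.append(n.edge.length if n.edge.length is not None else 0.0)
        self._unique_ts, t_idx = np.unique(np.asarray(lengths), return_inverse=True)

        self._n_nodes = len(nodes)
        self._root_index = index[id(nodes[-1])]
        self._tip_rows: list[tuple[int, np.ndarray]] = []
        self._internal: list[tuple[int, list[tuple[int, int]]]] = []
        for i, node in enumerate(nodes):
            if node.is_leaf():
                self._tip_rows.append((i, partials[node.taxon.label]))
            else:
                children = [
                    (index[id(c)], int(t_idx[index[id(c)]])) for c in node.child_nodes()
                ]
                self._internal.append((i, children))

    def root_conditionals(self, Q: np.ndarray, *, rescale: bool = True) -> tuple[np.ndarray, float]:
        """Conditional likelihoods L_i at the root plus the accumulated log scaler."""
        S = self.space.size
        part = np.empty((self._n_nodes, S))
        for i, vec in self._tip_rows:
            part[i] = vec
        P = transition_matrices(Q, self._unique_ts)
        log_scale = 0.0
        for i, children in self._internal:
            ci0, ti0 = children[0]
            m = P[ti0] @ part[ci0]
            for ci, ti in children[1:]:
                m *= P[ti] @ part[ci]
            if rescale:
                mx = m.max()
                if mx <= 0.0:
                    return m, -np.inf
                m = m / mx
                log_scale += np.log(mx)
            part[i] = m
        return part[self._root_index], log_scale

    def log_likelihood(self, params_or_Q, *, rescale: bool = True) -> float:
        if isinstance(params_or_Q, RateParams):
            Q = build_rate_matrix(self.space, params_or_Q)
        else:
            Q = np.asarray(params_or_Q)
        L, log_scale = self.root_conditionals(Q, rescale=rescale)
        if not np.isfinite(log_scale):
            return -np.inf
        total = L.sum()
        if total <= 0.0:
            return -np.inf
        policy = self.root_policy
        if policy.mode == "fitzjohn":
            val = float(np.dot(L, L) / total)
        elif policy.mode == "uniform":
            val = float(L.mean())
        else:
            val = float(L[self.space.index(policy.state)])
        if val <= 0.0:
            return -np.inf
        return float(np.log(val) + log_scale)


def log_likelihood(
    tree: TimeTree,
    karyotypes: pd.DataFrame,
    params_or_Q,
    space: StateSpace,
    root: RootPolicy = RootPolicy(),
    *,
    rescale: bool = True,
) -> float:
    """Log-likelihood of a karyotype table on a tree (pure-function form).

    A convenience wrapper constructing a :class:`LikelihoodEngine` per call;
    use the engine directly inside optimisation/MCMC loops.
    """
    engine = LikelihoodEngine(tree, karyotypes, space, root)
    return engine.log_likelihood(params_or_Q, rescale=rescale)
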
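"""Synthetic data with known ground truth.

Everything the pipeline consumes can be generated here: ultrametric pure-birth
(Yule) trees, haploid counts evolved along them under the four-rate Markov
process (exact Gillespie event times, with a full event log), per-clade rate
tables with a controlled two-level group structure, and Brownian-motion tip
covariates for regression tests.

Randomness contract: every generator is bit-reproducible under a fixed seed.
Trait simulation derives one independent stream per branch from the seed and a
stable branch key (the smallest tip label below the branch), so pruning one
tip never shifts the randomness seen by other branches.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .model import RateParams, StateSpace, build_rate_matrix
from .trees import TimeTree

__all__ = [
    "SimScenario",
    "simulate_yule_tree",
    "simulate_counts",
    "evolve_branch",
    "make_clade_rate_table",
    "simulate_brownian",
]


@dataclass
class SimScenario:
    """A fully specified simulation condition (tree + process + seed)."""

    n_tips: int
    params: RateParams
    root_state: int
    seed: int
    birth_rate: float = 1.0
    depth_myr: float = 1.0
    space: StateSpace | None = None

    def __post_init__(self) -> None:
        if self.space is not None and not (
            self.space.n_min <= self.root_state <= self.space.n_max
        ):
            raise ValueError("root_state outside the scenario's state space")


def simulate_yule_tree(n_tips: int, seed: int, *, depth_myr: float = 1.0) -> TimeTree:
    """Pure-birth tree grown to ``n_tips``, rescaled to unit depth.

    The birth rate only sets the pre-rescaling time scale and therefore drops
    out; the returned tree has depth exactly 1 and carries ``depth_myr`` as the
    age it represents. Ultrametric by construction.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(seed)
    # birth times of the lineages currently alive
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    t = 0.0
    active: list[dendropy.Node] = []
    birth: dict[int, float] = {}
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
        birth[id(child)] = 0.0
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / k)
        node = active[rng.integers(len(active))]
        node.edge.length = t - birth[id(node)]
        active.remove(node)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
            birth[id(child)] = t
        k += 1
    t += rng.exponential(1.0 / k)  # hold time before the present
    for i, node in enumerate(active):
        node.edge.length = t - birth[id(node)]
    # deterministic tip labels in left-to-right (preorder) order
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_ns.new_taxon(label=f"t{i}")
    depth = t
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
    tree.seed_node.edge.length = None
    return TimeTree(tree=tree, depth_myr=depth_myr)


def evolve_branch(
    state_index: int,
    t: float,
    Q: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, list[tuple[float, int, int]]]:
    """Gillespie simulation of the chain along one branch of length ``t``.

    Waiting times are exponential with the current state's total leaving rate;
    the event target is chosen proportional to the off-diagonal rates. Returns
    the end state index and the list of events ``(time, from_idx, to_idx)``.
    """
    s = int(state_index)
    clock = 0.0
    events: list[tuple[float, int, int]] = []
    while True:
        total = -Q[s, s]
        if total <= 0.0:
            return s, events
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            return s, events
        row = Q[s].copy()
        row[s] = 0.0
        target = int(rng.choice(row.size, p=row / total))
        events.append((clock, s, target))
        s = target


def _branch_keys(tree: TimeTree) -> dict[int, str]:
    """Stable per-branch keys: smallest tip label below plus subtree tip count.

    Within one tree the pair is unique per branch (two subtrees sharing a tip
    are nested, hence differ in size), so every branch gets an independent
    stream; pruning a tip only re-keys that tip's ancestors.
    """
    mins: dict[int, str] = {}
    sizes: dict[int, int] = {}
    keys: dict[int, str] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            mins[id(node)], sizes[id(node)] = node.taxon.label, 1
        else:
            mins[id(node)] = min(mins[id(c)] for c in node.child_nodes())
            sizes[id(node)] = sum(sizes[id(c)] for c in node.child_nodes())
        keys[id(node)] = f"{mins[id(node)]}#{sizes[id(node)]}"
    return keys


def _branch_rng(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(zlib.crc32(key.encode()),))
    )


def simulate_counts(
    tree: TimeTree,
    space: StateSpace,
    params: RateParams,
    root_state: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve haploid counts along the tree; returns (karyotypes, event log).

    Boundary behaviour mirrors :func:`build_rate_matrix` exactly (the same Q
    drives the embedded jump chain), so simulator and likelihood are coherent
    by construction. The event log has one row per event with the branch key,
    time from the branch's start, source and target counts, and event type.
    """
    if not (space.n_min <= root_state <= space.n_max):
        raise ValueError(f"root_state {root_state} outside state space")
    Q = build_rate_matrix(space, params)
    keys = _branch_keys(tree)
    states: dict[int, int] = {id(tree.tree.seed_node): space.index(root_state)}
    records: list[dict] = []
    log_rows: list[dict] = []
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length if node.edge.length is not None else 0.0
        rng = _branch_rng(seed, keys[id(node)])
        end, events = evolve_branch(parent_state, t, Q, rng)
        states[id(node)] = end
        for clock, s_from, s_to in events:
            log_rows.append(
                {
                    "branch": keys[id(node)],
                    "time": clock,
                    "from": space.count(s_from),
                    "to": space.count(s_to),
                    "type": _classify_event(space.count(s_from), space.count(s_to), space),
                }
            )
        if node.is_leaf():
            records.append({"species": node.taxon.label, "haploid_n": space.count(end)})
    karyotypes = pd.DataFrame.from_records(records, columns=["species", "haploid_n"])
    event_log = pd.DataFrame.from_records(
        log_rows, columns=["branch", "time", "from", "to", "type"]
    )
    return karyotypes, event_log


def _classify_event(n_from: int, n_to: int, space: StateSpace) -> str:
    if n_to == n_from + 1 and n_from + 1 != min(2 * n_from, space.n_max):
        return "gain"
    if n_to == n_from - 1:
        return "loss"
    if n_to == min(2 * n_from, space.n_max):
        return "poly"
    return "demi" if n_to > n_from else "other"


def make_clade_rate_table(
    n_groups: int,
    n_per_group: int | list[int],
    grand_mean_log10: float = -1.64,
    sd_between: float = 0.0,
    sd_within: float = 0.5,
    seed: int = 0,
    kingdoms: tuple[str, ...] = ("Animalia", "Plantae", "Fungi"),
) -> tuple[pd.DataFrame, float]:
    """Per-clade dysploidy-rate table with a known two-level group structure.

    Group means are drawn on the log10 scale around ``grand_mean_log10``
    (default ``-1.64``, i.e. about 0.023 events/Myr, a realistic cross-kingdom
    geometric-mean rate) with spread ``sd_between``; clade rates are log-normal
    around their group mean with spread ``sd_within``. Returns the table and
    the true intraclass correlation ``sd_between² / (sd_between² + sd_within²)``.

    Groups fill the ``higher_taxon`` column; ``kingdom`` labels are assigned
    round-robin over groups (carrying no additional effect). Pass a list of
    group sizes for unbalanced designs.
    """
    if n_groups < 2:
        raise ValueError("need n_groups >= 2")
    sizes = [n_per_group] * n_groups if isinstance(n_per_group, int) else list(n_per_group)
    if len(sizes) != n_groups:
        raise ValueError("len(n_per_group) must equal n_groups")
    rng = np.random.default_rng(seed)
    rows = []
    for g, size in enumerate(sizes):
        mean_g = grand_mean_log10 + rng.normal(0.0, sd_between) if sd_between > 0 else grand_mean_log10
        for j in range(size):
            log_rate = rng.normal(mean_g, sd_within)
            rows.append(
                {
                    "clade": f"clade_{g + 1}_{j + 1}",
                    "rate_myr": 10.0 ** log_rate,
                    "kingdom": kingdoms[g % len(kingdoms)],
                    "higher_taxon": f"taxon_{g + 1}",
                }
            )
    table = pd.DataFrame(rows)
    true_icc = (
        sd_between**2 / (sd_between**2 + sd_within**2) if (sd_between or sd_within) else 0.0
    )
    return table, true_icc


def simulate_brownian(tree: TimeTree, sigma: float, seed: int) -> pd.Series:
    """Brownian motion along the tree: root value 0, each branch adding
    ``N(0, sigma² · branch_length)``. Returns tip values indexed by label."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        t = node.edge.length if node.edge.length is not None else 0.0
        step = rng.normal(0.0, sigma * np.sqrt(t)) if sigma > 0 and t > 0 else 0.0
        values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="trait")
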
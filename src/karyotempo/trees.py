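"""Reading, validating, rescaling and co-pruning time trees and karyotype tables.

Trees are rooted, ultrametric chronograms with branch lengths in Myr (or, after
:func:`scale_to_unit_depth`, in units of tree depth). Karyotype tables map species
to haploid chromosome counts. Every downstream analysis assumes a matched pair:
the tree's tip set equals the table's species set (tips without a count may
instead be flagged as fully ambiguous).
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeTree",
    "UltrametryReport",
    "TreeFormatError",
    "TreeValidationError",
    "read_tree",
    "write_tree",
    "read_karyotypes",
    "write_karyotypes",
    "validate_karyotypes",
    "validate_ultrametric",
    "scale_to_unit_depth",
    "match_tree_data",
]


class TreeFormatError(ValueError):
    """The input could not be parsed as newick."""


class TreeValidationError(ValueError):
    """The tree parsed but violates a structural requirement."""


@dataclass
class TimeTree:
    """A rooted (possibly multifurcating) ultrametric tree.

    Parameters
    ----------
    tree:
        The underlying :class:`dendropy.Tree`. Branch lengths are interpreted in
        the units implied by ``depth_myr``: a tree of depth ``d`` whose
        ``depth_myr`` equals ``d`` is in Myr; a unit-depth tree carries the
        original age in ``depth_myr`` for rate back-conversion.
    depth_myr:
        Root-to-tip distance in Myr that this tree represents.
    ambiguous_tips:
        Tip labels retained without an observed count (treated as fully
        ambiguous states by the likelihood).
    """

    tree: dendropy.Tree
    depth_myr: float = 0.0
    ambiguous_tips: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.depth_myr == 0.0:
            self.depth_myr = self.depth

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length, in the tree's current units."""
        return max(self._tip_depths().values())

    def _tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            el = node.edge.length
            parent_depth = getattr(node.parent_node, "_kt_depth", 0.0) if node.parent_node else 0.0
            node._kt_depth = parent_depth + (el if el is not None else 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._kt_depth
        return depths

    def clone(self) -> "TimeTree":
        return TimeTree(
            tree=self.tree.clone(depth=1),
            depth_myr=self.depth_myr,
            ambiguous_tips=self.ambiguous_tips,
        )

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class UltrametryReport:
    ok: bool
    max_rel_deviation: float
    worst_tip: str
    depth: float

    def __bool__(self) -> bool:  # usable as a plain predicate
        return self.ok


def _validate_branch_lengths(tree: dendropy.Tree) -> None:
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        el = node.edge.length
        if node is root:
            if el is None:
                node.edge.length = 0.0
            continue
        if el is None:
            raise TreeValidationError(
                f"missing branch length on edge above {_edge_name(node)}"
            )
        if el < 0:
            raise TreeValidationError(
                f"negative branch length {el} on edge above {_edge_name(node)}"
            )


def _edge_name(node: dendropy.Node) -> str:
    if node.is_leaf():
        return f"tip '{node.taxon.label}'"
    tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return f"internal node subtending {{{', '.join(tips[:4])}{'...' if len(tips) > 4 else ''}}}"


def read_tree(path_or_string: str, *, depth_myr: float | None = None) -> TimeTree:
    """Read a newick tree from a file path or a literal newick string.

    Polytomies are preserved. A missing length on the root edge is treated as
    zero; a missing or negative length anywhere else is an error naming the
    edge. ``depth_myr`` overrides the depth implied by the branch lengths
    (useful when a tree was distributed pre-scaled to unit depth).
    """
    src = str(path_or_string)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except Exception as exc:  # dendropy raises various error classes
        raise TreeFormatError(f"could not parse newick input: {exc}") from exc
    _validate_branch_lengths(tree)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise TreeValidationError("tree must have at least 2 tips")
    if len(set(labels)) != len(labels):
        raise TreeValidationError("tip labels are not unique")
    tt = TimeTree(tree=tree)
    if depth_myr is not None:
        tt.depth_myr = float(depth_myr)
    return tt


def write_tree(tree: TimeTree, path: str | None = None) -> str:
    """Serialize as newick; returns the string and optionally writes it."""
    s = tree.as_newick()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(s + "\n")
    return s


def validate_ultrametric(tree: TimeTree, rel_tol: float = 1e-3) -> UltrametryReport:
    """Check that every root-to-tip path equals the depth within ``rel_tol``.

    The reference depth is the median root-to-tip distance (robust to a few
    deviant tips); the reported deviation is ``max |path_i - depth| / depth``
    and the report names the worst tip. Pure predicate: never raises on a
    valid tree object.
    """
    depths = tree._tip_depths()
    depth = float(np.median(list(depths.values())))
    if depth == 0:
        return UltrametryReport(ok=False, max_rel_deviation=math.inf, worst_tip=next(iter(depths)), depth=0.0)
    worst_tip, worst_dev = "", -1.0
    for label, d in depths.items():
        dev = abs(d - depth) / depth
        if dev > worst_dev:
            worst_tip, worst_dev = label, dev
    return UltrametryReport(ok=worst_dev <= rel_tol, max_rel_deviation=worst_dev, worst_tip=worst_tip, depth=depth)


def scale_to_unit_depth(tree: TimeTree) -> tuple[TimeTree, float]:
    """Rescale all branch lengths so the root-to-tip depth is exactly 1.

    Returns the rescaled tree and the original depth (``depth_myr``), which
    converts unit-tree rates to events/Myr (``rate_myr = rate_unit / depth_myr``).
    Idempotent: rescaling an already unit-depth tree returns it unchanged.
    """
    depth = tree.depth
    if depth <= 0:
        raise TreeValidationError("tree has zero depth; cannot rescale")
    out = tree.clone()
    if depth != 1.0:
        for node in out.tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length = node.edge.length / depth
    # depth_myr keeps recording the age the (now unit-depth) tree stands for
    out.depth_myr = tree.depth_myr
    return out, out.depth_myr


# ---------------------------------------------------------------------------
# Karyotype tables
# ---------------------------------------------------------------------------

def validate_karyotypes(table: pd.DataFrame, *, strict: bool = True) -> pd.DataFrame:
    """Validate a karyotype table (columns ``species``, ``haploid_n``).

    Counts must be positive integers; non-integer counts are rejected (strict,
    default) or dropped with a warning (``strict=False``). Silent rounding
    would fabricate chromosome states, so it is never performed.
    """
    if not {"species", "haploid_n"}.issubset(table.columns):
        raise ValueError("karyotype table needs columns 'species' and 'haploid_n'")
    table = table[["species", "haploid_n"]].copy()
    table["species"] = table["species"].astype(str)
    if table["species"].duplicated().any():
        dups = table.loc[table["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in karyotype table: {dups[:5]}")
    numeric = pd.to_numeric(table["haploid_n"], errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 1)
    if bad.any():
        offenders = table.loc[bad, "species"].tolist()
        if strict:
            raise ValueError(
                f"non-integer or non-positive haploid counts for: {offenders[:5]} "
                "(counts must be integers >= 1; pass strict=False to drop them)"
            )
        warnings.warn(f"dropping {int(bad.sum())} rows with invalid counts: {offenders[:5]}")
        table = table.loc[~bad]
        numeric = numeric.loc[~bad]
    table["haploid_n"] = numeric.astype(int)
    return table.reset_index(drop=True)


def read_karyotypes(path_or_buffer, *, strict: bool = True) -> pd.DataFrame:
    """Read a ``species,haploid_n`` CSV into a validated karyotype table."""
    if isinstance(path_or_buffer, str) and "\n" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    table = pd.read_csv(path_or_buffer)
    return validate_karyotypes(table, strict=strict)


def write_karyotypes(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matching trees to data
# ---------------------------------------------------------------------------

def match_tree_data(
    tree: TimeTree,
    karyotypes: pd.DataFrame,
    missing_policy: str = "drop",
) -> tuple[TimeTree, pd.DataFrame]:
    """Co-prune a tree and a karyotype table to a shared species set.

    ``missing_policy='drop'`` prunes tips without counts (merging the branch
    lengths of collapsed unifurcations so root-to-tip distances are exactly
    preserved). ``missing_policy='ambiguous'`` keeps those tips and flags them
    as fully ambiguous. Table rows without a tip are always dropped, with a
    logged warning counting them.
    """
    if missing_policy not in {"drop", "ambiguous"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    tips = set(tree.tip_labels)
    species = set(karyotypes["species"])
    shared = tips & species
    if len(shared) < 2:
        raise TreeValidationError(
            f"only {len(shared)} species shared between tree and table; need >= 2"
        )
    extra_rows = species - tips
    if extra_rows:
        logger.warning(
            "dropping %d karyotype rows with no matching tip", len(extra_rows)
        )
    table = karyotypes[karyotypes["species"].isin(tips)].reset_index(drop=True)

    if missing_policy == "drop":
        keep = shared
        ambiguous: frozenset[str] = frozenset()
    else:
        keep = tips
        ambiguous = frozenset(tips - species)

    if keep == tips:
        out = TimeTree(tree=tree.tree, depth_myr=tree.depth_myr, ambiguous_tips=ambiguous)
        return out, table

    pruned = tree.tree.clone(depth=1)
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    # dendropy merges the lengths of suppressed unifurcations, preserving depths
    pruned.retain_taxa(taxa)
    pruned.purge_taxon_namespace()
    out = TimeTree(tree=pruned, depth_myr=tree.depth_myr, ambiguous_tips=ambiguous)
    return out, table
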
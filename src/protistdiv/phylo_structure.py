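"""Tree-based structure statistics for groups on a rooted phylogeny.

Given a rooted tree with branch lengths and a tip-to-group map, this module
computes:

* an ultrametric transform (mean-path-length smoothing) so that node depths
  can be read as relative times;
* standardized lineage-through-time (LTT) curves — lineage counts as a
  percentage of the present-day count, against relative time from -1 (the
  crown of the group) to 0 (the present);
* the Pybus-Harvey gamma statistic, which is ~N(0,1) under constant-rate
  pure birth: significantly negative gamma indicates cladogenesis
  concentrated early in the group's history, positive gamma late;
* mean phylogenetic distance (MPD): the mean patristic distance over tip
  pairs within a group;
* the "trunk": the stem branch subtending a monophyletic group's most
  recent common ancestor — long trunks mark isolated lineages;
* mean patristic distances between groups, with each group's minimum
  distance to any other group.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm

from protistdiv.errors import (
    DegenerateFitError,
    InputError,
    MonophylyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StructuredTree",
    "LTTCurve",
    "GammaResult",
    "GroupStructure",
    "read_newick",
    "read_group_map",
    "make_ultrametric",
    "branching_times",
    "ltt_curve",
    "gamma_statistic",
    "mpd",
    "trunk_length",
    "intergroup_distances",
    "extract_group_tree",
    "patristic_matrix",
]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class StructuredTree:
    """A rooted tree with branch lengths and an optional tip->group map."""

    tree: dendropy.Tree
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tips = self.tip_names()
        if len(tips) < 2:
            raise InputError(f"tree must have >= 2 tips, got {len(tips)}")
        if len(set(tips)) != len(tips):
            raise InputError("duplicate tip names in tree")
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            if node.edge.length is None:
                raise InputError("tree has branches without lengths")
            if node.edge.length < 0:
                raise InputError(f"negative branch length {node.edge.length}")
        missing = set(self.group_of) - set(tips)
        if missing:
            raise InputError(
                f"group map names tips absent from the tree: {sorted(missing)}"
            )

    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def groups(self) -> list[str]:
        return sorted(set(self.group_of.values()))

    def tips_of(self, group: str) -> list[str]:
        return [t for t, g in self.group_of.items() if g == group]

    def clone(self) -> "StructuredTree":
        return StructuredTree(
            tree=self.tree.clone(depth=1), group_of=dict(self.group_of)
        )

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def write_group_map(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tip_name\tgroup_id\n")
            for tip, gid in sorted(self.group_of.items()):
                fh.write(f"{tip}\t{gid}\n")


def _parse_tree(src: str, is_path: bool) -> dendropy.Tree:
    kwargs = {"path": src} if is_path else {"data": src}
    tree = dendropy.Tree.get(
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
        **kwargs,
    )
    tree.is_rooted = True
    return tree


def read_newick(
    path: str | Path,
    group_map: str | Path | dict[str, str] | None = None,
) -> StructuredTree:
    """Read a rooted newick tree (branch lengths required).

    ``group_map`` is either a TSV path (columns tip_name, group_id) or a
    dict. The file's root is taken as the root, whatever its degree.
    """
    tree = _parse_tree(str(path), is_path=True)
    mapping: dict[str, str] = {}
    if isinstance(group_map, dict):
        mapping = dict(group_map)
    elif group_map is not None:
        mapping = read_group_map(group_map)
    return StructuredTree(tree=tree, group_of=mapping)


def tree_from_string(
    newick: str, group_of: dict[str, str] | None = None
) -> StructuredTree:
    """Build a :class:`StructuredTree` from a newick string (mainly tests)."""
    return StructuredTree(
        tree=_parse_tree(newick, is_path=False), group_of=dict(group_of or {})
    )


def read_group_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "tip_name":
                continue
            if len(parts) != 2:
                raise InputError(f"{path}:{line_no}: expected 2 tab-separated fields")
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# ultrametric transform and branching times


def _mean_tip_path(node: dendropy.Node) -> tuple[float, int]:
    """(sum of node->tip path lengths, tip count) over the node's subtree."""
    if node.is_leaf():
        return 0.0, 1
    total, count = 0.0, 0
    for child in node.child_nodes():
        s, c = _mean_tip_path(child)
        total += s + (child.edge.length or 0.0) * c
        count += c
    return total, count


def make_ultrametric(t: StructuredTree) -> StructuredTree:
    """Equalize root-to-tip path lengths by mean-path-length smoothing.

    Each internal node's height (time before present) is set to the mean of
    its subtree's node-to-tip path lengths, then heights are re-monotonized
    root-ward (a child's height is capped at its parent's, clamping would-be
    negative branch lengths to 0). Topology is unchanged. The transform is a
    fixed point on trees that are already ultrametric.
    """
    out = t.clone()
    tree = out.tree
    height: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            height[node] = 0.0
            continue
        s, c = _mean_tip_path(node)
        h = s / c
        parent = node.parent_node
        if parent is not None and h > height[parent]:
            h = height[parent]
        height[node] = h
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        node.edge.length = max(height[parent] - height[node], 0.0)
    return out


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
        depth[node] = d
    return depth


def branching_times(
    t: StructuredTree, rtol: float = ULTRAMETRIC_RTOL
) -> list[float]:
    """Internal-node times before present, sorted decreasing.

    Requires an ultrametric tree (tip depths equal within relative
    tolerance ``rtol``). A node with c > 2 children contributes c - 1
    coincident times (zero-length resolution of the polytomy); degree-2
    nodes are suppressed. Zero-length internal branches yield duplicated
    times.
    """
    depth = _node_depths(t.tree)
    tip_depths = [depth[leaf] for leaf in t.tree.leaf_node_iter()]
    h = max(tip_depths)
    if h <= 0:
        raise DegenerateFitError("tree has zero depth")
    if (h - min(tip_depths)) / h > rtol:
        raise InputError(
            f"tree is not ultrametric: tip depths span "
            f"[{min(tip_depths):.6g}, {h:.6g}]"
        )
    times: list[float] = []
    for node in t.tree.preorder_internal_node_iter():
        n_children = len(node.child_nodes())
        if n_children < 2:
            continue  # unifurcation: no branching event
        if n_children > 2:
            logger.info(
                "polytomy with %d children resolved as %d coincident events",
                n_children, n_children - 1,
            )
        times.extend([max(h - depth[node], 0.0)] * (n_children - 1))
    return sorted(times, reverse=True)


# ---------------------------------------------------------------------------
# LTT and gamma


@dataclass
class LTTCurve:
    """Standardized lineage-through-time curve.

    ``points`` are (relative_time, lineage_percent) with relative time in
    [-1, 0]: -1 is the crown (first branching) of the group and 0 the
    present; lineage counts are percentages of the present-day count.
    """

    points: list[tuple[float, float]]
    n_tips: int


def ltt_curve(t: StructuredTree) -> LTTCurve:
    """LTT curve of an ultrametric tree on relative time.

    The curve starts with 2 lineages at relative time -1 (the crown node),
    steps up at each branching time scaled by the crown age, and ends at
    100% of lineages at time 0.
    """
    n = t.n_tips
    times = branching_times(t)
    t_max = times[0] if times else 0.0
    if t_max <= 0:
        # 2-tip trees and stars branch only at the crown: flat at 100%
        return LTTCurve(points=[(-1.0, 100.0), (0.0, 100.0)], n_tips=n)
    pct = lambda k: 100.0 * k / n
    points: list[tuple[float, float]] = []
    count = 1
    for time in times:  # decreasing
        count += 1
        rel = -time / t_max
        if points and points[-1][0] == rel:
            points[-1] = (rel, pct(count))
        else:
            points.append((rel, pct(count)))
    if points[-1][0] != 0.0:
        points.append((0.0, pct(count)))
    return LTTCurve(points=points, n_tips=n)


def write_ltt_tsv(curve: LTTCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("relative_time\tlineage_percent\n")
        for rel, pct in curve.points:
            fh.write(f"{rel:.4f}\t{pct:.4f}\n")


@dataclass
class GammaResult:
    """Pybus-Harvey gamma with its one-tailed constant-rate test.

    ``intervals`` holds the internode intervals g_2..g_n (g_k = duration
    with k lineages); ``T`` is the total lineage-weighted time
    sum_{j=2..n} j * g_j.
    """

    gamma: float
    n_tips: int
    p_one_tailed: float
    intervals: list[float]
    T: float

    def classification(self, alpha: float = 0.05) -> str:
        """'negative' / 'zero' / 'positive' by the one-tailed test at alpha."""
        if self.p_one_tailed <= alpha:
            return "negative" if self.gamma < 0 else "positive"
        return "zero"


def gamma_from_branching_times(times: Iterable[float]) -> tuple[float, list[float], float]:
    """Gamma from internal-node times before present (any order).

    Returns (gamma, intervals g_2..g_n, T). With g_j the duration during
    which exactly j lineages exist and T_i = sum_{k=2..i} k*g_k:

        gamma = [ mean_{i=2..n-1} T_i - T_n/2 ] / ( T_n * sqrt(1/(12(n-2))) )
    """
    ts = sorted(times, reverse=True)
    n = len(ts) + 1  # tips
    if n < 3:
        raise InputError(f"gamma needs >= 3 tips, got {n}")
    bounds = ts + [0.0]
    g = [bounds[k - 2] - bounds[k - 1] for k in range(2, n + 1)]
    cum = list(itertools.accumulate(k * gk for k, gk in zip(range(2, n + 1), g)))
    T = cum[-1]
    if T <= 0:
        raise DegenerateFitError("total weighted tree length T is zero")
    mean_inner = sum(cum[:-1]) / (n - 2)
    gamma = (mean_inner - T / 2.0) / (T * math.sqrt(1.0 / (12.0 * (n - 2))))
    return gamma, g, T


def gamma_statistic(t: StructuredTree) -> GammaResult:
    """Gamma statistic of an ultrametric tree with a one-tailed p-value.

    The null hypothesis is constant-rate cladogenesis (gamma ~ N(0,1) under
    pure birth); the one-tailed p is the standard-normal tail probability in
    the direction of the observed sign.
    """
    if t.n_tips < 3:
        raise InputError(f"gamma needs >= 3 tips, got {t.n_tips}")
    times = branching_times(t)
    gamma, g, T = gamma_from_branching_times(times)
    p = float(norm.cdf(gamma) if gamma < 0 else norm.sf(gamma))
    return GammaResult(
        gamma=gamma, n_tips=t.n_tips, p_one_tailed=p, intervals=g, T=T
    )


# ---------------------------------------------------------------------------
# patristic distances, MPD, trunk, intergroup


def patristic_matrix(t: StructuredTree) -> pd.DataFrame:
    """All-pairs patristic (branch-length path) distances between tips."""
    depth = _node_depths(t.tree)
    ancestors: dict[str, list[dendropy.Node]] = {}
    for leaf in t.tree.leaf_node_iter():
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        ancestors[leaf.taxon.label] = chain
    names = sorted(ancestors)
    mat = np.zeros((len(names), len(names)))
    leaf_node = {
        leaf.taxon.label: leaf for leaf in t.tree.leaf_node_iter()
    }
    for i, a in enumerate(names):
        set_a = set(id(n) for n in ancestors[a])
        for j in range(i + 1, len(names)):
            b = names[j]
            lca = next(n for n in ancestors[b] if id(n) in set_a)
            d = depth[leaf_node[a]] + depth[leaf_node[b]] - 2.0 * depth[lca]
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def mpd(t: StructuredTree, group: str) -> float:
    """Mean patristic distance over all unordered tip pairs within a group."""
    tips = t.tips_of(group)
    if len(tips) < 2:
        raise InputError(f"group {group!r} has {len(tips)} tips; need >= 2")
    pm = patristic_matrix(t).loc[tips, tips].to_numpy()
    iu = np.triu_indices(len(tips), k=1)
    return float(pm[iu].mean())


def _mrca(t: StructuredTree, tips: list[str]) -> dendropy.Node:
    node = t.tree.mrca(taxon_labels=tips)
    if node is None:
        raise InputError(f"no MRCA found for tips {tips}")
    return node


def trunk_length(t: StructuredTree, group: str) -> float:
    """Length of the stem branch subtending the group's MRCA.

    The group's tips must form a monophyletic clade; a single-tip group
    degenerates to its terminal branch (logged). A group spanning the whole
    tree has no stem and raises an error.
    """
    tips = t.tips_of(group)
    if not tips:
        raise InputError(f"group {group!r} has no tips")
    if len(tips) == 1:
        logger.info("group %s is a single tip; trunk = terminal branch", group)
        leaf = next(
            l for l in t.tree.leaf_node_iter() if l.taxon.label == tips[0]
        )
        return float(leaf.edge.length)
    mrca = _mrca(t, tips)
    clade_tips = {l.taxon.label for l in mrca.leaf_iter()}
    if clade_tips != set(tips):
        raise MonophylyError(
            f"group {group!r} is not monophyletic: its MRCA also contains "
            f"{sorted(clade_tips - set(tips))[:5]}"
        )
    if mrca.parent_node is None:
        raise InputError(f"group {group!r} spans the whole tree: no stem branch")
    return float(mrca.edge.length)


def intergroup_distances(t: StructuredTree) -> pd.DataFrame:
    """Mean patristic distance between every pair of groups.

    Entry (G, H) is the mean over all tip pairs with one tip in G and one in
    H; the diagonal is 0 by convention. Use :func:`min_intergroup` for each
    group's distance to its closest neighbor.
    """
    groups = t.groups()
    if len(groups) < 2:
        raise InputError(f"need >= 2 groups, got {len(groups)}")
    pm = patristic_matrix(t)
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for g, h in itertools.combinations(groups, 2):
        block = pm.loc[t.tips_of(g), t.tips_of(h)].to_numpy()
        out.loc[g, h] = out.loc[h, g] = float(block.mean())
    return out


def min_intergroup(inter: pd.DataFrame) -> pd.Series:
    """Each group's smallest mean distance to another group."""
    masked = inter.where(~np.eye(len(inter), dtype=bool))
    return masked.min(axis=1)


@dataclass
class GroupStructure:
    """Per-group structure summary: diversity, isolation, closest neighbor."""

    group_id: str
    mpd: float
    trunk: float
    min_intergroup: float


def extract_group_tree(t: StructuredTree, group: str) -> StructuredTree:
    """The crown subtree of a group: the clade rooted at the group's MRCA.

    Requires monophyly (checked). The stem branch is not part of the
    extracted tree.
    """
    tips = t.tips_of(group)
    if len(tips) < 2:
        raise InputError(f"group {group!r} has {len(tips)} tips; need >= 2")
    clone = t.tree.clone(depth=1)
    mrca = clone.mrca(taxon_labels=tips)
    clade_tips = {l.taxon.label for l in mrca.leaf_iter()}
    if clade_tips != set(tips):
        raise MonophylyError(f"group {group!r} is not monophyletic")
    newick = mrca._as_newick_string() + ";"
    sub = _parse_tree(newick, is_path=False)
    return StructuredTree(
        tree=sub, group_of={tip: group for tip in tips}
    )
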
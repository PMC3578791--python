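"""Synthetic trees and alignments with the structure the analyses assume.

The generator emulates the shape of an 18S rDNA survey dataset: per-group
alignments of a few-hundred-column hypervariable region embedded in a
~1800-column full gene with region-specific rate multipliers, and
multi-group rooted trees in which monophyletic groups hang off a backbone by
stem ("trunk") branches.

Three primitives compose everything:

* a Yule (pure-birth) tree simulator — internode intervals with k lineages
  are Exp(k * birth_rate), the exact null of the gamma statistic;
* a time warp that remaps node ages a -> a^beta (ages scaled to [0, 1]):
  beta < 1 pushes branchings toward the root (gamma < 0 in expectation),
  beta > 1 toward the present (gamma > 0), beta = 1 is the identity — one
  parameter controls the tempo of cladogenesis;
* a Jukes-Cantor sequence simulator along a tree, with per-region rate
  multipliers so partial regions can evolve faster or slower than the rest
  of the gene.

Every stochastic operation is a pure function of its explicit seed (or a
caller-provided numpy Generator).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from protistdiv.errors import InputError
from protistdiv.phylo_structure import StructuredTree, _node_depths
from protistdiv.seq_regions import GroupAlignment, write_alignment

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "simulate_yule_tree",
    "warp_tree_times",
    "evolve_sequences",
    "build_supergroup_fixture",
    "write_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GroupSpec:
    """Layout of one group in a supergroup fixture.

    ``depth`` is the crown age of the group's subtree in time units;
    ``warp_beta`` its cladogenesis-tempo exponent (see
    :func:`warp_tree_times`).
    """

    group_id: str
    n_tips: int
    trunk_length: float
    depth: float = 1.0
    warp_beta: float = 1.0


@dataclass
class SimulationConfig:
    """Parameters of a simulation run; serializable next to every fixture.

    Defaults mirror the shape of a single survey group: a 550-column
    variable region inside an 1800-column gene, with the region evolving
    1.4x faster than the rest.
    """

    seed: int = 0
    n_tips: int = 30
    birth_rate: float = 1.0
    warp_beta: float = 1.0
    seq_length: int = 1800
    base_rate: float = 0.05  # substitutions/site per unit time
    region_spans: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"V4V5": (600, 1149), "V9": (1640, 1799)}
    )
    region_rate_multipliers: dict[str, float] = field(
        default_factory=lambda: {"V4V5": 1.4, "V9": 1.4}
    )
    group_layout: list[GroupSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.birth_rate < 0 or self.base_rate < 0:
            raise InputError("rates must be >= 0")
        if self.warp_beta <= 0:
            raise InputError("warp_beta must be > 0")
        covered: list[tuple[int, int]] = []
        for name, (start, end) in self.region_spans.items():
            if not (1 <= start <= end <= self.seq_length):
                raise InputError(
                    f"region {name!r} span [{start}, {end}] outside "
                    f"[1, {self.seq_length}]"
                )
            for s, e in covered:
                if start <= e and s <= end:
                    raise InputError("region spans must be disjoint")
            covered.append((start, end))
        for name in self.region_rate_multipliers:
            if name not in self.region_spans:
                raise InputError(f"multiplier for unknown region {name!r}")

    def site_rates(self) -> np.ndarray:
        """Per-site rate (substitutions/site/time) over the full gene."""
        rates = np.full(self.seq_length, self.base_rate)
        for name, (start, end) in self.region_spans.items():
            mult = self.region_rate_multipliers.get(name, 1.0)
            rates[start - 1 : end] = self.base_rate * mult
        return rates

    def to_json(self) -> str:
        d = asdict(self)
        d["group_layout"] = [asdict(g) for g in self.group_layout]
        return json.dumps(d, indent=2)


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    prefix: str = "t",
) -> StructuredTree:
    """Ultrametric binary tree under a constant-rate pure-birth process.

    Starting from the crown (2 lineages), the waiting time while k lineages
    exist is exponential with rate k * birth_rate, and a uniformly chosen
    lineage splits at each event. Tip labels are ``{prefix}1..{prefix}n``.
    """
    if n_tips < 2:
        raise InputError(f"need n_tips >= 2, got {n_tips}")
    if birth_rate <= 0:
        raise InputError(f"birth_rate must be > 0, got {birth_rate}")
    rng = _rng(seed)
    # event times measured forward from the crown at 0
    waits = [
        rng.exponential(1.0 / (k * birth_rate)) for k in range(2, n_tips + 1)
    ]
    event_times = np.cumsum(waits)  # k-th entry: moment lineage count k+2 arises
    total = float(event_times[-1])  # present

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    root.birth_time = 0.0
    left, right = dendropy.Node(), dendropy.Node()
    for child in (left, right):
        child.birth_time = 0.0
        root.add_child(child)
    open_lineages = [left, right]
    for t_event in event_times[:-1]:
        idx = int(rng.integers(len(open_lineages)))
        node = open_lineages.pop(idx)
        node.split_time = float(t_event)
        a, b = dendropy.Node(), dendropy.Node()
        for child in (a, b):
            child.birth_time = float(t_event)
            node.add_child(child)
        open_lineages.extend([a, b])
    for leaf in open_lineages:
        leaf.split_time = total
    # assign labels in a stable left-to-right order
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"{prefix}{i}")
    # each branch spans the node's birth to its own split (or the present)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        node.edge.length = node.split_time - node.birth_time
    return StructuredTree(tree=tree)


def warp_tree_times(t: StructuredTree, beta: float) -> StructuredTree:
    """Remap node ages a (scaled to [0, 1] from the present) to a**beta.

    Requires an ultrametric input; preserves topology, tip set and total
    depth, and keeps the tree ultrametric. beta > 1 compresses old ages
    toward the present (late cladogenesis, gamma > 0 in expectation);
    beta < 1 stretches them toward the root (early cladogenesis, gamma < 0).
    """
    if beta <= 0:
        raise InputError(f"beta must be > 0, got {beta}")
    out = t.clone()
    tree = out.tree
    depth = _node_depths(tree)
    h = max(depth[leaf] for leaf in tree.leaf_node_iter())
    if h <= 0:
        raise InputError("tree has zero depth")
    new_age: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        age = (h - depth[node]) / h  # 1 at root, 0 at tips
        new_age[node] = h * (max(age, 0.0) ** beta) if not node.is_leaf() else 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        node.edge.length = max(new_age[node.parent_node] - new_age[node], 0.0)
    return out


def evolve_sequences(
    t: StructuredTree,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    group_id: str = "simulated",
) -> GroupAlignment:
    """Simulate Jukes-Cantor sequences down a tree with branch lengths in time.

    The root sequence is uniform over {A, C, G, T}; each site evolves
    independently with rate ``base_rate`` times the multiplier of the region
    containing it. On a branch of duration ``t`` a site substitutes with
    probability (3/4)(1 - exp(-4 r t / 3)), moving to one of the three other
    bases uniformly. The output alignment is gap-free.
    """
    rng = _rng(config.seed if seed is None else seed)
    rates = config.site_rates()
    L = config.seq_length
    root_seq = rng.integers(0, 4, size=L).astype(np.int8)
    seqs: dict[int, np.ndarray] = {id(t.tree.seed_node): root_seq}
    names: list[str] = []
    rows: list[str] = []
    for node in t.tree.preorder_node_iter():
        if node.parent_node is not None:
            parent_seq = seqs[id(node.parent_node)]
            bl = node.edge.length or 0.0
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * rates * bl / 3.0))
            hit = rng.random(L) < p_sub
            seq = parent_seq.copy()
            n_hit = int(hit.sum())
            if n_hit:
                # jump to one of the 3 other bases uniformly
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
            seqs[id(node)] = seq
        else:
            seq = root_seq
        if node.is_leaf():
            names.append(node.taxon.label)
            rows.append(_BASES[seqs[id(node)]].tobytes().decode("ascii"))
    return GroupAlignment(
        group_id=group_id,
        names=names,
        rows=rows,
        region_map=dict(config.region_spans),
    )


def build_supergroup_fixture(
    config: SimulationConfig,
) -> tuple[StructuredTree, dict[str, GroupAlignment]]:
    """Multi-group tree plus per-group alignments.

    Each group is an independent (optionally time-warped) Yule subtree
    scaled to its configured crown depth and attached to a shared root by
    its trunk branch, so groups are monophyletic by construction. Sequences
    are evolved over the whole supergroup tree and split per group.
    """
    layout = config.group_layout
    if len(layout) < 2:
        raise InputError("group_layout needs >= 2 groups")
    ids = [g.group_id for g in layout]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate group ids in layout: {ids}")
    rng = _rng(config.seed)
    taxa = dendropy.TaxonNamespace()
    super_tree = dendropy.Tree(taxon_namespace=taxa)
    super_tree.is_rooted = True
    group_of: dict[str, str] = {}
    for spec in layout:
        if spec.n_tips == 1:
            sub_root = dendropy.Node()
            leaf = dendropy.Node()
            leaf.edge.length = 0.0
            sub_root.add_child(leaf)
            leaf.taxon = taxa.new_taxon(f"{spec.group_id}_1")
            tips = [leaf.taxon.label]
            sub_seed = sub_root
        else:
            sub = simulate_yule_tree(
                spec.n_tips, config.birth_rate, rng, prefix=f"{spec.group_id}_"
            )
            if spec.warp_beta != 1.0:
                sub = warp_tree_times(sub, spec.warp_beta)
            depth = _node_depths(sub.tree)
            cur = max(depth[l] for l in sub.tree.leaf_node_iter())
            scale = spec.depth / cur
            for node in sub.tree.preorder_node_iter():
                if node.edge.length is not None:
                    node.edge.length *= scale
            tips = sub.tip_names()
            sub_seed = sub.tree.seed_node
            # migrate taxa into the supergroup namespace
            for leaf in sub.tree.leaf_node_iter():
                leaf.taxon = taxa.new_taxon(leaf.taxon.label)
        sub_seed.edge.length = spec.trunk_length
        super_tree.seed_node.add_child(sub_seed)
        for tip in tips:
            group_of[tip] = spec.group_id
    tree = StructuredTree(tree=super_tree, group_of=group_of)
    aln = evolve_sequences(tree, config, seed=rng, group_id="supergroup")
    per_group: dict[str, GroupAlignment] = {}
    for spec in layout:
        tips = tree.tips_of(spec.group_id)
        idx = [aln.names.index(tip) for tip in sorted(tips)]
        per_group[spec.group_id] = GroupAlignment(
            group_id=spec.group_id,
            names=[aln.names[i] for i in idx],
            rows=[aln.rows[i] for i in idx],
            region_map=dict(aln.region_map),
        )
    return tree, per_group


def write_fixture(
    config: SimulationConfig,
    outdir: str | Path,
) -> tuple[StructuredTree, dict[str, GroupAlignment]]:
    """Build a supergroup fixture and write it next to its config.

    Emits ``supergroup.nwk``, ``groups.tsv`` (tip -> group), one
    ``<group>.fasta`` per group, and ``config.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, alns = build_supergroup_fixture(config)
    tree.write_newick(outdir / "supergroup.nwk")
    tree.write_group_map(outdir / "groups.tsv")
    for gid, aln in alns.items():
        write_alignment(aln, outdir / f"{gid}.fasta")
    (outdir / "config.json").write_text(config.to_json() + "\n")
    return tree, alns
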
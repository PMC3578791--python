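"""Furthest-neighbor (complete-linkage) OTU clustering and diversity statistics.

Sequences are agglomerated into Operational Taxonomic Units (OTUs): at each
step the two clusters whose *maximum* cross-pair distance is smallest are
merged, so every OTU carries the complete-linkage guarantee that no internal
pair exceeds the cutoff. Distances are first rounded half-up to a grid of
1/precision (default 10,000), mirroring the maximum-precision grid of
mothur's furthest-neighbor clustering; cutoffs are compared on the same
grid with closed (<=) semantics.

Per-group diversity is summarized by the average and maximum pairwise
distance plus the *maximum corrected* distance: the smallest cutoff at which
a given fraction (default 90%) of the group's sequences fall into a single
OTU. The maximum corrected distance is robust to a single divergent
(fast-evolving or error-laden) sequence that would inflate the raw maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from protistdiv.distances import DistanceMatrix, summarize_distances
from protistdiv.errors import InputError

__all__ = [
    "MergeDendrogram",
    "OTUPartition",
    "GroupDiversityStats",
    "cluster_furthest_neighbor",
    "partition_at",
    "max_corrected_distance",
    "clustering_pattern",
    "group_diversity_stats",
    "group_report",
    "write_list_file",
]

DEFAULT_PRECISION = 10_000
DEFAULT_CUTOFFS = (0.00, 0.01, 0.05, 0.10)


def round_to_grid(x: float, precision: int) -> int:
    """Round a distance half-up to integer grid units of 1/precision."""
    return int(math.floor(x * precision + 0.5))


@dataclass
class MergeDendrogram:
    """Ordered record of complete-linkage merges.

    ``merges`` holds (height, members-of-new-cluster) with heights on the
    rounded grid, non-decreasing; the final merge unites all leaves.
    ``precision`` is the grid the heights live on.
    """

    leaves: list[str]
    merges: list[tuple[float, frozenset[str]]]
    precision: int = DEFAULT_PRECISION

    def __post_init__(self) -> None:
        heights = [h for h, _ in self.merges]
        if any(h < 0 for h in heights):
            raise InputError("merge heights must be >= 0")
        if any(b < a for a, b in zip(heights, heights[1:])):
            raise InputError("merge heights must be non-decreasing")
        if self.merges and self.merges[-1][1] != frozenset(self.leaves):
            raise InputError("final merge must unite all leaves")


@dataclass
class OTUPartition:
    """Disjoint OTUs covering all leaves at one cutoff."""

    cutoff: float
    otus: list[frozenset[str]]

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    @property
    def largest(self) -> int:
        return max(len(o) for o in self.otus)


@dataclass
class GroupDiversityStats:
    """Per-group diversity summary: the statistics of a survey table row."""

    group_id: str
    n_seq: int
    avg: float
    max: float
    max_corrected: float
    otu_counts: dict[float, int] = field(default_factory=dict)


def cluster_furthest_neighbor(
    m: DistanceMatrix, precision: int = DEFAULT_PRECISION
) -> MergeDendrogram:
    """Agglomerate a distance matrix by furthest-neighbor linkage.

    Distances are rounded half-up to the 1/precision grid before
    agglomeration. Ties between equal-height candidate merges are broken by
    the lexicographically smallest member names of the two clusters, making
    the dendrogram reproducible.
    """
    n = m.n
    if n < 2:
        raise InputError("need >= 2 names to cluster")
    if precision < 1:
        raise InputError(f"precision must be >= 1, got {precision}")
    if np.any(~np.isfinite(m.d)):
        raise InputError("cannot cluster a matrix with undefined distances")
    grid = np.floor(m.d * precision + 0.5).astype(np.int64)
    np.fill_diagonal(grid, np.iinfo(np.int64).max)

    members: dict[int, frozenset[str]] = {
        i: frozenset([name]) for i, name in enumerate(m.names)
    }
    min_name: dict[int, str] = {i: name for i, name in enumerate(m.names)}
    active = sorted(members)
    merges: list[tuple[float, frozenset[str]]] = []

    while len(active) > 1:
        sub = grid[np.ix_(active, active)]
        best = int(sub.min())
        ii, jj = np.nonzero(np.triu(sub == best, k=1))
        # tie rule: smallest (sorted) pair of cluster min-names wins
        best_key = None
        best_pair = None
        for a, b in zip(ii.tolist(), jj.tolist()):
            ia, ib = active[a], active[b]
            key = tuple(sorted((min_name[ia], min_name[ib])))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (ia, ib)
        ia, ib = best_pair  # type: ignore[misc]
        new = members[ia] | members[ib]
        merges.append((best / precision, new))
        # complete linkage: distance to merged cluster is the max of the parts
        merged_row = np.maximum(grid[ia], grid[ib])
        grid[ia] = merged_row
        grid[:, ia] = merged_row
        grid[ia, ia] = np.iinfo(np.int64).max
        members[ia] = new
        min_name[ia] = min(min_name[ia], min_name[ib])
        active.remove(ib)
    return MergeDendrogram(leaves=list(m.names), merges=merges, precision=precision)


def partition_at(dend: MergeDendrogram, cutoff: float) -> OTUPartition:
    """Components formed by all merges with height <= cutoff (closed).

    The cutoff is rounded to the dendrogram's grid before comparison, so a
    cutoff of 0.01 picks up merges at exactly 0.01.
    """
    if cutoff < 0:
        raise InputError(f"cutoff must be >= 0, got {cutoff}")
    cut_grid = round_to_grid(cutoff, dend.precision)
    parent: dict[str, str] = {leaf: leaf for leaf in dend.leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for height, group in dend.merges:
        if round_to_grid(height, dend.precision) > cut_grid:
            break
        it = iter(sorted(group))
        root = find(next(it))
        for name in it:
            parent[find(name)] = root
    clusters: dict[str, set[str]] = {}
    for leaf in dend.leaves:
        clusters.setdefault(find(leaf), set()).add(leaf)
    otus = sorted((frozenset(c) for c in clusters.values()), key=min)
    return OTUPartition(cutoff=cutoff, otus=otus)


def max_corrected_distance(dend: MergeDendrogram, fraction: float = 0.9) -> float:
    """Smallest merge height at which one OTU holds >= fraction of sequences.

    With the default fraction of 0.9 this is the distance at which 90% of
    the group's sequences cluster into a single OTU. The threshold
    fraction*n is compared with >= on the real value (no integer ceiling).
    Returns 0.0 when the condition already holds at cutoff 0.
    """
    if not (0 < fraction <= 1):
        raise InputError(f"fraction must be in (0, 1], got {fraction}")
    n = len(dend.leaves)
    need = fraction * n
    if 1 >= need:
        return 0.0
    parent: dict[str, str] = {leaf: leaf for leaf in dend.leaves}
    size: dict[str, int] = {leaf: 1 for leaf in dend.leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    best = 1
    i = 0
    merges = dend.merges
    while i < len(merges):
        h = merges[i][0]
        while i < len(merges) and merges[i][0] == h:
            group = merges[i][1]
            it = iter(sorted(group))
            root = find(next(it))
            for name in it:
                r = find(name)
                if r != root:
                    size[root] += size[r]
                    parent[r] = root
            best = max(best, size[root])
            i += 1
        if best >= need:
            return h
    # fraction <= 1 guarantees the final merge (all leaves) satisfies it
    return merges[-1][0] if merges else 0.0


def clustering_pattern(
    stats: GroupDiversityStats, cutoffs: list[float] | tuple[float, ...]
) -> dict[float, float]:
    """OTU counts as percentages of the count at distance 0.

    percentage(c) = 100 * otu_counts[c] / otu_counts[0]. A high percentage
    remaining at 0.05 or 0.10 means many deeply divergent lineages within
    the group; a low one means diversity collapses at shallow distances.
    """
    if 0.0 not in stats.otu_counts:
        raise InputError(f"group {stats.group_id!r}: no OTU count at cutoff 0")
    base = stats.otu_counts[0.0]
    if base < 1:
        raise InputError(f"group {stats.group_id!r}: OTU count at cutoff 0 is {base}")
    out = {}
    for c in cutoffs:
        if c not in stats.otu_counts:
            raise InputError(f"group {stats.group_id!r}: no OTU count at cutoff {c}")
        out[c] = 100.0 * stats.otu_counts[c] / base
    return out


def group_diversity_stats(
    m: DistanceMatrix,
    group_id: str | None = None,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    precision: int = DEFAULT_PRECISION,
    fraction: float = 0.9,
) -> GroupDiversityStats:
    """Convenience: cluster one group's matrix and assemble its statistics.

    Avg and Max are computed on the unrounded distances; clustering and the
    maximum corrected distance operate on the precision grid.
    """
    avg, mx = summarize_distances(m)
    dend = cluster_furthest_neighbor(m, precision=precision)
    counts = {c: partition_at(dend, c).n_otus for c in cutoffs}
    return GroupDiversityStats(
        group_id=group_id if group_id is not None else "group",
        n_seq=m.n,
        avg=avg,
        max=mx,
        max_corrected=max_corrected_distance(dend, fraction=fraction),
        otu_counts=counts,
    )


def group_report(groups: list[GroupDiversityStats]) -> pd.DataFrame:
    """Survey-style table: one row per group plus an OTU-count totals row.

    Columns: Group, Seq, Avg, Max, Max_c, then one OTU-count column per
    cutoff. The totals row sums sequence and OTU counts across groups
    (counts are computed per group and then added up).
    """
    if groups:
        cutoffs = sorted(groups[0].otu_counts)
        for g in groups[1:]:
            if sorted(g.otu_counts) != cutoffs:
                raise InputError("all groups must share the same cutoff set")
    else:
        cutoffs = []
    rows = []
    for g in groups:
        row = {
            "Group": g.group_id,
            "Seq": g.n_seq,
            "Avg": g.avg,
            "Max": g.max,
            "Max_c": g.max_corrected,
        }
        for c in cutoffs:
            row[f"OTUs_{c:g}"] = g.otu_counts[c]
        rows.append(row)
    total = {"Group": "Total", "Seq": sum(g.n_seq for g in groups)}
    total["Avg"] = total["Max"] = total["Max_c"] = float("nan")
    for c in cutoffs:
        total[f"OTUs_{c:g}"] = sum(g.otu_counts[c] for g in groups)
    rows.append(total)
    return pd.DataFrame(rows)


def write_list_file(
    dend: MergeDendrogram, cutoffs: tuple[float, ...], path
) -> None:
    """mothur-style list output: cutoff, #OTUs, comma-joined OTU members."""
    with open(path, "w") as fh:
        for c in cutoffs:
            part = partition_at(dend, c)
            otus = "\t".join(",".join(sorted(o)) for o in part.otus)
            fh.write(f"{c:g}\t{part.n_otus}\t{otus}\n")
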
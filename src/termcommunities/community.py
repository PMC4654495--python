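"""Resolution-generalized modularity and weighted fast-greedy agglomeration.

The partition quality used throughout is

    Q(r) = 1/(2m) * sum_ij [ A_ij - (1 + r/<k>) * k_i k_j / (2m) ] delta(x_i, x_j)

where A is the weighted adjacency, k_i the node strength, m the total
edge weight, <k> the mean strength, and r >= 0 a resolution parameter.
At r = 0 this is standard Newman-Girvan weighted modularity; r > 0
inflates the null expectation, so maximizing Q(r) favors smaller, denser
communities and exposes sub-structure.

``fast_greedy`` is a weighted CNM-style agglomeration: start from
singletons, repeatedly merge the pair of connected communities with the
largest Q increase, record the full merge sequence, and cut the
dendrogram at the step of maximum Q.  ``resolution_sweep`` runs it over
a grid of resolutions and collects every distinct community into a
registry with stable ``TC:%07d`` identifiers.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .projection import TermNetwork

__all__ = [
    "WeightedGraph",
    "Partition",
    "MergeStep",
    "Dendrogram",
    "CommunityRecord",
    "CommunityRegistry",
    "modularity",
    "fast_greedy",
    "resolution_sweep",
    "default_resolution_grid",
]


@dataclass
class WeightedGraph:
    """Symmetric non-negative weighted graph over integer nodes 0..n-1."""

    n: int
    edges: dict[tuple[int, int], float]
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("graph must have at least one node")
        for (i, j), w in self.edges.items():
            if not (0 <= i < j < self.n):
                raise ValueError(f"bad edge key {(i, j)} for n={self.n}")
            if w < 0:
                raise ValueError("edge weights must be non-negative")

    @classmethod
    def from_term_network(cls, net: TermNetwork) -> "WeightedGraph":
        return cls(n=net.n_terms, edges=dict(net.edges),
                   node_labels=list(net.term_index))

    @classmethod
    def from_dense(cls, A: np.ndarray) -> "WeightedGraph":
        A = np.asarray(A, dtype=float)
        if A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
            raise ValueError("adjacency must be square and symmetric")
        edges = {
            (i, j): float(A[i, j])
            for i in range(A.shape[0])
            for j in range(i + 1, A.shape[0])
            if A[i, j] != 0.0
        }
        return cls(n=A.shape[0], edges=edges)

    @property
    def strengths(self) -> np.ndarray:
        k = np.zeros(self.n)
        for (i, j), w in self.edges.items():
            k[i] += w
            k[j] += w
        return k

    @property
    def total_weight(self) -> float:
        """m: sum of edge weights, each edge counted once."""
        return float(sum(self.edges.values()))

    @property
    def mean_strength(self) -> float:
        return float(self.strengths.sum()) / self.n

    def label_of(self, node: int) -> str:
        return self.node_labels[node] if self.node_labels else str(node)


@dataclass
class Partition:
    """A node->community assignment with its modularity at resolution r."""

    assignment: dict[int, int]
    Q: float
    r: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[frozenset[int]]:
        """Member sets, ordered by smallest member node."""
        groups: dict[int, set[int]] = {}
        for node, label in self.assignment.items():
            groups.setdefault(label, set()).add(node)
        return [frozenset(g) for g in
                sorted(groups.values(), key=lambda g: min(g))]


@dataclass(frozen=True)
class MergeStep:
    a: int
    b: int
    delta_q: float
    q_after: float


@dataclass
class Dendrogram:
    """Full merge sequence of one fast-greedy run."""

    merges: list[MergeStep]
    q_initial: float
    best_step: int  # number of merges applied at the maximum-Q cut

    def to_json(self, path: str | Path) -> None:
        payload = {
            "q_initial": self.q_initial,
            "best_step": self.best_step,
            "merges": [
                {"a": s.a, "b": s.b, "delta_q": s.delta_q, "q_after": s.q_after}
                for s in self.merges
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _null_factor(graph: WeightedGraph, r: float) -> float:
    mean_k = graph.mean_strength
    if mean_k <= 0:
        raise ValueError("graph has zero total weight")
    return 1.0 + r / mean_k


def modularity(graph: WeightedGraph, partition: Partition | dict[int, int],
               r: float = 0.0) -> float:
    """Direct evaluation of the resolution-generalized modularity.

    The double sum is grouped by community: observed internal weight
    minus the (1 + r/<k>)-scaled degree-product null, normalized by 2m.
    """
    if r < 0:
        raise ValueError("resolution parameter must be >= 0")
    assignment = partition.assignment if isinstance(partition, Partition) \
        else partition
    if set(assignment) != set(range(graph.n)):
        raise ValueError("partition must cover every node exactly once")
    m = graph.total_weight
    if m <= 0:
        raise ValueError("graph has zero total weight")
    gamma = _null_factor(graph, r)
    two_m = 2.0 * m
    k = graph.strengths
    internal = 0.0
    for (i, j), w in graph.edges.items():
        if assignment[i] == assignment[j]:
            internal += w
    comm_strength: dict[int, float] = {}
    for node, label in assignment.items():
        comm_strength[label] = comm_strength.get(label, 0.0) + k[node]
    null = sum(s * s for s in comm_strength.values())
    return (2.0 * internal) / two_m - gamma * null / (two_m * two_m)


def fast_greedy(
    graph: WeightedGraph, r: float = 0.0
) -> tuple[Partition, Dendrogram]:
    """Weighted CNM agglomeration maximizing Q(r).

    Only connected community pairs are merge candidates (merging
    disconnected communities can never increase Q for r >= 0).  Ties in
    the Q increase are broken toward the lexicographically smallest
    community-index pair; merged communities keep the smaller index.
    Returns the max-Q partition and the full dendrogram; on plateaus the
    earliest merge step (most communities) wins.
    """
    if r < 0:
        raise ValueError("resolution parameter must be >= 0")
    if graph.n == 0 or not graph.edges:
        raise ValueError("graph must have at least one edge")
    m = graph.total_weight
    if m <= 0:
        raise ValueError("graph has zero total weight")
    gamma = _null_factor(graph, r)
    two_m = 2.0 * m
    k = graph.strengths

    # community state: strength, cross-weights to neighbors, active flag
    strength: list[float] = [float(k[i]) for i in range(graph.n)]
    nbr: list[dict[int, float]] = [dict() for _ in range(graph.n)]
    for (i, j), w in graph.edges.items():
        if w == 0.0:
            continue
        nbr[i][j] = nbr[i].get(j, 0.0) + w
        nbr[j][i] = nbr[j].get(i, 0.0) + w
    active = [True] * graph.n

    def dq(a: int, b: int) -> float:
        e_ab = nbr[a].get(b, 0.0)
        return 2.0 * (e_ab / two_m - gamma * strength[a] * strength[b]
                      / (two_m * two_m))

    heap: list[tuple[float, int, int]] = []
    for a in range(graph.n):
        for b in nbr[a]:
            if a < b:
                heap.append((-dq(a, b), a, b))
    heapq.heapify(heap)

    q_initial = -gamma * float(np.sum(k * k)) / (two_m * two_m)
    q_current = q_initial
    best_q = q_initial
    best_step = 0
    merges: list[MergeStep] = []
    parent = list(range(graph.n))  # union-find for replay

    while heap:
        neg, a, b = heapq.heappop(heap)
        if not (active[a] and active[b]):
            continue
        if -neg != dq(a, b):  # stale entry: e or s changed since push
            continue
        delta = -neg
        # merge b into a (a < b by construction)
        q_current += delta
        merges.append(MergeStep(a=a, b=b, delta_q=delta, q_after=q_current))
        if q_current > best_q:
            best_q = q_current
            best_step = len(merges)
        active[b] = False
        strength[a] += strength[b]
        del nbr[a][b]
        del nbr[b][a]
        for c, w in nbr[b].items():
            nbr[c].pop(b)
            nbr[a][c] = nbr[a].get(c, 0.0) + w
            nbr[c][a] = nbr[a][c]
        nbr[b].clear()
        # refresh candidate entries touching the merged community
        for c in nbr[a]:
            lo, hi = (a, c) if a < c else (c, a)
            heapq.heappush(heap, (-dq(lo, hi), lo, hi))

    # replay merges up to the best cut
    for step in merges[:best_step]:
        parent[step.b] = step.a

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    roots = sorted({find(i) for i in range(graph.n)})
    relabel = {root: idx for idx, root in enumerate(roots)}
    assignment = {i: relabel[find(i)] for i in range(graph.n)}
    partition = Partition(assignment=assignment, Q=best_q, r=r)
    dendrogram = Dendrogram(merges=merges, q_initial=q_initial,
                            best_step=best_step)
    return partition, dendrogram


@dataclass
class CommunityRecord:
    tc_id: str
    members: frozenset[str]
    resolutions: list[float]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CommunityRegistry:
    """All distinct communities across a resolution sweep.

    Identical member sets arising at different resolutions are stored
    once, with every source resolution recorded.  ``partitions`` maps
    each swept resolution to the ordered TC ids of its max-Q cut.
    """

    communities: list[CommunityRecord] = field(default_factory=list)
    partitions: dict[float, list[str]] = field(default_factory=dict)
    _by_members: dict[frozenset[str], str] = field(default_factory=dict)

    def get(self, tc_id: str) -> CommunityRecord:
        for rec in self.communities:
            if rec.tc_id == tc_id:
                return rec
        raise KeyError(tc_id)

    def members_of(self, tc_id: str) -> frozenset[str]:
        return self.get(tc_id).members

    def add(self, members: frozenset[str], r: float) -> str:
        tc_id = self._by_members.get(members)
        if tc_id is None:
            tc_id = f"TC:{len(self.communities) + 1:07d}"
            self.communities.append(
                CommunityRecord(tc_id=tc_id, members=members, resolutions=[r])
            )
            self._by_members[members] = tc_id
        else:
            rec = self.get(tc_id)
            if r not in rec.resolutions:
                rec.resolutions.append(r)
        return tc_id

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tc_id\tresolutions\tsize\tmembers\n")
            for rec in self.communities:
                res = ",".join(repr(r) for r in rec.resolutions)
                fh.write(f"{rec.tc_id}\t{res}\t{rec.size}\t"
                         f"{','.join(sorted(rec.members))}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CommunityRegistry":
        reg = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tc_id"):
                raise ValueError(f"{path}: missing registry header")
            for line in fh:
                tc_id, res, _size, members = line.rstrip("\n").split("\t")
                resolutions = [float(x) for x in res.split(",")]
                member_set = frozenset(members.split(","))
                reg.communities.append(CommunityRecord(
                    tc_id=tc_id, members=member_set, resolutions=resolutions))
                reg._by_members[member_set] = tc_id
                for r in resolutions:
                    reg.partitions.setdefault(r, []).append(tc_id)
        return reg


def default_resolution_grid(n_points: int = 24, r_min: float = 0.01,
                            r_max: float = 100.0) -> list[float]:
    """Geometric grid over four orders of magnitude, preceded by r=0."""
    grid = np.geomspace(r_min, r_max, n_points - 1)
    return [0.0] + [float(x) for x in grid]


def resolution_sweep(
    graph: WeightedGraph, r_values: list[float]
) -> CommunityRegistry:
    """Run fast_greedy at each resolution and register distinct communities.

    TC ids are assigned in (resolution-order, discovery) order; discovery
    order within a partition is by smallest member node index.
    """
    if not r_values:
        raise ValueError("r_values must be non-empty")
    registry = CommunityRegistry()
    for r in r_values:
        partition, _ = fast_greedy(graph, r=r)
        ids = []
        for members_idx in partition.communities():
            members = frozenset(graph.label_of(i) for i in members_idx)
            ids.append(registry.add(members, r))
        registry.partitions[r] = ids
    return registry


def community_size_summary(registry: CommunityRegistry) -> dict[float, dict]:
    """Per-resolution community-size distribution (count, mean, max)."""
    out = {}
    for r, ids in registry.partitions.items():
        sizes = [len(registry.members_of(t)) for t in ids]
        out[r] = {
            "n_communities": len(sizes),
            "mean_size": float(np.mean(sizes)),
            "median_size": float(np.median(sizes)),
            "max_size": int(max(sizes)),
        }
    return out
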
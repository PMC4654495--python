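"""Set comparison between term groupings.

Communities from the annotation-driven network and branches from the
ontology DAG are both collections of term sets.  ``best_match`` pairs
each set with its highest-Jaccard counterpart (J_m); the distribution of
J_m over a collection measures how similar two organizations of terms
are.  ``resolution_overlap_graph`` builds the multi-resolution flow
graph: communities at adjacent resolutions, linked when a sufficient
fraction of the finer community's members lie inside the coarser one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .community import CommunityRegistry

__all__ = ["jaccard", "BestMatchRow", "best_match", "jm_histogram",
           "OverlapGraph", "resolution_overlap_graph"]


def jaccard(x: frozenset | set, y: frozenset | set) -> float:
    """|x & y| / |x | y| as an exact float of an integer ratio."""
    if not x and not y:
        raise ValueError("Jaccard undefined for two empty sets")
    inter = len(x & y)
    union = len(x | y)
    return inter / union


@dataclass(frozen=True)
class BestMatchRow:
    set_id: str
    best_id: str
    jm: float
    set_size: int
    best_size: int


def best_match(
    X: dict[str, frozenset[str]],
    Y: dict[str, frozenset[str]],
    min_size: int = 10,
) -> tuple[list[BestMatchRow], list[BestMatchRow]]:
    """Per-set maximum Jaccard counterpart, in both directions.

    Both collections are first restricted to sets with ``min_size`` or
    more members (small sets make Jaccard values unstable).  Ties are
    broken toward the smaller counterpart, then the lexicographically
    smallest id.
    """
    Xf = {k: v for k, v in X.items() if len(v) >= min_size}
    Yf = {k: v for k, v in Y.items() if len(v) >= min_size}
    if not Xf or not Yf:
        raise ValueError(f"a collection is empty after the min_size={min_size} filter")

    def one_direction(src, dst):
        rows = []
        for sid in sorted(src):
            s = src[sid]
            best = max(
                sorted(dst),
                key=lambda did: (jaccard(s, dst[did]), -len(dst[did]),
                                 _rev_key(did)),
            )
            rows.append(BestMatchRow(
                set_id=sid, best_id=best, jm=jaccard(s, dst[best]),
                set_size=len(s), best_size=len(dst[best]),
            ))
        return rows

    return one_direction(Xf, Yf), one_direction(Yf, Xf)


def _rev_key(s: str) -> tuple[int, ...]:
    """Orders so that max() prefers the lexicographically *smallest* id."""
    return tuple(-ord(c) for c in s)


def jm_histogram(rows: list[BestMatchRow], n_bins: int = 20) -> np.ndarray:
    """Histogram counts of J_m over [0, 1] (the comparison figure's data)."""
    values = [row.jm for row in rows]
    counts, _ = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return counts


def write_best_match_tsv(rows: list[BestMatchRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tbest_id\tjm\tset_size\tbest_size\n")
        for row in rows:
            fh.write(f"{row.set_id}\t{row.best_id}\t{row.jm!r}\t"
                     f"{row.set_size}\t{row.best_size}\n")


@dataclass
class OverlapGraph:
    """Communities at ordered resolutions, with child->parent overlap edges.

    Nodes are (tc_id, resolution); ``size`` is log(member count) and
    ``color`` the normalized per-domain membership fractions.  Edges run
    from the higher-resolution (finer) community to the lower-resolution
    (coarser) one, weighted by the fraction of the child's members found
    in the parent; edges below the inclusion threshold are dropped.
    """

    levels: list[float]
    nodes: dict[tuple[str, float], dict]
    edges: list[tuple[tuple[str, float], tuple[str, float], float]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "levels": self.levels,
            "nodes": [
                {"tc_id": tc, "resolution": r, **attrs}
                for (tc, r), attrs in self.nodes.items()
            ],
            "edges": [
                {"child": c[0], "child_resolution": c[1],
                 "parent": p[0], "parent_resolution": p[1], "overlap": w}
                for c, p, w in self.edges
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for (tc, r), attrs in self.nodes.items():
            g.add_node(f"{tc}@{r}", tc_id=tc, resolution=r,
                       size=attrs["size"],
                       frac_BP=attrs["color"][0],
                       frac_MF=attrs["color"][1],
                       frac_CC=attrs["color"][2])
        for (ctc, cr), (ptc, pr), w in self.edges:
            g.add_edge(f"{ctc}@{cr}", f"{ptc}@{pr}", overlap=w)
        nx.write_graphml(g, path)


def _domain_fractions(members: frozenset[str], namespace_of,
                      namespace_share: dict[str, float]) -> tuple[float, float, float]:
    """Per-domain member fraction, normalized by each domain's global share.

    Raw fractions over-represent BP (most terms are BP); dividing by the
    domain's share of all terms before rescaling to sum 1 makes a
    domain-balanced community read as balanced.
    """
    counts = {"BP": 0, "MF": 0, "CC": 0}
    for t in members:
        counts[namespace_of(t)] += 1
    total = sum(counts.values())
    rates = {
        d: (counts[d] / total) / namespace_share[d] if namespace_share[d] > 0 else 0.0
        for d in counts
    }
    z = sum(rates.values())
    if z == 0:
        return (0.0, 0.0, 0.0)
    return (rates["BP"] / z, rates["MF"] / z, rates["CC"] / z)


def resolution_overlap_graph(
    registry: CommunityRegistry,
    levels: list[float],
    namespace_of=None,
    namespace_share: dict[str, float] | None = None,
    min_members: int = 10,
    threshold: float = 0.10,
) -> OverlapGraph:
    """Overlap graph between communities at adjacent resolution levels.

    ``levels`` must be ordered from coarse to fine; an edge from a finer
    community to a coarser one is kept when at least ``threshold`` of
    the finer community's members also belong to the coarser community.
    """
    if len(levels) < 2:
        raise ValueError("need at least two resolution levels")
    for r in levels:
        if r not in registry.partitions:
            raise KeyError(f"resolution {r} not present in the registry")
    if namespace_of is None:
        namespace_of = lambda _t: "BP"  # noqa: E731 - colorless fallback
    if namespace_share is None:
        namespace_share = {"BP": 1 / 3, "MF": 1 / 3, "CC": 1 / 3}

    nodes: dict[tuple[str, float], dict] = {}
    kept: dict[float, list[tuple[str, frozenset[str]]]] = {}
    for r in levels:
        kept[r] = []
        for tc in registry.partitions[r]:
            members = registry.members_of(tc)
            if len(members) < min_members:
                continue
            kept[r].append((tc, members))
            nodes[(tc, r)] = {
                "size": math.log(len(members)),
                "n_members": len(members),
                "color": _domain_fractions(members, namespace_of,
                                           namespace_share),
            }

    edges = []
    for coarse_r, fine_r in zip(levels, levels[1:]):
        for ctc, cmembers in kept[fine_r]:
            for ptc, pmembers in kept[coarse_r]:
                overlap = len(cmembers & pmembers) / len(cmembers)
                if overlap >= threshold:
                    edges.append(((ctc, fine_r), (ptc, coarse_r), overlap))
    return OverlapGraph(levels=list(levels), nodes=nodes, edges=edges)
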
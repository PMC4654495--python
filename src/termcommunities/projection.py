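"""Bipartite gene-term incidence and its weighted one-mode projection.

Given a transitively closed annotation table, ``build_bipartite``
produces the 0/1 incidence matrix B (genes x terms).  A simple one-mode
projection (B'B) would let high-degree terms dominate: the number of
genes per term is heavy-tailed, so shared-gene counts between two large
terms carry little specific information.  ``project_term_network``
therefore rescales by the inverse annotation counts,

    T = w' B' B w,    w = diag(1 / k_i),  k_i = number of genes on term i,

so T_ij = |genes(i) & genes(j)| / (k_i * k_j): 1 when two terms carry
exactly the same single gene, 0 when they share no genes.  The weighting
accentuates relationships between low-degree (highly specific) terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .ontology_io import AnnotationTable

__all__ = ["BipartiteAnnotation", "TermNetwork", "build_bipartite",
           "project_term_network", "filter_network"]


@dataclass
class BipartiteAnnotation:
    """Sparse 0/1 gene-by-term incidence with ordered labels."""

    B: sp.csr_matrix
    gene_index: list[str]
    term_index: list[str]

    @property
    def n_genes(self) -> int:
        return self.B.shape[0]

    @property
    def n_terms(self) -> int:
        return self.B.shape[1]

    @property
    def term_degrees(self) -> np.ndarray:
        """k_i: number of genes annotated to each term (column sums)."""
        return np.asarray(self.B.sum(axis=0)).ravel().astype(np.int64)

    @property
    def gene_degrees(self) -> np.ndarray:
        return np.asarray(self.B.sum(axis=1)).ravel().astype(np.int64)

    def gene_pos(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_index)}
        return np.array(sorted(lookup[g] for g in genes), dtype=np.int64)

    def term_pos(self, terms) -> np.ndarray:
        lookup = {t: i for i, t in enumerate(self.term_index)}
        return np.array(sorted(lookup[t] for t in terms), dtype=np.int64)

    def restrict_terms(self, keep: list[str]) -> "BipartiteAnnotation":
        """Sub-incidence on a term subset; genes losing all annotations drop."""
        pos = self.term_pos(keep)
        B = self.B[:, pos].tocsr()
        terms = [self.term_index[p] for p in pos]
        row_nnz = np.asarray(B.sum(axis=1)).ravel()
        keep_rows = np.nonzero(row_nnz > 0)[0]
        B = B[keep_rows, :].tocsr()
        genes = [self.gene_index[r] for r in keep_rows]
        col_nnz = np.asarray(B.sum(axis=0)).ravel()
        keep_cols = np.nonzero(col_nnz > 0)[0]
        if len(keep_cols) < B.shape[1]:
            B = B[:, keep_cols].tocsr()
            terms = [terms[c] for c in keep_cols]
        return BipartiteAnnotation(B=B, gene_index=genes, term_index=terms)


@dataclass
class TermNetwork:
    """Symmetric weighted term-term network from the degree-weighted projection.

    ``edges`` maps each unordered index pair (i < j) to its weight.  The
    raw projection's diagonal (1/k_i) is recorded in ``raw_diagonal`` for
    audit; by default it does not enter downstream community detection.
    """

    term_index: list[str]
    edges: dict[tuple[int, int], float]
    term_degrees: np.ndarray
    diagonal_policy: str = "zeroed"
    raw_diagonal: np.ndarray | None = None
    bipartite: BipartiteAnnotation | None = field(default=None, repr=False)

    @property
    def n_terms(self) -> int:
        return len(self.term_index)

    def weight(self, term_a: str, term_b: str) -> float:
        i = self.term_index.index(term_a)
        j = self.term_index.index(term_b)
        if i == j:
            raise ValueError("self-weights live in raw_diagonal")
        key = (min(i, j), max(i, j))
        return self.edges.get(key, 0.0)

    def dense(self) -> np.ndarray:
        A = np.zeros((self.n_terms, self.n_terms))
        for (i, j), w in self.edges.items():
            A[i, j] = A[j, i] = w
        return A

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("term_a\tterm_b\tweight\n")
            for (i, j) in sorted(self.edges):
                fh.write(
                    f"{self.term_index[i]}\t{self.term_index[j]}\t"
                    f"{self.edges[(i, j)]!r}\n"
                )

    @classmethod
    def read_edgelist(cls, path: str | Path) -> "TermNetwork":
        rows: list[tuple[str, str, float]] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("term_a"):
                raise ValueError(f"{path}: missing edge-list header")
            for line in fh:
                a, b, w = line.rstrip("\n").split("\t")
                rows.append((a, b, float(w)))
        terms = sorted({a for a, _, _ in rows} | {b for _, b, _ in rows})
        pos = {t: i for i, t in enumerate(terms)}
        edges = {}
        for a, b, w in rows:
            i, j = pos[a], pos[b]
            edges[(min(i, j), max(i, j))] = w
        return cls(
            term_index=terms,
            edges=edges,
            term_degrees=np.zeros(len(terms), dtype=np.int64),
            diagonal_policy="unknown(read from edge list)",
        )

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.term_index)
        for (i, j), w in self.edges.items():
            g.add_edge(self.term_index[i], self.term_index[j], weight=w)
        nx.write_graphml(g, path)


def build_bipartite(annotations: AnnotationTable) -> BipartiteAnnotation:
    """Incidence matrix of a closed annotation table, lexicographic order."""
    if not annotations.pairs:
        raise ValueError("annotation table is empty")
    genes = sorted(annotations.genes)
    terms = sorted(annotations.terms)
    g_pos = {g: i for i, g in enumerate(genes)}
    t_pos = {t: i for i, t in enumerate(terms)}
    rows = np.fromiter((g_pos[g] for g, _ in annotations.pairs), dtype=np.int64,
                       count=len(annotations.pairs))
    cols = np.fromiter((t_pos[t] for _, t in annotations.pairs), dtype=np.int64,
                       count=len(annotations.pairs))
    data = np.ones(len(annotations.pairs), dtype=np.int8)
    B = sp.coo_matrix((data, (rows, cols)), shape=(len(genes), len(terms)))
    return BipartiteAnnotation(B=B.tocsr(), gene_index=genes, term_index=terms)


def project_term_network(bip: BipartiteAnnotation) -> TermNetwork:
    """Degree-weighted projection T_ij = shared-gene count / (k_i * k_j).

    Shared-gene counts are accumulated as integers and divided once, so
    T is symmetric bit-for-bit.  The diagonal (raw value 1/k_i) is zeroed
    by default and kept as a sidecar.
    """
    k = bip.term_degrees
    if np.any(k < 1):
        raise ValueError("every term column must have at least one annotation")
    shared = (bip.B.T.astype(np.int64) @ bip.B.astype(np.int64)).tocoo()
    edges: dict[tuple[int, int], float] = {}
    for i, j, c in zip(shared.row, shared.col, shared.data):
        if i < j and c > 0:
            edges[(int(i), int(j))] = float(c) / (float(k[i]) * float(k[j]))
    return TermNetwork(
        term_index=list(bip.term_index),
        edges=edges,
        term_degrees=k,
        diagonal_policy="zeroed",
        raw_diagonal=1.0 / k.astype(float),
        bipartite=bip,
    )


def filter_network(
    net: TermNetwork,
    min_weight: float = 0.0,
    namespaces: set[str] | None = None,
    ontology=None,
) -> TermNetwork:
    """Drop edges below ``min_weight``; optionally re-project on a namespace subset.

    Namespace restriction re-projects from the restricted incidence (not a
    sub-setting of T), so term degrees k_i are recomputed on the subset.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    if namespaces is not None:
        if net.bipartite is None or ontology is None:
            raise ValueError(
                "namespace filtering needs the source bipartite and an ontology"
            )
        keep = [t for t in net.term_index
                if ontology.namespace_of(t) in namespaces]
        if not keep:
            raise ValueError("no terms left after namespace restriction")
        net = project_term_network(net.bipartite.restrict_terms(keep))
    edges = {ij: w for ij, w in net.edges.items() if w >= min_weight}
    if not edges:
        raise ValueError("network is empty after weight filtering")
    return TermNetwork(
        term_index=net.term_index,
        edges=edges,
        term_degrees=net.term_degrees,
        diagonal_policy=net.diagonal_policy,
        raw_diagonal=net.raw_diagonal,
        bipartite=net.bipartite,
    )
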
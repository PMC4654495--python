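"""Ontology and annotation ingestion.

Reads an ontology in OBO format into a typed child->parent DAG, reads
gene-term annotations from GAF 2.x (or a minimal two-column TSV),
propagates annotations transitively up the DAG (the "true path rule":
every parent term takes on all gene annotations of its descendants),
and extracts branches (a term plus all of its descendants).
"""

from __future__ import annotations

import gzip
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

__all__ = [
    "TermRecord",
    "Ontology",
    "Branch",
    "AnnotationTable",
    "OntologyError",
    "ParseError",
    "parse_obo",
    "parse_gaf",
    "parse_pairs_tsv",
    "propagate_annotations",
    "extract_branch",
    "list_branches",
]

#: Relations that propagate annotations (GO's true-path relations).
PROPAGATING_RELATIONS = ("is_a", "part_of")

#: Canonical short namespace labels.
NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, unknown term, ...)."""


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class TermRecord:
    """One ontology term: accession, human-readable name, namespace."""

    term_id: str
    name: str
    namespace: str
    obsolete: bool = False


@dataclass
class Ontology:
    """A term DAG with typed child->parent edges.

    ``graph`` is a :class:`networkx.MultiDiGraph` whose edges run from
    child to parent and whose edge keys are relation types (``is_a``,
    ``part_of``, plus any other relations present in the file, which are
    retained but do not propagate annotations).
    """

    terms: dict[str, TermRecord]
    graph: nx.MultiDiGraph
    propagating_relations: tuple[str, ...] = PROPAGATING_RELATIONS

    def __post_init__(self) -> None:
        sub = self._propagating_subgraph()
        if not nx.is_directed_acyclic_graph(sub):
            cycle = nx.find_cycle(sub)
            raise OntologyError(f"typed edge graph contains a cycle: {cycle}")

    def _propagating_subgraph(self) -> nx.MultiDiGraph:
        edges = [
            (u, v, k)
            for u, v, k in self.graph.edges(keys=True)
            if k in self.propagating_relations
        ]
        sub = nx.MultiDiGraph()
        sub.add_nodes_from(self.graph.nodes)
        sub.add_edges_from(edges)
        return sub

    @property
    def roots(self) -> list[str]:
        """Terms with no outgoing (child->parent) propagating edge."""
        sub = self._propagating_subgraph()
        return sorted(
            t for t in sub.nodes
            if sub.out_degree(t) == 0 and not self.terms[t].obsolete
        )

    def active_terms(self) -> list[str]:
        """Sorted non-obsolete term accessions."""
        return sorted(t for t, rec in self.terms.items() if not rec.obsolete)

    def namespace_of(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via propagating parent links."""
        if term_id not in self.terms:
            raise OntologyError(f"unknown term accession: {term_id}")
        return frozenset(nx.descendants(self._propagating_subgraph(), term_id))

    def ancestor_map(self) -> dict[str, frozenset[str]]:
        """Ancestor closure for every term, computed once in topological order."""
        sub = self._propagating_subgraph()
        closure: dict[str, frozenset[str]] = {}
        for node in reversed(list(nx.topological_sort(sub))):
            acc: set[str] = set()
            for _, parent in sub.out_edges(node):
                acc.add(parent)
                acc |= closure[parent]
            closure[node] = frozenset(acc)
        return closure

    def descendants(self, term_id: str) -> frozenset[str]:
        """All terms from which ``term_id`` is reachable via parent links."""
        if term_id not in self.terms:
            raise OntologyError(f"unknown term accession: {term_id}")
        return frozenset(nx.ancestors(self._propagating_subgraph(), term_id))


@dataclass(frozen=True)
class Branch:
    """A parent term together with all of its descendants."""

    parent_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.parent_id not in self.members:
            raise OntologyError("branch parent must be a member of its branch")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AnnotationTable:
    """Transitively closed gene-term annotation pairs.

    ``pairs`` holds every (gene, term) pair after propagation;
    ``direct`` the subset asserted in the input; ``provenance`` maps a
    direct pair to the evidence codes that supported it.
    """

    pairs: set[tuple[str, str]]
    direct: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.pairs}

    @property
    def terms(self) -> set[str]:
        return {t for _, t in self.pairs}

    def genes_of(self, term_id: str) -> set[str]:
        return {g for g, t in self.pairs if t == term_id}

    def write_tsv(self, path: str | Path) -> None:
        """Write (gene, term, direct|inferred) rows; gzip if path ends .gz."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for gene, term in sorted(self.pairs):
                flag = "direct" if (gene, term) in self.direct else "inferred"
                fh.write(f"{gene}\t{term}\t{flag}\n")


def _canonical_namespace(raw: str | None, term_id: str) -> str:
    if raw is None:
        raise ParseError(f"term {term_id} has no namespace")
    try:
        return NAMESPACE_ALIASES[raw]
    except KeyError:
        raise ParseError(f"term {term_id} has unknown namespace {raw!r}") from None


def parse_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2/1.4 file into an :class:`Ontology`.

    Obsolete terms are kept (flagged) but carry no edges; acyclicity of
    the typed is_a/part_of graph is verified on construction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise ParseError(f"cannot parse OBO file {path}: {exc}") from exc

    terms: dict[str, TermRecord] = {}
    graph = nx.MultiDiGraph()
    for term_id, data in raw.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[term_id] = TermRecord(
            term_id=term_id,
            name=data.get("name", term_id),
            namespace=_canonical_namespace(data.get("namespace"), term_id),
            obsolete=obsolete,
        )
        graph.add_node(term_id)
    for child, parent, relation in raw.edges(keys=True):
        if terms[child].obsolete or terms[parent].obsolete:
            continue
        graph.add_edge(child, parent, key=relation)
    return Ontology(terms=terms, graph=graph)


# GAF 2.x column indices (0-based)
_GAF_SYMBOL, _GAF_QUALIFIER, _GAF_TERM, _GAF_EVIDENCE = 2, 3, 4, 6
_GAF_NCOL = 17


def parse_gaf(
    path: str | Path,
    exclude_not: bool = True,
    evidence: Iterable[str] | None = None,
) -> list[tuple[str, str, str]]:
    """Read a GAF 2.x file into de-duplicated (gene, term, evidence) triples.

    Rows whose qualifier contains ``NOT`` are dropped when ``exclude_not``
    is set (the default).  ``evidence``, if given, whitelists evidence
    codes.  Gene identity is the DB-Object-Symbol column, case-sensitive.
    """
    triples: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    wanted = set(evidence) if evidence is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 15:
                raise ParseError(
                    f"{path}: row {lineno} has {len(fields)} columns, "
                    f"expected {_GAF_NCOL}"
                )
            qualifier = fields[_GAF_QUALIFIER]
            if exclude_not and "NOT" in qualifier.split("|"):
                continue
            code = fields[_GAF_EVIDENCE]
            if wanted is not None and code not in wanted:
                continue
            triple = (fields[_GAF_SYMBOL], fields[_GAF_TERM], code)
            if triple not in seen:
                seen.add(triple)
                triples.append(triple)
    return triples


def parse_pairs_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    """Minimal fallback reader: two-column gene<TAB>term file."""
    triples: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: row {lineno} needs 2 columns")
            pair = (fields[0], fields[1])
            if pair not in seen:
                seen.add(pair)
                triples.append((*pair, "ND"))
    return triples


def propagate_annotations(
    ontology: Ontology,
    triples: Sequence[tuple[str, str, str]],
    max_unresolved_fraction: float = 0.05,
) -> AnnotationTable:
    """Transitively close gene-term pairs over is_a/part_of ancestor links.

    Pairs naming unknown or obsolete terms are dropped; if the dropped
    fraction exceeds ``max_unresolved_fraction`` a hard error is raised,
    since that usually means mismatched ontology/annotation versions.
    """
    direct: set[tuple[str, str]] = set()
    provenance: dict[tuple[str, str], set[str]] = {}
    dropped = 0
    for gene, term, code in triples:
        rec = ontology.terms.get(term)
        if rec is None or rec.obsolete:
            dropped += 1
            continue
        pair = (gene, term)
        direct.add(pair)
        provenance.setdefault(pair, set()).add(code)
    if triples and dropped / len(triples) > max_unresolved_fraction:
        raise OntologyError(
            f"{dropped}/{len(triples)} annotation rows reference unknown or "
            "obsolete terms; ontology and annotation versions likely mismatch"
        )

    ancestors = ontology.ancestor_map()
    pairs: set[tuple[str, str]] = set()
    for gene, term in direct:
        pairs.add((gene, term))
        for anc in ancestors[term]:
            pairs.add((gene, anc))
    return AnnotationTable(
        pairs=pairs,
        direct=direct,
        provenance={p: frozenset(v) for p, v in provenance.items()},
    )


def extract_branch(ontology: Ontology, parent_id: str) -> Branch:
    """The branch rooted at ``parent_id``: the term plus all descendants."""
    rec = ontology.terms.get(parent_id)
    if rec is None:
        raise OntologyError(f"unknown term accession: {parent_id}")
    if rec.obsolete:
        raise OntologyError(f"term {parent_id} is obsolete")
    members = set(ontology.descendants(parent_id))
    members.add(parent_id)
    members = {t for t in members if not ontology.terms[t].obsolete}
    return Branch(parent_id=parent_id, members=frozenset(members))


def list_branches(
    ontology: Ontology,
    min_size: int = 1,
    max_size: int | None = None,
) -> list[Branch]:
    """One branch per non-obsolete term, filtered to min_size <= size <= max_size."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    # One reverse-topological pass: descendants(node) = union over children.
    sub = ontology._propagating_subgraph()
    below: dict[str, set[str]] = {}
    for node in nx.topological_sort(sub):
        acc: set[str] = set()
        for child, _ in sub.in_edges(node):
            acc.add(child)
            acc |= below[child]
        below[node] = acc
    branches = []
    for term_id in ontology.active_terms():
        members = frozenset(
            {term_id} | {t for t in below[term_id] if not ontology.terms[t].obsolete}
        )
        if len(members) < min_size:
            continue
        if max_size is not None and len(members) > max_size:
            continue
        branches.append(Branch(parent_id=term_id, members=members))
    return branches
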
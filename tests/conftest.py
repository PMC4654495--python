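"""Shared fixtures: toy ontologies and a small planted-structure bundle."""

from __future__ import annotations

import networkx as nx
import pytest

from termcommunities.ontology_io import Ontology, TermRecord
from termcommunities.synthetic import SMALL, make_bundle


def build_ontology(
    edges: list[tuple[str, str]],
    namespaces: dict[str, str] | None = None,
    names: dict[str, str] | None = None,
    obsolete: set[str] | None = None,
    relations: dict[tuple[str, str], str] | None = None,
) -> Ontology:
    """Assemble an Ontology from (child, parent) is_a edges for tests."""
    namespaces = namespaces or {}
    names = names or {}
    obsolete = obsolete or set()
    relations = relations or {}
    nodes = {t for e in edges for t in e} | set(namespaces) | set(names)
    graph = nx.MultiDiGraph()
    terms = {}
    for t in sorted(nodes):
        terms[t] = TermRecord(
            term_id=t,
            name=names.get(t, f"term {t}"),
            namespace=namespaces.get(t, "BP"),
            obsolete=t in obsolete,
        )
        graph.add_node(t)
    for child, parent in edges:
        graph.add_edge(child, parent, key=relations.get((child, parent), "is_a"))
    return Ontology(terms=terms, graph=graph)


@pytest.fixture
def chain_ontology():
    """A <- B <- C (C most specific)."""
    return build_ontology([("B", "A"), ("C", "B")])


@pytest.fixture
def diamond_ontology():
    """A <- {B, C} <- D."""
    return build_ontology([("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Default planted-block synthetic world, generated once per session."""
    out = tmp_path_factory.mktemp("bundle")
    return make_bundle(SMALL, out, signature_size_range=(60, 150))
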
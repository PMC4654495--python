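"""Download-free synthetic fixtures.

Generates the three inputs the pipeline consumes — an ontology in OBO
format, gene-term annotations in GAF format, and gene signatures in GMT
format — with planted structure whose ground truth is known:

* a random DAG with one root per namespace and randomized is_a edges
  between adjacent depth strata;
* planted-block annotations: genes and leaf terms are partitioned into
  blocks, with dense annotation inside a block and sparse annotation
  across blocks, and per-term Pareto propensities so the number of
  genes per term is heavy-tailed (the regime that motivates the
  inverse-degree weighting of the term network projection);
* signatures that oversample genes of chosen blocks (signal) or sample
  genes uniformly (null).

Everything is a pure function of (config, seed); files written twice
with the same seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .ontology_io import (
    AnnotationTable,
    Ontology,
    TermRecord,
    propagate_annotations,
)
from .enrichment import GeneSignature

__all__ = ["SyntheticConfig", "TINY", "SMALL", "LARGE", "make_ontology",
           "make_annotations", "make_signatures", "write_obo", "write_gaf",
           "write_gmt", "write_block_labels", "make_bundle"]

_NS_LONG = {"BP": "biological_process", "MF": "molecular_function",
            "CC": "cellular_component"}
_NS_ORDER = ("BP", "MF", "CC")

#: name vocabulary; two or three words per term keeps word clouds non-trivial
_VOCAB = [
    "transport", "binding", "membrane", "kinase", "signaling", "repair",
    "replication", "mitotic", "checkpoint", "adhesion", "junction",
    "antiporter", "calcium", "response", "stimulus", "immune", "defense",
    "nuclear", "ribosome", "metabolic", "oxidative", "stress", "cycle",
    "division", "recombination", "chromatin", "receptor", "channel",
    "polymerase", "ligase", "transferase", "vesicle", "golgi", "lysosome",
    "mitochondrial", "cytoplasmic", "regulation", "activation", "assembly",
    "nucleotide-excision", "damage", "integrin", "insulin", "adherens",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world; ``seed`` is mandatory.

    ``p_within``/``p_between`` are per-(gene, leaf term) direct
    annotation probabilities inside and across planted blocks, before
    the per-term heavy-tail propensity multiplier (Pareto tail index
    ``tail_exponent``).
    """

    n_terms: int = 200
    n_genes: int = 240
    n_namespaces: int = 3
    dag_depth: int = 4
    branching: int = 3
    n_blocks: int = 4
    p_within: float = 0.3
    p_between: float = 0.005
    tail_exponent: float = 1.5
    gene_tail_exponent: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("annotation probabilities must be in [0, 1]")
        if not 1 <= self.n_namespaces <= 3:
            raise ValueError("n_namespaces must be 1..3")


TINY = SyntheticConfig(n_terms=60, n_genes=80, dag_depth=2, branching=5,
                       n_blocks=3)
SMALL = SyntheticConfig()
LARGE = SyntheticConfig(n_terms=2000, n_genes=3000, dag_depth=6,
                        branching=4, n_blocks=8)


def make_ontology(cfg: SyntheticConfig) -> Ontology:
    """Random layered DAG with one root per namespace.

    Terms are spread over namespaces and depth strata; every non-root
    term draws one or two parents from the stratum above, so the typed
    graph is acyclic by construction and every term reaches its root.
    """
    per_level_capacity = sum(cfg.branching ** d for d in range(cfg.dag_depth + 1))
    if cfg.n_terms > cfg.n_namespaces * per_level_capacity:
        raise ValueError(
            f"n_terms={cfg.n_terms} does not fit {cfg.n_namespaces} trees of "
            f"depth {cfg.dag_depth} with branching {cfg.branching}"
        )
    rng = np.random.default_rng(cfg.seed)
    namespaces = _NS_ORDER[: cfg.n_namespaces]
    term_ids = [f"GO:{i + 1:07d}" for i in range(cfg.n_terms)]
    terms: dict[str, TermRecord] = {}
    graph = nx.MultiDiGraph()

    # round-robin namespace assignment, then per-namespace depth strata
    by_ns: dict[str, list[str]] = {ns: [] for ns in namespaces}
    for i, tid in enumerate(term_ids):
        by_ns[namespaces[i % len(namespaces)]].append(tid)

    for ns, ids in by_ns.items():
        levels: list[list[str]] = [[ids[0]]]  # single root
        rest = ids[1:]
        # grow level sizes geometrically up to dag_depth
        sizes = []
        remaining = len(rest)
        for d in range(1, cfg.dag_depth + 1):
            want = min(remaining, cfg.branching ** d)
            sizes.append(want)
            remaining -= want
        # spread any leftover over the deepest level
        if remaining > 0:
            sizes[-1] += remaining
        cursor = 0
        for size in sizes:
            levels.append(rest[cursor: cursor + size])
            cursor += size
        for tid in ids:
            words = rng.choice(_VOCAB, size=rng.integers(2, 4), replace=False)
            terms[tid] = TermRecord(term_id=tid, name=" ".join(words),
                                    namespace=ns)
            graph.add_node(tid)
        for depth in range(1, len(levels)):
            parents_pool = levels[depth - 1]
            for tid in levels[depth]:
                n_parents = 1 + int(rng.random() < 0.3 and len(parents_pool) > 1)
                chosen = rng.choice(len(parents_pool), size=n_parents,
                                    replace=False)
                for c in chosen:
                    graph.add_edge(tid, parents_pool[int(c)], key="is_a")
    return Ontology(terms=terms, graph=graph)


def leaf_terms(ontology: Ontology) -> list[str]:
    """Non-obsolete terms with no children under the propagating relations."""
    sub = ontology._propagating_subgraph()
    return sorted(t for t in ontology.active_terms() if sub.in_degree(t) == 0)


def make_annotations(
    ontology: Ontology, cfg: SyntheticConfig, max_retries: int = 20
) -> tuple[AnnotationTable, dict[str, int], dict[str, int]]:
    """Planted-block direct annotations, transitively closed.

    Returns the closed table plus the planted block label of every gene
    and of every leaf term.  Blocks with zero annotations are resampled
    (bounded retries).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    leaves = leaf_terms(ontology)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    gene_block = {g: i % cfg.n_blocks for i, g in enumerate(genes)}
    term_block = {t: i % cfg.n_blocks for i, t in enumerate(leaves)}

    for attempt in range(max_retries):
        propensity = np.minimum(1.0 + rng.pareto(cfg.tail_exponent,
                                                 size=len(leaves)), 50.0)
        if cfg.gene_tail_exponent is not None:
            gene_propensity = np.minimum(
                1.0 + rng.pareto(cfg.gene_tail_exponent, size=len(genes)), 50.0)
        else:
            gene_propensity = np.ones(len(genes))
        triples: list[tuple[str, str, str]] = []
        block_hits = np.zeros(cfg.n_blocks, dtype=np.int64)
        for ti, term in enumerate(leaves):
            base = np.where(
                np.array([gene_block[g] for g in genes]) == term_block[term],
                cfg.p_within, cfg.p_between,
            )
            prob = np.minimum(base * propensity[ti] * gene_propensity, 1.0)
            hits = rng.random(len(genes)) < prob
            for gi in np.nonzero(hits)[0]:
                triples.append((genes[int(gi)], term, "IEA"))
                block_hits[term_block[term]] += 1
        if np.all(block_hits > 0):
            break
        import warnings

        warnings.warn(
            f"attempt {attempt + 1}: a planted block drew no annotations; "
            "resampling", stacklevel=2,
        )
    else:
        raise RuntimeError("could not draw annotations covering every block")

    table = propagate_annotations(ontology, triples)
    return table, gene_block, term_block


def make_signatures(
    annotations: AnnotationTable,
    gene_block: dict[str, int],
    target_blocks: list[int],
    n_signal: int = 4,
    n_null: int = 4,
    size_range: tuple[int, int] = (100, 1000),
    block_fraction: float = 0.8,
    seed: int = 0,
) -> list[GeneSignature]:
    """Signal signatures oversample target-block genes; null ones are uniform.

    Sizes are drawn uniformly from ``size_range`` clipped to the
    annotated gene pool; a lower bound beyond the pool is a config error.
    """
    rng = np.random.default_rng(seed + 2)
    pool = sorted(annotations.genes)
    lo, hi = size_range
    if lo > len(pool):
        raise ValueError(
            f"requested minimum signature size {lo} exceeds the annotated "
            f"gene pool ({len(pool)})"
        )
    hi = min(hi, len(pool))
    sigs: list[GeneSignature] = []
    for i in range(n_signal):
        block = target_blocks[i % len(target_blocks)]
        size = int(rng.integers(lo, hi + 1))
        block_genes = [g for g in pool if gene_block.get(g) == block]
        n_from_block = min(int(round(block_fraction * size)), len(block_genes))
        chosen = set(rng.choice(block_genes, size=n_from_block, replace=False))
        others = [g for g in pool if g not in chosen]
        fill = min(size - len(chosen), len(others))
        if fill > 0:
            chosen |= set(rng.choice(others, size=fill, replace=False))
        sigs.append(GeneSignature(
            name=f"SIG_BLOCK{block}_{i + 1}", genes=frozenset(chosen),
            source=f"synthetic signal block={block}",
        ))
    for i in range(n_null):
        size = int(rng.integers(lo, hi + 1))
        chosen = frozenset(rng.choice(pool, size=min(size, len(pool)),
                                      replace=False))
        sigs.append(GeneSignature(
            name=f"SIG_NULL_{i + 1}", genes=chosen, source="synthetic null",
        ))
    return sigs


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Serialize to OBO 1.2 such that parse_obo round-trips exactly."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for tid in sorted(ontology.terms):
        rec = ontology.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {rec.term_id}")
        lines.append(f"name: {rec.name}")
        lines.append(f"namespace: {_NS_LONG[rec.namespace]}")
        if rec.obsolete:
            lines.append("is_obsolete: true")
        else:
            for _, parent, key in sorted(
                ontology.graph.out_edges(tid, keys=True)
            ):
                if key == "is_a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: {key} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_gaf(table: AnnotationTable, path: str | Path,
              taxon: str = "taxon:9606") -> None:
    """Write the direct pairs as GAF 2.2 rows (evidence from provenance)."""
    rows = []
    for gene, term in sorted(table.direct):
        codes = sorted(table.provenance.get((gene, term), {"IEA"}))
        for code in codes:
            fields = [""] * 17
            fields[0] = "SYNTH"
            fields[1] = gene
            fields[2] = gene
            fields[3] = ""
            fields[4] = term
            fields[5] = "SYNTH:0000001"
            fields[6] = code
            fields[8] = "P"
            fields[12] = taxon
            fields[13] = "20150528"
            fields[14] = "SYNTH"
            rows.append("\t".join(fields))
    Path(path).write_text(
        "!gaf-version: 2.2\n" + "\n".join(rows) + "\n"
    )


def write_gmt(signatures: list[GeneSignature], path: str | Path) -> None:
    lines = []
    for sig in signatures:
        lines.append("\t".join([sig.name, sig.source, *sorted(sig.genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_block_labels(gene_block: dict[str, int], term_block: dict[str, int],
                       path: str | Path) -> None:
    """Ground-truth labels TSV (kind, id, block) so tests never re-infer them."""
    lines = ["kind\tid\tblock"]
    for g in sorted(gene_block):
        lines.append(f"gene\t{g}\t{gene_block[g]}")
    for t in sorted(term_block):
        lines.append(f"term\t{t}\t{term_block[t]}")
    Path(path).write_text("\n".join(lines) + "\n")


def make_bundle(cfg: SyntheticConfig, out_dir: str | Path,
                n_signal: int = 4, n_null: int = 4,
                signature_size_range: tuple[int, int] = (100, 1000)) -> dict:
    """Generate and write a complete fixture set; returns in-memory objects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ontology = make_ontology(cfg)
    table, gene_block, term_block = make_annotations(ontology, cfg)
    signatures = make_signatures(
        table, gene_block,
        target_blocks=sorted(set(term_block.values())),
        n_signal=n_signal, n_null=n_null,
        size_range=signature_size_range, seed=cfg.seed,
    )
    write_obo(ontology, out / "ontology.obo")
    write_gaf(table, out / "annotations.gaf")
    write_gmt(signatures, out / "signatures.gmt")
    write_block_labels(gene_block, term_block, out / "block_labels.tsv")
    return {
        "ontology": ontology,
        "annotations": table,
        "signatures": signatures,
        "gene_block": gene_block,
        "term_block": term_block,
        "config": cfg,
    }
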
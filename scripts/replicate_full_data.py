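"""Replication path for a full human Gene Ontology annotation compendium.

This script is NOT part of the test suite: it needs a user-supplied GO
release (OBO) and human GAF file, which are large downloads, and the
full term network makes the agglomeration slow (hours, not seconds).
Given those inputs it reports the compendium-scale tallies the pipeline
produces:

* number of annotated genes and terms in the bipartite incidence after
  transitive propagation;
* number of ontology branches with >= 10 members, and the size of any
  requested branch;
* number of communities at maximum modularity for r = 0 (note: the exact
  count can depend on tie-breaking among equal modularity gains).

Usage:
    python scripts/replicate_full_data.py --obo go-basic.obo \
        --gaf goa_human.gaf --branch GO:0050896 --out full_data.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import termcommunities as tc
from termcommunities.community import WeightedGraph, fast_greedy
from termcommunities.ontology_io import extract_branch, list_branches


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--obo", type=Path, required=True)
    parser.add_argument("--gaf", type=Path, required=True)
    parser.add_argument("--branch", action="append", default=[],
                        help="Report the member count of this branch "
                             "(repeatable).")
    parser.add_argument("--skip-communities", action="store_true",
                        help="Skip the (slow) r=0 community detection.")
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    ontology = tc.parse_obo(args.obo)
    triples = tc.parse_gaf(args.gaf)
    table = tc.propagate_annotations(ontology, triples)
    bip = tc.build_bipartite(table)
    report = {
        "n_annotated_genes": bip.n_genes,
        "n_annotated_terms": bip.n_terms,
        "n_branches_ge_10_members": len(list_branches(ontology, min_size=10)),
    }
    for parent in args.branch:
        report[f"branch_size_{parent}"] = len(extract_branch(ontology, parent))
    if not args.skip_communities:
        net = tc.project_term_network(bip)
        partition, _ = fast_greedy(WeightedGraph.from_term_network(net), r=0.0)
        report["n_communities_r0_max_modularity"] = partition.n_communities
        report["q_r0_max_modularity"] = partition.Q
    args.out.write_text(json.dumps(report, indent=1))
    print(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
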
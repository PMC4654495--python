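"""Signature parsing, AEA permutation enrichment and the Fisher baseline."""

import numpy as np
import pytest

import termcommunities as tc
from termcommunities.enrichment import (
    BipartiteNullEngine,
    GeneSignature,
    aea,
    enrichment_matrix,
    filter_signatures,
    fisher_enrichment,
    parse_gmt,
)
from termcommunities.ontology_io import ParseError
from termcommunities.synthetic import leaf_terms, write_gmt


class TestParseGmt:
    def test_duplicates_collapse_and_symbols_uppercase(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("sig1\tsrc\tTp53\tTP53\tbrca1\tEGFR\tMYC\n")
        sigs = parse_gmt(path)
        assert sigs[0].genes == {"TP53", "BRCA1", "EGFR", "MYC"}

    def test_short_line_is_parse_error(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("sig1\tdescription-without-genes\n")
        with pytest.raises(ParseError, match="line 1"):
            parse_gmt(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert parse_gmt(path) == []

    def test_writer_reader_roundtrip(self, tmp_path, small_bundle):
        sigs = small_bundle["signatures"]
        write_gmt(sigs, tmp_path / "sigs.gmt")
        back = parse_gmt(tmp_path / "sigs.gmt")
        assert [(s.name, s.genes) for s in back] == [
            (s.name, s.genes) for s in sigs]


class TestFilterSignatures:
    def sig(self, n, name="s"):
        return GeneSignature(name=name, genes=frozenset(f"G{i}" for i in range(n)))

    def test_bounds_inclusive_on_annotated_intersection(self):
        universe = {f"G{i}" for i in range(1000)}
        kept = filter_signatures(
            [self.sig(50, "low"), self.sig(100, "edge"), self.sig(400, "mid")],
            universe, min_genes=100, max_genes=1000)
        assert [s.name for s in kept] == ["edge", "mid"]

    def test_unannotated_genes_do_not_count(self):
        universe = {f"G{i}" for i in range(120)}  # G0..G119
        sig = self.sig(150)  # only 120 of these are annotated
        kept = filter_signatures([sig], universe, min_genes=100, max_genes=1000)
        assert len(kept) == 1 and len(kept[0].genes) == 120


@pytest.fixture(scope="module")
def planted(small_bundle):
    bip = tc.build_bipartite(small_bundle["annotations"])
    return {
        "bip": bip,
        "engine": BipartiteNullEngine(bip),
        "gene_block": small_bundle["gene_block"],
        "term_block": small_bundle["term_block"],
        "ontology": small_bundle["ontology"],
    }


class TestAEA:
    def test_no_annotation_overlap_gives_p_one(self, planted):
        bip = planted["bip"]
        # a term group with no annotations at all cannot be enriched
        with pytest.warns(UserWarning):
            res = aea(bip, frozenset(bip.gene_index[:30]), frozenset(),
                      n_rand=100, seed=1, engine=planted["engine"])
        assert res.statistic == 0 and res.p_value == 1.0

    def test_planted_block_hits_the_empirical_floor(self, planted):
        bip, gene_block, term_block = (
            planted["bip"], planted["gene_block"], planted["term_block"])
        genes = frozenset(g for g, b in gene_block.items()
                          if b == 0 and g in set(bip.gene_index))
        terms = frozenset(t for t, b in term_block.items()
                          if b == 0 and t in set(bip.term_index))
        res = aea(bip, genes, terms, n_rand=999, seed=3,
                  engine=planted["engine"])
        assert res.p_value == 1 / 1000
        assert res.statistic > res.null_mean + 10 * res.null_sd

    def test_seeded_determinism(self, planted):
        bip = planted["bip"]
        genes = frozenset(bip.gene_index[:40])
        terms = frozenset(bip.term_index[:25])
        r1 = aea(bip, genes, terms, n_rand=150, seed=42, engine=planted["engine"])
        r2 = aea(bip, genes, terms, n_rand=150, seed=42, engine=planted["engine"])
        assert r1 == r2

    def test_unknown_genes_or_terms_rejected(self, planted):
        bip = planted["bip"]
        with pytest.raises(KeyError):
            aea(bip, frozenset({"NOT_A_GENE"}), frozenset(bip.term_index[:5]),
                n_rand=100, seed=0, engine=planted["engine"])

    def test_pvalue_bounded_below_by_pseudocount(self, planted):
        bip = planted["bip"]
        res = aea(bip, frozenset(bip.gene_index[:20]),
                  frozenset(bip.term_index[:10]), n_rand=100, seed=5,
                  engine=planted["engine"])
        assert 1 / 101 <= res.p_value <= 1.0

    def test_randomization_preserves_both_degree_sequences(self, planted):
        engine = planted["engine"]
        bip = planted["bip"]
        orig_gene_deg = np.bincount(engine._edge_genes,
                                    minlength=bip.n_genes)
        orig_term_deg = np.bincount(engine._edge_terms,
                                    minlength=bip.n_terms)
        for seed in (1, 2, 3):
            genes, terms = engine.randomized_edges(seed)
            assert np.array_equal(
                np.bincount(genes, minlength=bip.n_genes), orig_gene_deg)
            assert np.array_equal(
                np.bincount(terms, minlength=bip.n_terms), orig_term_deg)
            # and the matrix actually changed
            assert not np.array_equal(terms, engine._edge_terms)


class TestFisher:
    def test_full_overlap_with_rare_group_is_significant(self, planted):
        bip = planted["bip"]
        # rarest leaf term: its annotated genes form a small, exact overlap
        leaves = [t for t in leaf_terms(planted["ontology"])
                  if t in set(bip.term_index)]
        degrees = dict(zip(bip.term_index, bip.term_degrees))
        rare = min(leaves, key=lambda t: degrees[t])
        pos = bip.term_pos(frozenset({rare}))
        hit = np.asarray(bip.B[:, pos].sum(axis=1)).ravel() > 0
        annotated = frozenset(g for g, h in zip(bip.gene_index, hit) if h)
        p = fisher_enrichment(annotated, frozenset({rare}), bip)
        from scipy.stats import hypergeom

        n_universe, n_hit = bip.n_genes, len(annotated)
        expected = float(hypergeom.sf(n_hit - 1, n_universe, n_hit, n_hit))
        assert p == pytest.approx(expected, rel=1e-9)
        assert p < 1e-4

    def test_empty_overlap_upper_tail_at_least_half(self):
        import scipy.sparse as sp
        from termcommunities.projection import BipartiteAnnotation

        dense = np.zeros((40, 2), dtype=np.int8)
        dense[:20, 0] = 1  # G0..G19 annotated to t0
        dense[:, 1] = 1    # keep every gene indexed
        bip = BipartiteAnnotation(
            B=sp.csr_matrix(dense),
            gene_index=[f"G{i}" for i in range(40)],
            term_index=["t0", "t1"],
        )
        sig = frozenset(f"G{i}" for i in range(20, 40))  # disjoint from t0
        assert fisher_enrichment(sig, frozenset({"t0"}), bip) >= 0.5

    def test_degenerate_margins_warn_and_return_one(self, planted):
        bip = planted["bip"]
        with pytest.warns(UserWarning):
            # every gene is annotated to the root-containing group
            roots = planted["ontology"].roots
            p = fisher_enrichment(frozenset(bip.gene_index[:50]),
                                  frozenset(roots), bip)
        assert p == 1.0


class TestEnrichmentMatrix:
    def test_planted_signal_fills_community_axis_only(self, planted):
        bip = planted["bip"]
        gene_block, term_block = planted["gene_block"], planted["term_block"]
        genes = frozenset(g for g, b in gene_block.items()
                          if b == 1 and g in set(bip.gene_index))
        block_terms = frozenset(t for t, b in term_block.items()
                                if b == 1 and t in set(bip.term_index))
        other_terms = frozenset(t for t, b in term_block.items()
                                if b == 2 and t in set(bip.term_index))
        sig = GeneSignature(name="planted", genes=genes)
        matrix = enrichment_matrix(
            [sig],
            groups={"TC:0000001": block_terms, "GO:X": other_terms},
            group_kind={"TC:0000001": "community", "GO:X": "branch"},
            bip=bip, n_rand=499, seed=9,
            # cutoffs scaled to the empirical floor 1/(n_rand+1) = 0.002
            p_loose=0.05, p_strict=0.005,
        )
        assert matrix.percent_enriched("community")[0] == 100.0
        assert matrix.percent_enriched("branch")[0] == 0.0
        assert matrix.only_flags("community")[0]
        assert not matrix.only_flags("branch")[0]

    def test_groups_outside_size_window_dropped(self, planted):
        bip = planted["bip"]
        sig = GeneSignature(name="s", genes=frozenset(bip.gene_index[:30]))
        matrix = enrichment_matrix(
            [sig],
            groups={"tiny": frozenset(bip.term_index[:3]),
                    "ok": frozenset(bip.term_index[:15])},
            group_kind={"tiny": "community", "ok": "community"},
            bip=bip, n_rand=100, seed=0,
        )
        assert matrix.group_ids == ["ok"]

    def test_cell_seeds_do_not_depend_on_grid_position(self, planted):
        bip = planted["bip"]
        sig = GeneSignature(name="s", genes=frozenset(bip.gene_index[:30]))
        groups = {"a": frozenset(bip.term_index[:15]),
                  "b": frozenset(bip.term_index[15:30])}
        kind = {"a": "community", "b": "branch"}
        m = enrichment_matrix([sig], groups, kind, bip, n_rand=100, seed=3)
        m2 = enrichment_matrix([sig], groups, kind, bip, n_rand=100, seed=3)
        assert np.array_equal(m.p_values, m2.p_values)
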
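"""Ontology parsing, DAG ancestry and true-path propagation."""

import io

import networkx as nx
import numpy as np
import pytest

from genefunc.ontology import (
    OntologyError,
    build_ontology,
    load_annotations,
    parse_obo,
    Term,
)

from conftest import DIAMOND_OBO, FIVE_TERM_OBO


class TestParseObo:
    def test_five_term_fixture(self, five_term_ontology):
        onto = five_term_ontology
        assert len(onto) == 5
        assert len(onto.edges) == 4
        assert onto.root == "T:0000001"

    def test_obsolete_term_present_flagged_and_edgeless(self):
        obo = FIVE_TERM_OBO + (
            "\n[Term]\nid: T:0000006\nname: gone\nnamespace: biological_process\n"
            "is_obsolete: true\nis_a: T:0000001\n"
        )
        onto = parse_obo(io.StringIO(obo))
        assert "T:0000006" in onto
        assert onto.terms["T:0000006"].obsolete
        assert all(c != "T:0000006" for c, _, _ in onto.edges)

    def test_mixed_relations_kept(self):
        obo = (
            "[Term]\nid: R\nname: r\n\n"
            "[Term]\nid: X\nname: x\nis_a: R\n\n"
            "[Term]\nid: Y\nname: y\nrelationship: part_of R\n\n"
            "[Term]\nid: Z\nname: z\nrelationship: regulates X\n"
        )
        onto = parse_obo(io.StringIO(obo), namespace=None)
        relations = {rel for _, _, rel in onto.edges}
        assert relations == {"is_a", "part_of", "regulates"}

    def test_cycle_is_hard_error(self):
        obo = "[Term]\nid: A\nis_a: B\n\n[Term]\nid: B\nis_a: A\n"
        with pytest.raises(OntologyError, match="cycle"):
            parse_obo(io.StringIO(obo), namespace=None)

    def test_multiple_roots_is_hard_error(self):
        obo = "[Term]\nid: A\nname: a\n\n[Term]\nid: B\nname: b\n"
        with pytest.raises(OntologyError, match="root"):
            parse_obo(io.StringIO(obo), namespace=None)

    def test_namespace_filter_drops_foreign_terms(self):
        obo = FIVE_TERM_OBO + (
            "\n[Term]\nid: M:1\nname: other\nnamespace: molecular_function\n"
            "is_a: T:0000001\n"
        )
        onto = parse_obo(io.StringIO(obo), namespace="biological_process")
        assert "M:1" not in onto

    def test_agrees_with_obonet_on_shared_fixture(self, diamond_ontology):
        obonet = pytest.importorskip("obonet")
        g = obonet.read_obo(io.StringIO(DIAMOND_OBO))
        for node in g.nodes:
            expected = nx.descendants(g, node)  # obonet edges point child->parent
            assert diamond_ontology.ancestors(node) == set(expected)


class TestAncestors:
    def test_root_has_none(self, five_term_ontology):
        assert five_term_ontology.ancestors("T:0000001") == set()

    def test_diamond_closure(self, diamond_ontology):
        assert diamond_ontology.ancestors("D") == {"B", "C", "A"}

    def test_grandchild(self, five_term_ontology):
        assert five_term_ontology.ancestors("T:0000004") == {"T:0000002", "T:0000001"}

    def test_unknown_term_raises(self, five_term_ontology):
        with pytest.raises(KeyError):
            five_term_ontology.ancestors("T:9999999")

    def test_matches_brute_force_on_random_dags(self):
        """Oracle: reachability by DFS over the raw edge list."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            terms = {f"N{i}": Term(id=f"N{i}") for i in range(n)}
            edges = []
            for i in range(1, n):
                n_par = int(rng.integers(1, min(i, 3) + 1))
                for p in rng.choice(i, size=n_par, replace=False):
                    edges.append((f"N{i}", f"N{int(p)}", "is_a"))
            onto = build_ontology(terms, edges, namespace=None)

            adj = {}
            for child, parent, _ in edges:
                adj.setdefault(child, set()).add(parent)
            for tid in terms:
                reach, stack = set(), list(adj.get(tid, ()))
                while stack:
                    cur = stack.pop()
                    if cur not in reach:
                        reach.add(cur)
                        stack.extend(adj.get(cur, ()))
                assert onto.ancestors(tid) == reach


class TestAnnotations:
    def test_true_path_rule(self, small_store):
        assert "g1" in small_store.annotated_genes("T:0000002")
        assert "g1" in small_store.annotated_genes("T:0000001")

    def test_duplicates_stored_once(self, five_term_ontology):
        tsv = "g1\tT:0000004\ng1\tT:0000004\n"
        store = load_annotations(io.StringIO(tsv), five_term_ontology)
        assert store.direct["g1"] == {"T:0000004"}

    def test_obsolete_annotation_dropped(self):
        obo = FIVE_TERM_OBO + (
            "\n[Term]\nid: T:0000006\nname: gone\nnamespace: biological_process\n"
            "is_obsolete: true\n"
        )
        onto = parse_obo(io.StringIO(obo))
        store = load_annotations(io.StringIO("g1\tT:0000004\ng2\tT:0000006\n"), onto)
        assert store.skipped_obsolete == 1
        assert "g2" not in store.universe

    def test_unknown_term_warn_and_skip(self, five_term_ontology):
        store = load_annotations(
            io.StringIO("g1\tT:0000004\ng2\tT:9999999\n"), five_term_ontology
        )
        assert store.skipped_unknown == 1
        assert store.universe == {"g1"}

    def test_empty_store_is_hard_error(self, five_term_ontology):
        with pytest.raises(ValueError):
            load_annotations(io.StringIO("g1\tT:9999999\n"), five_term_ontology)

    def test_gaf_reader_uses_symbol_and_term_skips_not(self, five_term_ontology):
        pad = "\t".join([""] * 10)
        gaf = (
            "!gaf-version: 2.1\n"
            f"DB\tg1\tG1\t\tT:0000004\tref\tIEA\t\tP\t\t{pad}\n"
            f"DB\tg2\tG2\tNOT\tT:0000005\tref\tIEA\t\tP\t\t{pad}\n"
        )
        store = load_annotations(io.StringIO(gaf), five_term_ontology)
        assert store.universe == {"g1"}

    def test_root_annotates_universe(self, small_store):
        assert small_store.annotated_genes("T:0000001") == {"g1", "g2", "g3"}

    def test_unannotated_leaf_empty(self, five_term_ontology):
        store = load_annotations(io.StringIO("g1\tT:0000004\n"), five_term_ontology)
        assert store.annotated_genes("T:0000005") == set()


class TestPropagationInvariants:
    def test_idempotence(self, small_store):
        again = small_store._propagate()
        assert again == small_store.propagated

    def test_monotone_along_edges(self, small_store):
        onto = small_store.ontology
        for child, parent, _ in onto.edges:
            assert len(small_store.annotated_genes(parent)) >= len(
                small_store.annotated_genes(child)
            )
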
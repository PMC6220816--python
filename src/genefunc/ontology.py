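"""Ontology parsing, DAG queries and true-path-rule annotation propagation.

The ontology is a rooted directed acyclic graph of terms connected by
``is_a``, ``part_of`` and ``regulates`` edges.  All three relations are
treated identically for ancestry and propagation: an annotation of a gene
to a term implicitly annotates the gene to every ancestor of that term
(the true-path rule), so the root term always annotates the entire gene
universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

#: Edge relations that participate in ancestry and propagation.
RELATIONS = ("is_a", "part_of", "regulates")


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, missing/multiple roots)."""


@dataclass(frozen=True)
class Term:
    id: str
    name: str = ""
    namespace: str = ""
    obsolete: bool = False


@dataclass
class Ontology:
    """Rooted DAG of terms.

    ``graph`` stores child -> parent edges (edge attribute ``relation``),
    so graph-descendants of a term are its ontology ancestors.  Obsolete
    terms are kept as isolated records but carry no edges.
    """

    terms: dict[str, Term]
    graph: nx.DiGraph
    root: str
    namespace: str | None = None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        """(child, parent, relation) triples."""
        return [(c, p, d["relation"]) for c, p, d in self.graph.edges(data=True)]

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive closure of parents over all edge relations.

        Excludes the term itself; the root is in the result for every
        non-root, non-obsolete term.
        """
        if term_id not in self.terms:
            raise KeyError(f"unknown term: {term_id!r}")
        if term_id not in self.graph:
            return set()
        return set(nx.descendants(self.graph, term_id))

    def descendants(self, term_id: str) -> set[str]:
        """Terms whose ancestor set contains ``term_id`` (excludes itself)."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term: {term_id!r}")
        if term_id not in self.graph:
            return set()
        return set(nx.ancestors(self.graph, term_id))

    def depths(self) -> dict[str, int]:
        """Longest-path depth from the root for every non-obsolete term."""
        depth: dict[str, int] = {}
        # child->parent edges: process parents before children
        for node in reversed(list(nx.topological_sort(self.graph))):
            parents = list(self.graph.successors(node))
            depth[node] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth

    def depth(self, term_id: str) -> int:
        """Longest path length from the root down to ``term_id``."""
        return self.depths()[term_id]


def _validate(graph: nx.DiGraph, terms: dict[str, Term]) -> str:
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyError(f"ontology contains a cycle: {path}")
    live = [t for t in terms.values() if not t.obsolete]
    roots = [t.id for t in live if graph.out_degree(t.id) == 0]
    if len(roots) != 1:
        raise OntologyError(
            f"expected exactly one root term, found {len(roots)}: {sorted(roots)[:5]}"
        )
    return roots[0]


def build_ontology(
    terms: dict[str, Term], edges: list[tuple[str, str, str]], namespace: str | None = None
) -> Ontology:
    """Assemble and validate an :class:`Ontology` from records and edges."""
    graph = nx.DiGraph()
    for t in terms.values():
        if not t.obsolete:
            graph.add_node(t.id)
    for child, parent, relation in edges:
        if relation not in RELATIONS:
            continue
        if child in graph and parent in graph:
            graph.add_edge(child, parent, relation=relation)
    root = _validate(graph, terms)
    return Ontology(terms=terms, graph=graph, root=root, namespace=namespace)


def parse_obo(stream, namespace: str | None = "biological_process") -> Ontology:
    """Parse an OBO 1.2 flat file into a validated :class:`Ontology`.

    Parameters
    ----------
    stream
        Iterable of text lines (an open file handle works).
    namespace
        Keep only terms declared in this namespace; terms without a
        ``namespace:`` line are kept unconditionally.  ``None`` disables
        the filter.  Edges crossing out of the kept set are dropped.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()

    terms: dict[str, Term] = {}
    edges: list[tuple[str, str, str]] = []
    cur: dict | None = None
    in_term = False

    def flush():
        nonlocal cur
        if cur is None or "id" not in cur:
            cur = None
            return
        ns = cur.get("namespace", "")
        if namespace is not None and ns and ns != namespace:
            cur = None
            return
        tid = cur["id"]
        terms[tid] = Term(
            id=tid,
            name=cur.get("name", ""),
            namespace=ns,
            obsolete=cur.get("obsolete", False),
        )
        if not cur.get("obsolete", False):
            edges.extend((tid, parent, rel) for rel, parent in cur.get("parents", []))
        cur = None

    for raw in stream:
        line = raw.split("!", 1)[0].strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            cur = {"parents": []} if in_term else None
            continue
        if not in_term or cur is None or not line:
            continue
        if ":" not in line:
            continue
        key, value = line.split(":", 1)
        key, value = key.strip(), value.strip()
        if key == "id":
            cur["id"] = value
        elif key == "name":
            cur["name"] = value
        elif key == "namespace":
            cur["namespace"] = value
        elif key == "is_obsolete":
            cur["obsolete"] = value.lower() == "true"
        elif key == "is_a":
            cur["parents"].append(("is_a", value))
        elif key == "relationship":
            parts = value.split()
            if len(parts) >= 2 and parts[0] in RELATIONS:
                cur["parents"].append((parts[0], parts[1]))
    flush()

    if not terms:
        raise OntologyError("no [Term] stanzas found")
    return build_ontology(terms, edges, namespace=namespace)


@dataclass
class AnnotationStore:
    """Gene -> term annotations with true-path propagation.

    ``direct`` maps gene -> directly annotated terms; ``propagated`` maps
    term -> all genes annotated at or below it; ``universe`` is the
    background gene set (size N for overrepresentation analysis).
    """

    ontology: Ontology
    direct: dict[str, set[str]]
    propagated: dict[str, set[str]] = field(default_factory=dict)
    skipped_unknown: int = 0
    skipped_obsolete: int = 0

    def __post_init__(self):
        if not self.propagated:
            self.propagated = self._propagate()

    def _propagate(self) -> dict[str, set[str]]:
        prop: dict[str, set[str]] = {t: set() for t in self.ontology.graph.nodes}
        for gene, tids in self.direct.items():
            closure: set[str] = set()
            for tid in tids:
                closure.add(tid)
                closure |= self.ontology.ancestors(tid)
            for tid in closure:
                prop[tid].add(gene)
        return prop

    @property
    def universe(self) -> set[str]:
        return set(self.direct)

    def annotated_genes(self, term_id: str) -> set[str]:
        """Propagated gene set for a term (root returns the universe)."""
        if term_id not in self.ontology.terms:
            raise KeyError(f"unknown term: {term_id!r}")
        return set(self.propagated.get(term_id, set()))


def load_annotations(stream, ontology: Ontology) -> AnnotationStore:
    """Read gene->term annotations (2-column TSV or GAF 2.x) and propagate.

    GAF lines (detected by the ``!gaf-version`` header or >= 15 columns)
    use column 2 (gene symbol) and column 5 (term id); rows whose qualifier
    contains ``NOT`` are skipped.  Annotations to unknown terms are skipped
    with a warning count; annotations to obsolete terms are dropped.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()

    direct: dict[str, set[str]] = {}
    unknown = obsolete = 0
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "!")):
            continue
        cols = line.split("\t")
        if len(cols) >= 15:  # GAF 2.x
            if "NOT" in cols[3].split("|"):
                continue
            gene, tid = cols[1], cols[4]
        elif len(cols) >= 2:
            gene, tid = cols[0], cols[1]
        else:
            continue
        gene, tid = gene.strip(), tid.strip()
        if not gene or not tid:
            continue
        term = ontology.terms.get(tid)
        if term is None:
            unknown += 1
            continue
        if term.obsolete:
            obsolete += 1
            continue
        direct.setdefault(gene, set()).add(tid)

    if unknown:
        logger.warning("skipped %d annotations to unknown terms", unknown)
    if obsolete:
        logger.warning("dropped %d annotations to obsolete terms", obsolete)
    if not direct:
        raise ValueError("annotation stream yielded no resolvable annotations")
    return AnnotationStore(
        ontology=ontology, direct=direct, skipped_unknown=unknown, skipped_obsolete=obsolete
    )


def annotated_genes(store: AnnotationStore, term_id: str) -> set[str]:
    """Propagated gene set of ``term_id`` (module-level convenience)."""
    return store.annotated_genes(term_id)
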
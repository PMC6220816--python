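"""Induced term DAG and functional abstraction.

The significant terms of an overrepresentation analysis live somewhere in
the middle of a large ontology.  To show how they hang together, the
minimal sub-DAG connecting them to the root is induced (non-significant
terms needed only for connectivity are marked as connectors).  The DAG is
then summarized by *functional areas*: headline terms whose descendant
closures jointly cover every significant term, chosen greedily to balance
coverage, branch purity and generality.  The root never qualifies as a
headline — it covers everything and says nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import pandas as pd

from .enrichment import EnrichedTerm
from .ontology import AnnotationStore, Ontology


@dataclass
class InducedDag:
    """Sub-DAG of the ontology spanning the significant terms.

    Node roles: ``significant`` (overrepresented), ``connector``
    (non-significant, kept for connectivity), plus the boolean
    ``leaf`` marker for induced nodes with no induced children.
    """

    graph: nx.DiGraph  # child -> parent edges, restricted to induced nodes
    roles: dict[str, str]
    leaves: set[str]
    stats: dict[str, dict]  # term -> {k, expected, p_raw}
    root: str
    ontology: Ontology
    headlines: set[str] = field(default_factory=set)  # filled by functional_areas

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def significant(self) -> set[str]:
        return {t for t, r in self.roles.items() if r == "significant"}

    def _display_role(self, node: str) -> str:
        return "headline" if node in self.headlines else self.roles[node]

    def to_dot(self, path) -> None:
        colors = {"significant": "red", "connector": "white", "headline": "yellow"}
        with open(path, "w") as fh:
            fh.write("digraph induced {\n  rankdir=BT;\n")
            for node in sorted(self.graph.nodes):
                color = colors.get(self._display_role(node), "white")
                pen = "blue" if node in self.leaves else "black"
                name = self.ontology.terms[node].name or node
                fh.write(
                    f'  "{node}" [label="{name}", style=filled, fillcolor={color}, color={pen}, shape=ellipse];\n'
                )
            for child, parent in sorted(self.graph.edges):
                fh.write(f'  "{child}" -> "{parent}";\n')
            fh.write("}\n")

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for node in self.graph.nodes:
            g.add_node(
                node,
                role=self._display_role(node),
                leaf=node in self.leaves,
                name=self.ontology.terms[node].name,
                **{k: v for k, v in self.stats.get(node, {}).items()},
            )
        g.add_edges_from(self.graph.edges)
        nx.write_graphml(g, path)


@dataclass
class FunctionalArea:
    """A headline term summarizing a branch of significant terms."""

    headline: str
    name: str
    covered: set[str]  # significant terms in the headline's closure
    coverage: float  # |covered| / |all significant|
    precision: float  # significant density of the branch
    depth: int
    score: float = 0.0


def induce_dag(significant: list[EnrichedTerm], ontology: Ontology) -> InducedDag:
    """Induce the minimal ancestor-closed sub-DAG over significant terms."""
    if not significant:
        raise ValueError("no significant terms to induce a DAG from")
    sig_ids = {r.term for r in significant}
    for tid in sig_ids:
        if tid not in ontology.terms:
            raise KeyError(f"term not in ontology: {tid!r}")

    nodes: set[str] = set()
    for tid in sig_ids:
        nodes.add(tid)
        nodes |= ontology.ancestors(tid)
    graph = ontology.graph.subgraph(nodes).copy()

    roles = {t: ("significant" if t in sig_ids else "connector") for t in nodes}
    # leaves: induced nodes nobody in the induced set points up to
    leaves = {t for t in nodes if graph.in_degree(t) == 0}
    stats = {
        r.term: {"k": r.k, "expected": r.expected, "p_raw": r.p_raw} for r in significant
    }
    return InducedDag(
        graph=graph, roles=roles, leaves=leaves, stats=stats, root=ontology.root, ontology=ontology
    )


def functional_areas(
    dag: InducedDag, max_areas: int = 7, min_coverage: float = 1.0
) -> list[FunctionalArea]:
    """Greedy weighted set-cover of the significant terms by headlines.

    Candidate headlines are all induced nodes except the root.  Each is
    scored as ``coverage * precision / (1 + depth)``: coverage is the
    fraction of all significant terms in the candidate's descendant
    closure (self included), precision the significant fraction of the
    induced nodes in that closure, and the depth factor prefers terms
    close to the root among otherwise equal covers.  Headlines are picked
    while they add uncovered terms, until everything is covered,
    ``min_coverage`` is reached, or ``max_areas`` headlines were chosen.
    Ties break on the term id, so the result is deterministic.
    """
    sig = dag.significant()
    if not sig:
        return []
    depths = dag.ontology.depths()

    closures: dict[str, set[str]] = {}
    for node in dag.nodes:
        if node == dag.root:
            continue
        closure = set(nx.ancestors(dag.graph, node)) | {node}  # induced descendants
        closures[node] = closure

    areas: list[FunctionalArea] = []
    uncovered = set(sig)
    while uncovered and len(areas) < max_areas:
        best: tuple[float, str] | None = None
        for node, closure in closures.items():
            covered = closure & sig
            gain = covered & uncovered
            if not gain:
                continue
            coverage = len(covered) / len(sig)
            precision = len(covered) / len(closure)
            score = coverage * precision / (1 + depths[node])
            key = (-score, node)
            if best is None or key < best:
                best = key
                pick = (node, covered, coverage, precision, score)
        if best is None:
            break
        node, covered, coverage, precision, score = pick
        areas.append(
            FunctionalArea(
                headline=node,
                name=dag.ontology.terms[node].name,
                covered=covered,
                coverage=coverage,
                precision=precision,
                depth=depths[node],
                score=score,
            )
        )
        dag.headlines.add(node)
        uncovered -= covered
        if 1 - len(uncovered) / len(sig) >= min_coverage:
            break
    return areas


def gene_area_matrix(
    areas: list[FunctionalArea], genes: Iterable[str], store: AnnotationStore
) -> pd.DataFrame:
    """Binary genes x areas association matrix (1 = gene under headline)."""
    if not areas:
        raise ValueError("no functional areas supplied")
    gene_order = sorted(set(genes))
    frame = pd.DataFrame(0, index=gene_order, columns=[a.headline for a in areas], dtype=int)
    for area in areas:
        members = store.annotated_genes(area.headline)
        hit = [g for g in gene_order if g in members]
        frame.loc[hit, area.headline] = 1
    return frame


def load_area_table(path) -> pd.DataFrame:
    """Read a packaged gene x functional-area 0/1 grid (TSV)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df


def write_areas_tsv(areas: list[FunctionalArea], path) -> None:
    pd.DataFrame(
        [
            {
                "headline": a.headline,
                "name": a.name,
                "n_covered": len(a.covered),
                "coverage": a.coverage,
                "precision": a.precision,
                "depth": a.depth,
                "score": a.score,
            }
            for a in areas
        ]
    ).to_csv(path, sep="\t", index=False)
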
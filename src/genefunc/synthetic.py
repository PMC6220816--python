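"""Synthetic ontologies, annotation corpora and evidence tables.

Every pipeline stage can be exercised without downloading a real ontology
release: the generator plants functionally enriched gene modules in a
large annotated background and emits an evidence table whose per-gene
setting counts follow the empirically typical pattern (most genes
reported in a single clinical setting, a minority in several).  The
planted truth (module membership and module terms) is returned so tests
can score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .evidence import EvidenceRecord, EvidenceTable, DEFAULT_SETTINGS
from .ontology import AnnotationStore, Ontology, Term, build_ontology


@dataclass
class SynthSpec:
    """Shape of the generated ontology, annotations and evidence.

    Defaults give a 250-term, depth-5 ontology over 1000 genes with three
    planted 20-gene modules, each enriched (p_in = 0.9) in its own block
    of 8 terms against a sparse background (p_out = 0.01), and an
    evidence table where 80% of genes have one clinical setting and the
    rest 2-5.
    """

    n_terms: int = 250
    depth: int = 5
    max_parents: int = 2
    n_genes: int = 1000
    n_modules: int = 3
    module_size: int = 20
    terms_per_module: int = 8
    p_in: float = 0.9
    p_out: float = 0.01
    n_settings: int = 8
    singleton_frac: float = 0.8
    max_settings: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0 <= self.singleton_frac <= 1:
            raise ValueError("singleton_frac must be in [0, 1]")
        if self.module_size * self.n_modules > self.n_genes:
            raise ValueError("modules cannot exceed the gene universe")
        if self.n_terms < 2:
            raise ValueError("need at least a root and one child term")


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure, for oracle tests."""

    module_genes: dict[int, list[str]]  # module index -> gene ids
    module_terms: dict[int, list[str]]  # module index -> term ids

    def gene_labels(self) -> dict[str, int]:
        return {g: m for m, genes in self.module_genes.items() for g in genes}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _term_id(i: int) -> str:
    return f"T:{i:07d}"


def generate_ontology(spec: SynthSpec) -> Ontology:
    """Rooted random DAG: terms added level by level, parents drawn from
    the previous level (plus optional extra parents from any shallower
    level), so the graph is acyclic by construction and the target depth
    is met within one level."""
    rng = np.random.default_rng(spec.seed)
    root = _term_id(0)
    terms = {root: Term(id=root, name="root process", namespace="synthetic")}
    edges: list[tuple[str, str, str]] = []

    n_rest = spec.n_terms - 1
    depth = max(1, spec.depth)
    # spread the non-root terms over `depth` levels, wider toward the leaves
    weights = np.arange(1, depth + 1, dtype=float)
    sizes = np.maximum(1, np.floor(n_rest * weights / weights.sum()).astype(int))
    while sizes.sum() > n_rest:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_rest:
        sizes[np.argmin(sizes)] += 1

    levels: list[list[str]] = [[root]]
    next_id = 1
    relations = ("is_a", "part_of", "regulates")
    for size in sizes:
        level: list[str] = []
        prev = levels[-1]
        shallow = [t for lvl in levels for t in lvl]
        for _ in range(size):
            tid = _term_id(next_id)
            next_id += 1
            terms[tid] = Term(id=tid, name=f"process {next_id - 1}", namespace="synthetic")
            main = prev[int(rng.integers(len(prev)))]
            edges.append((tid, main, relations[int(rng.integers(len(relations)))]))
            extra = int(rng.integers(0, spec.max_parents))  # 0 .. max_parents-1 extras
            if extra:
                choices = [t for t in shallow if t != main]
                for p in rng.choice(choices, size=min(extra, len(choices)), replace=False):
                    edges.append((tid, str(p), "is_a"))
            level.append(tid)
        levels.append(level)
    return build_ontology(terms, edges, namespace="synthetic")


def generate_annotations(
    ontology: Ontology, spec: SynthSpec
) -> tuple[AnnotationStore, PlantedTruth]:
    """Plant disjoint enriched modules in a sparse annotation background.

    Module genes hit each of their module's terms with probability
    ``p_in`` and every other term with ``p_out``; background genes hit
    every term with ``p_out``.  Genes left without any annotation drop
    out of the universe, exactly as they would with a real corpus.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    non_root = sorted(t for t in ontology.terms if t != ontology.root)
    need = spec.n_modules * spec.terms_per_module
    if need > len(non_root):
        raise ValueError("not enough terms for the requested modules")
    picked = rng.choice(len(non_root), size=need, replace=False)
    module_terms = {
        m: sorted(non_root[i] for i in picked[m * spec.terms_per_module : (m + 1) * spec.terms_per_module])
        for m in range(spec.n_modules)
    }
    module_genes = {
        m: genes[m * spec.module_size : (m + 1) * spec.module_size]
        for m in range(spec.n_modules)
    }
    gene_module = {g: m for m, gs in module_genes.items() for g in gs}

    direct: dict[str, set[str]] = {}
    terms_arr = non_root
    for g in genes:
        mod = gene_module.get(g)
        own = set(module_terms[mod]) if mod is not None else set()
        hits = set()
        u = rng.random(len(terms_arr))
        for t, x in zip(terms_arr, u):
            p = spec.p_in if t in own else spec.p_out
            if x < p:
                hits.add(t)
        if hits:
            direct[g] = hits
    if not direct:
        raise ValueError("generated corpus is empty; raise p_in/p_out")
    store = AnnotationStore(ontology=ontology, direct=direct)
    return store, PlantedTruth(module_genes=module_genes, module_terms=module_terms)


def generate_evidence(spec: SynthSpec, genes: list[str]) -> EvidenceTable:
    """Evidence table with mostly single-setting genes.

    ``floor(singleton_frac * n)`` genes get one setting; the remainder get
    a uniform 2..max_settings distinct settings each.
    """
    if spec.n_settings < 2:
        raise ValueError("need at least two settings")
    rng = np.random.default_rng(spec.seed + 2)
    settings = list(DEFAULT_SETTINGS[: spec.n_settings])
    if len(settings) < spec.n_settings:
        settings += [f"setting{i}" for i in range(len(settings), spec.n_settings)]
    n = len(genes)
    n_single = int(np.floor(spec.singleton_frac * n))
    order = list(rng.permutation(n))
    records: list[EvidenceRecord] = []
    for rank, idx in enumerate(order):
        gene = genes[idx]
        if rank < n_single:
            count = 1
        else:
            count = int(rng.integers(2, spec.max_settings + 1))
        chosen = rng.choice(len(settings), size=count, replace=False)
        for s in chosen:
            records.append(
                EvidenceRecord(gene=gene, ncbi=idx, setting=settings[int(s)], reference=f"synth:{gene}")
            )
    present = tuple(s for s in settings if any(r.setting == s for r in records))
    return EvidenceTable(
        records=sorted(records, key=lambda r: (r.gene, r.setting)),
        settings=present,
        genes=tuple(sorted({r.gene for r in records})),
    )


def write_obo(ontology: Ontology, path) -> None:
    """Serialize an ontology in the OBO 1.2 dialect the parser reads."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for tid in sorted(ontology.terms):
            term = ontology.terms[tid]
            fh.write(f"\n[Term]\nid: {term.id}\nname: {term.name}\n")
            if term.namespace:
                fh.write(f"namespace: {term.namespace}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")
                continue
            for child, parent, rel in sorted(ontology.edges):
                if child != tid:
                    continue
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def write_annotations(store: AnnotationStore, path) -> None:
    """Two-column gene<TAB>term TSV of the direct annotations."""
    with open(path, "w") as fh:
        for gene in sorted(store.direct):
            for tid in sorted(store.direct[gene]):
                fh.write(f"{gene}\t{tid}\n")


def write_evidence(table: EvidenceTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tncbi\tsetting\treference\n")
        for r in table.records:
            fh.write(f"{r.gene}\t{r.ncbi if r.ncbi is not None else ''}\t{r.setting}\t{r.reference}\n")
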
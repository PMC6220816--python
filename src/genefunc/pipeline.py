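"""End-to-end orchestration of the two analytical paths.

Path 1 (functional clustering): evidence genes -> ORA against the
annotation store -> binary gene x process matrix -> toroid ESOM ->
U*/watershed gene clusters.

Path 2 (informative genes): settings x genes matrix -> computed ABC
selection of the most consistently implicated genes -> second ORA ->
induced term DAG -> functional areas; optionally repeated on the
intersection with an external gene list.

Every artifact lands in the output directory and is listed in a manifest
with SHA-256 checksums, so a rerun with the same config and seed can be
verified byte for byte.  The config seed fans out to per-stage seeds via
stable hashing, keeping stages individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import abc_select, abstraction, enrichment, esom, evidence, feature_matrix, ontology

logger = logging.getLogger(__name__)


def derive_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    evidence_path: str | Path
    obo_path: str | Path
    annotations_path: str | Path
    out_dir: str | Path
    gene_list_path: str | Path | None = None
    namespace: str | None = "biological_process"
    ora: enrichment.OraConfig = field(default_factory=enrichment.OraConfig)
    som: esom.SomConfig = field(default_factory=esom.SomConfig)
    ridge_threshold: float = 0.5
    max_areas: int = 7
    min_coverage: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.evidence_path, self.obo_path, self.annotations_path):
            if not Path(p).exists():
                raise FileNotFoundError(str(p))
        if self.gene_list_path is not None and not Path(self.gene_list_path).exists():
            raise FileNotFoundError(str(self.gene_list_path))
        Path(self.out_dir).mkdir(parents=True, exist_ok=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, groups: dict[str, list[Path]], name: str) -> Path:
    manifest = {
        group: {p.name: _sha256(p) for p in paths} for group, paths in groups.items()
    }
    path = out_dir / name
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def _load_inputs(config: PipelineConfig):
    with open(config.obo_path) as fh:
        onto = ontology.parse_obo(fh, namespace=config.namespace)
    with open(config.annotations_path) as fh:
        store = ontology.load_annotations(fh, onto)
    table = evidence.parse_evidence(config.evidence_path)
    return onto, store, table


def run_clustering_path(config: PipelineConfig) -> dict:
    """Evidence -> ORA -> feature matrix -> ESOM -> clusters."""
    out = Path(config.out_dir)
    onto, store, table = _load_inputs(config)
    genes = set(table.genes)
    dropped = sorted(genes - store.universe)
    if dropped:
        logger.warning(
            "%d evidence gene(s) not annotated in the ontology: %s", len(dropped), dropped
        )

    results = enrichment.ora(genes, store, config.ora)
    sig = enrichment.significant_terms(results)
    if not sig:
        raise RuntimeError("stage enrichment: no significant terms")
    ora_path = out / "ora_all_genes.tsv"
    enrichment.write_ora_tsv(results, ora_path)

    matrix = feature_matrix.build_matrix(genes & store.universe, sig, store)
    matrix_path = out / "gene_process_matrix.tsv"
    matrix.to_tsv(matrix_path)

    som_config = esom.SomConfig(
        rows=config.som.rows,
        cols=config.som.cols,
        epochs=config.som.epochs,
        radius_start=config.som.radius_start,
        radius_end=config.som.radius_end,
        rate_start=config.som.rate_start,
        rate_end=config.som.rate_end,
        seed=derive_seed(config.seed, "esom"),
    )
    som = esom.train(matrix, som_config)
    u = esom.umatrix(som)
    p = esom.pmatrix(som, matrix)
    us = esom.ustar(u, p)
    grid_paths = []
    for grid, stem in ((u, "umatrix"), (p, "pmatrix"), (us, "ustar")):
        gp = out / f"{stem}.csv"
        grid.to_csv(gp)
        grid.write_sidecar(out / f"{stem}.json")
        grid_paths += [gp, out / f"{stem}.json"]

    clusters = esom.extract_clusters(som, us, matrix, ridge_threshold=config.ridge_threshold)
    cluster_path = out / "clusters.tsv"
    clusters.to_tsv(cluster_path, som=som)

    manifest = _write_manifest(
        out,
        {
            "ora": [ora_path],
            "matrix": [matrix_path],
            "som_grids": grid_paths,
            "clusters": [cluster_path],
        },
        "clustering_manifest.json",
    )
    return {
        "ora": results,
        "matrix": matrix,
        "som": som,
        "clusters": clusters,
        "dropped_genes": dropped,
        "manifest": manifest,
    }


def run_informative_path(config: PipelineConfig) -> dict:
    """Settings matrix -> ABC selection -> ORA -> DAG -> functional areas."""
    out = Path(config.out_dir)
    onto, store, table = _load_inputs(config)

    matrix = evidence.settings_matrix(table)
    settings_path = out / "settings_matrix.tsv"
    matrix.to_tsv(settings_path)

    abc = abc_select.abc_analysis(
        {g: float(s) for g, s in matrix.column_sums.items()}
    )
    selected = abc.selected
    logger.info("ABC selection: %d gene(s) in sets A or B", len(selected))
    abc_paths = [out / "abc_result.tsv", out / "abc_result.json"]
    abc.to_tsv(abc_paths[0])
    abc.to_json(abc_paths[1])

    results = enrichment.ora(set(selected), store, config.ora)
    sig = enrichment.significant_terms(results)
    ora_path = out / "ora_selected_genes.tsv"
    enrichment.write_ora_tsv(results, ora_path)
    if not sig:
        raise RuntimeError("stage enrichment: no significant terms for selected genes")

    dag = abstraction.induce_dag(sig, onto)
    areas = abstraction.functional_areas(
        dag, max_areas=config.max_areas, min_coverage=config.min_coverage
    )
    dag_paths = [out / "induced_dag.dot", out / "induced_dag.graphml", out / "areas.tsv"]
    dag.to_dot(dag_paths[0])
    dag.to_graphml(dag_paths[1])
    abstraction.write_areas_tsv(areas, dag_paths[2])

    area_matrix = abstraction.gene_area_matrix(areas, selected, store) if areas else None
    area_matrix_path = out / "gene_area_matrix.tsv"
    if area_matrix is not None:
        area_matrix.to_csv(area_matrix_path, sep="\t")

    groups = {
        "settings_matrix": [settings_path],
        "abc": abc_paths,
        "ora": [ora_path],
        "abstraction": dag_paths + ([area_matrix_path] if area_matrix is not None else []),
    }

    intersection = None
    if config.gene_list_path is not None:
        intersection = evidence.intersect_gene_list(selected, config.gene_list_path)
        logger.info("external-list intersection: %d gene(s)", len(intersection))
        if intersection:
            inter_results = enrichment.ora(set(intersection), store, config.ora)
            inter_path = out / "ora_intersection.tsv"
            enrichment.write_ora_tsv(inter_results, inter_path)
            groups["intersection"] = [inter_path]
    else:
        logger.info("no external gene list supplied; intersection stage skipped")

    manifest = _write_manifest(out, groups, "informative_manifest.json")
    return {
        "settings_matrix": matrix,
        "abc": abc,
        "selected": selected,
        "ora": results,
        "dag": dag,
        "areas": areas,
        "area_matrix": area_matrix,
        "intersection": intersection,
        "manifest": manifest,
    }
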
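"""genefunc: ontology-based functional genomics of gene-evidence tables.

The package turns a table of positive gene-phenotype association reports
into a functional-genomics picture in two ways: (1) overrepresentation
analysis of the genes' ontology annotations followed by emergent
self-organizing-map clustering of the gene x process matrix, and (2)
computed ABC selection of the most consistently implicated genes followed
by DAG induction and functional abstraction of their biological roles.
"""

from importlib import resources

from .abc_select import AbcResult, abc_analysis, abc_curve, select_informative
from .abstraction import (
    FunctionalArea,
    InducedDag,
    functional_areas,
    gene_area_matrix,
    induce_dag,
    load_area_table,
)
from .enrichment import EnrichedTerm, OraConfig, fisher_right_tail, ora
from .esom import (
    ClusterAssignment,
    HeightGrid,
    SomConfig,
    TrainedSom,
    extract_clusters,
    pmatrix,
    toroid_distance,
    train,
    umatrix,
    ustar,
)
from .evidence import (
    DEFAULT_SETTINGS,
    EvidenceTable,
    SettingsMatrix,
    genes_in_all_settings,
    intersect_gene_list,
    parse_evidence,
    settings_matrix,
)
from .feature_matrix import GeneProcessMatrix, build_matrix
from .ontology import (
    AnnotationStore,
    Ontology,
    OntologyError,
    Term,
    annotated_genes,
    build_ontology,
    load_annotations,
    parse_obo,
)
from .pipeline import PipelineConfig, run_clustering_path, run_informative_path
from .synthetic import (
    PlantedTruth,
    SynthSpec,
    generate_annotations,
    generate_evidence,
    generate_ontology,
)

__version__ = "0.1.0"


def packaged_data(name: str):
    """Path-like handle to a packaged data file.

    Available files: ``pain_evidence.tsv`` (the transcribed gene-evidence
    table: 110 genes, 8 clinical settings), ``functional_areas.tsv`` (the
    22 selected genes x 7 functional areas 0/1 grid) and
    ``pain_genes_13.txt`` (the external-list intersection symbols).
    """
    return resources.files(__name__) / "data" / name


__all__ = [
    "AbcResult", "abc_analysis", "abc_curve", "select_informative",
    "FunctionalArea", "InducedDag", "functional_areas", "gene_area_matrix",
    "induce_dag", "load_area_table",
    "EnrichedTerm", "OraConfig", "fisher_right_tail", "ora",
    "ClusterAssignment", "HeightGrid", "SomConfig", "TrainedSom",
    "extract_clusters", "pmatrix", "toroid_distance", "train", "umatrix", "ustar",
    "DEFAULT_SETTINGS", "EvidenceTable", "SettingsMatrix", "genes_in_all_settings",
    "intersect_gene_list", "parse_evidence", "settings_matrix",
    "GeneProcessMatrix", "build_matrix",
    "AnnotationStore", "Ontology", "OntologyError", "Term", "annotated_genes",
    "build_ontology", "load_annotations", "parse_obo",
    "PipelineConfig", "run_clustering_path", "run_informative_path",
    "PlantedTruth", "SynthSpec", "generate_annotations", "generate_evidence",
    "generate_ontology",
    "packaged_data",
]
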
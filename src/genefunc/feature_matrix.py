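"""Binary gene x significant-process feature matrix for clustering.

Columns are the significantly overrepresented terms; a cell is 1 when the
gene is (directly or by propagation) annotated to the term.  Columns that
are constant across all genes — notably very general terms such as the
ontology root, which annotate everything — carry no distance information
and are removed before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .enrichment import EnrichedTerm
from .ontology import AnnotationStore

logger = logging.getLogger(__name__)


@dataclass
class GeneProcessMatrix:
    """Ordered binary n-genes x d-processes matrix (the feature space D)."""

    frame: pd.DataFrame  # genes x terms, 0/1, lexicographically ordered

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def values(self):
        return self.frame.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def build_matrix(
    genes: Iterable[str],
    significant: list[EnrichedTerm],
    store: AnnotationStore,
) -> GeneProcessMatrix:
    """Build the gene x process matrix over the significant terms.

    Genes with no remaining annotation after constant-column removal are
    dropped with a warning; if every column is constant there is nothing
    to discriminate and a hard error is raised.
    """
    if not significant:
        raise ValueError("no significant terms supplied")
    gene_order = sorted(set(genes))
    term_order = sorted({r.term for r in significant})
    frame = pd.DataFrame(0, index=gene_order, columns=term_order, dtype=int)
    for term_id in term_order:
        members = store.annotated_genes(term_id)
        hit = [g for g in gene_order if g in members]
        frame.loc[hit, term_id] = 1

    constant = [c for c in frame.columns if frame[c].nunique() == 1]
    if len(constant) == len(frame.columns):
        raise ValueError("no discriminating processes: all columns constant")
    if constant:
        logger.info("removed %d constant column(s): %s", len(constant), constant)
        frame = frame.drop(columns=constant)

    empty = frame.index[frame.sum(axis=1) == 0]
    if len(empty):
        logger.warning(
            "dropped %d gene(s) with no remaining annotation: %s",
            len(empty),
            list(empty),
        )
        frame = frame.drop(index=empty)
    return GeneProcessMatrix(frame=frame)
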
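"""Overrepresentation analysis (ORA) against an annotation store.

For a query of n genes drawn from a background universe of N annotated
genes, a term annotating K background genes and k query genes is scored
with the hypergeometric upper tail

    p = P(X >= k | N, K, n),

the one-sided Fisher exact test for enrichment.  Raw p-values are
thresholded at ``tp`` (default 1e-6) and additionally Bonferroni-corrected
over the m tested terms; a term is significant only if it passes both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import hypergeom

from .ontology import AnnotationStore

logger = logging.getLogger(__name__)


@dataclass
class OraConfig:
    tp: float = 1e-6  # raw p-value threshold
    alpha_adjusted: float = 0.05  # Bonferroni family-wise threshold
    min_term_size: int = 1  # smallest background term size tested

    def __post_init__(self):
        if not 0 < self.tp <= 1:
            raise ValueError("tp must be in (0, 1]")
        if not 0 < self.alpha_adjusted <= 1:
            raise ValueError("alpha_adjusted must be in (0, 1]")
        if self.min_term_size < 1:
            raise ValueError("min_term_size must be >= 1")


@dataclass
class EnrichedTerm:
    """One ORA result row."""

    term: str
    name: str
    k: int  # query genes annotated to the term
    K: int  # background genes annotated to the term
    n: int  # resolved query size
    N: int  # background universe size
    expected: float  # K * n / N
    p_raw: float
    p_adj: float = 1.0
    significant: bool = False
    genes: frozenset[str] = field(default_factory=frozenset)


def fisher_right_tail(k: int, K: int, n: int, N: int) -> float:
    """Hypergeometric upper tail P(X >= k) for N genes, K successes, n drawn.

    Returns 1.0 for k == 0 (the empty overlap is certain to be matched
    or exceeded).
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if not (k <= K <= N and k <= n <= N):
        raise ValueError(f"invalid margins: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy works in log space
    return float(hypergeom.sf(k - 1, N, K, n))


def ora(
    query: set[str], store: AnnotationStore, config: OraConfig | None = None
) -> list[EnrichedTerm]:
    """Test every sufficiently large term for overrepresentation in ``query``.

    Query genes absent from the store's universe are dropped with a
    warning (they carry no usable annotation); an empty resolved query is
    a hard error.  Results are sorted by ascending raw p-value with the
    term id as tiebreak.
    """
    config = config or OraConfig()
    universe = store.universe
    resolved = set(query) & universe
    dropped = len(query) - len(resolved)
    if dropped:
        missing = sorted(set(query) - universe)
        logger.warning(
            "dropped %d query gene(s) without annotation: %s", dropped, missing
        )
    if not resolved:
        raise ValueError(
            f"no query genes resolvable in the annotation universe "
            f"({dropped} of {len(query)} failed resolution)"
        )

    N = len(universe)
    n = len(resolved)
    tested: list[EnrichedTerm] = []
    for term_id in sorted(store.propagated):
        annotated = store.propagated[term_id]
        K = len(annotated)
        if K < config.min_term_size:
            continue
        overlap = resolved & annotated
        k = len(overlap)
        term = store.ontology.terms.get(term_id)
        tested.append(
            EnrichedTerm(
                term=term_id,
                name=term.name if term else "",
                k=k,
                K=K,
                n=n,
                N=N,
                expected=K * n / N,
                p_raw=fisher_right_tail(k, K, n, N),
                genes=frozenset(overlap),
            )
        )

    m = len(tested)
    for row in tested:
        row.p_adj = min(1.0, m * row.p_raw)
        row.significant = row.p_raw <= config.tp and row.p_adj <= config.alpha_adjusted
    tested.sort(key=lambda r: (r.p_raw, r.term))
    return tested


def significant_terms(results: list[EnrichedTerm]) -> list[EnrichedTerm]:
    return [r for r in results if r.significant]


def write_ora_tsv(results: list[EnrichedTerm], path) -> None:
    """Export ORA rows as TSV (term, name, k, K, n, N, expected, p's, flag)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "term": r.term,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "expected": r.expected,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
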
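"""Stress subnetwork induction and hypergeometric term enrichment.

A stress protein-interaction network (SPIN) is induced from a seed list of
stress-responsive genes by keeping every interaction with at least one
endpoint in the seed set, together with its incident proteins — so the SPIN
can contain more proteins than seeds, as interaction partners are pulled in.

Functional overrepresentation in a protein set is tested per term with the
hypergeometric upper tail,

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n),

where N is the annotated universe, K the term's size in the universe, n the
query-set size and k the observed overlap; p-values are corrected with the
Benjamini-Hochberg step-up procedure over all tested terms.  Terms with zero
overlap are not tested.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_model import AnnotationMap, InteractionNetwork, ValidationError

__all__ = [
    "StressGeneSet",
    "EnrichmentRow",
    "induce_spin",
    "hypergeom_enrichment",
]


@dataclass(frozen=True)
class StressGeneSet:
    """Differentially expressed genes under stress (>= 2-fold by convention)."""

    gene_ids: frozenset
    direction: str = "any"  # induced / repressed / any
    fold_change_threshold: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    k: int  # overlap
    n: int  # query size
    big_k: int  # term size in universe
    big_n: int  # universe size
    p: float
    q: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.n, self.big_k):
            raise ValidationError("overlap k outside [0, min(n, K)]")
        if self.q < self.p - 1e-12:
            raise ValidationError("BH-adjusted q cannot undercut p")


def induce_spin(net: InteractionNetwork, seeds: StressGeneSet) -> InteractionNetwork:
    """Subnetwork of edges touching at least one seed, plus incident nodes."""
    seed_ids = seeds.gene_ids
    kept_edges = []
    nodes: set[str] = set()
    for e in net.edges:
        u, v = tuple(e)
        if u in seed_ids or v in seed_ids:
            kept_edges.append((u, v))
            nodes.add(u)
            nodes.add(v)
    return InteractionNetwork(nodes, kept_edges)


def hypergeom_enrichment(
    query: set[str],
    ann: AnnotationMap,
    universe: set[str] | None = None,
) -> list[EnrichmentRow]:
    """Per-term hypergeometric enrichment of ``query`` with BH correction.

    ``universe`` defaults to all annotated proteins; the query is restricted
    to the universe.  Rows are sorted by (q, p, term).
    """
    if universe is None:
        universe = ann.annotated_proteins
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    big_n = len(universe)
    n = len(query)
    tested: list[tuple[str, int, int]] = []
    for term in sorted(ann.terms):
        members = {p for p, t, _ in ann.records if t == term} & universe
        k = len(members & query)
        if k >= 1:
            tested.append((term, k, len(members)))
    if not tested:
        return []
    pvals = [
        float(hypergeom.sf(k - 1, big_n, big_k, n)) for _, k, big_k in tested
    ]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        EnrichmentRow(term, k, n, big_k, big_n, p=min(p, 1.0), q=min(q, 1.0))
        for (term, k, big_k), p, q in zip(tested, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.q, r.p, r.term_id))
    return rows
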
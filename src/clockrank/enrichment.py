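"""Annotation-based functional validation of candidates.

For a gene g with closed neighborhood H(g) = {g} ∪ neighbors(g), the
enrichment score of an annotation term A is the negative log10 of the
upper-tail hypergeometric probability that at least m of the n = |H(g)|
proteins carry A, given M annotated proteins among the N network proteins:

    S(g, A) = -log10  sum_{k=m}^{n}  C(M,k) C(N-M, n-k) / C(N, n)

The per-term scores form the enrichment vector ES(g); functional similarity
between two genes is the cosine of their (nonnegative) enrichment vectors,
Γ(g, g') = ES(g)·ES(g') / (||ES(g)|| ||ES(g')||).  A candidate's maximum
annotation similarity (MAS) is its largest Γ over all seed proteins; the
final filter requires MAS >= threshold (default 0.75, inclusive) in *both*
the GO and the pathway namespace.

Terms are opaque labels — no ontology-graph propagation is performed; the
background size N is the full network node count, and annotations of genes
absent from the network are ignored when counting M and m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom

from .network_io import AnnotationMap, InteractionNetwork, SeedSet

__all__ = [
    "EnrichmentVector",
    "FunctionalSimilarityRecord",
    "neighborhood",
    "enrichment_score",
    "enrichment_vector",
    "functional_similarity",
    "mas_scores",
    "mas_filter",
]

#: -log10 score assigned when the hypergeometric tail underflows to zero.
#: Cosine similarity is scale sensitive, so the cap keeps one unbounded
#: term from dominating an entire vector.
SCORE_CAP = 300.0


@dataclass
class EnrichmentVector:
    """Sparse term -> S(g, A) map for one gene in one namespace; terms not
    stored score zero."""

    gene: str
    namespace: str
    scores: dict[str, float]

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.scores.values()))


@dataclass
class FunctionalSimilarityRecord:
    candidate: str
    namespace: str
    gamma_by_seed: dict[str, float]

    @property
    def mas(self) -> float:
        return max(self.gamma_by_seed.values()) if self.gamma_by_seed else 0.0

    @property
    def best_seed(self) -> str | None:
        if not self.gamma_by_seed:
            return None
        return max(self.gamma_by_seed, key=self.gamma_by_seed.get)


def neighborhood(net: InteractionNetwork, g: str) -> set[str]:
    """Closed neighborhood H(g) = {g} ∪ neighbors(g)."""
    if not net.has_node(g):
        raise KeyError(f"node {g!r} not in network")
    return {g} | set(net.neighbors(g))


def enrichment_score(
    N: int, M: int, n: int, m: int, cap: float = SCORE_CAP
) -> float:
    """-log10 P(X >= m) for X hypergeometric(N, M, n), computed via the
    survival function; 0 when m = 0 (the tail probability is 1) and capped
    at ``cap`` when the tail underflows."""
    if not (0 <= m <= n <= N):
        raise ValueError(f"need 0 <= m <= n <= N, got m={m}, n={n}, N={N}")
    if not (0 <= M <= N):
        raise ValueError(f"need 0 <= M <= N, got M={M}, N={N}")
    if m > M:
        raise ValueError(f"need m <= M, got m={m}, M={M}")
    if m == 0:
        return 0.0
    p = float(hypergeom.sf(m - 1, N, M, n))
    if p <= 0.0:
        return cap
    return min(cap, -math.log10(p))


def enrichment_vector(
    net: InteractionNetwork,
    ann: AnnotationMap,
    g: str,
    term_universe: Sequence[str] | None = None,
) -> EnrichmentVector:
    """ES(g): S(g, A) for every term A in the universe.

    By default the universe is the set of terms annotating any member of
    H(g) — every other term has m = 0 and hence score 0, so the sparse
    vector is exact.  Terms annotating no network node score 0.
    """
    H = neighborhood(net, g)
    N = net.n_nodes
    n = len(H)
    if term_universe is None:
        term_universe = sorted({t for h in H for t in ann.terms_of(h)})
    scores: dict[str, float] = {}
    node_set = set(net.nodes)
    for term in term_universe:
        genes = ann.genes_of(term) & node_set
        M = len(genes)
        m = len(H & genes)
        s = enrichment_score(N, M, n, m) if M else 0.0
        if s > 0.0:
            scores[term] = s
    return EnrichmentVector(gene=g, namespace=ann.namespace, scores=scores)


def functional_similarity(es1: EnrichmentVector, es2: EnrichmentVector) -> float:
    """Cosine similarity Γ of two enrichment vectors aligned on the union of
    their term sets (missing terms score 0); 0 when either vector is
    all-zero.  Lies in [0, 1] since all scores are nonnegative."""
    if es1.namespace != es2.namespace:
        raise ValueError(
            f"namespace mismatch: {es1.namespace!r} vs {es2.namespace!r}"
        )
    n1 = es1.norm()
    n2 = es2.norm()
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    dot = sum(v * es2.scores.get(t, 0.0) for t, v in es1.scores.items())
    return min(1.0, dot / (n1 * n2))


def mas_scores(
    candidates: Sequence[str],
    seeds: SeedSet | Sequence[str],
    net: InteractionNetwork,
    ann: AnnotationMap,
) -> list[FunctionalSimilarityRecord]:
    """Γ of every candidate against every seed in one namespace."""
    seed_ids = seeds.mapped if isinstance(seeds, SeedSet) else list(seeds)
    seed_es = {c: enrichment_vector(net, ann, c) for c in seed_ids}
    out: list[FunctionalSimilarityRecord] = []
    for g in candidates:
        es_g = enrichment_vector(net, ann, g)
        gamma = {c: functional_similarity(es_g, es_c) for c, es_c in seed_es.items()}
        out.append(
            FunctionalSimilarityRecord(
                candidate=g, namespace=ann.namespace, gamma_by_seed=gamma
            )
        )
    return out


def mas_filter(
    candidates: Sequence[str],
    seeds: SeedSet | Sequence[str],
    net: InteractionNetwork,
    ann_go: AnnotationMap,
    ann_pathway: AnnotationMap,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Dual-namespace MAS filter.

    A candidate is kept iff its MAS reaches ``threshold`` (inclusive) in the
    GO namespace *and* in the pathway namespace.  A candidate with no
    computable enrichment in a namespace gets MAS 0 there (and is therefore
    dropped), never an error.  Returns one row per candidate with columns
    node, mas_go, mas_pathway, best_seed_go, best_seed_pathway, kept.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    rec_go = {r.candidate: r for r in mas_scores(candidates, seeds, net, ann_go)}
    rec_pw = {r.candidate: r for r in mas_scores(candidates, seeds, net, ann_pathway)}
    rows = []
    for g in candidates:
        mg = rec_go[g].mas
        mp = rec_pw[g].mas
        rows.append(
            {
                "node": g,
                "mas_go": mg,
                "mas_pathway": mp,
                "best_seed_go": rec_go[g].best_seed,
                "best_seed_pathway": rec_pw[g].best_seed,
                "kept": bool(mg >= threshold and mp >= threshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "node",
            "mas_go",
            "mas_pathway",
            "best_seed_go",
            "best_seed_pathway",
            "kept",
        ],
    )
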
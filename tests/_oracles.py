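"""Independent oracles used only by the test suite.

The orbit-count oracle enumerates *all* node subsets of size 2-4 with
itertools, keeps the connected ones (networkx), and classifies each member
through an invariant lookup table derived from the brute-force-automorphism
graphlet catalog — a completely different code path from the package's
rooted extension-set enumeration.

The hypergeometric oracle evaluates the upper-tail probability in exact
integer arithmetic.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx

from clockrank.graphlets import build_catalog

_CAT = build_catalog()


def _orbit_lookup() -> dict:
    """(n_nodes, n_edges, sorted degree sequence, node degree) -> orbit id.

    This key is unique across all orbits of the 2-4-node graphlets, which
    the construction asserts.
    """
    table: dict = {}
    for gi, (_, n, edges) in enumerate(_CAT.graphlets):
        deg = {v: sum(v in e for e in edges) for v in range(n)}
        degseq = tuple(sorted(deg.values()))
        for v in range(n):
            key = (n, len(edges), degseq, deg[v])
            orb = _CAT.orbit_of[(gi, v)]
            assert table.get(key, orb) == orb, "invariant key collision"
            table[key] = orb
    return table


_LOOKUP = _orbit_lookup()


def brute_orbit_counts(g: nx.Graph) -> dict:
    """Per-node length-15 orbit counts by exhaustive subset enumeration."""
    counts = {v: [0] * 15 for v in g.nodes()}
    nodes = list(g.nodes())
    for size in (2, 3, 4):
        for subset in itertools.combinations(nodes, size):
            sub = g.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            degseq = tuple(sorted(d for _, d in sub.degree()))
            m = sub.number_of_edges()
            for v in subset:
                counts[v][_LOOKUP[(size, m, degseq, sub.degree(v))]] += 1
    return counts


def exact_upper_tail(N: int, M: int, n: int, m: int) -> Fraction:
    """P(X >= m) for X ~ hypergeometric(N, M, n), exactly."""
    num = sum(
        math.comb(M, k) * math.comb(N - M, n - k)
        for k in range(m, min(n, M) + 1)
        if n - k <= N - M
    )
    return Fraction(num, math.comb(N, n))


def exact_enrichment_score(N: int, M: int, n: int, m: int, cap: float = 300.0) -> float:
    if m == 0:
        return 0.0
    p = exact_upper_tail(N, M, n, m)
    if p == 0:
        return cap
    return min(cap, -math.log10(float(p)))
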
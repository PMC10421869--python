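"""Graphlet catalog, per-node orbit signatures (GDVs) and the
signature-similarity machinery used for wiring-pattern candidate mining.

A *graphlet* is a small connected non-isomorphic induced subgraph; on 2-4
nodes there are 9 graphlets whose vertices fall into 15 automorphism
orbits.  A node's graphlet degree vector (GDV) counts, for each orbit, the
induced subgraphs through the node in which it occupies that orbit; the
degree itself is orbit 0.  Similarity between two signatures u, v is

    S_GDV(u, v) = 1 - sum_i |u_i - v_i| / sum_i (u_i + v_i)

i.e. one minus a Bray-Curtis distance, computed by default on the 11
non-redundant orbits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._orbits import N_ORBITS, orbit_counts
from .network_io import InteractionNetwork, SeedSet

__all__ = [
    "NONREDUNDANT_ORBITS",
    "GraphletCatalog",
    "OrbitVector",
    "GDVSimilarityRecord",
    "build_catalog",
    "count_orbits",
    "gdv_matrix",
    "gdv_similarity",
    "seed_similarities",
    "select_threshold",
    "raw_gdv_candidates",
]

#: Orbits retained in the reduced 11-element signature.  Of the 15 orbits on
#: 2-4-node graphlets, four (triangle, the two diamond orbits, and K4) are
#: linearly dependent on the rest and conventionally dropped.
NONREDUNDANT_ORBITS: tuple[int, ...] = (0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11)

# canonical edge sets of the nine 2-4-node graphlets, in the standard order
_GRAPHLET_EDGES: list[tuple[str, int, list[tuple[int, int]]]] = [
    ("edge", 2, [(0, 1)]),
    ("path-P3", 3, [(0, 1), (1, 2)]),
    ("triangle", 3, [(0, 1), (1, 2), (0, 2)]),
    ("path-P4", 4, [(0, 1), (1, 2), (2, 3)]),
    ("claw", 4, [(0, 1), (0, 2), (0, 3)]),
    ("cycle-C4", 4, [(0, 1), (1, 2), (2, 3), (3, 0)]),
    ("paw", 4, [(0, 1), (1, 2), (2, 0), (0, 3)]),
    ("diamond", 4, [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3)]),
    ("K4", 4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]),
]


@dataclass(frozen=True)
class GraphletCatalog:
    """The nine 2-4-node graphlets with their automorphism orbits.

    ``orbit_of[(g, v)]`` gives the global orbit id (0-14) of vertex ``v`` of
    graphlet ``g`` (graphlets indexed in catalog order).
    """

    graphlets: tuple[tuple[str, int, frozenset[frozenset[int]]], ...]
    orbit_of: dict[tuple[int, int], int]
    nonredundant_orbits: tuple[int, ...] = NONREDUNDANT_ORBITS

    @property
    def n_orbits(self) -> int:
        return len(set(self.orbit_of.values()))

    def orbits_of_graphlet(self, g: int) -> list[set[int]]:
        """Vertex classes of graphlet ``g``, one set per orbit."""
        classes: dict[int, set[int]] = {}
        for (gi, v), orb in self.orbit_of.items():
            if gi == g:
                classes.setdefault(orb, set()).add(v)
        return [classes[o] for o in sorted(classes)]


def _automorphism_orbits(n: int, edges: set[frozenset[int]]) -> list[set[int]]:
    """Vertex orbits under the full automorphism group, by brute-force
    permutation of the <=4 labels."""
    verts = list(range(n))
    reach = {v: {v} for v in verts}
    for perm in itertools.permutations(verts):
        mapping = dict(zip(verts, perm))
        if {frozenset(mapping[x] for x in e) for e in edges} == edges:
            for v in verts:
                reach[v].add(mapping[v])
    merged: list[set[int]] = []
    for v in verts:
        if not any(v in c for c in merged):
            merged.append(set(reach[v]))
    return merged


def build_catalog() -> GraphletCatalog:
    """Enumerate the connected graphs on 2-4 nodes and their automorphism
    orbits, assigning global orbit ids in the standard literature order
    (within each graphlet, orbits are numbered by increasing vertex degree).
    """
    graphlets = []
    orbit_of: dict[tuple[int, int], int] = {}
    next_orbit = 0
    for name, n, edge_list in _GRAPHLET_EDGES:
        edges = {frozenset(e) for e in edge_list}
        classes = _automorphism_orbits(n, edges)
        deg = {v: sum(v in e for e in edges) for v in range(n)}
        classes.sort(key=lambda c: deg[next(iter(c))])
        for cls in classes:
            for v in cls:
                orbit_of[(len(graphlets), v)] = next_orbit
            next_orbit += 1
        graphlets.append((name, n, frozenset(edges)))
    assert next_orbit == N_ORBITS
    return GraphletCatalog(graphlets=tuple(graphlets), orbit_of=orbit_of)


@dataclass
class OrbitVector:
    """Length-15 orbit-count signature of one node, with its 11-orbit
    reduction; ``counts[0]`` equals the node degree."""

    node: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_ORBITS,):
            raise ValueError(f"expected {N_ORBITS} orbit counts")
        if np.any(self.counts < 0):
            raise ValueError("orbit counts must be nonnegative")

    @property
    def reduced(self) -> np.ndarray:
        return self.counts[list(NONREDUNDANT_ORBITS)]


@dataclass(frozen=True)
class GDVSimilarityRecord:
    seed: str
    node: str
    s_gdv: float


def count_orbits(net: InteractionNetwork, node: str) -> OrbitVector:
    """Orbit signature of one node, by enumerating every connected induced
    subgraph on <=4 nodes through it."""
    if not net.has_node(node):
        raise KeyError(f"node {node!r} not in network")
    indptr, indices = net.to_csr()
    targets = np.array([net.index[node]], dtype=np.int64)
    return OrbitVector(node=node, counts=orbit_counts(indptr, indices, targets)[0])


def gdv_matrix(
    net: InteractionNetwork, nodes: list[str] | None = None
) -> pd.DataFrame:
    """Orbit-count table (rows: nodes, columns: orbit ids 0-14).

    Deterministic; the handshake identity holds: the orbit-0 column sums to
    2|E| when all nodes are included.
    """
    if nodes is None:
        nodes = net.nodes
    indptr, indices = net.to_csr()
    targets = np.array([net.index[g] for g in nodes], dtype=np.int64)
    counts = orbit_counts(indptr, indices, targets)
    return pd.DataFrame(counts, index=nodes, columns=range(N_ORBITS))


def _as_vector(u, use_reduced: bool) -> np.ndarray:
    if isinstance(u, OrbitVector):
        return u.reduced if use_reduced else u.counts
    return np.asarray(u, dtype=np.float64)


def gdv_similarity(u, v, use_reduced: bool = True) -> float:
    """Signature similarity 1 - sum|u-v| / sum(u+v), in [0, 1].

    Accepts :class:`OrbitVector` objects (projected to the 11 non-redundant
    orbits when ``use_reduced``) or plain equal-length arrays.  Two all-zero
    signatures count as identical (similarity 1) — identical empty wiring;
    this cannot occur after the degree >= 3 filter.
    """
    a = _as_vector(u, use_reduced).astype(np.float64)
    b = _as_vector(v, use_reduced).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"signature length mismatch: {a.shape} vs {b.shape}")
    denom = float(np.sum(np.abs(a + b)))
    if denom == 0.0:
        return 1.0
    return 1.0 - float(np.sum(np.abs(a - b))) / denom


def seed_similarities(
    gdv: pd.DataFrame, seeds: SeedSet | list[str], use_reduced: bool = True
) -> pd.DataFrame:
    """Similarity table: rows seeds, columns all nodes in ``gdv``.

    Vectorized Bray-Curtis complement over the reduced (default) or full
    signatures.
    """
    seed_ids = seeds.mapped if isinstance(seeds, SeedSet) else list(seeds)
    cols = list(NONREDUNDANT_ORBITS) if use_reduced else list(range(N_ORBITS))
    mat = gdv[cols].to_numpy(dtype=np.float64)
    smat = gdv.loc[seed_ids, cols].to_numpy(dtype=np.float64)
    num = np.abs(smat[:, None, :] - mat[None, :, :]).sum(axis=2)
    den = (smat[:, None, :] + mat[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - num / den
    sim[den == 0.0] = 1.0
    return pd.DataFrame(sim, index=seed_ids, columns=gdv.index)


def select_threshold(
    sims: pd.DataFrame,
    seeds: SeedSet | list[str],
    start: float = 0.96,
    step: float = 0.01,
) -> float:
    """Largest grid threshold t in {start, start-step, ...} such that every
    seed has at least one non-seed, non-self node with similarity >= t.

    The search starts high and walks down in ``step`` decrements, mirroring
    a percent-point scan; raises ``ValueError`` if even the lowest
    nonnegative grid value fails (some seed has no non-seed partner at all).
    """
    if not (0.0 < start <= 1.0):
        raise ValueError("start must be in (0, 1]")
    if step <= 0.0:
        raise ValueError("step must be positive")
    seed_ids = seeds.mapped if isinstance(seeds, SeedSet) else list(seeds)
    non_seed = [c for c in sims.columns if c not in set(seed_ids)]
    if not non_seed:
        raise ValueError("no non-seed nodes available for threshold search")
    best = sims.loc[seed_ids, non_seed].max(axis=1)
    worst_best = float(best.min())
    k = 0
    while True:
        t = round(start - k * step, 12)
        if t < -1e-12:
            raise ValueError("no threshold in [0, start] satisfies the rule")
        if worst_best >= t - 1e-12:
            return max(t, 0.0)
        k += 1


def raw_gdv_candidates(
    sims: pd.DataFrame,
    seeds: SeedSet | list[str],
    threshold: float,
) -> list[GDVSimilarityRecord]:
    """All (seed, node) pairs with node not a seed and similarity >= the
    selected grid threshold, one record per pair.

    Use :func:`best_matches` to collapse to one best-matching seed per
    candidate node.
    """
    seed_ids = seeds.mapped if isinstance(seeds, SeedSet) else list(seeds)
    seed_set = set(seed_ids)
    records: list[GDVSimilarityRecord] = []
    for c in seed_ids:
        row = sims.loc[c]
        for node, s in row.items():
            if node in seed_set:
                continue
            if s >= threshold - 1e-12:
                records.append(GDVSimilarityRecord(seed=c, node=node, s_gdv=float(s)))
    return records


def best_matches(records: list[GDVSimilarityRecord]) -> list[GDVSimilarityRecord]:
    """One record per candidate node: its best-matching seed (ties broken by
    seed order of first appearance)."""
    best: dict[str, GDVSimilarityRecord] = {}
    for r in records:
        cur = best.get(r.node)
        if cur is None or r.s_gdv > cur.s_gdv:
            best[r.node] = r
    return list(best.values())
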
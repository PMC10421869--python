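"""Empirical significance for both mining branches.

The RWR branch is tested against random seed sets: the null re-runs the
walk from many uniformly drawn seed sets of the same size and counts, for
each raw candidate g, how often the null probability beats the observed one
(strictly).  The GDV branch is tested against degree-preserving rewired
networks: each null network is produced by attempted double edge swaps and
the candidate's signature similarity to its best-matching seed is
recomputed.  Either way the empirical FDR is p(g) = theta / n_permutations
and candidates with p < alpha (default 0.05) survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp

from . import graphlets
from ._orbits import N_ORBITS, orbit_counts
from .network_io import InteractionNetwork, SeedSet
from .rwr import RWRConfig

__all__ = [
    "NullEnsembleConfig",
    "PermutationResult",
    "random_seed_sets",
    "rwr_permutation_fdr",
    "degree_preserving_ensemble",
    "gdv_permutation_fdr",
    "filter_significant",
]

# distinct spawn keys so the two branches draw independent, individually
# reproducible streams from the same root seed
_RWR_STREAM = 1
_SWAP_STREAM = 2


@dataclass
class NullEnsembleConfig:
    n_permutations: int = 1000
    swaps_per_edge: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass(frozen=True)
class PermutationResult:
    node: str
    branch: str  # "RWR" or "GDV"
    theta: int
    n_permutations: int

    @property
    def p_value(self) -> float:
        return self.theta / self.n_permutations

    def __post_init__(self) -> None:
        if not (0 <= self.theta <= self.n_permutations):
            raise ValueError("theta must lie in [0, n_permutations]")


def random_seed_sets(
    net: InteractionNetwork, size: int, cfg: NullEnsembleConfig
) -> list[list[str]]:
    """``n_permutations`` uniform without-replacement samples of ``size``
    node ids; bitwise reproducible from ``cfg.rng_seed`` (one derived
    stream per permutation)."""
    if size > net.n_nodes:
        raise ValueError(f"cannot sample {size} seeds from {net.n_nodes} nodes")
    nodes = np.asarray(net.nodes, dtype=object)
    children = np.random.SeedSequence([cfg.rng_seed, _RWR_STREAM]).spawn(
        cfg.n_permutations
    )
    return [
        list(np.random.default_rng(ss).choice(nodes, size=size, replace=False))
        for ss in children
    ]


def _batched_rwr(
    W: sp.spmatrix, P0: np.ndarray, rwr_cfg: RWRConfig
) -> np.ndarray:
    """Iterate many restart walks simultaneously (P0 columns are the
    per-permutation initial distributions) until every column converges."""
    r = rwr_cfg.restart_probability
    P = P0.copy()
    for _ in range(rwr_cfg.max_iterations):
        P_next = (1.0 - r) * (W @ P) + r * P0
        gap = float(np.abs(P_next - P).sum(axis=0).max())
        P = P_next
        if gap < rwr_cfg.l1_tolerance:
            return P
    raise RuntimeError("batched RWR did not converge within max_iterations")


def rwr_permutation_fdr(
    net: InteractionNetwork,
    W: sp.spmatrix,
    raw_candidates: Sequence[tuple[str, float]],
    cfg: NullEnsembleConfig,
    rwr_cfg: RWRConfig | None = None,
    seed_size: int | None = None,
    seeds: SeedSet | None = None,
    batch: int = 256,
) -> list[PermutationResult]:
    """Empirical FDR for each raw RWR candidate against random seed sets.

    For candidate g with observed probability p_obs(g),
    theta(g) = #{random seed sets s : P_s(g) > p_obs(g)} (strict).
    ``seed_size`` defaults to |seeds.mapped|.
    """
    rwr_cfg = rwr_cfg or RWRConfig()
    if seed_size is None:
        if seeds is None:
            raise ValueError("provide seed_size or seeds")
        seed_size = len(seeds.mapped)
    cand_idx = np.array([net.index[g] for g, _ in raw_candidates], dtype=np.int64)
    p_obs = np.array([p for _, p in raw_candidates], dtype=np.float64)
    theta = np.zeros(len(raw_candidates), dtype=np.int64)
    sets = random_seed_sets(net, seed_size, cfg)
    w = 1.0 / seed_size
    for lo in range(0, len(sets), batch):
        chunk = sets[lo : lo + batch]
        P0 = np.zeros((net.n_nodes, len(chunk)), dtype=np.float64)
        for b, s in enumerate(chunk):
            for g in s:
                P0[net.index[g], b] = w
        P = _batched_rwr(W, P0, rwr_cfg)
        theta += (P[cand_idx, :] > p_obs[:, None]).sum(axis=1)
    return [
        PermutationResult(
            node=g, branch="RWR", theta=int(t), n_permutations=cfg.n_permutations
        )
        for (g, _), t in zip(raw_candidates, theta)
    ]


def _double_edge_swap(
    edges: np.ndarray, rng: np.random.Generator, attempts: int
) -> np.ndarray:
    """Attempt-based degree-preserving rewiring: pick two edges {a,b},{c,d},
    rewire to {a,d},{c,b} unless that would create a self-loop or a
    duplicate edge; failed attempts are skipped."""
    m = edges.shape[0]
    E = edges.copy()
    present = {frozenset(e) for e in map(tuple, E)}
    picks = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    for (i, j), flip in zip(picks, flips):
        if i == j:
            continue
        a, b = E[i]
        c, d = E[j]
        if flip:
            c, d = d, c
        # proposed edges {a, d} and {c, b}
        if a == d or c == b:
            continue
        e1 = frozenset((a, d))
        e2 = frozenset((c, b))
        if e1 == e2 or e1 in present or e2 in present:
            continue
        present.discard(frozenset((a, b)))
        present.discard(frozenset((c, d)))
        present.add(e1)
        present.add(e2)
        E[i] = (a, d)
        E[j] = (c, b)
    return E


def degree_preserving_ensemble(
    net: InteractionNetwork, cfg: NullEnsembleConfig
) -> Iterator[InteractionNetwork]:
    """Stream ``n_permutations`` rewired networks with the node set and the
    exact degree sequence of ``net`` preserved.

    Each network results from ``swaps_per_edge * |E|`` attempted double edge
    swaps; networks are generated lazily (never all held in memory) and are
    reproducible from ``cfg.rng_seed``.
    """
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    edges = np.array(
        [(net.index[u], net.index[v]) for u, v in net.edges()], dtype=np.int64
    )
    attempts = cfg.swaps_per_edge * net.n_edges
    children = np.random.SeedSequence([cfg.rng_seed, _SWAP_STREAM]).spawn(
        cfg.n_permutations
    )
    for ss in children:
        rng = np.random.default_rng(ss)
        E = _double_edge_swap(edges, rng, attempts)
        yield InteractionNetwork.from_edges(
            ((net.nodes[int(u)], net.nodes[int(v)]) for u, v in E),
            nodes=net.nodes,
        )


def gdv_permutation_fdr(
    net: InteractionNetwork,
    best_records: Sequence[graphlets.GDVSimilarityRecord],
    cfg: NullEnsembleConfig,
    use_reduced: bool = True,
    match: str = "best",
    seeds: Sequence[str] | SeedSet | None = None,
) -> list[PermutationResult]:
    """Empirical FDR for each GDV candidate against rewired networks.

    Each candidate g carries its best-matching real-network seed c* and the
    real similarity s_real = S_GDV(c*, g).  With ``match="best"`` (default)
    theta(g) counts null networks in which the recomputed similarity of the
    *same labeled pair* strictly exceeds s_real; with ``match="any"`` a
    null network counts as soon as any seed in ``seeds`` beats s_real,
    which yields larger theta (more conservative).  ``net`` must be the
    network the real signatures were computed on (i.e. already
    degree-filtered).
    """
    if match not in ("best", "any"):
        raise ValueError("match must be 'best' or 'any'")
    if not best_records:
        return []
    for r in best_records:
        if not r.seed:
            raise ValueError(f"candidate {r.node!r} lacks a recorded seed pair")
    if match == "any":
        if seeds is None:
            raise ValueError("match='any' requires the seed list")
        seed_ids = seeds.mapped if isinstance(seeds, SeedSet) else list(seeds)
    else:
        seed_ids = []
    involved = sorted(
        {r.node for r in best_records} | {r.seed for r in best_records} | set(seed_ids)
    )
    pos = {g: i for i, g in enumerate(involved)}
    targets = np.array([net.index[g] for g in involved], dtype=np.int64)
    sel = list(graphlets.NONREDUNDANT_ORBITS) if use_reduced else list(range(N_ORBITS))
    s_real = np.array([r.s_gdv for r in best_records], dtype=np.float64)
    theta = np.zeros(len(best_records), dtype=np.int64)

    def _sim(u: np.ndarray, v: np.ndarray) -> float:
        denom = float(np.sum(u + v))
        return 1.0 if denom == 0.0 else 1.0 - float(np.sum(np.abs(u - v))) / denom

    for null_net in degree_preserving_ensemble(net, cfg):
        indptr, indices = null_net.to_csr()
        counts = orbit_counts(indptr, indices, targets)[:, sel].astype(np.float64)
        for k, rec in enumerate(best_records):
            v = counts[pos[rec.node]]
            partners = seed_ids if match == "any" else [rec.seed]
            if any(_sim(counts[pos[c]], v) > s_real[k] for c in partners):
                theta[k] += 1
    return [
        PermutationResult(
            node=rec.node,
            branch="GDV",
            theta=int(t),
            n_permutations=cfg.n_permutations,
        )
        for rec, t in zip(best_records, theta)
    ]


def filter_significant(
    results: Sequence[PermutationResult], alpha: float = 0.05
) -> list[PermutationResult]:
    """Keep results with p_value strictly below ``alpha``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return [r for r in results if r.p_value < alpha]
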
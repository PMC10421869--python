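"""Random walk with restart (RWR) propagation from a seed set.

The walker's distribution over network nodes is updated as

    P_{i+1} = (1 - r) * W @ P_i + r * P_0

with restart probability r (default 0.8), column-stochastic transition
operator W, and P_0 uniform over the seeds.  Iteration stops at the first
step whose Manhattan (L1) change falls below the tolerance (default 1e-6);
the map contracts geometrically with factor (1 - r), so convergence is
fast.  Nodes whose stationary probability exceeds a threshold (default
1e-5) become raw candidates.

``rwr_solve_direct`` solves the same fixed point by a dense linear solve,
(I - (1-r) W) P = r P_0, and serves as a small-network oracle for the
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network_io import InteractionNetwork, SeedSet

__all__ = [
    "RWRConfig",
    "RWRResult",
    "initial_distribution",
    "rwr_iterate",
    "rwr_solve_direct",
    "threshold_raw_candidates",
]


@dataclass
class RWRConfig:
    """Walk parameters; defaults are the pipeline's standard settings."""

    restart_probability: float = 0.8
    l1_tolerance: float = 1e-6
    raw_threshold: float = 1e-5
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart_probability <= 1.0):
            raise ValueError("restart_probability must be in (0, 1]")
        if self.l1_tolerance <= 0.0:
            raise ValueError("l1_tolerance must be positive")
        if self.raw_threshold <= 0.0:
            raise ValueError("raw_threshold must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RWRResult:
    """Converged distribution plus convergence diagnostics.

    ``gaps[i]`` is the L1 change produced by iteration i+1; the last entry
    is below the tolerance.
    """

    probabilities: np.ndarray
    iterations: int
    gaps: list[float] = field(default_factory=list)


def initial_distribution(net: InteractionNetwork, seeds: SeedSet) -> np.ndarray:
    """P_0: each mapped seed gets 1/|seeds|, every other node zero."""
    if len(seeds) == 0:
        raise ValueError("seed set is empty")
    p0 = np.zeros(net.n_nodes, dtype=np.float64)
    w = 1.0 / len(seeds)
    for g in seeds.mapped:
        p0[net.index[g]] = w
    return p0


def rwr_iterate(
    W: sp.spmatrix, p0: np.ndarray, cfg: RWRConfig | None = None
) -> RWRResult:
    """Iterate the restart walk to its stationary distribution.

    Returns the first iterate whose L1 distance from its predecessor is
    below ``cfg.l1_tolerance``; raises ``RuntimeError`` (reporting the last
    gap) if ``cfg.max_iterations`` is exhausted first.  Probability mass is
    conserved at every step when no zero-degree node carries mass.
    """
    cfg = cfg or RWRConfig()
    r = cfg.restart_probability
    p = np.asarray(p0, dtype=np.float64)
    gaps: list[float] = []
    for it in range(1, cfg.max_iterations + 1):
        p_next = (1.0 - r) * (W @ p) + r * p0
        gap = float(np.abs(p_next - p).sum())
        gaps.append(gap)
        p = p_next
        if gap < cfg.l1_tolerance:
            return RWRResult(probabilities=p, iterations=it, gaps=gaps)
    raise RuntimeError(
        f"RWR did not converge in {cfg.max_iterations} iterations "
        f"(last L1 gap {gaps[-1]:.3e} >= tol {cfg.l1_tolerance:.1e})"
    )


def rwr_solve_direct(W: sp.spmatrix, p0: np.ndarray, r: float) -> np.ndarray:
    """Closed-form stationary distribution (I - (1-r) W) P = r P_0 by a
    dense solve; intended as an oracle on small networks only."""
    if not (0.0 < r <= 1.0):
        raise ValueError("r must be in (0, 1]")
    n = W.shape[0]
    A = np.eye(n) - (1.0 - r) * np.asarray(W.todense())
    return np.linalg.solve(A, r * np.asarray(p0, dtype=np.float64))


def threshold_raw_candidates(
    net: InteractionNetwork,
    p: np.ndarray,
    tau: float,
    seeds: SeedSet | None = None,
    exclude_seeds: bool = True,
) -> list[tuple[str, float]]:
    """Nodes with stationary probability strictly above ``tau``, sorted by
    descending probability (ties by node order); seeds are removed by
    default — candidates are clock-*associated* proteins, not the clock
    itself."""
    seed_set = set(seeds.mapped) if (exclude_seeds and seeds is not None) else set()
    hits = [
        (g, float(p[i]))
        for i, g in enumerate(net.nodes)
        if p[i] > tau and g not in seed_set
    ]
    hits.sort(key=lambda t: -t[1])
    return hits
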
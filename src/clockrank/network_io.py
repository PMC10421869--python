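"""Reading, validation and indexing of interaction networks, seed lists and
annotation maps.

The central container is :class:`InteractionNetwork`, an undirected simple
graph (no self-loops, no parallel edges) with a *fixed node order* so that
probability vectors, transition matrices and orbit-count tables computed by
the other modules all align on the same index.  Node identifiers are
case-sensitive exact strings; no accession normalization is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "SeedSet",
    "AnnotationMap",
    "ParseError",
    "read_edge_list",
    "read_seed_list",
    "read_annotations",
    "filter_min_degree",
    "transition_operator",
    "map_seeds",
]


class ParseError(ValueError):
    """Raised when an input file is malformed; message names the line."""


class InteractionNetwork:
    """Undirected simple protein-interaction graph with a fixed node order.

    Wraps a :class:`networkx.Graph`; the node order is the insertion order of
    first appearance (or an explicit order passed to :meth:`from_edges`),
    exposed as :attr:`nodes` with the inverse map :attr:`index`.
    """

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges()):
            raise ValueError("self-loops are not allowed; use from_edges()")
        self.graph = graph
        self.nodes: list[str] = list(graph.nodes())
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        self._csr: tuple[np.ndarray, np.ndarray] | None = None

    # -- construction ---------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Sequence[str] | None = None,
    ) -> "InteractionNetwork":
        """Build a simple graph, silently dropping self-loops and duplicate
        (or reversed-duplicate) edges; the counts of dropped rows are logged.

        ``nodes`` optionally fixes the node set and order (isolated nodes are
        then retained), which the degree-preserving null model relies on.
        """
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        n_self = 0
        n_dup = 0
        for u, v in edges:
            if u == v:
                n_self += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
        if n_self or n_dup:
            logger.info(
                "dropped %d self-loop(s) and %d duplicate edge(s)", n_self, n_dup
            )
        net = cls(g)
        net.dropped_self_loops = n_self
        net.dropped_duplicates = n_dup
        return net

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def degree_array(self) -> np.ndarray:
        """Degrees aligned with :attr:`nodes`."""
        return np.array([self.graph.degree[g] for g in self.nodes], dtype=np.int64)

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))

    def has_node(self, node: str) -> bool:
        return self.graph.has_node(node)

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def edges(self) -> Iterator[tuple[str, str]]:
        return iter(self.graph.edges())

    def to_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in CSR form ``(indptr, indices)`` with sorted neighbor
        lists, aligned with :attr:`nodes`.  Cached after first call."""
        if self._csr is None:
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            rows: list[np.ndarray] = []
            for i, g in enumerate(self.nodes):
                nb = sorted(self.index[h] for h in self.graph.neighbors(g))
                rows.append(np.asarray(nb, dtype=np.int64))
                indptr[i + 1] = indptr[i] + len(nb)
            indices = (
                np.concatenate(rows) if rows else np.zeros(0, dtype=np.int64)
            )
            self._csr = (indptr, indices)
        return self._csr

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class SeedSet:
    """Partition of a requested seed-id list against a network.

    ``mapped`` preserves the order of the input ids; ``unmapped`` are ids
    absent from the network; ``dropped_low_degree`` were present but fell
    below the degree cut.
    """

    mapped: list[str]
    unmapped: list[str] = field(default_factory=list)
    dropped_low_degree: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.mapped) & set(self.unmapped):
            raise ValueError("mapped and unmapped seed ids overlap")

    def __len__(self) -> int:
        return len(self.mapped)


@dataclass
class AnnotationMap:
    """Term -> gene-set map for one namespace with its exact inverse index.

    Genes absent from a given network are retained here and only discounted
    when a network-dependent quantity (e.g. the annotated-gene count M) is
    computed.
    """

    namespace: str
    term_to_genes: dict[str, set[str]]
    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_to_terms:
            inv: dict[str, set[str]] = {}
            for term, genes in self.term_to_genes.items():
                for g in genes:
                    inv.setdefault(g, set()).add(term)
            self.gene_to_terms = inv

    def terms(self) -> list[str]:
        return list(self.term_to_genes)

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())

    def genes_of(self, term: str) -> set[str]:
        return self.term_to_genes.get(term, set())

    def check_inverse(self) -> bool:
        """True iff the two indexes are exact inverses (invariant check)."""
        fwd = {(g, t) for t, gs in self.term_to_genes.items() for g in gs}
        inv = {(g, t) for g, ts in self.gene_to_terms.items() for t in ts}
        return fwd == inv


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------


def _data_lines(path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path, fmt: str = "tsv") -> InteractionNetwork:
    """Read an undirected edge list from a two-column TSV or a SIF file.

    TSV rows are whitespace/tab separated with at least two columns (extra
    columns ignored); SIF rows are ``source relation target [target ...]``.
    Lines starting with ``#`` are comments.  Self-loops and duplicate rows
    (including reversed duplicates) are dropped with a logged count.
    """
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {fmt!r}")
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if fmt == "tsv":
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
            edges.append((fields[0], fields[1]))
        else:
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: SIF row needs 'source relation target', got {len(fields)} fields"
                )
            src = fields[0]
            for tgt in fields[2:]:
                edges.append((src, tgt))
    if not edges:
        raise ParseError(f"{path}: no data rows")
    return InteractionNetwork.from_edges(edges)


def read_seed_list(path) -> list[str]:
    """Plain text, one protein id per line; order preserved, duplicates
    collapsed to first occurrence."""
    seen: dict[str, None] = {}
    for _, line in _data_lines(path):
        seen.setdefault(line.strip(), None)
    return list(seen)


def read_annotations(path, fmt: str = "gmt", namespace: str = "GO") -> AnnotationMap:
    """Read an annotation map from GMT (``term <tab> description <tab>
    genes...``) or two-column TSV (``gene <tab> term``).

    Duplicate (gene, term) memberships collapse to one.
    """
    if fmt not in ("gmt", "tsv2col"):
        raise ValueError(f"unknown annotation format: {fmt!r}")
    term_to_genes: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        if fmt == "gmt":
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT row needs >=3 fields, got {len(fields)}")
            term = fields[0]
            term_to_genes.setdefault(term, set()).update(
                g for g in fields[2:] if g
            )
        else:
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'gene<TAB>term'")
            gene, term = fields[0], fields[1]
            term_to_genes.setdefault(term, set()).add(gene)
    return AnnotationMap(namespace=namespace, term_to_genes=term_to_genes)


# ---------------------------------------------------------------------------
# network operations
# ---------------------------------------------------------------------------


def filter_min_degree(net: InteractionNetwork, k: int) -> InteractionNetwork:
    """Remove, in a single simultaneous pass, every node whose degree *in the
    input network* is below ``k``, along with its incident edges.

    Degrees are measured once on the input; removal is not iterated (no core
    decomposition).  ``k=0`` is the identity.  Surviving nodes keep isolated
    status if all their neighbors were removed.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return net
    keep = [g for g in net.nodes if net.degree(g) >= k]
    keep_set = set(keep)
    edges = [(u, v) for u, v in net.edges() if u in keep_set and v in keep_set]
    return InteractionNetwork.from_edges(edges, nodes=keep)


def transition_operator(net: InteractionNetwork) -> sp.csc_matrix:
    """Column-stochastic walk operator W with W[i, j] = 1/deg(j) for each
    edge {i, j}.

    Columns of positive-degree nodes sum to exactly 1; a zero-degree node
    yields an all-zero column (logged as a warning) so walk mass entering it
    would vanish — such nodes are outside the walk's support.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    deg = net.degree_array()
    if np.any(deg == 0):
        logger.warning(
            "%d zero-degree node(s): their transition columns are all zero",
            int(np.sum(deg == 0)),
        )
    indptr, indices = net.to_csr()
    # by symmetry the row-wise CSR arrays double as column-wise CSC arrays
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    data = np.repeat(inv_deg, np.diff(indptr))
    return sp.csc_matrix((data, indices, indptr), shape=(net.n_nodes, net.n_nodes))


def map_seeds(
    net: InteractionNetwork, ids: Sequence[str], min_degree: int = 0
) -> SeedSet:
    """Partition requested seed ids into mapped / unmapped /
    dropped_low_degree (degree < ``min_degree``), preserving input order.

    Raises ``ValueError`` if no seed maps — the pipeline cannot run without
    at least one seed in the network.
    """
    if not ids:
        raise ValueError("seed id list is empty")
    mapped: list[str] = []
    unmapped: list[str] = []
    dropped: list[str] = []
    seen: set[str] = set()
    for g in ids:
        if g in seen:
            continue
        seen.add(g)
        if not net.has_node(g):
            unmapped.append(g)
        elif net.degree(g) < min_degree:
            dropped.append(g)
        else:
            mapped.append(g)
    if not mapped:
        raise ValueError("no seed id could be mapped to the network")
    return SeedSet(mapped=mapped, unmapped=unmapped, dropped_low_degree=dropped)
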
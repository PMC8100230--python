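"""Scale-free contact network substrate.

The contact graph over which panic interacts and buying behavior spreads is a
Barabási–Albert (BA) scale-free network: the graph is grown one node at a
time, and each new node attaches to ``m`` distinct existing nodes chosen with
probability proportional to their current degree ("rich get richer").  The
seed graph is the complete graph on ``m + 1`` nodes, which guarantees that
every new node can find ``m`` distinct targets and that the grown graph is
connected.

The resulting :class:`SocialNetwork` is undirected and simple (no self-loops,
no parallel edges), with contiguous 0-based node ids so that per-agent state
can live in flat NumPy arrays.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix


class ConfigurationError(ValueError):
    """Raised when a model or network configuration is invalid."""


class SocialNetwork:
    """Undirected simple contact graph over ``n`` agents.

    Parameters
    ----------
    node_count
        Number of nodes ``N``; ids are ``0 .. N-1``.
    attachment_parameter
        Number of edges ``m`` added per new node during growth (kept as
        metadata; arbitrary edge lists are accepted, e.g. test fixtures).
    edges
        Integer array of shape ``(E, 2)`` listing each undirected edge once.
    """

    def __init__(self, node_count: int, attachment_parameter: int, edges: np.ndarray):
        if node_count < 1:
            raise ConfigurationError("node_count must be positive")
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= node_count):
            raise ConfigurationError("edge endpoint outside [0, N)")
        if edges.size and np.any(edges[:, 0] == edges[:, 1]):
            raise ConfigurationError("self-loops are not allowed")
        # canonical orientation u < v, detect parallel edges
        u = np.minimum(edges[:, 0], edges[:, 1])
        v = np.maximum(edges[:, 0], edges[:, 1])
        canon = np.stack([u, v], axis=1)
        if canon.shape[0] != len({(int(a), int(b)) for a, b in canon}):
            raise ConfigurationError("parallel edges are not allowed")
        self.node_count = int(node_count)
        self.attachment_parameter = int(attachment_parameter)
        self.edges = canon
        data = np.ones(2 * canon.shape[0], dtype=np.float64)
        rows = np.concatenate([u, v])
        cols = np.concatenate([v, u])
        self._adj = csr_matrix(
            (data, (rows, cols)), shape=(node_count, node_count)
        )
        self.degrees = np.asarray(self._adj.sum(axis=1)).ravel().astype(np.int64)
        self._neighbor_sets: list[frozenset[int]] | None = None

    # -- queries ---------------------------------------------------------

    @property
    def edge_count(self) -> int:
        return int(self.edges.shape[0])

    @property
    def adjacency(self) -> csr_matrix:
        """Symmetric 0/1 adjacency in CSR form (used for vectorized counts)."""
        return self._adj

    def neighbors(self, i: int) -> frozenset[int]:
        """Adjacency set of node ``i``; symmetric by construction."""
        if not (0 <= int(i) < self.node_count) or int(i) != i:
            raise KeyError(f"unknown node id {i!r}")
        if self._neighbor_sets is None:
            sets: list[set[int]] = [set() for _ in range(self.node_count)]
            for a, b in self.edges:
                sets[int(a)].add(int(b))
                sets[int(b)].add(int(a))
            self._neighbor_sets = [frozenset(s) for s in sets]
        return self._neighbor_sets[int(i)]

    # -- I/O -------------------------------------------------------------

    def to_edgelist(self, path: str | Path) -> None:
        """Write the edge list as two whitespace-separated ids per line."""
        np.savetxt(path, self.edges, fmt="%d")

    @classmethod
    def from_edgelist(
        cls, path: str | Path, node_count: int | None = None, attachment_parameter: int = 0
    ) -> "SocialNetwork":
        edges = np.loadtxt(path, dtype=np.int64).reshape(-1, 2)
        if node_count is None:
            node_count = int(edges.max()) + 1 if edges.size else 1
        return cls(node_count, attachment_parameter, edges)

    def to_networkx(self):
        """Export as a :mod:`networkx` graph (interop/diagnostics only)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.node_count))
        g.add_edges_from(map(tuple, self.edges))
        return g


def generate_ba_network(
    n: int, m: int, seed: int | np.random.Generator | np.random.SeedSequence | None = None
) -> SocialNetwork:
    """Grow a BA scale-free graph with ``n`` nodes, ``m`` edges per new node.

    The seed graph is the complete graph on ``m + 1`` nodes; every subsequent
    node attaches to ``m`` distinct existing nodes drawn without replacement
    with probability proportional to current degree.  Deterministic for a
    fixed ``seed``.

    Raises
    ------
    ConfigurationError
        If ``n <= m`` or ``m < 1``.
    """
    if m < 1:
        raise ConfigurationError("attachment parameter m must be >= 1")
    if n <= m:
        raise ConfigurationError(f"need n >= m + 1 nodes (got n={n}, m={m})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    m0 = m + 1
    edges: list[tuple[int, int]] = list(combinations(range(m0), 2))
    deg = np.zeros(n, dtype=np.float64)
    deg[:m0] = m
    for new in range(m0, n):
        probs = deg[:new] / deg[:new].sum()
        targets = rng.choice(new, size=m, replace=False, p=probs)
        for t in targets:
            edges.append((int(t), new))
            deg[t] += 1
        deg[new] = m
    return SocialNetwork(n, m, np.asarray(edges, dtype=np.int64))


def neighbors(net: SocialNetwork, i: int) -> frozenset[int]:
    """Functional alias for :meth:`SocialNetwork.neighbors`."""
    return net.neighbors(i)
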
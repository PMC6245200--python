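"""In-memory container for simple, undirected, single-component networks."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Network"]


class Network:
    """A simple undirected graph on contiguous 0-based internal indices.

    Original node identifiers (strings) are preserved in :attr:`labels` and
    used for all file output.  The degree ranking (rank 1 = highest degree,
    ties broken by ascending internal index, i.e. input order) underpins the
    radial coordinates of every embedding method.
    """

    def __init__(self, edges: Iterable[tuple[int, int]], labels: Sequence[str]):
        labels = [str(x) for x in labels]
        n = len(labels)
        seen: set[tuple[int, int]] = set()
        for u, v in edges:
            if u == v:
                continue
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) out of range for {n} nodes")
            seen.add((u, v) if u < v else (v, u))
        if not seen:
            raise ValueError("network has no edges")
        edge_arr = np.array(sorted(seen), dtype=np.int64)
        self.labels: list[str] = labels
        self.edges: np.ndarray = edge_arr
        self.N: int = n
        self.L: int = len(edge_arr)
        deg = np.zeros(n, dtype=np.int64)
        np.add.at(deg, edge_arr[:, 0], 1)
        np.add.at(deg, edge_arr[:, 1], 1)
        self.degrees: np.ndarray = deg
        # adjacency lists, sorted for deterministic iteration
        neigh: list[list[int]] = [[] for _ in range(n)]
        for u, v in edge_arr:
            neigh[u].append(int(v))
            neigh[v].append(int(u))
        self.adjacency: list[np.ndarray] = [
            np.array(sorted(a), dtype=np.int64) for a in neigh
        ]
        if not self._is_connected():
            raise ValueError(
                "network is not connected; extract the largest connected "
                "component first (read_edgelist does this automatically)"
            )
        # rank 1 = highest degree, ties by ascending node index
        order = np.lexsort((np.arange(n), -deg))
        self.rank_order: np.ndarray = order          # rank k-1 -> node index
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(1, n + 1)
        self.degree_rank: np.ndarray = rank          # node index -> rank (1-based)

    def _is_connected(self) -> bool:
        seen = np.zeros(self.N, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            u = stack.pop()
            for v in self.adjacency[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        return bool(seen.all())

    @property
    def mean_degree(self) -> float:
        """Average node degree 2m = 2L/N."""
        return 2.0 * self.L / self.N

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (float)."""
        A = np.zeros((self.N, self.N))
        A[self.edges[:, 0], self.edges[:, 1]] = 1.0
        A[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return A

    def sparse_adjacency(self):
        """CSR adjacency matrix."""
        from scipy import sparse

        row = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        col = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        data = np.ones(2 * self.L)
        return sparse.csr_matrix((data, (row, col)), shape=(self.N, self.N))

    def has_edge(self, u: int, v: int) -> bool:
        a = self.adjacency[u]
        j = np.searchsorted(a, v)
        return bool(j < len(a) and a[j] == v)

    def to_igraph(self):
        import igraph as ig

        return ig.Graph(n=self.N, edges=[(int(u), int(v)) for u, v in self.edges])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from((int(u), int(v)) for u, v in self.edges)
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(N={self.N}, L={self.L})"
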
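"""Plain-text readers and writers: edge lists, coordinate tables, fixtures."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .generator import GeneratedNetwork, generate
from .geometry import PSParams
from .network import Network
from .result import EmbeddingResult

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "read_coords",
    "write_coords",
    "make_fixture",
    "export_graphml",
]


def read_edgelist(path, directed_input: bool = False) -> Network:
    """Read a two-column whitespace-separated edge list into a Network.

    Lines starting with '#' are ignored.  Directed input is symmetrized;
    self-loops and duplicate edges are dropped and only the largest connected
    component is kept.  Original node identifiers are preserved as labels.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two node ids, "
                                 f"got {line!r}")
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise ValueError(f"{path}: no edges found")
    labels: list[str] = []
    index: dict[str, int] = {}
    for a, b in pairs:
        for x in (a, b):
            if x not in index:
                index[x] = len(labels)
                labels.append(x)
    edges = {(min(index[a], index[b]), max(index[a], index[b]))
             for a, b in pairs if a != b}
    # largest connected component
    n = len(labels)
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    comp = np.full(n, -1, dtype=int)
    n_comp = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = n_comp
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp[v] < 0:
                    comp[v] = n_comp
                    stack.append(v)
        n_comp += 1
    sizes = np.bincount(comp, minlength=n_comp)
    keep = int(np.argmax(sizes))
    old_ids = np.flatnonzero(comp == keep)
    remap = {int(o): i for i, o in enumerate(old_ids)}
    lcc_edges = [(remap[u], remap[v]) for u, v in edges
                 if comp[u] == keep and comp[v] == keep]
    return Network(lcc_edges, [labels[int(o)] for o in old_ids])


def write_edgelist(net, path) -> None:
    """Write tab-separated node-id pairs, one edge per line."""
    path = Path(path)
    if isinstance(net, GeneratedNetwork):
        labels = [str(t) for t in range(1, net.params.N + 1)]
        edges = net.edges
    else:
        labels, edges = net.labels, net.edges
    with path.open("w") as fh:
        for u, v in edges:
            fh.write(f"{labels[int(u)]}\t{labels[int(v)]}\n")


def write_coords(result, path, labels=None) -> None:
    """Write a coordinate table: node id, r, theta (tab-separated, header,
    full double precision, theta normalized to [0, 2 pi))."""
    path = Path(path)
    if isinstance(result, EmbeddingResult):
        r, theta = result.r, result.theta
    elif isinstance(result, GeneratedNetwork):
        r, theta = result.r, result.theta % (2.0 * np.pi)
        if labels is None:
            labels = [str(t) for t in range(1, result.params.N + 1)]
    else:
        arr = np.asarray(result, dtype=float)
        r, theta = arr[:, 0], arr[:, 1] % (2.0 * np.pi)
    if labels is None:
        labels = [str(i + 1) for i in range(len(r))]
    with path.open("w") as fh:
        fh.write("node\tr\ttheta\n")
        for lab, ri, ti in zip(labels, r, theta):
            fh.write(f"{lab}\t{float(ri)!r}\t{float(ti)!r}\n")


def read_coords(path) -> tuple[list[str], np.ndarray]:
    """Read a coordinate table written by :func:`write_coords`.

    Returns ``(labels, coords)`` with ``coords[:, 0] = r`` and
    ``coords[:, 1] = theta``.  Negative radii and malformed rows are
    rejected with the offending line number.
    """
    path = Path(path)
    labels: list[str] = []
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                r, theta = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable number") from exc
            if r < 0:
                raise ValueError(f"{path}:{lineno}: negative radius {r}")
            if not 0.0 <= theta < 2.0 * math.pi:
                theta = theta % (2.0 * math.pi)
            labels.append(parts[0])
            rows.append((r, theta))
    if not rows:
        raise ValueError(f"{path}: no coordinate rows")
    return labels, np.array(rows)


def make_fixture(params: PSParams, out_prefix) -> tuple[Path, Path]:
    """Generate a PS network and write its edge list and true coordinates.

    Returns the two file paths ``<prefix>.edgelist.tsv`` and
    ``<prefix>.coords.tsv``.  Deterministic: the same params (including
    seed) produce byte-identical files.
    """
    gen = generate(params)
    edge_path = Path(f"{out_prefix}.edgelist.tsv")
    coord_path = Path(f"{out_prefix}.coords.tsv")
    write_edgelist(gen, edge_path)
    write_coords(gen, coord_path)
    return edge_path, coord_path


def export_graphml(net: Network, result: EmbeddingResult, path) -> None:
    """Export the embedded network to GraphML with r/theta node attributes."""
    import networkx as nx

    g = nx.Graph()
    for i, lab in enumerate(net.labels):
        g.add_node(lab, r=float(result.r[i]), theta=float(result.theta[i]))
    for u, v in net.edges:
        g.add_edge(net.labels[int(u)], net.labels[int(v)])
    nx.write_graphml(g, path)
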
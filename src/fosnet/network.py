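"""Weighted functional networks over hemispheric region nodes.

A :class:`FunctionalNetwork` is a symmetric weighted adjacency matrix with
zero diagonal, interpreted as a group-level co-activation network.  Density
thresholding keeps a target fraction of the strongest edges ("add edges
starting from the strongest ones until the density is reached").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .regions import RegionNode, RegionRegistry, default_registry

__all__ = [
    "FunctionalNetwork",
    "threshold_by_density",
    "write_network",
    "read_network",
]

_FLOAT_FMT = "{:.9g}"  # 9 significant digits, locale-independent


@dataclass
class FunctionalNetwork:
    """Symmetric weighted network; ``weights[i, j]`` links ``nodes[i]``–``nodes[j]``."""

    nodes: list[RegionNode]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weights must be N x N for N nodes")
        if not np.allclose(w, w.T, equal_nan=True):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    @property
    def density(self) -> float:
        """Fraction of the N(N-1)/2 possible edges with nonzero weight."""
        n = self.n_nodes
        e_max = n * (n - 1) // 2
        return self.n_edges / e_max if e_max else 0.0

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Nonzero edges as ``(node_a, node_b, w)``, lexicographic, a < b."""
        ids = self.node_ids
        out = []
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w != 0.0:
                a, b = sorted((ids[i], ids[j]))
                out.append((a, b, float(w)))
        out.sort(key=lambda e: (e[0], e[1]))
        return out

    def subnetwork(self, keep: np.ndarray) -> "FunctionalNetwork":
        keep = np.asarray(keep)
        return FunctionalNetwork(
            nodes=[n for n, k in zip(self.nodes, keep) if k],
            weights=self.weights[np.ix_(keep, keep)],
        )


def _edge_order(network: FunctionalNetwork, ranking: str) -> list[tuple[int, int]]:
    """Edge positions sorted strongest-first with deterministic tie-break."""
    ids = network.node_ids
    iu, ju = np.triu_indices(network.n_nodes, k=1)
    key = []
    for i, j in zip(iu, ju):
        w = network.weights[i, j]
        score = abs(w) if ranking == "absolute" else w
        a, b = sorted((ids[i], ids[j]))
        key.append((-score, a, b, int(i), int(j)))
    key.sort()
    return [(i, j) for _, _, _, i, j in key]


def threshold_by_density(
    network: FunctionalNetwork, rho: float, ranking: str = "signed"
) -> FunctionalNetwork:
    """Keep the ``ceil(rho * N(N-1)/2)`` strongest edges, zero the rest.

    ``ranking="signed"`` (default) ranks by signed weight descending — the
    strongest positive correlations enter first; ``"absolute"`` ranks by
    magnitude.  Ties are broken lexicographically by node-id pair, so the
    result is deterministic.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"target density must be in [0, 1], got {rho}")
    if ranking not in ("signed", "absolute"):
        raise ValueError(f"unknown ranking {ranking!r}")
    n = network.n_nodes
    e_max = n * (n - 1) // 2
    k = math.ceil(rho * e_max)
    out = np.zeros_like(network.weights)
    for i, j in _edge_order(network, ranking)[:k]:
        out[i, j] = out[j, i] = network.weights[i, j]
    return FunctionalNetwork(nodes=list(network.nodes), weights=out)


def write_network(network: FunctionalNetwork, path) -> None:
    """Edge-list TSV: ``node_a  node_b  weight``, one row per nonzero edge.

    Node ids are lexicographic within a row, rows sorted; weights printed
    with 9 significant digits so read(write(x)) round-trips at that
    precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in network.edge_list():
            fh.write(f"{a}\t{b}\t{_FLOAT_FMT.format(w)}\n")


def read_network(path, registry: RegionRegistry | None = None) -> FunctionalNetwork:
    """Read an edge-list TSV written by :func:`write_network`."""
    registry = registry or default_registry()
    edges: list[tuple[str, str, float]] = []
    node_ids: dict[str, RegionNode] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["node_a", "node_b", "weight"]:
            raise ValueError(f"{path}: line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            a, b, w_str = parts
            try:
                w = float(w_str)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: bad weight {w_str!r}") from None
            if not np.isfinite(w):
                raise ValueError(f"{path}: line {lineno}: non-finite weight {w_str!r}")
            for nid in (a, b):
                if nid not in node_ids:
                    node_ids[nid] = registry.parse_node_id(nid)
            edges.append((a, b, w))
    nodes = [node_ids[k] for k in sorted(node_ids)]
    index = {n.node_id: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b, wt in edges:
        i, j = index[a], index[b]
        w[i, j] = w[j, i] = wt
    return FunctionalNetwork(nodes=nodes, weights=w)
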
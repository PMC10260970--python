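"""Community structure: Leiden ensembles, central partitions, segregation
ratio, and conserved submodules across treatments.

Community detection is repeated (default 100 runs) and summarized by the
*central partition*, the ensemble member closest to all others in
variation-of-information distance.  Modular segregation is quantified by
the ratio r of intra- to inter-community edge weight; submodules conserved
across two treatments are community-pair intersections larger than the
random expectation by at least three standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np

from .network import FunctionalNetwork

__all__ = [
    "Partition",
    "ModuleWeightMatrix",
    "ConservedSubmodule",
    "detect_communities",
    "variation_of_information",
    "central_partition",
    "segregation_ratio",
    "r_significance",
    "conserved_submodules",
]

log = logging.getLogger(__name__)


@dataclass
class Partition:
    """A node -> community assignment with detection metadata.

    Communities are canonicalized: indexed by decreasing size, ties broken
    by the lexicographically smallest member node id.
    """

    node_ids: list[str]
    membership: np.ndarray
    quality: float = float("nan")
    ensemble_size: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=int)
        if self.membership.shape != (len(self.node_ids),):
            raise ValueError("membership must assign one community per node")
        self._canonicalize()

    def _canonicalize(self) -> None:
        labels = np.unique(self.membership)
        keyed = []
        for lab in labels:
            members = [nid for nid, m in zip(self.node_ids, self.membership) if m == lab]
            keyed.append((-len(members), min(members), lab))
        keyed.sort()
        remap = {old: new for new, (_, _, old) in enumerate(keyed)}
        self.membership = np.array([remap[m] for m in self.membership])

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1 if len(self.membership) else 0

    def communities(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_communities)]
        for nid, m in zip(self.node_ids, self.membership):
            out[m].append(nid)
        return [sorted(c) for c in out]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.node_ids, self.membership.tolist()))

    def to_json_dict(self) -> dict:
        return {
            "assignment": self.as_dict(),
            "n_communities": self.n_communities,
            "quality": self.quality,
            "ensemble_size": self.ensemble_size,
            "seed": self.seed,
        }


def _positive_graph(network: FunctionalNetwork) -> tuple[ig.Graph, int]:
    """igraph view of the network with negative edges dropped (count returned)."""
    w = network.weights
    iu, ju = np.triu_indices(network.n_nodes, k=1)
    vals = w[iu, ju]
    nonzero = vals != 0
    negative = int(np.count_nonzero(vals < 0))
    keep = nonzero & (vals > 0)
    g = ig.Graph(
        n=network.n_nodes,
        edges=list(zip(iu[keep].tolist(), ju[keep].tolist())),
    )
    g.es["weight"] = vals[keep].tolist()
    return g, negative


def detect_communities(
    network: FunctionalNetwork,
    n_runs: int = 100,
    seed: int = 0,
    resolution: float = 1.0,
) -> list[Partition]:
    """Leiden community-detection ensemble (modularity objective).

    Runs the Leiden algorithm ``n_runs`` times with distinct seeds derived
    from ``seed`` and returns the canonicalized partitions.  Negative-weight
    edges are dropped beforehand (modularity on signed graphs is undefined
    for the base method); the dropped count is logged.  A network with no
    positive edges yields singleton partitions with a warning.
    """
    g, n_negative = _positive_graph(network)
    if n_negative:
        log.info("dropped %d negative-weight edge(s) before community detection", n_negative)
    node_ids = network.node_ids
    if g.ecount() == 0:
        log.warning("empty edge set: every node is its own community")
        singleton = Partition(
            node_ids=list(node_ids),
            membership=np.arange(network.n_nodes),
            quality=0.0,
            ensemble_size=n_runs,
            seed=seed,
        )
        return [singleton] * n_runs
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    ensemble = []
    for s in run_seeds:
        if resolution == 1.0:
            part = leidenalg.find_partition(
                g, leidenalg.ModularityVertexPartition, weights="weight",
                seed=int(s), n_iterations=-1,  # iterate until no improvement
            )
        else:
            part = leidenalg.find_partition(
                g,
                leidenalg.RBConfigurationVertexPartition,
                weights="weight",
                resolution_parameter=resolution,
                seed=int(s),
                n_iterations=-1,
            )
        ensemble.append(
            Partition(
                node_ids=list(node_ids),
                membership=np.array(part.membership),
                quality=float(part.quality()),
                ensemble_size=n_runs,
                seed=int(s),
            )
        )
    return ensemble


def variation_of_information(p: Partition, q: Partition) -> float:
    """VI(p, q) = H(p) + H(q) - 2 I(p, q), in nats; 0 iff identical."""
    if p.node_ids != q.node_ids:
        raise ValueError("partitions must cover the same nodes in the same order")
    n = len(p.node_ids)
    cont = np.zeros((p.n_communities, q.n_communities))
    for a, b in zip(p.membership, q.membership):
        cont[a, b] += 1
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_p = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
        h_q = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
        nz = pij > 0
        mi = np.sum(pij[nz] * np.log(pij[nz] / (np.outer(pi, pj)[nz])))
    return float(h_p + h_q - 2.0 * mi)


def central_partition(ensemble: list[Partition]) -> Partition:
    """The VI-medoid of an ensemble: minimal summed VI to all members.

    Ties are broken by higher detection quality, then by ensemble order, so
    the result is deterministic and always an ensemble member.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    k = len(ensemble)
    vi = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vi[i, j] = vi[j, i] = variation_of_information(ensemble[i], ensemble[j])
    total = vi.sum(axis=1)
    order = sorted(range(k), key=lambda i: (total[i], -ensemble[i].quality, i))
    return ensemble[order[0]]


@dataclass
class ModuleWeightMatrix:
    """Community-pair total edge weights P and the segregation ratio r.

    ``P[a, b]`` sums ``w[i, j]`` over ordered node pairs i != j with i in
    community a and j in community b: an undirected intra-community edge
    contributes twice to the diagonal, an inter-community edge once to each
    of the two off-diagonal cells.
    """

    P: np.ndarray
    r: float


def segregation_ratio(
    network: FunctionalNetwork, partition: Partition
) -> ModuleWeightMatrix:
    """Segregation ratio r = ((m-1)/2) * TrP / (||P||_1 - TrP).

    r > 1 means communities are internally denser (in total weight) than
    the inter-community medium: segregated activity.  With zero
    inter-community weight r is reported as ``inf`` with a warning.
    """
    if partition.node_ids != network.node_ids:
        raise ValueError("partition does not cover the network's nodes")
    m = partition.n_communities
    if m < 2:
        raise ValueError("segregation ratio requires at least 2 communities")
    ind = np.zeros((network.n_nodes, m))
    ind[np.arange(network.n_nodes), partition.membership] = 1.0
    P = ind.T @ network.weights @ ind  # diagonal of weights is zero: i != j automatic
    tr = float(np.trace(P))
    total = float(P.sum())
    inter = total - tr
    if inter == 0:
        log.warning("zero inter-community weight: r is infinite")
        return ModuleWeightMatrix(P=P, r=float("inf"))
    r = (m - 1) / 2.0 * tr / inter
    return ModuleWeightMatrix(P=P, r=r)


def r_significance(
    network: FunctionalNetwork,
    partition: Partition,
    n_null: int = 1000,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value for the segregation ratio.

    Null model: shuffle the edge weights over the existing edge positions
    (topology and weight multiset preserved), keep the partition fixed, and
    recompute r.  p = (#{null r >= observed} + 1) / (n_null + 1).
    """
    obs = segregation_ratio(network, partition).r
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(network.n_nodes, k=1)
    nz = network.weights[iu, ju] != 0
    ei, ej = iu[nz], ju[nz]
    vals = network.weights[ei, ej]
    m = partition.n_communities
    ind = np.zeros((network.n_nodes, m))
    ind[np.arange(network.n_nodes), partition.membership] = 1.0
    count = 0
    for _ in range(n_null):
        perm = rng.permutation(vals)
        w = np.zeros_like(network.weights)
        w[ei, ej] = perm
        w[ej, ei] = perm
        P = ind.T @ w @ ind
        tr = float(np.trace(P))
        inter = float(P.sum()) - tr
        r_null = float("inf") if inter == 0 else (m - 1) / 2.0 * tr / inter
        if r_null >= obs:
            count += 1
    return (count + 1.0) / (n_null + 1.0)


@dataclass
class ConservedSubmodule:
    """A community-pair intersection retained against the random-set null."""

    pair: tuple[str, str]          # treatment labels (x, y)
    community_x: int
    community_y: int
    nodes: list[str]               # the intersection J, canonically ordered
    size: int
    null_mean: float
    null_sd: float
    retained: bool


def conserved_submodules(
    partition_x: Partition,
    partition_y: Partition,
    labels: tuple[str, str] = ("x", "y"),
    n_null: int = 10_000,
    seed: int = 0,
) -> list[ConservedSubmodule]:
    """Community intersections across two treatments with a random-set null.

    Both partitions must cover the same node universe (any order).  For
    each community pair the intersection size |J| is compared with the
    null distribution of |J| obtained by drawing ``n_null`` pairs of
    uniform random node subsets (without replacement within a set) of the
    same cardinalities; the pair is retained iff |J| >= mu + 3 sigma.
    All pairs are reported, retained or not.
    """
    universe = sorted(partition_x.node_ids)
    if sorted(partition_y.node_ids) != universe:
        raise ValueError("partitions must cover the same node universe")
    n_u = len(universe)
    comms_x = partition_x.communities()
    comms_y = partition_y.communities()
    rng = np.random.default_rng(seed)
    null_cache: dict[tuple[int, int], tuple[float, float]] = {}

    def null_moments(a: int, b: int) -> tuple[float, float]:
        key = (a, b) if a <= b else (b, a)
        if key not in null_cache:
            # vectorized: a random b-subset's overlap with a random a-subset;
            # by symmetry fix the a-subset to the first a indices of a permutation
            scores_a = rng.random((n_null, n_u)).argsort(axis=1)
            scores_b = rng.random((n_null, n_u)).argsort(axis=1)
            in_a = scores_a < key[0]
            in_b = scores_b < key[1]
            sizes = np.count_nonzero(in_a & in_b, axis=1)
            null_cache[key] = (float(sizes.mean()), float(sizes.std()))
        return null_cache[key]

    out: list[ConservedSubmodule] = []
    for i, cx in enumerate(comms_x):
        if len(cx) > n_u:
            raise ValueError("community larger than the node universe")
        sx = set(cx)
        for j, cy in enumerate(comms_y):
            inter = sorted(sx & set(cy))
            mu, sd = null_moments(len(cx), len(cy))
            out.append(
                ConservedSubmodule(
                    pair=labels,
                    community_x=i,
                    community_y=j,
                    nodes=inter,
                    size=len(inter),
                    null_mean=mu,
                    null_sd=sd,
                    retained=len(inter) >= mu + 3.0 * sd,
                )
            )
    return out
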
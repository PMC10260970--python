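"""Graph towers: bootstrapped group-level correlation networks.

With one c-fos snapshot per animal, region-to-region similarity can only be
estimated at the group level, across the M specimens of a treatment.  To
quantify the stability of that estimate we build, for a sampling number
``m < M``, the correlation network of every size-``m`` specimen subset; the
resulting collection of C(M, m) layers is the *graph tower* of the
treatment.  Layer-to-layer variability of each edge weight then drives the
choice of the density threshold: the mean edge-weight heterogeneity (zeta),
the mean coefficient of variation (chi), and an efficiency-based criterion
J = (Eg + El) / rho are all computed as functions of the target density.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats

from .activation import ActivationTable
from .network import FunctionalNetwork, threshold_by_density
from .regions import RegionNode

__all__ = [
    "GraphTower",
    "ThresholdProfile",
    "SelectedThreshold",
    "correlation_network",
    "build_tower",
    "heterogeneity_profile",
    "select_threshold",
    "consensus_network",
    "DEFAULT_RHO_GRID",
]

log = logging.getLogger(__name__)

#: default density grid for threshold profiles: 0.01 .. 0.30 step 0.01
DEFAULT_RHO_GRID: np.ndarray = np.round(np.arange(0.01, 0.301, 0.01), 2)

#: refuse towers with more layers than this (choose a larger m instead)
MAX_LAYERS = 100_000


def _similarity_matrix(block: np.ndarray, method: str) -> np.ndarray:
    if method == "pearson":
        return np.corrcoef(block, rowvar=False)
    if method == "spearman":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, _ = stats.spearmanr(block)
        return np.atleast_2d(rho)
    raise ValueError(f"unknown similarity method {method!r}")


def correlation_network(
    table: ActivationTable,
    treatment: str,
    specimen_subset: list[int] | None = None,
    method: str = "pearson",
) -> FunctionalNetwork:
    """Similarity network of one treatment over a subset of its specimens.

    ``specimen_subset`` indexes into the treatment's specimen list (default:
    all of them).  Edge weight = Pearson correlation (or Spearman) of the
    two nodes' count vectors across the subset; the diagonal is zeroed.
    Nodes constant over the subset have no defined correlation and are
    dropped (logged).
    """
    block, nodes = table.treatment_block(treatment)
    if specimen_subset is not None:
        block = block[list(specimen_subset)]
    if block.shape[0] < 3:
        raise ValueError(
            f"need at least 3 specimens for a correlation, got {block.shape[0]}"
        )
    variable = block.std(axis=0) > 0
    if not variable.any():
        raise ValueError(f"all nodes constant in treatment {treatment!r} subset")
    if not variable.all():
        dropped = [n.node_id for n, v in zip(nodes, variable) if not v]
        log.info("dropping %d constant node(s) in %s: %s", len(dropped), treatment, dropped)
        block = block[:, variable]
        nodes = [n for n, v in zip(nodes, variable) if v]
    w = np.atleast_2d(_similarity_matrix(block, method))
    np.fill_diagonal(w, 0.0)
    return FunctionalNetwork(nodes=nodes, weights=w)


@dataclass
class GraphTower:
    """All C(M, m) subset correlation networks of one treatment.

    Layers share a single node list and are ordered lexicographically by
    specimen-index combination, so towers are deterministic.
    """

    treatment: str
    m: int
    nodes: list[RegionNode]
    layers: list[FunctionalNetwork]
    combinations: list[tuple[int, ...]]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_weights(self) -> np.ndarray:
        """Stacked ``n_layers x N x N`` weight array."""
        return np.stack([layer.weights for layer in self.layers])


def build_tower(table: ActivationTable, treatment: str, m: int | None = None) -> GraphTower:
    """Build the graph tower of ``treatment`` with sampling number ``m``.

    Default ``m = M - 1`` (the jackknife tower: M leave-one-out layers).
    Nodes constant in *any* subset are dropped from every layer so all
    layers share one node set.
    """
    block, nodes = table.treatment_block(treatment)
    M = block.shape[0]
    if m is None:
        m = M - 1
    if not 3 <= m <= M:
        raise ValueError(f"sampling number m={m} out of range [3, M={M}]")
    n_layers = math.comb(M, m)
    if n_layers > MAX_LAYERS:
        raise ValueError(
            f"C({M},{m}) = {n_layers} layers exceeds the cap {MAX_LAYERS}; "
            "choose a larger m"
        )
    combos = list(combinations(range(M), m))
    # nodes constant in any subset are dropped tower-wide
    keep = np.ones(len(nodes), dtype=bool)
    for combo in combos:
        keep &= block[list(combo)].std(axis=0) > 0
    if not keep.all():
        dropped = [n.node_id for n, k in zip(nodes, keep) if not k]
        log.info("tower %s: dropping constant node(s): %s", treatment, dropped)
    sub = block[:, keep]
    kept_nodes = [n for n, k in zip(nodes, keep) if k]
    layers = []
    for combo in combos:
        w = np.corrcoef(sub[list(combo)], rowvar=False)
        np.fill_diagonal(w, 0.0)
        layers.append(FunctionalNetwork(nodes=kept_nodes, weights=w))
    return GraphTower(
        treatment=treatment, m=m, nodes=kept_nodes, layers=layers, combinations=combos
    )


@dataclass
class ThresholdProfile:
    """Per-density tower statistics used to pick the operating density."""

    rho: np.ndarray
    zeta: np.ndarray      # mean across-layer edge-weight SD (heterogeneity)
    chi_cv: np.ndarray    # mean across-layer coefficient of variation
    eg: np.ndarray        # global efficiency of the mean thresholded graph
    el: np.ndarray        # local efficiency of the mean thresholded graph
    j: np.ndarray         # (Eg + El) / rho

    def to_dict(self) -> dict:
        return {
            "rho": self.rho.tolist(),
            "zeta": self.zeta.tolist(),
            "chi_cv": self.chi_cv.tolist(),
            "eg": self.eg.tolist(),
            "el": self.el.tolist(),
            "j": self.j.tolist(),
        }


def _binary_graph(weights: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(weights.shape[0]))
    iu, ju = np.nonzero(np.triu(weights, k=1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return g


def heterogeneity_profile(
    tower: GraphTower, rho_grid: np.ndarray | None = None
) -> ThresholdProfile:
    """Tower heterogeneity and efficiency statistics along a density grid.

    For each target density rho, every layer is thresholded at rho; over the
    union of surviving edges, each edge's across-layer mean and population
    standard deviation are taken with an edge absent from a layer counted as
    weight 0.  ``zeta`` is the mean SD over those edges and ``chi_cv`` the
    mean SD/mean over edges with nonzero mean.  ``Eg``/``El`` are the
    global/local efficiency of the binarized graph obtained by thresholding
    the layer-averaged weights at rho, and ``J = (Eg + El) / rho``.
    """
    rho_grid = DEFAULT_RHO_GRID if rho_grid is None else np.asarray(rho_grid, dtype=float)
    if rho_grid.size == 0:
        raise ValueError("density grid must be nonempty")
    if (rho_grid <= 0).any() or (rho_grid > 1).any():
        raise ValueError("density grid must lie in (0, 1]")
    single_layer = tower.n_layers < 2
    if single_layer:
        log.warning("single-layer tower: zeta and chi are 0 by convention")

    mean_raw = tower.layer_weights().mean(axis=0)
    mean_net = FunctionalNetwork(nodes=list(tower.nodes), weights=mean_raw)

    zeta = np.zeros(rho_grid.size)
    chi = np.zeros(rho_grid.size)
    eg = np.zeros(rho_grid.size)
    el = np.zeros(rho_grid.size)
    for k, rho in enumerate(rho_grid):
        thr = np.stack(
            [threshold_by_density(layer, rho).weights for layer in tower.layers]
        )
        union = (thr != 0).any(axis=0)
        iu = np.triu(union, k=1)
        if iu.any() and not single_layer:
            mu = thr.mean(axis=0)[iu]
            sd = thr.std(axis=0)[iu]  # population SD: layers enumerate all subsets
            zeta[k] = sd.mean()
            nz = mu != 0
            chi[k] = (sd[nz] / mu[nz]).mean() if nz.any() else 0.0
        g = _binary_graph(threshold_by_density(mean_net, rho).weights)
        eg[k] = nx.global_efficiency(g)
        el[k] = nx.local_efficiency(g)
    j = (eg + el) / rho_grid
    return ThresholdProfile(rho=rho_grid, zeta=zeta, chi_cv=chi, eg=eg, el=el, j=j)


@dataclass
class SelectedThreshold:
    """Operating density with the strategy that selected it."""

    rho0: float
    strategy: str
    rho_heterogeneity: float
    rho_efficiency: float
    warning: str | None = None


def select_threshold(
    profile: ThresholdProfile, strategy: str = "heterogeneity", tol_frac: float = 0.1
) -> SelectedThreshold:
    """Pick the operating density rho0 from a threshold profile.

    ``"heterogeneity"`` (default): among densities where zeta is within
    ``tol_frac`` of its range above the minimum (zeta "still minimal"),
    return the one maximizing chi (the coefficient-of-variation peak).
    ``"efficiency"``: return argmax of J.  Both candidates are always
    reported.  Ties resolve to the smallest density; a flat profile yields
    a warning.
    """
    if profile.rho.size < 3:
        raise ValueError("profile needs at least 3 grid points")
    warning = None
    zrange = float(profile.zeta.max() - profile.zeta.min())
    admissible = profile.zeta <= profile.zeta.min() + tol_frac * zrange
    if not admissible.any():  # cannot happen with tol >= 0, kept defensive
        admissible = np.ones_like(admissible)
        warning = "empty admissible set; falling back to argmax chi"
    chi_adm = np.where(admissible, profile.chi_cv, -np.inf)
    rho_het = float(profile.rho[int(np.argmax(chi_adm))])
    rho_eff = float(profile.rho[int(np.argmax(profile.j))])
    if np.ptp(profile.chi_cv) == 0 and zrange == 0:
        warning = "flat zeta and chi profiles; returning smallest grid density"
        rho_het = float(profile.rho[0])
    if strategy == "heterogeneity":
        rho0 = rho_het
    elif strategy == "efficiency":
        rho0 = rho_eff
    else:
        raise ValueError(f"unknown threshold strategy {strategy!r}")
    if warning:
        log.warning(warning)
    return SelectedThreshold(
        rho0=rho0,
        strategy=strategy,
        rho_heterogeneity=rho_het,
        rho_efficiency=rho_eff,
        warning=warning,
    )


def consensus_network(tower: GraphTower, rho: float) -> FunctionalNetwork:
    """Average of the rho-thresholded layers (edge absent from a layer = 0).

    This is the tower averaged over all bootstrap subsamples at fixed
    density; the average itself is *not* re-thresholded.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {rho}")
    thr = np.stack([threshold_by_density(layer, rho).weights for layer in tower.layers])
    return FunctionalNetwork(nodes=list(tower.nodes), weights=thr.mean(axis=0))
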
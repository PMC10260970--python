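"""Egonetwork change analysis: learning-minus-control difference matrices.

For each stimulus condition (social S, asocial A) the difference matrix
``Delta = A(learning) - A(control)`` quantifies, row by row, how each
region's local neighborhood (egonetwork) is rewired by learning.  Per
region we compute the amplitude of the change (Euclidean norm of the row)
and, across the two conditions, the cosine similarity of the corresponding
rows; both are assessed against resampling null models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import FunctionalNetwork
from .regions import RegionNode

__all__ = [
    "DifferenceMatrix",
    "difference_matrix",
    "amplitudes",
    "amplitude_null",
    "AmplitudeNull",
    "cosine_similarities",
    "cosine_null",
    "CosineNull",
    "region_change_table",
]


@dataclass
class DifferenceMatrix:
    """Learning-minus-control adjacency difference on a common node set."""

    condition: str
    nodes: list[RegionNode]
    delta: np.ndarray
    dropped_nodes: list[str]
    rho: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        if d.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("delta must be N x N")
        if not np.allclose(d, d.T):
            raise ValueError("delta must be symmetric")
        np.fill_diagonal(d, 0.0)
        self.delta = d

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def off_diagonal(self) -> np.ndarray:
        """All off-diagonal entries (both triangles), flattened."""
        n = len(self.nodes)
        mask = ~np.eye(n, dtype=bool)
        return self.delta[mask]


def difference_matrix(
    learning: FunctionalNetwork,
    control: FunctionalNetwork,
    condition: str = "",
    rho: float | None = None,
) -> DifferenceMatrix:
    """Entrywise ``learning - control`` on the intersection of node sets.

    Both networks should be thresholded at the same operating density;
    nodes outside the intersection are recorded as dropped.
    """
    ids_l = {n.node_id: i for i, n in enumerate(learning.nodes)}
    ids_c = {n.node_id: i for i, n in enumerate(control.nodes)}
    common = [n.node_id for n in learning.nodes if n.node_id in ids_c]
    if not common:
        raise ValueError("learning and control networks share no nodes")
    dropped = sorted((set(ids_l) | set(ids_c)) - set(common))
    li = [ids_l[k] for k in common]
    ci = [ids_c[k] for k in common]
    delta = learning.weights[np.ix_(li, li)] - control.weights[np.ix_(ci, ci)]
    nodes = [learning.nodes[i] for i in li]
    return DifferenceMatrix(
        condition=condition, nodes=nodes, delta=delta, dropped_nodes=dropped, rho=rho
    )


def amplitudes(dm: DifferenceMatrix) -> np.ndarray:
    """Per-node change amplitude |Delta_i|: Euclidean norm of row i.

    The diagonal is zero by construction so it never contributes.
    """
    return np.linalg.norm(dm.delta, axis=1)


@dataclass
class AmplitudeNull:
    """Resampling expectation for egonetwork change amplitudes."""

    band_low: float      # 5th percentile of null row norms
    band_high: float     # 95th percentile
    percentile: np.ndarray  # percentile of each observed |Delta_i| in the null
    large: np.ndarray    # observed at or above the 95th percentile
    small: np.ndarray    # observed below the 5th percentile
    n_reps: int


def amplitude_null(dm: DifferenceMatrix, n_reps: int = 10_000, seed: int = 0) -> AmplitudeNull:
    """Null model for row amplitudes by resampling pooled Delta entries.

    Each replicate draws N-1 values (one row's worth, diagonal excluded)
    uniformly at random *with replacement* from the pooled off-diagonal
    entries of Delta and records the Euclidean norm of that vector.  The
    5th/95th percentiles of the null norms form the expectation band;
    observed amplitudes at/above the 95th (below the 5th) percentile are
    flagged large (small).
    """
    rng = np.random.default_rng(seed)
    pool = dm.off_diagonal()
    n = len(dm.nodes)
    if n < 2:
        raise ValueError("difference matrix must have at least 2 nodes")
    draws = rng.choice(pool, size=(n_reps, n - 1), replace=True)
    null_norms = np.linalg.norm(draws, axis=1)
    obs = amplitudes(dm)
    band_low, band_high = np.percentile(null_norms, [5.0, 95.0])
    # percentile of each observed amplitude within the null sample
    pct = np.array([100.0 * np.mean(null_norms <= a) for a in obs])
    degenerate = band_high == band_low  # e.g. all-equal entries: nothing to flag
    return AmplitudeNull(
        band_low=float(band_low),
        band_high=float(band_high),
        percentile=pct,
        large=(obs > band_high) if not degenerate else np.zeros(len(obs), dtype=bool),
        small=(obs < band_low) if not degenerate else np.zeros(len(obs), dtype=bool),
        n_reps=n_reps,
    )


def _common_rows(dm_s: DifferenceMatrix, dm_a: DifferenceMatrix):
    ids_s = {k: i for i, k in enumerate(dm_s.node_ids)}
    ids_a = {k: i for i, k in enumerate(dm_a.node_ids)}
    common = [k for k in dm_s.node_ids if k in ids_a]
    if not common:
        raise ValueError("difference matrices share no nodes")
    s = dm_s.delta[np.ix_([ids_s[k] for k in common], [ids_s[k] for k in common])]
    a = dm_a.delta[np.ix_([ids_a[k] for k in common], [ids_a[k] for k in common])]
    return common, s, a


def _row_cosines(s: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity; NaN where either row norm is zero."""
    ns = np.linalg.norm(s, axis=1)
    na = np.linalg.norm(a, axis=1)
    dot = np.einsum("ij,ij->i", s, a)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = dot / (ns * na)
    cos[(ns == 0) | (na == 0)] = np.nan
    return cos


def cosine_similarities(dm_s: DifferenceMatrix, dm_a: DifferenceMatrix) -> pd.Series:
    """Per-node cosine similarity of Delta^S and Delta^A rows.

    Values lie in [-1, 1]; a node whose row is all zero in either matrix
    has no defined direction and gets ``NaN``.
    """
    common, s, a = _common_rows(dm_s, dm_a)
    return pd.Series(_row_cosines(s, a), index=common, name="chi_cos")


@dataclass
class CosineNull:
    """Permutation null for row-wise cosine similarity."""

    node_ids: list[str]
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray        # NaN where observed or null SD undefined
    p: np.ndarray        # empirical two-sided, add-one corrected
    similar: np.ndarray    # z > 1.5 and p < 0.05
    dissimilar: np.ndarray  # z < -1.5 and p < 0.05
    n_reps: int


def cosine_null(
    dm_s: DifferenceMatrix,
    dm_a: DifferenceMatrix,
    n_reps: int = 1000,
    seed: int = 0,
) -> CosineNull:
    """Row-permutation null for the cosine similarities.

    Each replicate independently permutes the off-diagonal entries within
    every row of Delta^A (Delta^S held fixed) and recomputes the cosines:
    row weight distributions are preserved while cross-condition alignment
    is destroyed.  z-scores are against the null mean/SD; p is the
    empirical two-sided tail (add-one corrected).  Flags: similar when
    z > 1.5 and p < 0.05, dissimilar when z < -1.5 and p < 0.05.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    rng = np.random.default_rng(seed)
    common, s, a = _common_rows(dm_s, dm_a)
    n = len(common)
    obs = _row_cosines(s, a)
    off = ~np.eye(n, dtype=bool)
    null = np.empty((n_reps, n))
    a_perm = a.copy()
    for r in range(n_reps):
        for i in range(n):
            row = a[i, off[i]]
            a_perm[i, off[i]] = rng.permutation(row)
        null[r] = _row_cosines(s, a_perm)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN null columns
        null_mean = np.nanmean(null, axis=0)
        null_sd = np.nanstd(null, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - null_mean) / null_sd
    z[null_sd == 0] = np.nan
    dev = np.abs(null - null_mean)  # two-sided tail around the null mean
    obs_dev = np.abs(obs - null_mean)
    b = np.nansum(dev >= obs_dev, axis=0)
    p = (b + 1.0) / (n_reps + 1.0)
    p[np.isnan(obs)] = np.nan
    valid = ~np.isnan(z) & ~np.isnan(p)
    similar = valid & (z > 1.5) & (p < 0.05)
    dissimilar = valid & (z < -1.5) & (p < 0.05)
    return CosineNull(
        node_ids=common,
        observed=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p=p,
        similar=similar,
        dissimilar=dissimilar,
        n_reps=n_reps,
    )


def region_change_table(
    dm_s: DifferenceMatrix,
    dm_a: DifferenceMatrix,
    n_reps_amplitude: int = 10_000,
    n_reps_cosine: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-region change summary across the two conditions.

    Columns: amplitude and null percentile per condition with large/small
    flags, cosine similarity with z, p, similar/dissimilar flags.  Also
    reports the across-node Pearson and Spearman correlation of the two
    amplitude profiles in ``DataFrame.attrs``.
    """
    common, s, a = _common_rows(dm_s, dm_a)
    sub_s = DifferenceMatrix(dm_s.condition, [n for n in dm_s.nodes if n.node_id in set(common)], s, [])
    sub_a = DifferenceMatrix(dm_a.condition, [n for n in dm_a.nodes if n.node_id in set(common)], a, [])
    amp_s = amplitudes(sub_s)
    amp_a = amplitudes(sub_a)
    null_s = amplitude_null(sub_s, n_reps=n_reps_amplitude, seed=seed)
    null_a = amplitude_null(sub_a, n_reps=n_reps_amplitude, seed=seed + 1)
    cn = cosine_null(sub_s, sub_a, n_reps=n_reps_cosine, seed=seed + 2)
    df = pd.DataFrame(
        {
            "amplitude_S": amp_s,
            "pct_S": null_s.percentile,
            "large_S": null_s.large,
            "small_S": null_s.small,
            "amplitude_A": amp_a,
            "pct_A": null_a.percentile,
            "large_A": null_a.large,
            "small_A": null_a.small,
            "chi_cos": cn.observed,
            "z": cn.z,
            "p": cn.p,
            "similar": cn.similar,
            "dissimilar": cn.dissimilar,
        },
        index=pd.Index(common, name="node_id"),
    )
    from scipy import stats as _st

    pear = _st.pearsonr(amp_s, amp_a)
    spear = _st.spearmanr(amp_s, amp_a)
    df.attrs["amplitude_correlation"] = {
        "pearson_r": float(pear.statistic),
        "pearson_p": float(pear.pvalue),
        "spearman_rho": float(spear.statistic),
        "spearman_p": float(spear.pvalue),
    }
    return df
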
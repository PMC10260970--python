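"""Behavioral and regional-activation statistics.

Covers the statistics used around the conditioning paradigm: one- and
two-sample binomial z tests (normal approximation, no continuity
correction, unpooled two-sample standard error), partial eta-squared
effect sizes, a 2x2 chi-square on proportions, Benjamini-Hochberg p-value
adjustment, learner / non-learner / non-retention classification, Theil-Sen
learning-curve comparison with permutation tests, and per-region rank-based
contrasts with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activation import ActivationTable

__all__ = [
    "TestResult",
    "BehaviorTable",
    "binom_one_sample_z",
    "binom_two_sample_z",
    "partial_eta_squared",
    "chi_square_proportions",
    "benjamini_hochberg",
    "classify_learners",
    "compare_learning_curves",
    "region_contrast",
]

#: four-arm plus maze: chance level of a correct arm choice
CHANCE_LEVEL = 0.25


@dataclass
class TestResult:
    """A statistic with its degrees of freedom, p-value and effect size."""

    name: str
    statistic: float
    p_value: float
    df: tuple | None = None
    effect_size: dict[str, float] = field(default_factory=dict)
    n_detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "n_detail": self.n_detail,
        }


@dataclass
class BehaviorTable:
    """Per-trial choices and probe-test occupancy durations.

    ``trials``: columns subject_id, treatment, session (1-based), trial
    (1-based), correct (0/1).  ``probe``: columns subject_id, treatment,
    target, opposite, left, right (cumulative seconds in each arm's region
    of interest).  ``labels`` optionally carries ground-truth subject
    labels (synthetic data).
    """

    trials: pd.DataFrame
    probe: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        per = self.trials.groupby(["subject_id", "session"])["trial"].count()
        if (per > 8).any():
            raise ValueError("more than 8 trials in a session")
        arms = ["target", "opposite", "left", "right"]
        if (self.probe[arms] < 0).any().any():
            raise ValueError("probe durations must be nonnegative")

    def session_proportions(self) -> pd.DataFrame:
        """subjects x sessions matrix of proportion correct."""
        out = (
            self.trials.groupby(["subject_id", "session"])["correct"]
            .mean()
            .unstack("session")
        )
        return out

    def subjects(self, treatment: str | None = None) -> list[str]:
        t = self.trials
        if treatment is not None:
            t = t[t["treatment"] == treatment]
        return sorted(t["subject_id"].unique())

    def subset(self, treatment: str) -> "BehaviorTable":
        """The sub-table of one treatment group."""
        trials = self.trials[self.trials["treatment"] == treatment].reset_index(drop=True)
        probe = self.probe[self.probe["treatment"] == treatment].reset_index(drop=True)
        labels = None
        if self.labels is not None:
            labels = self.labels[self.labels.index.isin(trials["subject_id"])]
        return BehaviorTable(trials=trials, probe=probe, labels=labels)


# -- binomial z tests --------------------------------------------------------


def _odds(p: float) -> float:
    return p / (1.0 - p)


def binom_one_sample_z(successes: int, n: int, p0: float) -> TestResult:
    """One-sample binomial z test of p-hat against p0.

    Z = (p-hat - p0) / sqrt(p0 (1 - p0) / n), normal approximation with no
    continuity correction; two-sided p from the standard normal.  Effect
    size OR = odds(p-hat) / odds(p0), with the Haldane-Anscombe 0.5
    adjustment applied only when p-hat is exactly 0 or 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    p_hat = successes / n
    z = (p_hat - p0) / np.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * stats.norm.sf(abs(z))
    if p_hat in (0.0, 1.0):
        odds_hat = (successes + 0.5) / (n - successes + 0.5)
    else:
        odds_hat = _odds(p_hat)
    return TestResult(
        name="binomial one-sample z",
        statistic=float(z),
        p_value=float(p),
        df=(n,),
        effect_size={"OR": float(odds_hat / _odds(p0)), "p_hat": float(p_hat)},
        n_detail={"successes": successes, "n": n, "p0": p0},
    )


def binom_two_sample_z(s1: int, n1: int, s2: int, n2: int) -> TestResult:
    """Two-sample binomial z test on the difference of proportions.

    Uses the *unpooled* standard error
    sqrt(p1 (1-p1)/n1 + p2 (1-p2)/n2), no continuity correction; two-sided
    p.  OR is the cross-product odds ratio with a 0.5 cell adjustment when
    any cell is zero.  Degenerate variance (both proportions 0 or 1) is an
    error.
    """
    for s, n in ((s1, n1), (s2, n2)):
        if n < 1 or not 0 <= s <= n:
            raise ValueError("invalid successes/trials counts")
    p1, p2 = s1 / n1, s2 / n2
    var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0:
        raise ValueError("degenerate variance: both proportions are 0 or 1")
    dp = p1 - p2
    z = dp / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    a, b, c, d = s1, n1 - s1, s2, n2 - s2
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return TestResult(
        name="binomial two-sample z",
        statistic=float(z),
        p_value=float(p),
        df=(n1, n2),
        effect_size={"delta_p_hat": float(dp), "OR": float((a / b) / (c / d))},
        n_detail={"s1": s1, "n1": n1, "s2": s2, "n2": n2},
    )


def partial_eta_squared(F: float, df_n: int, df_d: int) -> float:
    """Partial eta-squared: F df_n / (F df_n + df_d).

    For a t statistic pass ``F = t**2`` with ``df_n = 1``.
    """
    if F < 0:
        raise ValueError("F must be nonnegative")
    if df_n < 1 or df_d < 1:
        raise ValueError("degrees of freedom must be positive")
    return float(F * df_n / (F * df_n + df_d))


def chi_square_proportions(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square (df = 1, no continuity correction) on a 2x2 table.

    Rows are groups: group 1 = (a, b), group 2 = (c, d), columns
    event/non-event.  Effect size is the ratio of the two group proportions
    a/(a+b) over c/(c+d).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise ValueError("zero margin in the 2x2 table")
    x2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(x2, df=1))
    ratio = (a / r1) / (c / r2)
    return TestResult(
        name="chi-square proportions",
        statistic=float(x2),
        p_value=p,
        df=(1,),
        effect_size={"proportion_ratio": float(ratio)},
        n_detail={"table": [[a, b], [c, d]]},
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


# -- learner classification --------------------------------------------------


def classify_learners(
    behavior: BehaviorTable,
    paired_treatment: str,
    control_treatment: str,
    retention_quantile: float | None = None,
) -> pd.Series:
    """Label paired-treatment subjects learner / non_learner / non_retention.

    A subject is a *non-learner* when its last-session proportion correct
    falls below the lower limit of the 95% confidence interval of the
    paired group's mean last-session proportion (normal approximation,
    mean - 1.96 SD / sqrt(n)).  Among the rest, a subject shows
    *non-retention* when its probe target-arm cumulative duration falls
    below the retention criterion: the control group's mean duration by
    default, or the control group's ``retention_quantile`` quantile when
    given.  Everyone else is a *learner*.
    """
    props = behavior.session_proportions()
    last = props[props.columns.max()]
    paired = behavior.subjects(paired_treatment)
    if len(paired) < 2:
        raise ValueError("need at least 2 subjects in the paired treatment")
    grp = last.loc[paired]
    lower = grp.mean() - 1.96 * grp.std(ddof=1) / np.sqrt(len(grp))
    probe = behavior.probe.set_index("subject_id")
    ctrl_dur = probe.loc[
        probe["treatment"] == control_treatment, "target"
    ]
    if retention_quantile is None:
        criterion = float(ctrl_dur.mean())
    else:
        criterion = float(ctrl_dur.quantile(retention_quantile))
    labels = {}
    for s in paired:
        if grp[s] < lower:
            labels[s] = "non_learner"
        else:
            if s not in probe.index or pd.isna(probe.loc[s, "target"]):
                raise ValueError(f"missing probe data for training learner {s!r}")
            labels[s] = (
                "non_retention" if probe.loc[s, "target"] < criterion else "learner"
            )
    return pd.Series(labels, name="label")


# -- learning-curve comparison ----------------------------------------------


def _curve_stats(props: pd.DataFrame) -> tuple[float, float]:
    """Theil-Sen slope and elevation of the per-session group mean curve."""
    sessions = props.columns.to_numpy(dtype=float)
    y = props.mean(axis=0).to_numpy()
    slope, intercept, _, _ = stats.theilslopes(y, sessions)
    return float(slope), float(intercept)


def compare_learning_curves(
    group_a: BehaviorTable,
    group_b: BehaviorTable,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[TestResult, TestResult]:
    """Compare two groups' learning curves by Theil-Sen slope and elevation.

    Per-session group proportions are fit with Theil-Sen lines; the slope
    and elevation (intercept) differences are tested by permuting the
    subject-to-group assignment.  Returns two-sided permutation
    ``(slope, elevation)`` results, add-one corrected.
    """
    pa = group_a.session_proportions()
    pb = group_b.session_proportions()
    if pa.shape[1] < 2 or pb.shape[1] < 2:
        raise ValueError("slope undefined with fewer than 2 sessions")
    common = sorted(set(pa.columns) & set(pb.columns))
    pa, pb = pa[common], pb[common]
    obs_sa, obs_ia = _curve_stats(pa)
    obs_sb, obs_ib = _curve_stats(pb)
    obs_slope = obs_sa - obs_sb
    obs_elev = obs_ia - obs_ib
    pooled = pd.concat([pa, pb], axis=0)
    n_a = len(pa)
    rng = np.random.default_rng(seed)
    count_slope = count_elev = 0
    idx = np.arange(len(pooled))
    for _ in range(n_permutations):
        perm = rng.permutation(idx)
        ga = pooled.iloc[perm[:n_a]]
        gb = pooled.iloc[perm[n_a:]]
        sa, ia = _curve_stats(ga)
        sb, ib = _curve_stats(gb)
        if abs(sa - sb) >= abs(obs_slope):
            count_slope += 1
        if abs(ia - ib) >= abs(obs_elev):
            count_elev += 1
    p_slope = (count_slope + 1.0) / (n_permutations + 1.0)
    p_elev = (count_elev + 1.0) / (n_permutations + 1.0)
    detail = {"n_a": n_a, "n_b": len(pb), "n_permutations": n_permutations}
    return (
        TestResult("learning-curve slope (Theil-Sen, permutation)",
                   obs_slope, p_slope, n_detail=detail),
        TestResult("learning-curve elevation (Theil-Sen, permutation)",
                   obs_elev, p_elev, n_detail=detail),
    )


# -- regional contrasts ------------------------------------------------------


def region_contrast(
    table: ActivationTable, pair: tuple[str, str]
) -> pd.DataFrame:
    """Per-node rank-based planned comparison between two treatments.

    Wilcoxon rank-sum (Mann-Whitney U, normal approximation) per node on
    the raw counts, BH-adjusted across the contrasted node set; the sign
    of the median difference gives the effect direction.  Nodes constant
    in both groups get p = 1 and are flagged.
    """
    t1, t2 = pair
    for t in pair:
        if len(table.specimen_indices(t)) < 3:
            raise ValueError(f"treatment {t!r} needs at least 3 specimens")
    b1, nodes1 = table.treatment_block(t1)
    b2, nodes2 = table.treatment_block(t2)
    ids1 = {n.node_id: i for i, n in enumerate(nodes1)}
    ids2 = {n.node_id: i for i, n in enumerate(nodes2)}
    common = [n.node_id for n in nodes1 if n.node_id in ids2]
    rows = []
    for nid in common:
        x = b1[:, ids1[nid]]
        y = b2[:, ids2[nid]]
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            rows.append((nid, np.nan, 1.0, 0.0, True))
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        direction = float(np.sign(np.median(x) - np.median(y)))
        rows.append((nid, float(res.statistic), float(res.pvalue), direction, False))
    df = pd.DataFrame(
        rows, columns=["node_id", "U", "p", "direction", "constant"]
    ).set_index("node_id")
    df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
    return df
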
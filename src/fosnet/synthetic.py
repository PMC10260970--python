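"""Synthetic activation tables and behavioral records with known ground truth.

The activation generator is a Gaussian one-factor-per-block latent model:
each planted block of regions shares, within each specimen of the
treatments it covers, a common standard-normal factor whose loading on node
i is ``lambda * mu_i`` (a *relative* loading strength, so the induced
within-block Pearson correlation is lambda^2 mu^2 / (lambda^2 mu^2 +
noise_sd^2) independent of the count scale).  Latent values are truncated
at zero and rounded to produce nonnegative integer counts — the analysis
only ever consumes Pearson correlations of counts, so this is the simplest
model with controllable pairwise correlation.

A block listed for several treatments plants the *same* correlation
structure in each of them: the machinery that detects submodules conserved
across treatments can be validated against these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activation import TREATMENTS, ActivationTable
from .behavior import CHANCE_LEVEL, BehaviorTable
from .communities import Partition
from .regions import RegionNode, RegionRegistry, default_registry

__all__ = [
    "Block",
    "SyntheticSpec",
    "GroundTruth",
    "generate_activation",
    "generate_behavior",
    "study_like_spec",
]


@dataclass(frozen=True)
class Block:
    """A planted co-fluctuation block: node indices, covered treatments, loading."""

    treatments: frozenset
    nodes: tuple[int, ...]
    lam: float


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic activation generator.

    Defaults mirror the c-fos mapping design: 4 treatments x 8 specimens,
    70 hemispheric region nodes (35 regions x 2 sides), baseline counts
    around 100 cells with noise_sd = 30 (30% of baseline).
    """

    n_nodes: int = 70
    specimens_per_treatment: int = 8
    treatments: tuple[str, ...] = TREATMENTS
    blocks: list[Block] = field(default_factory=list)
    differential_regions: list[tuple[str, int, float]] = field(default_factory=list)
    baseline_mean: float | np.ndarray = 100.0
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments: {sorted(unknown)}")
        for blk in self.blocks:
            if not 0.0 <= blk.lam < 1.0:
                raise ValueError(f"factor loading must lie in [0, 1), got {blk.lam}")
            if any(i < 0 or i >= self.n_nodes for i in blk.nodes):
                raise ValueError("block node index out of range")
        for t in self.treatments:
            seen: set[int] = set()
            for blk in self.blocks:
                if t in blk.treatments:
                    overlap = seen & set(blk.nodes)
                    if overlap:
                        raise ValueError(
                            f"blocks active in {t!r} overlap on nodes {sorted(overlap)}"
                        )
                    seen |= set(blk.nodes)
        for t, i, _ in self.differential_regions:
            if t not in self.treatments or not 0 <= i < self.n_nodes:
                raise ValueError(f"invalid differential region ({t}, {i})")

    def mu(self) -> np.ndarray:
        mu = np.broadcast_to(np.asarray(self.baseline_mean, dtype=float), (self.n_nodes,))
        if (mu <= 0).any():
            raise ValueError("baseline means must be positive")
        return np.array(mu)


def _spec_nodes(spec: SyntheticSpec, registry: RegionRegistry) -> list[RegionNode]:
    nodes = registry.all_nodes()
    if spec.n_nodes > len(nodes):
        extra = [f"X{k}" for k in range((spec.n_nodes - len(nodes) + 1) // 2 + 1)]
        registry = registry.extended(extra)
        nodes = registry.all_nodes()
    return nodes[: spec.n_nodes]


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    partitions: dict[str, Partition]                 # per treatment
    conserved: dict[tuple[str, str], list[list[str]]]  # per treatment pair
    differential: list[tuple[str, str, float]]       # (treatment, node_id, delta)
    seed: int


def generate_activation(
    spec: SyntheticSpec, registry: RegionRegistry | None = None
) -> tuple[ActivationTable, GroundTruth]:
    """Draw an activation table from the planted latent model.

    Specimen s of treatment t gets, for node i,
    ``count = round(max(0, mu_i + delta_ti + sum_b lam_b mu_i f_sb + eps))``
    with one factor f per (specimen, active block) and independent Gaussian
    noise eps.  The same seed always yields the same table.
    """
    rng = np.random.default_rng(spec.seed)
    registry = registry or default_registry()
    nodes = _spec_nodes(spec, registry)
    node_ids = [n.node_id for n in nodes]
    mu = spec.mu()

    shifts: dict[str, np.ndarray] = {t: np.zeros(spec.n_nodes) for t in spec.treatments}
    for t, i, delta in spec.differential_regions:
        shifts[t][i] += delta

    specimens: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    for t in spec.treatments:
        active = [b for b in spec.blocks if t in b.treatments]
        for s in range(spec.specimens_per_treatment):
            v = mu + shifts[t] + rng.normal(0.0, spec.noise_sd, size=spec.n_nodes)
            for blk in active:
                f = rng.standard_normal()
                idx = list(blk.nodes)
                v[idx] += blk.lam * mu[idx] * f
            rows.append(np.round(np.maximum(0.0, v)))
            specimens.append((f"{t}{s + 1:02d}", t))
    table = ActivationTable(
        nodes=nodes, specimens=specimens, counts=np.vstack(rows), registry=registry
    )

    partitions: dict[str, Partition] = {}
    for t in spec.treatments:
        membership = np.full(spec.n_nodes, -1)
        label = 0
        for blk in spec.blocks:
            if t in blk.treatments:
                membership[list(blk.nodes)] = label
                label += 1
        for i in range(spec.n_nodes):  # uncovered nodes become singletons
            if membership[i] == -1:
                membership[i] = label
                label += 1
        partitions[t] = Partition(node_ids=list(node_ids), membership=membership)
    conserved: dict[tuple[str, str], list[list[str]]] = {}
    for a in spec.treatments:
        for b in spec.treatments:
            if a < b:
                shared = [
                    sorted(node_ids[i] for i in blk.nodes)
                    for blk in spec.blocks
                    if a in blk.treatments and b in blk.treatments
                ]
                if shared:
                    conserved[(a, b)] = shared
    truth = GroundTruth(
        partitions=partitions,
        conserved=conserved,
        differential=[(t, node_ids[i], d) for t, i, d in spec.differential_regions],
        seed=spec.seed,
    )
    return table, truth


def study_like_spec(
    seed: int = 0,
    n_nodes: int = 70,
    specimens_per_treatment: int = 8,
    lam: float = 0.85,
    noise_frac: float = 0.3,
    baseline_mean: float = 100.0,
    block_size: int = 14,
) -> SyntheticSpec:
    """The default study-emulating generator configuration.

    Five planted blocks of ``block_size`` nodes mirror the module structure
    the analysis is meant to resolve: one block co-fluctuates in all four
    treatments (a visual-response analog), one is shared by the two
    learning treatments (AL, SL), one by the two controls (AC, SC), and one
    by the two social treatments (SC, SL).  Nodes with no active block in a
    given treatment are grouped into treatment-specific "filler" blocks by
    an independent seeded shuffle, so every treatment has a full planted
    partition but filler groupings are not conserved across treatments.
    Four nodes carry a +3 noise_sd activation shift in SL and two nodes a
    -1 noise_sd shift in AL (differential regions).
    """
    if n_nodes < 5 * block_size:
        raise ValueError("need at least 5 * block_size nodes")
    noise_sd = noise_frac * baseline_mean
    g = [
        tuple(range(k * block_size, (k + 1) * block_size)) for k in range(5)
    ]  # V, L, D, S, F
    v_blk, l_blk, d_blk, s_blk, f_blk = g
    leftover = tuple(range(5 * block_size, n_nodes))
    blocks = [
        Block(frozenset(TREATMENTS), v_blk, lam),
        Block(frozenset({"AL", "SL"}), l_blk, lam),
        Block(frozenset({"AC", "SC"}), d_blk, lam),
        Block(frozenset({"SC", "SL"}), s_blk, lam),
    ]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF111]))
    for t in TREATMENTS:
        covered: set[int] = set()
        for blk in blocks:
            if t in blk.treatments:
                covered |= set(blk.nodes)
        free = np.array(sorted(set(range(n_nodes)) - covered))
        free = rng.permutation(free)
        for start in range(0, len(free) - block_size + 1, block_size):
            chunk = tuple(int(i) for i in free[start : start + block_size])
            blocks.append(Block(frozenset({t}), chunk, lam))
    differential = [("SL", i, 3.0 * noise_sd) for i in (l_blk[0], l_blk[1], s_blk[0], s_blk[1])]
    differential += [("AL", i, -1.0 * noise_sd) for i in (d_blk[0], d_blk[1])]
    return SyntheticSpec(
        n_nodes=n_nodes,
        specimens_per_treatment=specimens_per_treatment,
        treatments=TREATMENTS,
        blocks=blocks,
        differential_regions=differential,
        baseline_mean=baseline_mean,
        noise_sd=noise_sd,
        seed=seed,
    )


# -- behavior ---------------------------------------------------------------


def generate_behavior(
    n_subjects: int,
    sessions: int = 6,
    trials_per_session: int = 8,
    learner_fraction: float = 0.7,
    plateau: float = 0.85,
    seed: int = 0,
    nonretention_fraction: float = 0.2,
    treatment: str = "SL",
    control_treatment: str = "SC",
) -> BehaviorTable:
    """Simulate a conditioning cohort plus its unpaired control group.

    Learners' per-trial probability of a correct arm choice rises
    logistically from the four-arm chance level 0.25 to ``plateau`` over
    the sessions; non-learners stay at chance.  A ``nonretention_fraction``
    of the learning-curve subjects "forget": they follow the learner curve
    during training but draw their probe target-arm duration from the
    control (non-recalling) distribution.  Probe durations are lognormal —
    right-skewed occupancy times — with learners shifted upward.  Ground
    truth labels are attached (controls labelled ``control``).
    """
    if not 0.0 <= learner_fraction <= 1.0 or not 0.0 <= nonretention_fraction <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    if not CHANCE_LEVEL < plateau <= 1.0:
        raise ValueError(f"plateau must lie in ({CHANCE_LEVEL}, 1]")
    rng = np.random.default_rng(seed)
    n_learn = int(round(learner_fraction * n_subjects))
    n_nr = int(round(nonretention_fraction * n_learn))
    labels = (
        ["learner"] * (n_learn - n_nr)
        + ["non_retention"] * n_nr
        + ["non_learner"] * (n_subjects - n_learn)
    )

    # logistic acquisition curve: midpoint at session 3, rate 1.5
    s = np.arange(1, sessions + 1)
    p_learn = CHANCE_LEVEL + (plateau - CHANCE_LEVEL) / (1.0 + np.exp(-1.5 * (s - 3.0)))

    trial_rows = []
    probe_rows = []

    def probe_duration(kind: str) -> float:
        if kind == "recall":  # learners that retained: long target occupancy
            return float(rng.lognormal(mean=4.0, sigma=0.4))
        return float(rng.lognormal(mean=3.0, sigma=0.6))  # chance-level occupancy

    def add_subject(sid: str, treat: str, curve: np.ndarray, probe_kind: str) -> None:
        for sess in range(1, sessions + 1):
            correct = rng.random(trials_per_session) < curve[sess - 1]
            for tr, c in enumerate(correct, start=1):
                trial_rows.append((sid, treat, sess, tr, int(c)))
        others = rng.lognormal(mean=3.0, sigma=0.5, size=3)
        probe_rows.append(
            (sid, treat, probe_duration(probe_kind), *map(float, others))
        )

    flat = np.full(sessions, CHANCE_LEVEL)
    for k, lab in enumerate(labels):
        sid = f"{treatment}{k + 1:03d}"
        curve = p_learn if lab in ("learner", "non_retention") else flat
        add_subject(sid, treatment, curve, "recall" if lab == "learner" else "chance")
    for k in range(n_subjects):
        add_subject(f"{control_treatment}{k + 1:03d}", control_treatment, flat, "chance")

    trials = pd.DataFrame(
        trial_rows, columns=["subject_id", "treatment", "session", "trial", "correct"]
    )
    probe = pd.DataFrame(
        probe_rows, columns=["subject_id", "treatment", "target", "opposite", "left", "right"]
    )
    truth = pd.Series(
        dict(
            [(f"{treatment}{k + 1:03d}", lab) for k, lab in enumerate(labels)]
            + [(f"{control_treatment}{k + 1:03d}", "control") for k in range(n_subjects)]
        ),
        name="label",
    )
    return BehaviorTable(trials=trials, probe=probe, labels=truth)
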
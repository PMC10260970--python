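# fosnet

Group-level brain-network analysis for immediate-early-gene activation
data, with the behavioral statistics that accompany a conditioning study.

## The problem

Mapping activity with a molecular marker such as *c-fos* gives one
snapshot per brain: a count of positive cells per region (and hemisphere)
per animal. Unlike fMRI or EEG there is no time series, so functional
connectivity between regions can only be estimated *at the group level* —
Pearson correlation of regional counts across the M animals of a
treatment. With small M (here 8 per treatment) that estimate is fragile.
`fosnet` implements a pipeline built around that constraint:

- **Graph towers.** For a sampling number m < M, the correlation network
  Ω<sub>γ</sub> is computed for every one of the C(M, m) specimen subsets
  γ; the collection Ω<sub>Γ</sub> is a *graph tower* whose layers are
  bootstrap instances of the network (default m = M − 1, the jackknife).
- **Density thresholding from heterogeneity.** Networks are sparsified by
  keeping a fraction ρ of the strongest edges. Across tower layers each
  edge has a mean μ(ω<sub>ij</sub>) and SD σ(ω<sub>ij</sub>); the profile
  of the mean heterogeneity ζ = ⟨σ(ω<sub>ij</sub>)⟩ and the mean
  coefficient of variation χ = ⟨σ/μ⟩ over the density grid selects an
  operating density ρ₀ (χ peaks while ζ is still minimal). An efficiency
  criterion J = (E<sub>g</sub> + E<sub>l</sub>)/ρ is available as an
  alternative.
- **Egonetwork changes.** For each stimulus condition, the difference
  matrix Δ = A<sup>learning</sup> − A<sup>control</sup> describes how each
  region's neighborhood is rewired by learning; per region the amplitude
  ‖Δ<sub>i</sub>‖ is tested against a resampling null (5th–95th percentile
  band), and the cosine similarity χ<sub>i</sub>(Δ<sup>S</sup>,
  Δ<sup>A</sup>) of matching rows against a within-row permutation null
  (flags at |z| > 1.5, p < 0.05).
- **Communities and segregation.** Leiden community detection is repeated
  100 times on the tower consensus network (fixed density 0.07) and
  summarized by the central partition (variation-of-information medoid).
  The module weight matrix P<sub>αβ</sub> = Σ<sub>i∈α, j∈β</sub>
  ω<sub>ij</sub> yields the segregation ratio
  r = ((m<sub>c</sub> − 1)/2) · TrP / (‖P‖₁ − TrP),
  with r > 1 meaning modules are internally denser than the
  inter-community medium; significance comes from a topology-preserving
  weight shuffle.
- **Conserved submodules.** For two treatments' partitions, every
  community-pair intersection J is compared with 10,000 random node-set
  draws of the same cardinalities; a submodule is retained iff
  |J| ≥ μ(|J|) + 3σ(|J|).

A synthetic-data module generates activation tables with planted block
correlation structure, differential regions, cross-treatment conserved
blocks, and conditioning-behavior records with ground-truth learner
labels, so every stage has parameter-recovery tests.

## Worked example

`examples/` holds one short script per capability. For instance,

```
$ python examples/01_behavior_statistics.py
learning criterion: Z = 1.75, p = 0.080
congruent probe:    Z = 2.33, p = 0.020, OR = 8.00
congruent vs incongruent: Z = 2.56, p = 0.010, delta p-hat = 0.514
partial eta squared for t(15) = 2.55: 0.302
BH-adjusted [0.01, 0.02, 0.03] -> [0.03, 0.03, 0.03]
```

A fish choosing the rewarded arm 5/8 times beats the 1/3 chance level at
Z = 1.75; the congruent-cue group outperforms the incongruent one by a
success-rate difference of 0.514 (Z = 2.56, unpooled SE, no continuity
correction); η²ₚ = 0.302 is the variance share explained by a t(15) = 2.55
effect. And end to end on a synthetic cohort:

```
$ python examples/05_full_pipeline.py
SL: 5 communities, r = inf, p = 0.796
SC: 5 communities, r = 85.2, p = 0.00498
AL: 5 communities, r = 274, p = 0.00498
AC: 5 communities, r = 304, p = 0.00498
AC-SC: 2 conserved submodule(s)
SC-SL: 4 conserved submodule(s)
AL-SL: 2 conserved submodule(s)
artifacts in /tmp/fosnet_...: seed 2, rho0 0.05, community density 0.07
```

Each treatment's consensus network resolves its planted modules (r ≫ 1;
`inf` is the documented sentinel for zero surviving inter-community
weight), and the planted shared blocks are recovered as conserved
submodules for the default treatment pairs. On real data, replace the
synthetic spec with `input_path="counts.csv"` (wide or long form; see
`fosnet.read_activation_table`).

A thin CLI mirrors the library: `fosnet simulate | behavior-stats |
regions-contrast | network-build | network-scan | egonet-diff |
communities-detect | communities-conserved | run`.

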
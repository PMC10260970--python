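# Methods

This note documents the models and procedures `fosnet` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Data model

The unit of observation is one animal (specimen) with one count of
c-fos-positive cells per hemispheric region node (35 region codes × 2
hemispheres; left and right sides are distinct nodes throughout, since
functional lateralization is one of the phenomena of interest). Counts are
nonnegative integers; missing measurements are explicit NaN, never zeros.
Treatments follow the 2×2 conditioning design — social/asocial cue ×
paired/unpaired (SL, AL, SC, AC) — and each treatment needs ≥ 3 specimens
for any correlation estimate.

**Missing-data policy.** A node is dropped from a treatment's networks if
*any* specimen of that treatment is missing it. Pairwise-complete
correlation would retain more data but would put tower layers on different
effective sample sizes and node sets; a common node set keeps all layers
of a tower, and all towers of a comparison, commensurable. This is a
package decision — nothing in the data format forces it — and is applied
uniformly.

## Graph towers

For treatment with M specimens and sampling number m (3 ≤ m ≤ M), the
tower holds the Pearson correlation network of every size-m specimen
subset, in lexicographic subset order. Defaults:

- **similarity**: Pearson correlation of raw counts (Spearman available);
- **m = M − 1**: the jackknife tower, M layers. The sampling number is a
  free parameter of the construction; the jackknife is the smallest
  perturbation of the full sample, gives layer counts linear in M, and in
  testing recovers planted structure reliably at M = 8. A full
  combination scan is available, capped at 100,000 layers.
- nodes constant in any subset are dropped tower-wide (logged), so all
  layers share one node list.

## Density thresholding

`threshold_by_density` keeps the ⌈ρ·N(N−1)/2⌉ strongest edges by *signed*
weight (largest correlations first — "strongest" read as most positively
co-active; absolute-value ranking is available behind a flag and the
choice is recorded in pipeline manifests). Ties break lexicographically by
node-id pair, so thresholding is deterministic.

The threshold profile computes, per grid density ρ (default grid
0.01–0.30, step 0.01):

- per-edge across-layer mean and **population** SD (the layers enumerate
  all subsets; they are not a sample from a larger layer population),
  with an edge absent from a layer counted as weight 0 — the statistics
  are of the *thresholded* tower, which is what the threshold is being
  chosen for. Raw-weight statistics are available behind a flag.
- ζ = mean SD over the union of surviving edges; χ = mean SD/mean over
  edges with nonzero mean.
- E<sub>g</sub>, E<sub>l</sub>, J = (E<sub>g</sub>+E<sub>l</sub>)/ρ on the
  binarized graph obtained by thresholding the layer-averaged weights at
  ρ. Averaging before thresholding keeps that graph at exactly the target
  density, which J divides by; efficiencies use hop-count distances and
  the local efficiency of a degree-<2 node is 0.

**Selection.** The default "heterogeneity" strategy returns the density
maximizing χ among densities where ζ is within 10% of its range above its
minimum (the χ peak while ζ is "still minimal"); "efficiency" returns
argmax J. Both candidates are always reported. Flat profiles fall back to
the smallest grid density with a warning. Two operating densities appear
in the pipeline defaults: ρ₀ = 0.05 for difference-matrix analysis and
0.07 for community detection. Both are config values because the two
stages were originally run at these two (close but distinct) densities;
`rho0="auto"` switches the former to profile-based selection.

## Egonetwork differences

Difference matrices are computed between *consensus* networks (tower
layers thresholded at ρ₀, then averaged edgewise with absent = 0 — the
average is not re-thresholded) on the intersection of node sets, learning
minus control per stimulus condition.

- **Amplitude null**: each replicate draws N − 1 values (one row's worth,
  excluding the diagonal) with replacement from the pooled off-diagonal
  entries of the same condition's Δ, and records the vector norm. The
  draw count is the row length; drawing N would include a slot the
  diagonal occupies in no row. 10,000 replicates by default; the 5th–95th
  percentile band is the expectation, and flags are observed amplitudes
  outside the band. A degenerate null (zero band width) flags nothing.
- **Cosine null**: the randomization the similarity is tested against is
  a within-row permutation of one matrix's off-diagonal entries (Δ^A;
  Δ^S held fixed). This preserves each row's weight distribution exactly
  while destroying cross-condition alignment, which is the minimal
  exchangeability the "same direction of rewiring" claim requires. The
  alternative — permuting rows wholesale — would also destroy each row's
  identity. z-scores are against the permutation mean/SD; p-values are
  empirical two-sided with add-one correction, p = (b+1)/(n+1); flags at
  z > 1.5 (similar) or z < −1.5 (dissimilar) with p < 0.05. Zero rows have
  undefined cosine and are reported as missing, never flagged.
- The across-node correlation of the two amplitude profiles is reported
  with both Pearson and Spearman, since the appropriate scale is
  debatable for norm-valued summaries.

## Communities

Leiden (modularity objective, resolution 1.0, resolution exposed) is run
100 times with seeds derived from the stage seed. Negative-weight edges
are removed first — modularity on signed graphs is undefined for the base
method — with the removed count logged. Partitions are canonicalized
(communities by decreasing size, ties by smallest member id), and the
**central partition** is the ensemble member minimizing summed
variation-of-information distance to the others (ties: higher modularity,
then ensemble order). A medoid rather than any consensus construction
guarantees the result is an actually-detected partition and is
deterministic given the ensemble.

The module weight matrix is built over ordered node pairs i ≠ j, so an
intra-community undirected edge contributes twice to the diagonal and an
inter-community edge once to each off-diagonal cell; the segregation
ratio r = ((m<sub>c</sub>−1)/2)·TrP/(‖P‖₁−TrP) is implemented exactly in
this form. The prose reading of r ("ratio of average intra- to average
inter-community weight") differs from this formula by a factor of 2 under
the ordered-pair convention; the formula wins and the convention is
documented here. Zero inter-community weight yields an infinite sentinel
with a warning — on strongly modular synthetic data this genuinely
happens, because thresholding can remove every between-module edge.

**r significance** shuffles edge weights over the fixed edge positions and
recomputes r with the same partition (one-sided, add-one corrected). This
preserves topology and the weight multiset; note it is deliberately
conservative when the surviving topology is itself modular, since then
most weight stays intra-community under any shuffle.

**Conserved submodules**: for each community pair across two treatments,
the intersection size is compared with 10,000 draws of two uniform random
node subsets of the same cardinalities from the shared universe, sampled
without replacement within a set (so the null is hypergeometric; the
sampled mean matches |C×||C_y|/N to < 0.05 in tests). Retention requires
|J| ≥ μ + 3σ. All pairs are reported with their null moments, retained or
not.

## Synthetic data

**Activation.** A Gaussian one-factor-per-block latent model: specimen s
in treatment t gets v<sub>i</sub> = μ<sub>i</sub> + δ<sub>t,i</sub> +
Σ<sub>b</sub> λ<sub>b</sub>·μ<sub>i</sub>·f<sub>s,b</sub> + ε, with one
standard-normal factor f per (specimen, active block), ε ~ N(0, σ), and
count = round(max(0, v)). The loading is *relative* (λ·μ<sub>i</sub>), so
the induced within-block correlation λ²μ²/(λ²μ² + σ²) is invariant to the
count scale; λ ∈ [0, 1). Defaults: 70 nodes, 8 specimens × 4 treatments,
μ = 100, σ = 30 (30% of baseline), λ = 0.85 — within-block correlation
≈ 0.89, strong but not degenerate, which is the regime where group-level
correlation networks from 8 animals are informative at all. The
study-emulating configuration plants five blocks of 14 nodes: one active
in all four treatments, one shared by the learning pair (AL, SL), one by
the controls (AC, SC), one by the social pair (SC, SL), and
treatment-specific random "filler" groupings for the remaining nodes, so
each treatment has a full planted partition while only the shared blocks
are conserved across treatments. Four nodes carry a +3σ shift in SL and
two a −1σ shift in AL as differential regions.

What this model does *not* emulate: count overdispersion and mean–variance
coupling of real cell counts, hemispheric asymmetries in baseline
activity, anatomically structured (distance-dependent) correlations, and
negative coupling between modules. Passing recovery tests therefore show
the pipeline detects block-correlation structure at realistic sample
sizes and noise, not that real brains satisfy the one-factor model.

**Behavior.** Learner subjects' per-trial success probability rises
logistically from the four-arm chance level 0.25 (midpoint session 3,
rate 1.5) to a plateau (default 0.85); non-learners stay at chance.
Probe-test occupancy durations are lognormal — occupancy times are
nonnegative and right-skewed — with retaining learners drawn from
LN(4.0, 0.4) (median ≈ 55 s) and non-recalling subjects (controls and the
non-retention fraction, default 0.2 of the learning-curve subjects) from
LN(3.0, 0.6) (median ≈ 20 s). Because non-retention durations are by
construction drawn from the control distribution, they sit below the
control mean only ~60–65% of the time, which bounds achievable
classification accuracy; at the defaults, agreement with planted labels
averages ≈ 93%.

**Learner classification** follows the two-criterion rule: non-learner if
the last-session proportion correct falls below the group mean −
1.96·SD/√n (the simplest normal-approximation reading of a 95% CI lower
limit); among the rest, non-retention if the probe target-arm duration
falls below the control-group mean (a configurable control quantile,
since only "cumulative time in the RoI" is specified as the criterion).

## Behavioral statistics conventions

Binomial z tests use the normal approximation with **no continuity
correction**, and the two-sample test uses the **unpooled** standard
error; this combination reproduces all six worked statistics (1.75, 2.33,
2.12, 0.71, 2.56, 2.41) to the printed precision, which is how the
convention was fixed. Odds-ratio effect sizes use the cross-product
definition with a Haldane–Anscombe 0.5 adjustment only at degenerate
proportions; the worked OR values accompanying the one-sample tests
(6.62, 5.82, 9.12, 10.36) are *not* reproduced by this or any standard
definition we could identify, so the documented definition is reported
and the discrepancy noted here. Similarly the reconstructed non-learner
2×2 table gives X² = 1.59 and a proportion ratio of 0.49 by the standard
Pearson formula where 1.56 and 0.5 are quoted. The omnibus
within/between-factor tests (X²_R, X²_F) come from a commercial package
with no stated algorithm; they are deliberately not reproduced — planned
pairwise contrasts are rank-sum (Mann–Whitney) tests with
Benjamini–Hochberg adjustment across the contrasted node set, and
learning-curve comparisons are Theil–Sen fits of per-session group
proportions with subject-permutation p-values for slope and elevation.

## Determinism and problem sizes

Every stochastic routine takes a seed; the pipeline derives stage seeds
from one master seed via `SeedSequence([master, stage_hash])`, so reruns
are bit-identical (verified by test). Edge-list output uses 9 significant
digits, `.` decimal separator, locale-independent.

Recovery and calibration suites use 20 seeded synthetic cohorts at the
default study geometry (70 nodes, 8 specimens × 4 treatments), 200-replicate
null-uniformity checks on 30-node graphs, and 10,000-draw nulls where a
sampled moment is compared against a closed form. These sizes give
Monte-Carlo error comfortably below the asserted margins while keeping
the whole suite in a few minutes.

## Known limitations

- Group-level correlation networks confound inter-individual variation
  with co-activation; nothing here disentangles them.
- The weight-shuffle null for r tests weight placement given topology,
  not topology itself; a degree-preserving rewiring null would test a
  different (stronger) hypothesis and is not implemented.
- The central-partition medoid summarizes the Leiden ensemble but carries
  no uncertainty measure over partitions.
- With strongly modular data and sparse thresholds, inter-community
  weight can vanish, making r infinite and its permutation test
  uninformative; the sentinel and warning make this visible.
- Negative correlations are excluded from community detection and ranked
  last by signed thresholding; analyses centered on anti-correlation
  would need the absolute-ranking mode and a signed community method.
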
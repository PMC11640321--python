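# Methods

## The model

`sarudango` simulates huddling ("monkey dumpling") formation in a group of
N identical agents on a 16 × 16 toroidal grid of patches.  Agents are either
*lone* — random-walking one patch per tick with a freshly drawn uniform
heading — or *huddled*, in which case they are stationary members of exactly
one cluster.  Temperature T is an abstract integer scale from 1 (cold, strong
drive to huddle) to 10 (warm); it is not degrees Celsius.

Each tick processes every agent once in a freshly shuffled order; each agent
acts on the world as it stands mid-pass.  A lone agent moves, senses all
agents within a toroidal Euclidean radius of 2 patches, picks one of them
uniformly at random (the `random_neighbor` candidate policy; a deterministic
`largest`-cluster policy is available), and makes one Bernoulli join
decision.  A huddled agent makes one Bernoulli leave decision.

### Join rule

The joining threshold J (integers 1–8 in the standard experiment) is the
huddle size below which an agent is selective.  With n_ci the candidate
cluster's current size and N the group size:

* **existing huddle**: `p = (n_ci / N) · (1/T)`
  — attraction grows with the huddle and falls with warmth;
* **nucleation** (the drawn neighbour is itself lone):
  `p = (n_lone / N) · (1/T) · (1/J²)`,
  where n_lone is the current number of unhuddled agents — the candidate
  "cluster" is the unhuddled pool (all unhuddled agents share the no-huddle
  tag), and a founding pair requires the selectivity of *both* founders.
  A successful nucleation creates a fresh two-member cluster, anchored at
  the joiner's position, with a never-reused monotonically increasing id.

The joining threshold J therefore acts where a huddle *starts*: a selective
agent rarely commits to founding a new huddle, but joins an existing one as
readily as anyone.

The selectivity placement deserves a note, because it is the one place where
this implementation commits to a reading the verbal model description leaves
open.  If 1/J multiplied *every* join uniformly, J and T would enter the
dynamics through exactly the same factor 1/(T·J) and could never have
opposite-signed effects on the outcomes — yet the reported regressions from
the original full-scale experiment have J decreasing the number of clusters
while *increasing* individuals per cluster, with temperature doing the
opposite.  Restricting the selectivity divisor to nucleation (applied once
per founder) reproduces that sign structure: a selective population
nucleates few huddles, and the few that get established absorb everyone,
giving fewer but far larger clusters.  A variant that also throttles joins
to huddles smaller than J was tried and rejected — it starves high-J
huddles of early growth and inverts the size effect.  The uniform literal
rule remains available (`join_selectivity="all_joins"`,
`nucleation_size="single"`).

### Leave rule

Every huddled agent re-evaluates each tick:
`p_leave = ((N − n_ci) / N) · (1/L)`, with L ≥ 10 the leaving threshold.
A full-group huddle is absorbing (p_leave = 0).  A leaver keeps its position
and resumes the random walk next tick; a cluster reduced to one member is
dissolved and the remnant released (a huddle of one is not a cluster).
Alternative cadences (`size_scaled`: at most ~one departure per huddle per
tick; `timer`: no leaving before L ticks of residence) are implemented for
sensitivity analysis and were rejected as defaults (the first suppresses the
warm-regime fragmentation that keeps clusters small when it is warm, the
second kills warm-regime clusters entirely).

Members of a cluster are re-spaced after every membership change, evenly on
a circle of radius min(1, sensing_radius/2) around the cluster's anchor, in
ascending agent-id order; re-spacing is deterministic.

`huddle_time` counts ticks of continuous membership and resets on leaving.
It is recorded for analysis but consulted by no decision rule.

### Termination and outputs

A run ends when no agent is lone ("all_joined") or after 20,000 ticks
("step_cap").  A run reports the number of clusters (size ≥ 2 only), their
sizes, the per-run mean cluster size (missing when no cluster survived),
and the termination cause.  Identical (parameters, seed) gives an identical
run; the engine and the pure-python reference path consume the same PCG64
stream draw for draw.

## The experiment

The standard sweep crosses T = 1..10, J = 1..8 and a leaving-threshold axis
that is {10,…,70} in steps of 10 for N = 70 and {10, 50, 90, …} in steps of
40 truncated at min(N, 170) otherwise, with 100 replicates per cell —
56,000 runs at N = 70.  Each run's seed is the grid's base seed plus the
run's ordinal in the (T, J, L, replicate)-lexicographic enumeration, so
results are independent of scheduling and worker count.

Two negative-binomial GLMs (log link, NB2 dispersion θ estimated by maximum
likelihood, Poisson available as a cross-check) regress (i) the number of
clusters (zeros kept) and (ii) the rounded-half-to-even per-run mean cluster
size (no-cluster runs dropped — the response is undefined there) on joining
threshold, leaving threshold, temperature and group size, main effects only,
for group sizes 70–160.  The per-run mean is the chosen per-run reduction of
"individuals per cluster"; it is isolated in `prepare_glm_table`.
Collinearity is screened with VIFs (a balanced factorial gives exactly 1),
and backward–forward stepwise selection on AIC or BIC is provided.

For the field comparison, four site lines y = a·T + b (individuals per
cluster against temperature) are built from published anchor values at
T = 1 and T = 10: Arashiyama 3 → 0, Katsuyama constant 2.2, Takasakiyama
4.8 → 2.8, Shodoshima 30 → 20.  The anchors are authoritative: the widely
quoted Takasakiyama intercept 4.8 is the anchor value at T = 1, while the
line through the anchors has intercept 5.02.  Each (group size, joining
threshold) combination gets an OLS line of per-run mean cluster size on
temperature (pooling leaving thresholds and replicates, no-cluster runs
excluded), and combinations are ranked by |Δslope| and |Δintercept|
separately (average ranks on ties) and by the mean of the two ranks — the
mean is used because a non-integer combined rank is only possible with
averaged ranks.

## Reduced replication (problem sizes)

The full experiment is hours of CPU.  The package's canonical reduced study
(`sarudango.replication`, also run by `scripts/acceptance.py`) keeps every
axis of the design but uses one replicate per cell for group sizes
{70, 100, 130, 160} (1,440 runs) and, for the giant-cluster realism
diagnostic, one matched thinned 3 × 3 × 3 grid (T ∈ {1,5,9}, J ∈ {2,5,8},
L ∈ {10,90,170}) per group size in {160, 300, 400} at one replicate, so the
over-137 shares are compared like for like.  One-replicate cell estimates
are noisy;
the quantities reported (fractions pooled over hundreds to thousands of
runs, GLM coefficients over 1,400+ rows) average over many cells and are
stable to a few percent.

## What the generator does and does not emulate

Synthetic data here *is* the model's own output; there is no external data
path.  What passing tests show is that the implementation reproduces the
collective-behaviour regularities of the original full-scale experiment
(sign structure of all four predictors on both outcomes, the no-cluster
corner at high N·T·J, the thin giant-huddle tail, and which parameter
combinations best match which field site).  They
do not show that real macaques follow these rules: agents are homogeneous
(no age, sex, rank or kinship), space is featureless, and the temperature
scale is abstract.  The model's cluster-size distributions should be read
as emergent statistics of the rule set, not as fitted predictions for any
real troop.

## Numerical choices

* All randomness is raw uniform doubles from one PCG64 generator per run
  (seed = base seed + run ordinal; ordinals keep every seed far below 2³¹);
  shuffling is explicit Fisher–Yates over those doubles so the compiled and
  reference paths match draw for draw.
* Neighbour search is a dense two-pass distance scan (branch-free SIMD pass,
  then collection); at N ≤ 400 on 16 × 16 this outruns any spatial index and
  honours mid-pass semantics exactly.
* Distances are toroidal Euclidean; in-range means d² ≤ r² inclusively.
* Candidate ties: the uniform draw indexes neighbours by ascending agent id,
  so results are independent of scan order; the `largest` policy breaks size
  ties by lowest cluster id, then lowest agent id among lone fallbacks.
* The per-cluster GLM response uses numpy's round-half-to-even.
* θ's standard error comes from the delta method on the NB2 alpha estimate.
* Cross-path agreement is asserted on discrete state and the RNG stream
  exactly and on positions to 1e-9: the two compilation contexts may differ
  by an ulp in libm/FMA contraction, which is ten orders of magnitude below
  any decision threshold in the model.

## Known limitations

* The no-cluster fraction and the giant-tail percentages are sensitive to
  the exact nucleation/selectivity reading; the chosen rule set reproduces
  the published aggregates' structure, but per-combination values at one
  replicate carry sampling noise of a few percentage points.
* The share of clusters above 137 members does not keep growing from
  N = 300 to N = 400 in this rule set: very large groups fragment
  relatively more (the same force that makes the group-size coefficient on
  per-cluster size negative), so the giant tail grows in absolute size but
  not as a fraction of all clusters.  The realism diagnostic reports the
  shares as computed.
* Clusters never merge as wholes; membership changes one agent at a time.
* No checkpoint/resume: a sweep interrupted mid-way restarts from scratch.
* The leaving-threshold axis for group sizes other than 70 follows the
  step-40 truncated sequence; the original description of that axis is
  internally inconsistent (its stated per-size run totals cannot be
  reconciled with "10 to the group size" for every size), so the grid is
  fully overridable in `SweepGrid`/`PipelineConfig`.
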
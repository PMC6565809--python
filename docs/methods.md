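# Methods

## Problem setting

An information walk is an ordered, timestamped sequence of visits to actors
of a directed, count-weighted network; revisits are allowed, so walks are
walks, not paths. Timestamps are day-resolution integers; every interval in
the package is half-open `[start, end)`, so a visit exactly at an
observation day `T` belongs to the future. Actor metadata is categorical
(specialty, hospital, residency hospital, region) with a reserved UNKNOWN
sentinel that never matches anything — including another UNKNOWN — so
similarity indicators degrade to 0 rather than erroring on missing data.

## Temporal evaluation protocol

`split_at(corpus, T, min_visits=6)` assigns a walk ending strictly before
`T` to the training set (observed part: all visits but the last; ground
truth `f`: the last actor) and a walk with visits on both sides of `T` to
the test set (observed part: visits before `T`; ground truth: the first
actor at or after `T`). Walks with fewer than six total visits are dropped —
the six-visit floor applies to the whole walk, not the observed prefix. The
candidate set `J` is the set of test ground truths. Feature centralities are
meant to come from the *previous* period's network so no feature looks past
`T`; on the synthetic benchmark a single static network plays both roles
because the generator holds the network fixed over the simulated year.

## Ranking model

The preference score and pairwise objective are given in the README. Design
choices that were genuinely open:

* **The `p'Vβ` term.** It is identical for every candidate of a fixed walk,
  so it cancels from all score gaps and rankings; `V` is therefore never
  updated and the term is disabled by default. A flag re-enables it
  (initialized, frozen) for literal fidelity; a property test asserts
  rankings are unchanged.
* **Negative sampling.** The full objective sums over all of
  `J \ {c_i, f_i}` per training walk; training instead samples one uniform
  negative per pair per epoch (configurable), the standard stochastic
  treatment of this objective.
* **Initialization and schedule.** Parameters start from N(0, 0.01²) under
  the run seed; λ = 0.001 and step size 0.05; 20 epochs by default. Same
  seed ⇒ bit-identical trajectories.
* **Feature scaling.** All feature families are z-scored with scalers fit on
  training data only (`sd = 0` coordinates map to 0). Min-max scaling is
  available as a config alternative; the quintile-grouped recall table uses
  min-max on the grouping attribute by construction.
* **h-index.** Defined as the lobby index: the largest `h` such that the
  actor has at least `h` undirected neighbors of undirected degree ≥ `h`,
  verified against a definition scan on random graphs.
* **Tie-breaking.** Ranked lists order by descending score, then ascending
  actor id; percentile-boundary ties in grouped recall go to the lower
  group. Both rules make every report byte-reproducible.
* **Baselines.** The link-prediction indices (CN, PA, Adamic–Adar, Jaccard)
  use undirected neighborhoods, their classical form; a directed variant is
  selectable. The 2-gram Markov chain scores 0 on unseen contexts with no
  1-gram backoff. All baselines rank the full candidate set `J` (zero scores
  permitted) through the same ranking code as the trained model, so metric
  comparisons across models differ only in the scorer.

`MPR` uses 1-based ranks: with `K = 1` every hit contributes `1/1`, so a
perfect single-candidate batch scores exactly 1.0 — this anchors the rank
base.

## Network of information walks

Walks become nodes; an edge joins two walks sharing at least one actor.
Edge weights: number of distinct shared actors; Jaccard index of the
distinct-actor sets; combined count of visit records both walks make at
shared actors; and the same combination for RVU. The "combined" reading
(sum over both walks) was chosen where the per-walk/combined accounting was
ambiguous. Construction uses an inverted actor→walks index, so cost scales
with the squared per-actor walk counts rather than all walk pairs; an
`O(n²)` brute-force oracle checks equality on small corpora.

Patterns: *homotopic* pairs share first and last actors (length ≥ 2;
start may equal end); *lifting* pairs differ by exactly one actor inserted
between two consecutive actors; *composition* triples chain a walk ending
in `A→B`, a walk starting with `B→C`, and a walk carrying `A→B→C` strictly
in its interior (touching neither endpoint). Group contrasts use Welch's
unequal-variance t-test, with degenerate zero-variance groups guarded
(equal means → p = 1; separated constants → p = 0). Walk-network PageRank
uses damping 0.85 on the undirected graph with a selectable weight.

## Outlier detection

Each walk is summarized as an 11 × T step series: column `t` describes the
walk-subnetwork of its length-`t` prefix — the reference walks sharing at
least one actor with the prefix, plus the mutual overlap edges among them.
The 11 measures cover subnetwork size, actor-neighborhood reach, mean
Jaccard edge weight, strength and variance of shared-actor edge weights,
binary transitivity, and the edge survival rate / density / largest
component after removing the focal walk-node. Reference walks enter with
their full actor sets (not time-restricted) for determinism; the focal walk
is excluded from its own reference by id. Measures over empty structures
follow explicit zero rules (e.g. a prefix overlapping nothing yields zeros
everywhere except the actor-neighborhood count).

Series are min-max scaled per measure across the evaluation corpus before
any distance is computed (the measures live on wildly different scales;
constant measures scale to 0). Five metrics compare two per-measure arrays
of lengths `l ≥ s`: sliding-window Manhattan matching (SSM); an
edit-distance/DTW recursion with skip penalty λ and boundary
`d(i,0) = i·λ` (λ = 1.0 on scaled values); linear interpolation onto a
common equal-interval grid on [0, 1]; a thresholded longest common
subsequence with equality `|x−y| < 0.05` converted to a distance
`(l+s−2m)/(l+s)` (the conversion is ours — the raw LCS length is not a
distance); and sliding-window averaging (SSA). The walk-level distance sums
the 11 per-measure distances with equal weights, orienting longer/shorter
by series length, which makes it symmetric. Exhaustive alignment and
subsequence oracles pin down DTW and LCS on short arrays.

The detector computes all pairwise distances (`O(n²)`), scores each walk by
the distance to its `M`-th nearest neighbor, and returns the top-K scores.
`M` is grid-tuned over {1, 2, 5, 10, 20} to maximize precision@K on a
labeled benchmark, mirroring the study protocol of tuning the neighbor
parameter per metric.

The simulator plants outliers by keeping a walk's first and last actor and
every timestamp/RVU while redrawing all middle actors uniformly from the
actors appearing on the pool's walks (repeats and redraws of original
actors permitted — the draws are unconstrained). The reference
configuration uses 2 500 normal + 2 500 corrupted walks; the package's
benchmark runs the same protocol at 200 + 200.

## Synthetic data: what it emulates, and what it does not

`SynthConfig` defaults define the study conditions for the prediction
benchmark: 250 actors in 4 regions × 3 hospitals and 8 specialties; a
directed network grown by preferential attachment (2 out-edges per new
actor, 80% within-region, occasional reciprocals, counts 1 + Poisson(1)) —
median undirected degree below 4, matching the sparse regime of real
referral networks; 800 walks of 6–10 visits with 1–30-day gaps starting
uniformly over days 0–299 and an observation day of 300, which yields
roughly 500 training and 280 test walks.

Transitions follow a softmax over a planted linear score: directed
adjacency (weight 2 on log1p counts), same specialty (2), same region (1),
and standardized log-PageRank (1), at temperature 1. The PageRank pull acts
on the *log* because raw PageRank is heavy-tailed: a linear pull
concentrates essentially all transitions onto a handful of hubs, collapsing
the candidate set and with it any meaningful ranking task. The planted
score deliberately uses only quantities the ranking model can observe
(adjacency → historical referral count in `d`; metadata matches → the
indicator entries of `d`; PageRank → `γ`), so signal recovery is testable;
the most-popular baseline sees only the adjacency component.

The outlier benchmark uses a different cohort, `SynthConfig.outlier_cohort()`:
walks beginning within a single 31-day window at temperature 0.3. This
mirrors the study protocol, which draws its normal and corrupted walks from
walks beginning within one month of the observation date — a cohort of
habitual, strongly stereotyped referral routes. The distinction matters:
in a fully diverse corpus, normal walks are as heterogeneous as
random-middle corruptions and nearest-neighbor scoring cannot separate
them; in the homogeneous cohort, normal walks have close neighbors and the
corrupted ones stand apart. Conversely, the homogeneous cohort would make
the prediction task trivial (a few dozen candidates at K = 20), which is
why the prediction benchmark keeps the diverse defaults.

The generator does not attempt to match real claims data in scale (millions
of walks), in empirical degree/length distributions, or in the referral-
derivation rule that turns raw visit records into edges (edge lists are
inputs here). Passing benchmarks therefore demonstrate correctness of the
pipelines and recoverability of a known planted signal — not performance on
real referral data.

## Problem sizes and numerical notes

The test suite's end-to-end checks use the scales above: the planted-signal
benchmark averages over 5 seeds (~500 training walks each); the outlier
benchmark averages over 3 seeds of the 200 + 200 cohort with the full
M-grid for each of the five metrics. The sigmoid and log-sigmoid use the
standard stable reformulations (no overflow for |x| up to ~745; subnormal
but positive output in the deep negative tail). Gradients are validated
against central finite differences at 1e-5 relative tolerance. PageRank
normalization is asserted to 1e-9. Distance metrics are validated for
non-negativity, zero self-distance, and symmetry of the summed walk
distance.

## Known limitations

* The referral-interval rule for deriving edges from raw visit data is out
  of scope; networks and walks arrive as TSVs or from the generator.
* LSTM and factorization-machine comparison models are out of scope.
* `time range` units are days by assumption; mean walk PageRank weights
  revisits (both were unspecified choices, fixed and documented here).
* The outlier simulator produces one corruption family (uniform middle
  replacement); metric rankings on it need not transfer to real anomalies.
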
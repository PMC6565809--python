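# infowalk

Tools for *information walks* — chronological, revisit-allowing node
sequences traversed by a single walker on a directed network. The motivating
instance is the referral sequence of a patient moving through a
shared-patient physician network: each visit hands the patient (and their
record — the "information") from one physician to the next. The package
answers three questions about such walks:

1. **Where will the walk go next?** A Bayesian-personalized-ranking model
   (BPR-IW) scores every candidate next node and returns a top-K list,
   evaluated by hit-rate and mean percentile rank against classical
   link-prediction baselines.
2. **How do walks relate to each other?** The derived *network of
   information walks* links two walks whenever they share an actor, with
   overlap-based edge weights, plus detectors for homotopic pairs, lifting
   pairs, and composition triples.
3. **Which walks are anomalous?** A proximity-based detector summarizes each
   walk as a per-step time series of 11 walk-subnetwork measures, compares
   walks with five distance metrics, and flags the walks furthest from their
   M-th nearest neighbor.

Real claims data is proprietary, so a seeded synthetic generator produces
referral-style networks (hospitals nested in regions, heavy-tailed degrees)
and walk corpora with a *planted* next-node preference, making every
pipeline testable end to end.

## The model

For a walk `i` with observed feature vector `p_i`, last node `c_i` and a
candidate next node `j`, the preference score is

```
X(p_i, c_i, j) = p_i' S γ_j + β_{c_i}' U γ_j + w · d(c_i, j)
```

where `γ_j` are candidate centrality features (clustering, PageRank,
h-index, cross-region referrals), `β_c` extends them with recency/RVU
features of the last visit, and `d(c, j)` is a profile-similarity vector
(same specialty / residency hospital / region, historical referral count).
`S`, `U`, `w` are learned by maximizing the pairwise objective

```
Σ log σ( X(p,c,f) − X(p,c,j) ) − (λ/2)‖Θ‖²
```

over training walks (true next node `f` vs sampled negatives `j`) with SGD
(λ = 0.001, step 0.05). A further term `p' V β` is candidate-independent —
it cancels in every score difference — so `V` is never trained and the term
is off by default.

Rankings are scored by hit-rate `HR = (1/|P_test|) Σ 1(f_i ∈ R_i)` and mean
percentile rank `MPR = mean over hits of rank(f_i)/K` (1-based ranks, so
K = 1 with all hits gives exactly 1.0).

## Worked example

```
$ python examples/01_next_node_prediction.py
250 actors, 800 walks -> 526 train / 274 test walks, 99 candidate next-nodes

    model   T  K       HR      MPR
   bpr_iw 300 20 0.759124 0.232692
bpr_no_iw 300 20 0.795620 0.238761
       mp 300 20 0.649635 0.215169
       cn 300 20 0.354015 0.420619
      mc2 300 20 0.489051 0.343284
```

The trained ranking model places the true next actor in its top-20 list for
76% of test walks, ahead of the raw historical-edge-count baseline (`mp`,
65%) and far ahead of common-neighbors (`cn`) — the planted transition
preference uses specialty, region, and centrality information that edge
counts alone cannot see. `examples/02_walk_network_patterns.py` prints the
walk-network worked example (two walks sharing 2 of 5 actors → Jaccard 0.4)
and pattern counts with Welch-test contrasts;
`examples/03_outlier_detection.py` runs the 200+200 planted-outlier
benchmark, where all five metrics reach precision@50 of 0.64–0.76 against a
0.5 base rate.

A thin CLI wraps the same pipelines:

```
infowalk generate --seed 1 --out-dir data/
infowalk predict --data-dir data/ --t 300 --k 20 --seed 1 --model bpr_iw --model mp
infowalk walknet --data-dir data/ --out-dir out/
infowalk outliers --data-dir data/ --seed 1 --k 50
```

## Layout

```
src/infowalk/
  netcore.py         domain types + TSV I/O (networks, walks)
  features.py        centralities and the p / β / γ / d feature vectors
  temporal_split.py  train/test/candidate split at an observation day
  bpr.py             preference score, pairwise objective, SGD training
  baselines.py       MP, CN, PA, Adamic-Adar, Jaccard, 2-gram Markov chain
  evaluation.py      hit-rate, MPR, quintile-grouped recall
  walknet.py         network of information walks + pattern detectors
  outlier.py         step measures, five distance metrics, M-th-NN scoring
  synthdata.py       seeded synthetic networks, walks, benchmarks
  pipeline.py        orchestration used by the CLI and examples
  cli.py             click commands: generate / predict / walknet / outliers
```
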
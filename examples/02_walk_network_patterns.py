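"""The derived network of information walks and its structural patterns.

Builds the walk-overlap network for a tiny hand-made corpus (three pairwise
overlapping walks) and for a synthetic corpus, then reports homotopic /
lifting / composition patterns and a Welch t-test contrasting homotopic
edges against the rest.

Run:  python examples/02_walk_network_patterns.py
"""

from infowalk.netcore import ActorProfile, InformationWalk, ReferralNetwork, Visit, WalkCorpus
from infowalk.pipeline import run_walknet
from infowalk.synthdata import SynthConfig, generate_network, generate_walks
from infowalk.walknet import build_walk_network


def make_walk(wid, actors):
    return InformationWalk(wid, [Visit(a, i) for i, a in enumerate(actors)])


# --- worked example: three walks that pairwise share actors -----------------
net = ReferralNetwork([ActorProfile(a) for a in "ABCDEFG"], {})
corpus = WalkCorpus(
    [make_walk("alpha", "ABCG"), make_walk("beta", "CDEF"), make_walk("gamma", "EFG")],
    net,
)
wn = build_walk_network(corpus)
print("walk network edges (3 walks -> 3-clique):")
print(wn.to_frame().to_string(index=False))
print("\nbeta and gamma share E and F: 2 common actors out of 5 distinct "
      "-> Jaccard 2/5 = 0.4.\n")

# --- patterns on a synthetic corpus ----------------------------------------
cfg = SynthConfig(seed=4, n_actors=40, n_walks=120, temperature=0.4)
network = generate_network(cfg)
synthetic = generate_walks(network, cfg)
result = run_walknet(synthetic)
print(f"synthetic corpus: {len(synthetic)} walks, "
      f"{len(result['walk_network'].edges)} overlap edges")
print(f"homotopic pairs (same start and end actor): {len(result['homotopic_pairs'])}")
print(f"lifting pairs (single-actor insertion):     {len(result['lifting_pairs'])}")
print(f"composition triples (interior A->B->C):     {len(result['composition_triples'])}")
for attr, c in result["contrasts"].items():
    print(f"  {attr}: homotopic mean {c['mean_homotopic']:.3f} vs other "
          f"{c['mean_other']:.3f} (Welch t = {c['t']:.2f}, p = {c['p']:.3g})")
print("\nA positive t with small p says walks sharing both endpoints overlap "
      "more strongly than arbitrary overlapping walk pairs.")
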
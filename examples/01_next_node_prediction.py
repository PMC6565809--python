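"""Next-node prediction on a synthetic referral network.

Generates a seeded network and walk corpus with a planted transition
preference, splits it temporally at the observation day, trains the
pairwise-ranking model, and compares it with classical baselines.

Run:  python examples/01_next_node_prediction.py
"""

from infowalk.bpr import BPRHyper
from infowalk.features import compute_centralities
from infowalk.pipeline import build_feature_context, prediction_report, run_prediction
from infowalk.synthdata import SynthConfig, generate_network, generate_walks
from infowalk.temporal_split import split_at

cfg = SynthConfig(seed=1)
network = generate_network(cfg)
corpus = generate_walks(network, cfg)
split = split_at(corpus, cfg.observation_day)
print(f"{len(network)} actors, {len(corpus)} walks -> "
      f"{len(split.train)} train / {len(split.test)} test walks, "
      f"{len(split.candidates)} candidate next-nodes\n")

centralities = compute_centralities(network)
ctx = build_feature_context(split, network, centralities)
runs = [
    run_prediction(split, network, centralities, model, k=20,
                   hyper=BPRHyper(seed=1), ctx=ctx)
    for model in ("bpr_iw", "bpr_no_iw", "mp", "cn", "mc2")
]
print(prediction_report(runs, cfg.observation_day).to_string(index=False))
print("\nHR is the share of test walks whose true next actor appears in the "
      "top-20 list; MPR is the average (1-based rank)/K over the hits — "
      "higher HR and lower MPR mean the truth sits near the top. The "
      "feature-driven ranking model (bpr_iw) should beat the raw edge-count "
      "baseline (mp) because the planted transition preference also uses "
      "specialty, region, and centrality information.")
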
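"""Centrality of a person's networks, raw vs detrended.

Runs the full pipeline for one simulated person with genuine residual
network structure, then ranks nodes by strength (sum of absolute edge
weights) in both the embedded-node network and the residual network,
and reports how the ordering shifts once temporal variation is removed.
"""

import numpy as np

from emanet import (
    TABLE_SYMPTOMS,
    GroundTruth,
    RunConfig,
    SimConfig,
    chain_precision,
    rank_nodes,
    run_person,
    simulate_person,
)
from emanet.synthetic_data import _scale_trend_cycles_to_r2

# 8 endorsed symptoms; genuine residual structure (a 0.45-partial chain)
# plus person-specific trends and cycles of varying strength
p = 8
rng = np.random.default_rng(21)
truth = GroundTruth(
    symptoms=TABLE_SYMPTOMS[:p],
    trend=rng.normal(0.0, 1.0, size=(p, 3)),
    amp24=rng.uniform(0, 1, p), phase24=rng.uniform(0, 2 * np.pi, p),
    amp12=rng.uniform(0, 0.5, p), phase12=rng.uniform(0, 2 * np.pi, p),
    baseline=np.full(p, 2.5),
    precision=chain_precision(p, 0.45),
    noise_sd=np.ones(p),
)
truth = _scale_trend_cycles_to_r2(truth, SimConfig(), rng.uniform(0.0, 0.3, p))

ds, _ = simulate_person(truth, SimConfig(), seed=21, person_id="demo")
res = run_person(ds, RunConfig(seed=21))

print("top 5 nodes by strength, embedded network (temporal nodes included):")
for i, node in enumerate(rank_nodes(res.centrality_raw, "strength")[:5], 1):
    print(f"  {i}. {node:26s} s = {res.centrality_raw.value(node, 'strength'):.3f}")

print("\ntop 5 symptom nodes by strength, residual network:")
for i, node in enumerate(rank_nodes(res.centrality_detrended, "strength")[:5], 1):
    print(f"  {i}. {node:26s} s = {res.centrality_detrended.value(node, 'strength'):.3f}")

comp = res.comparison
print("\nlargest rank shifts after detrending (negative = fell in ranking):")
moved = comp.reindex(comp["rank_shift"].abs().sort_values(ascending=False).index)
for _, row in moved.head(3).iterrows():
    print(f"  {row['symptom']:26s} rank {row['rank_raw']} -> {row['rank_detrended']}")
print(f"\nSpearman rank correlation between orderings: "
      f"{comp.attrs['rank_correlation']:.2f}")
print(
    "A temporal node ranking high in the embedded network means much of "
    "that person's symptom variation is trend- or cycle-driven; a large "
    "rank drop after detrending flags a symptom whose apparent centrality "
    "was carried by time."
)
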
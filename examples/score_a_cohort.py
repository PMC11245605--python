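"""Score a synthetic object-in-context cohort into D2 discrimination ratios.

Simulates 10 animals running four trials with a context-novel strategy of
strength 0.6, scores each trial under the context and recency framings, and
prints the per-cohort means. A positive context D2 near 0.6 with a recency
D2 near zero is the signature of contextual-mismatch-driven novelty
preference: both framings score the same two durations, but only the
context labelling lines up with the animals' actual choices.
"""

import numpy as np

from srtkit import SimulationConfig, score_cohort, simulate_object_in_context, summarize_cohort

cfg = SimulationConfig(strategy="context_novel", delta=0.6, kappa=20.0, seed=1)
records = simulate_object_in_context(cfg)
scores = score_cohort(records)
summaries = summarize_cohort(scores, records)

print(f"animals: {len(summaries)}, scored trials: {len(scores)}")
d2c = [s.mean_d2_context for s in summaries]
d2r = [s.mean_d2_recency for s in summaries]
print(f"mean context D2 across animals: {np.mean(d2c):+.3f}  (generative delta = 0.6)")
print(f"mean recency D2 across animals: {np.mean(d2r):+.3f}  (should sit near 0)")
for s in summaries[:3]:
    print(f"  {s.animal_id}: context D2 {s.mean_d2_context:+.3f}, "
          f"totals {s.sum_context_novel:.1f}s novel vs "
          f"{s.sum_context_familiar:.1f}s familiar")
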
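"""Locate the seizure-onset zone from connection strengths.

Classifies every channel pair as SOZ-SOZ, SOZ-OUT or OUT-OUT, compares mean
strength per class per state, and scores how well state-averaged connection
strength predicts SOZ-SOZ membership (ROC AUC against a sensor-relabeling
permutation null).
"""

import numpy as np

import netstates as ns

pre_spec, sz_spec = ns.paper_regime_specs(seed=5)
pre, sz = ns.make_event(pre_spec, sz_spec)
sensors = pre_spec.sensors

config = ns.PipelineConfig(seed=5, gamma_grid=(1.0,), n_optimizations=100,
                           n_permutations=10000)
result = ns.run_event(pre, sz, sensors, config)

cols = ["state", "mean_SOZ-SOZ", "mean_SOZ-OUT", "mean_OUT-OUT",
        "auc", "null_hi", "significant"]
print(result.geography[cols].round(3).to_string(index=False))
# SOZ-SOZ connections are the strongest class in every state, and the AUC
# exceeds the 97.5th percentile of 10000 random SOZ re-assignments: the
# planted hyper-coherent hub is recoverable from connection strength alone.

classes = ns.classify_pairs(sensors)
labels, counts = np.unique(classes, return_counts=True)
print("pair classes on the 6x6 grid with a 4-sensor SOZ:",
      {str(l): int(c) for l, c in zip(labels, counts)})
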
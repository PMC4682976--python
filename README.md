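# netstates

Tracking dynamic functional-network states in multichannel intracranial
recordings (ECoG), with a focus on how epileptic networks reorganize between
pre-seizure and seizure epochs.

## What it does

Seizures are increasingly understood as network events: the pattern of
pairwise statistical coupling between cortical sensors — the network's
*geometry* — reorganizes as a seizure starts, spreads and terminates.
`netstates` implements an analysis chain that makes this reorganization
quantitative:

1. **Dynamic functional networks.** Each epoch is cut into 1 s
   non-overlapping windows. Per window, signals are re-referenced to the
   common average, band-pass filtered (1–120 Hz) with a 60 Hz notch,
   pre-whitened with per-channel AR residuals, and every channel pair (i, j)
   gets a weight
   `A_ij = max_{|τ|≤τ_max} |Σ_t x_i(t) x_j(t+τ)| / (L s_i s_j) ∈ [0, 1]`
   — the magnitude-normalized cross-correlation maximized over lags.
   Stacking the N(N−1)/2 unique weights over the T windows yields the
   *configuration matrix*.
2. **Network states.** Windows whose configuration vectors are similar
   (Pearson correlation, giving a T×T similarity matrix **S**) are clustered
   by maximizing the Newman–Girvan modularity
   `Q = (1/2m) Σ_kl [W_kl − γ s_k s_l / 2m] δ(g_k, g_l)` with a Louvain-style
   greedy optimizer, a consensus over many seeded optimizations, and a
   resolution γ tuned per epoch to maximize partition reliability (mean
   pairwise adjusted Rand index). The three longest states per epoch are
   retained and relabeled in order of median occurrence (PS0–PS2, S0–S2).
3. **State statistics.** *Flexibility* (rate of window-to-window state
   changes), state *duration fractions*, *connection density* (mean weight),
   and the *connection type index* `B = (C_s − C_w)/(C_s + C_w)`, where C_s
   and C_w count connection instances above the 95th / below the 5th
   percentile of the event-pooled strength distribution.
4. **Geography and topography.** Pairs are classed by seizure-onset-zone
   (SOZ) membership (SOZ-SOZ / SOZ-OUT / OUT-OUT); per-state class means,
   ROC AUC for identifying SOZ-SOZ connections from strength (with a
   10000-fold sensor-relabeling permutation null), and the within-grid
   Spearman correlation between connection length (mm) and strength.

Clinical recordings are access-restricted, so the package ships a
first-class synthetic generator (`netstates.simulate`) that plants the
statistical structure the pipeline is designed to detect: scripted switching
between block-structured coupling regimes, a hyper-coherent SOZ-like sensor
block, coupling that decays with inter-sensor grid distance, and 1/f + 60 Hz
line noise at clinical sampling rates (500/512 Hz). Every planted feature is
ground truth for the test suite.

## Worked example

```python
import netstates as ns

pre_spec, sz_spec = ns.paper_regime_specs(seed=2)       # synthetic event
pre, sz = ns.make_event(pre_spec, sz_spec)              # paired 60 s epochs
config = ns.PipelineConfig(seed=2, gamma_grid=(1.0,),
                           n_optimizations=100, n_permutations=1000)
result = ns.run_event(pre, sz, pre_spec.sensors, config)

print({k: round(v, 3) for k, v in result.flexibility.items()})
cols = ["state", "duration_fraction", "density", "type_index"]
print(result.metrics[cols].round(3).to_string(index=False))
```

prints

```
{'pre-seizure': 0.186, 'seizure': 0.034}
state  duration_fraction  density  type_index
  PS0              0.250    0.210      -0.406
  PS1              0.250    0.208      -0.394
  PS2              0.250    0.208      -0.473
   S0              0.333    0.219       0.020
   S1              0.333    0.225       0.202
   S2              0.333    0.240       0.490
```

The pre-seizure epoch changes state ~5× faster than the seizure
(flexibility 0.19 vs 0.03) and its states are weak-dominant (B ≈ −0.4);
during the seizure, density rises and the balance flips to strong-dominant
(B up to +0.5) — the desynchronized-to-synchronized progression the method
is built to expose. `result.geography` and `result.topography` add the
spatial picture: SOZ-SOZ connections are the strongest class in every state
(AUC ≈ 1 against the permutation null) and strength falls off with
connection length (mean Spearman ρ ≈ −0.26 in late seizure states).

The `examples/` directory has one short script per capability; each prints
the numbers it computes and what they mean. A thin CLI covers the same
ground from the shell:

```bash
netstates simulate --out event0 --seed 1
netstates run --pre event0/pre_seizure.csv --seizure event0/seizure.csv \
              --sensors event0/sensors.csv --out results0
netstates report results0 --out cohort
```

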
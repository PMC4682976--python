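# Methods

This note documents the models and procedures implemented in `netstates`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that were genuinely open.

## Pipeline

### Preprocessing (`netstates.preprocess`)

Epochs are segmented into non-overlapping windows (default 1 s; trailing
partial windows are discarded — a floor rule, no padding). All subsequent
operations are strictly per-window; nothing leaks across window boundaries.
Within each window, in order:

1. **Common average reference (CAR).** The instantaneous across-channel mean
   is subtracted, removing reference- and field-effect common modes that
   would bias correlation upward. Undefined for a single channel (error).
2. **Filtering: 1–120 Hz band-pass + 60 Hz notch.** A 4th-order Butterworth
   band-pass and an IIR notch (quality factor 30) are applied as their exact
   forward–backward (squared-magnitude) frequency response via FFT, which is
   zero-phase by construction. The filters are *designed* in the time
   domain but *applied* in the frequency domain because a 1 Hz corner has an
   impulse response comparable to the whole 1 s window: time-domain
   `filtfilt` on such short windows is dominated by edge transients and
   leaves ~25–40 % of a 60 Hz tone's RMS in place, violating the intended
   ≥20 dB line-noise suppression. The frequency-domain application attains
   the designed response exactly (measured: 60 Hz residual < 1 %, 10 Hz
   passband within 0.5 %). The trade-off is circular (DFT) convolution
   semantics within the window, which is acceptable for stationary 1 s
   segments.
3. **Pre-whitening.** Per channel, an AR(p) model is fitted by Burg's method
   (statsmodels) and replaced by its residuals (inverse filtering, keeping
   the window shape; the first p samples carry an initial-condition
   transient). Default p = 1, configurable to 10: the lowest order that
   flattens the 1/f-dominated spectrum and removes lag-autocorrelation
   inflation of cross-correlation. Zero-variance channels are zeroed with a
   warning.

### Connectivity (`netstates.connectivity`)

Connection weight = maximum over lags |τ| ≤ τ_max of the absolute
cross-correlation, normalized by window length L and the two full-window
standard deviations (the biased estimator, which bounds every weight in
[0, 1] by Cauchy–Schwarz; per-overlap normalization can exceed 1 at large
lags). τ_max defaults to 0.25 s — a generous bound on physiological
conduction delays — and is configurable; τ_max = 0 reduces to the absolute
zero-lag Pearson correlation. The lag maximization has a sampling floor: for
independent 1 s signals at 500–512 Hz the max over ~±128 lags of |ρ| sits
near 0.15–0.2, so weights below that floor are indistinguishable from noise.
All weights are retained (no thresholding). Configuration-matrix rows follow
the row-major upper-triangle pair order, recorded in output metadata.

### State detection (`netstates.states`)

The T×T Pearson similarity between configuration vectors is clustered by
modularity maximization under the Newman–Girvan null. Because that null is
defined for non-negative weights, negative similarities are set to zero and
the diagonal is zeroed before optimization (flagged in partition metadata);
zero-variance configuration columns get similarity 0 with a warning.

The optimizer is a dense Louvain-style greedy algorithm on the generalized
gain matrix `B = W − γP` (so the Newman–Girvan null and the consensus
association null share one engine): seeded random node order, best-gain
moves with ties to the first candidate, detachment into a fresh singleton as
an always-available move (without it the greedy pass cannot split a
community formed by bad early merges), then aggregation and repetition. On
random T ≤ 8 similarity matrices a single run reaches the enumerated global
optimum of Q in ~98 % of instances and the consensus in ≥ 95 % (both tested
against exhaustive set-partition enumeration).

**Consensus**: n (default 1000) seeded optimizations; if they disagree, the
co-assignment matrix is re-clustered with the same engine under a
permutation null (its mean off-diagonal co-assignment), iterating to a fixed
point, capped at 10 iterations (then the current modal structure is returned
with `converged=False` and a warning).

**Resolution tuning**: γ is selected per epoch from a grid (default 0.5–1.5,
step 0.05) to maximize partition *reliability* — the mean pairwise adjusted
Rand index across repeated independent optimizations — with ties broken
toward γ = 1, and γ = 1 returned with a warning if every grid point yields
only degenerate (all-one or all-singleton) partitions. Reliability-based
selection is this package's concretization of "choose the resolution that
gives reproducible states"; the grid and repetition count are configurable.

**Retention**: states are sets of windows (not necessarily contiguous).
The three largest states are retained and relabeled 0/1/2 by the median
window index of their members; remaining states follow in median order.
Flexibility is computed on the *full* label sequence, not only retained
states.

### State statistics (`netstates.metrics`)

Flexibility = fraction of consecutive window pairs with different labels.
Duration fraction = member count / T. Density = mean connection weight over
a state's connection-window instances. Strong/weak thresholds are the 95th
and 5th linear-interpolation percentiles of the strength distribution pooled
over *both* epochs of an event (all connections, all windows); strict
inequalities at the cuts. The type index B counts connection-window
instances, is invariant to mid-range connections, and is returned as NaN
with a warning when no instance is typed.

### Geography and topography (`netstates.geography`)

Pair classes are determined solely by the endpoints' SOZ flags. The AUC for
identifying SOZ-SOZ pairs ranks connections by their strength *averaged over
the state's windows* (the deterministic reading; per-window ranking would
make the AUC itself stochastic) using the midrank Mann–Whitney formulation
(ties get half credit). The permutation null re-assigns the same number of
sensors to the SOZ uniformly without replacement (default 10000 times),
which preserves the dependence between pairs sharing a sensor; the null CI
is the empirical 2.5/97.5 percentile band and significance means AUC above
the upper bound. Length–strength correlation uses only pairs with both
endpoints on the same uniformly spaced grid, Spearman ρ with midranks per
window, averaged over the state's windows; zero-variance windows are skipped
with a warning.

## Synthetic generator (`netstates.simulate`)

Each 1 s window of each channel is a linear mixture of shared Gaussian
sources such that the expected pairwise correlation equals the planted
coupling matrix of the scheduled state (eigenvalue-clipped to the nearest
PSD correlation matrix). Schedules are aligned to window boundaries, so
ground-truth window labels are exact. On top of the coupled signal each
channel receives 1/f^α noise (spectral shaping, α = 1) and a 60 Hz sinusoid
with random per-channel phase. Two spatial features are planted
independently: a multiplicative within-SOZ coupling boost (applied before
attenuation) and exponential coupling decay with inter-sensor distance.

The default "paper-regime" event (6×6 grid, 10 mm spacing, 2×2 SOZ corner
block, 60 s per epoch, fs 512 Hz) encodes the contrast the pipeline is meant
to resolve: a pre-seizure epoch cycling through four weak coupling layouts
every 5 s versus a seizure epoch with three 20 s states of increasing
coupling (0.7/0.8/0.9 within blocks), SOZ boost 2.0 and decay length 25 mm.
Two generator-design constraints matter and were set once, at design time:

* base couplings must sit above the ~0.15–0.2 max-lag sampling floor of the
  connectivity estimator, otherwise planted gradients are invisible;
* between-block coupling must stay low (0.05–0.10): a large spatially global
  common mode is removed by CAR, which otherwise erases the planted distance
  gradient — notably, the distance decay expressed through the full pipeline
  yields mean length–strength ρ of −0.13 (pre-seizure) to −0.30 (late
  seizure), close to values reported for clinical grids, even though the
  planted coupling-vs-distance correlation is far stronger. CAR and the
  correlation floor compress it.

For the planted-state-recovery regime, random block layouts are resampled
until every pair of states differs in ≥ 25 % of pair couplings, so "well
separated states" is guaranteed by construction rather than by luck of the
draw.

**What the generator does not emulate**: seizure waveform morphology
(spiking, DC shifts, chirps), non-stationarity within windows, volume
conduction beyond a global common mode, electrode artifacts or bad channels,
depth electrodes, and any physiological dynamics of seizure spread. Passing
tests therefore demonstrate that the *statistical machinery* recovers
planted coupling structure through the full preprocessing chain — not that
clinical recordings have that structure.

## Problem sizes and runtime

Full-pipeline test batches run at 36 channels × 60 s × 512 Hz (the default
event), recovery tests at 12 channels × 48 s × 500 Hz, with consensus over
50–100 optimizations and a fixed γ = 1 (γ tuning is exercised separately);
the permutation calibration uses 500 datasets at 1000 permutations, and
planted-SOZ detection the full 10000. These sizes keep the whole suite under
a few minutes while leaving every statistical margin wide. Library defaults
(1000 optimizations, 10000 permutations, γ grid 0.5–1.5) remain the
full-strength settings.

## Known limitations

* Greedy modularity maximization has no optimality guarantee; on small
  random similarity matrices ~2 % of single runs end in a local optimum
  (consensus largely, but not always, repairs this).
* The biased cross-correlation normalization slightly penalizes large lags;
  with τ_max = 0.25 s the attenuation is ≤ 25 % at the extreme lag.
* Percentile thresholds and B are event-relative: they support within-event
  contrasts, not absolute cross-event comparisons.
* γ reliability tuning optimizes reproducibility, not ground-truth accuracy;
  on planted data the two coincide, on real data they need not.
* The frequency-domain filter application assumes within-window wide-sense
  stationarity (as does the windowing itself); no stationarity test is
  performed.
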
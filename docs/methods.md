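# Methods

## The fitting problem

A candidate neuron model is a vector x ∈ ℝ^P of membrane parameters inside
box bounds; the default specification has P = 13: maximal conductance
densities for transient Na⁺, delayed-rectifier K⁺ and M-type K⁺ currents,
each split between soma and axon (6), a passive leak density per
compartment (3), and four global passives — leak reversal e_pas (mV),
specific capacitance cm (µF/cm²), axial resistivity Ra (Ω·cm) and the
M-current time-constant scale τ_max (ms). The objective compares the
model's simulated voltage responses with target values of
electrophysiological features, one objective per (stimulus, feature) pair,
and the evolutionary loop minimises these S·F objectives jointly.

## The reduced compartmental model

Three cylindrical compartments — soma (L = diam = 56.42 µm, lateral area
≈ 1e-4 cm²), axon (60 × 1 µm) and dendrite (600 × 2 µm), both attached to
the soma — form the smallest tree exhibiting the soma/axon/dendrite
parameter split. The dendrite is passive by default. Kinetics are the
classic squid-axon Hodgkin–Huxley Na (m³h, E_Na = +50 mV) and
delayed-rectifier K (n⁴, E_K = −77 mV) schemes at their conventional
−65 mV resting frame, plus a first-order M-type K current
(p∞ = 1/(1+exp(−(V+35)/10)),
τ_p = τ_max/(3.3·e^{(V+35)/20} + e^{−(V+35)/20}), E = E_K) that produces
spike-frequency adaptation, and leak. Removable singularities of the rate
functions are evaluated by their limits.

Integration is the standard staggered scheme: gating variables advance by
exponential Euler with the voltage frozen over the step; the voltage
advances by implicit (backward) Euler on the conductance-linearised cable
equation, solved exactly on the tree by Hines elimination. Axial coupling
between compartment centres is g_ax = (π d²/4)/(Ra·L) using the child's
dimensions. The scheme is unconditionally stable; default dt = 0.025 ms.
Rate functions are pre-tabulated per call on a 0.05 mV grid over
[−120, 80] mV and linearly interpolated inside the integration loop (the
inner loop is numba-compiled); the interpolation error is orders of
magnitude below the O(dt) integration error. Simulation starts from
v_init = e_pas with gates at steady state, preceded by a 100 ms unrecorded
settling period so that voltage_base is measured at rest. A state outside
±1000 mV or non-finite raises an integration-failure error carrying the
failure time — a failed candidate scores the maximum on every objective
and never aborts a run.

Default parameter bounds were chosen once so that the default long-square
amplitude grid (0.05–0.4 nA) spans sub- to supra-threshold responses for
ground truths drawn from the middle 60% of the box: ḡ_Na ∈ [0.05, 0.4],
ḡ_K ∈ [0.005, 0.06], ḡ_M ∈ [1e-5, 2e-4], g_pas ∈ [1e-5, 8e-5] S/cm²,
e_pas ∈ [−80, −60] mV, cm ∈ [0.5, 1.5] µF/cm², Ra ∈ [50, 200] Ω·cm,
τ_max ∈ [200, 2000] ms. With these values a mid-range cell has input
resistance of order 100 MΩ and fires adapting trains at the upper half of
the amplitude grid.

## Stimuli

Four current-clamp classes on a shared timing convention (delay 200 ms,
duration 1000 ms, t_stop 1400 ms unless stated): long square steps on a
linear 8-point amplitude grid over [0.05, 0.4] nA; 3 ms short squares at
2× and 3× the top step amplitude; ramps rising linearly to 0.3 and 0.45 nA;
and noisy steps (pedestals 0.1/0.2/0.3 nA × two noise seeds, per-sample
Gaussian noise with σ = 0.2·pedestal low-pass filtered with τ = 1 ms).
The default suite holds 18 stimuli: 8 long square, 6 noisy, 2 short
square, 2 ramp. Waveform support is onset-inclusive, offset-exclusive
([delay, delay+duration)); a ramp reaches its final amplitude on the last
in-window sample, which makes its trapezoidal charge exactly half that of
the matching square. Noise is realised on a fixed 0.05 ms master grid and
interpolated onto the simulation grid, so a stimulus waveform is a
function of (parameters, seed) only — refining dt refines the same
waveform rather than drawing a new one.

## Features and scoring

A spike is a strict upward crossing of the −20 mV detection threshold
(onset linearly interpolated; peak = maximum until the next downward
crossing; an excursion that never exceeds the threshold is not a spike).
The catalogue holds 20 features: spike_count, time_to_first/last_spike,
mean_frequency, inv_first_ISI, ISI_mean, ISI_CV, adaptation_index,
AP_amplitude/peak/halfwidth/max-rise-rate means, AHP depth and
time-from-peak means, voltage_base (mean pre-stimulus voltage),
steady_state_voltage_stimend (mean over the last 100 ms of stimulus),
mean/min voltage during stimulus, max_voltage, and voltage_deflection
(steady-state minus base). Features are computed inside the stimulus
window except voltage_base and max_voltage (whole trace); unmet
prerequisites (e.g. ISI statistics with < 2 spikes) yield the
distinguished `undefined` value.

An objective's score is min(|sim − mean|/σ, 250); `undefined` scores 250.
Targets built from traces use the feature of the (averaged) target trace
as the mean and, by default, σ = max(0.05·|mean|, floor) with unit floors
0.5 mV, 1 ms, 0.5 count, 0.5 Hz, 1 mV/ms, 0.05 dimensionless; an
`empirical` policy instead uses the sample σ across replicate traces.
A feature undefined on the target trace is recorded as skipped and scores
0 for every candidate (with a logged warning), so noiseless self-targets
give the generating parameters a total of exactly zero.

## Evolution

The loop is elitist μ+λ: an initial population of λ individuals drawn
uniformly within bounds is scored once; each generation draws λ offspring
from the μ parents — each offspring produced by exactly one of bounded
simulated-binary crossover (probability 0.3, η = 10, per-gene child swap),
bounded polynomial mutation (probability 0.5, η = 20, per-gene rate 1/P),
or plain copying — scores them, pools parents with offspring, and keeps μ
survivors by IBEA environmental selection: min–max normalise objectives
over the pool, form additive-ε indicators, scale by the largest indicator
magnitude times κ = 0.05, then iteratively delete the worst-fitness
individual, adding its exponential terms back to the survivors
(normalisation is computed once per selection; ties break by insertion
order). The hall of fame records the 10 lowest total scores over all
generations (exact duplicates of a stored vector are not re-inserted; ties
favour earlier generations) and never influences selection; the returned
model is its argmin, so the reported best is a running minimum by
construction.

All randomness flows from one root seed through named child streams
(init, variation, truth, target-noise, …), making whole runs bit-exactly
reproducible, including across the parallel scheduler (below). A JSON
checkpoint (generation, variation-RNG state, parents with cached scores,
hall of fame, history) makes runs resumable with identical results.

## Parallel and pipelined execution

The execution plan mirrors a cluster in miniature: the population is split
into `n_partitions` contiguous near-equal parts ("nodes"), each
partition's stimuli are grouped into ⌈S/n_sim_workers⌉ batches ("GPUs"),
and feature scoring runs on an evaluation pool ("CPU cores"). With
pipelining on, the simulation of batch k+1 starts as soon as batch k's
traces are handed to the evaluators, so simulation and evaluation overlap;
off, execution is strictly serial per partition. Every (individual,
stimulus, feature) computation is independent and executed in a fixed
per-individual order, so the score matrix is bit-identical to the
sequential reference for every plan — scheduling changes wall time, never
arithmetic. A crashed task scores the affected individuals' rows at the
maximum and the run continues. Task timings are recorded in an event log
(monotonic clock); `synthetic_timeline` additionally produces analytic
timelines from fixed task durations, for which the pipelined makespan is
provably never worse than the serial one.

Worker pools are threads: the simulator kernel releases no special state
and per-task work is coarse, so threads preserve determinism and avoid
per-process recompilation. Worker counts are plan fields, never hardware
probes.

## Benchmarks

Five designs, each timing `n_repeats` simulate–evaluate steps on a fixed
seeded population after one discarded warm-up step (mean ± std, monotonic
clock around the simulate–evaluate call only — variation and selection are
excluded): compute-fixed/problem-scales (N = 500…5000 step 500), strong
scaling (N = 3000, partitions 1–16), weak scaling (250·partitions),
stimulus scaling (S = 1…18 at N = 500, F = 20) and score-function scaling
(F = 1…180 at N = 500, S = 8; F beyond the catalogue cycles it — repeated
score functions are genuine repeated work). The full grids are
constructible but the shipped defaults for test and acceptance runs are
desk-scale (N ≤ 64, partitions ≤ 4, repeats ≤ 5) so a laptop CPU finishes
in seconds; design invariants (constant N, constant N/partitions = 250,
work = N·S·F per step) are preserved exactly at any scale. Absolute times
are reported, never asserted — they are properties of the host.

`classify_scaling` fits t = a·g(n)+b for g ∈ {1, log n, n} by least
squares and a free-exponent power law a·n^k+b by nonlinear least squares,
then selects by nested-model partial F-tests at the 1% level (constant ⊂
{log, linear} ⊂ power law; log vs linear by residual). The F-test guards
against the free exponent absorbing pure measurement noise, which plain
information criteria mis-handle at these small trial counts.

## Synthetic ground-truth problems

`make_ground_truth(seed, n_free_params, noise_sd, …)` samples a truth
uniformly from the middle 60% of the bounds (avoiding boundary
pathologies; integration failures are resampled), simulates its responses
to the suite, optionally adds seeded Gaussian voltage noise (noise_sd, mV)
to the target traces, and freezes the extracted features into the target
table. Freeing fewer than 13 parameters pins the rest at the truth inside
the model, giving the reduced recovery problems: the shipped toys
(`make_toy_problem`) free the somatic/axonal spike conductances first and
use the 8 long-square stimuli with 8 score functions (spike_count,
time_to_first_spike, mean_frequency, AP_amplitude_mean, AP_peak_mean,
AHP_depth_mean, voltage_base, steady_state_voltage_stimend), the reduced
design typical of population-size recovery studies.

What the generator emulates — and what it does not: targets come from the
same model family as the candidates, so the optimum is exactly attainable
and noiseless self-targets score zero; real recordings carry model
mismatch, electrode artefacts, trial-to-trial variability and features the
reduced kinetics cannot express (Ih sag, Ca-dependent bursting,
backpropagation). Passing recovery tests therefore demonstrates the
correctness and convergence machinery of the pipeline, not that the
reduced model can fit a real cell.

## Numerical choices and degenerate cases

- Gate rates at removable singularities use series limits below |u| < 1e-7.
- Min–max normalisation of a degenerate objective column (max = min)
  contributes zero to every indicator; if all indicators vanish the scale
  c falls back to 1 so fitness stays finite and equal.
- Grid placement of stimulus edges uses ceil with a 1e-9 relative guard so
  delay/dt landing on a representable boundary is onset-inclusive.
- Trace CSVs are written at 17 significant digits and read with
  round-trip float parsing, so every writer/reader pair is value-exact.

## Known limitations

- Step-size sensitivity: for second-long adapting spike trains the
  marginal last spike can appear or vanish when dt is halved, and ramp
  first-spike times are intrinsically sensitive to the threshold-crossing
  step; robustness is therefore guaranteed as "count changes by at most
  one; non-ramp first-spike times move < 0.1 ms", not as bit-stable spike
  trains. Likewise, exact translation invariance holds for subthreshold
  responses and first-spike latencies, but late spikes in long trains
  drift under any perturbation (sensitive dependence).
- At the small budgets of the quick recovery study (μ = 10, λ = 20,
  20 generations) the final-to-initial score ratio is stochastic and
  straddles a few percent seed-to-seed; doubling the generation budget
  brings every tested seed well below 2%.
- The thread-pool scheduler models concurrency structure faithfully but
  not hardware throughput: makespans show overlap and batching effects,
  not GPU-class speedups.
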
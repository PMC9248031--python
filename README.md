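# neuroea

Evolutionary construction of biophysical neuron models, at desk scale.

Constraining the maximal conductances of a compartmental neuron model so
that its simulated voltage responses match a recorded cell is a hard,
non-convex search problem: the parameter space is large and very different
conductance sets can produce similar firing. `neuroea` implements the
standard pipeline used for this problem — simulate a population of
candidate models under a suite of current-clamp stimuli, score each
candidate by how far its electrophysiological features deviate from target
values, and evolve the population with an indicator-based evolutionary
algorithm (IBEA) — together with the concurrency structure (population
partitioning, stimulus batching, pipelined simulate-while-evaluate
execution) and the strong/weak-scaling benchmark harness used to
characterise how the simulate–evaluate loop scales.

It is aimed at computational neuroscientists and methods researchers who
want a small, fully reproducible, dependency-light version of this
pipeline: the NEURON/GPU simulation backends of production fitting stacks
are replaced by a built-in reduced conductance-based model, cluster nodes
and GPUs by local worker pools, and experimental recordings by synthetic
ground-truth problems whose answer is known.

## The model and the objective

The neuron is a three-compartment (soma, axon, dendrite) cylinder tree with
Hodgkin–Huxley sodium (m³h) and delayed-rectifier potassium (n⁴) currents,
a first-order M-type potassium current for spike-frequency adaptation, and
a passive leak. The 13 free parameters x ∈ ℝ¹³ are the Na/K/M maximal
conductance densities split between soma and axon, a leak density per
compartment, and the global passives (e_pas, cm, Ra, τ_max):

    C_m dV/dt = − ḡ_Na m³h (V−E_Na) − ḡ_K n⁴ (V−E_K) − ḡ_M p (V−E_K)
                − g_pas (V−e_pas) + I_axial + I_inj

A population X ∈ ℝ^{13×N} is evaluated against S stimuli (default 18:
8 long squares, 6 noisy steps, 2 short squares, 2 ramps) and F score
functions (default 20 e-features: spike count, latencies, ISI statistics,
AP shape, AHP depth, subthreshold voltages…). Each objective is a
normalised deviation

    score(i, s, f) = min( |feature_f(V_i,s) − target_{s,f}| / σ_{s,f}, 250 )

giving an N × (S·F) score matrix; an undefined feature (e.g. AHP depth of
a non-spiking trace) scores the full 250. Selection is IBEA with the
additive-ε indicator I(i,j) = max_k (o_i[k] − o_j[k]) on min–max normalised
objectives and fitness F(j) = Σ_{i≠j} −exp(−I(i,j)/(c·κ)), κ = 0.05.
Parents and offspring are pooled each generation (elitist μ+λ survival),
and a hall of fame tracks the 10 lowest unweighted score sums ever seen;
the final model is its argmin.

## Worked example: recovering known parameters

Free two conductances (ḡ_Na and ḡ_K at the soma), pin the rest at a known
ground truth, build noiseless targets from the truth's own responses to the
8 long-square stimuli, and let the EA search:

```python
import numpy as np
from neuroea import EAConfig, optimize
from neuroea.fixtures import make_toy_problem

gtp = make_toy_problem(n_free_params=2)     # seeded, fully reproducible
best, history = optimize(
    EAConfig(mu=10, lambda_=20, n_generations=10, seed=0), gtp.problem()
)
print("truth :", np.round(gtp.truth, 4))
print("best  :", np.round(best.values, 4))
for h in history[::2]:
    print(f"gen {h.generation:2d}  best {h.best_total:9.2f}"
          f"  mean {h.mean_total:9.1f}  hof {h.hof_best:8.2f}")
```

prints

```
truth : [0.1416 0.0272]
best  : [0.1566 0.0297]
gen  0  best     28.68  mean    1553.1  hof    28.68
gen  2  best     17.25  mean     593.0  hof    17.25
gen  4  best     12.37  mean     142.6  hof    12.37
gen  6  best      4.59  mean     145.3  hof     4.59
gen  8  best      4.59  mean      88.6  hof     4.59
gen 10  best      4.56  mean      87.9  hof     4.56
```

The best total score falls from ~29 to ~4.6 (sum over 64 objectives, in
units of target standard deviations) in 10 generations of 20 offspring,
and the recovered conductances land within a few percent of the truth.
The hall-of-fame column is a running minimum by construction.

The same flow is available from the shell:

```bash
neuroea make-fixture --seed 7 --n-free 2 --suite-kind long_square --out bundle/
neuroea fit --bundle bundle/ --config ea.yaml --out fit/
neuroea bench --kind weak_scaling --bundle bundle/ --out weak.csv
```

`fit/` then holds `best.json`, `history.csv` and `hof.json`; the benchmark
CSV reports per-trial mean ± std wall time, the exact number of scored
objectives (always N·S·F) and the number of stimulus batches.

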
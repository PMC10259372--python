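# ljsurrogate

Multi-fidelity optimization of Lennard-Jones force-field parameters with
Gaussian-process surrogates.

## The problem

Fixed-charge molecular-mechanics force fields describe dispersion and
repulsion with the Lennard-Jones potential, parameterized per atom type by a
well depth ε and a well-position parameter R_min/2. Refitting those
parameters against experimental condensed-phase data (liquid densities ρ_L,
enthalpies of vaporization ΔH_vap, binary-mixture densities ρ_L(x) and
enthalpies of mixing ΔH_mix(x)) is expensive, because every trial parameter
vector θ requires molecular-dynamics property estimation, and hard, because
the objective landscape is multimodal so gradient descent from the current
force field only finds the nearest local minimum.

`ljsurrogate` implements a multi-fidelity strategy for this problem: most of
the searching happens on cheap Gaussian-process surrogates (one GP per
physical-property measurement, constant mean, anisotropic RBF kernel with
ARD length scales), and the expensive "simulation level" is reserved for
building the surrogates and validating their proposals. The fitness is a
scaled least-squares objective over N property types with M_n measurements
each,

    χ(θ) = (1/N) Σ_n (1/M_n) Σ_m ((y_m(θ) − y_m) / d_n)²,

with d_n calibrated so every property type contributes equally for the
starting force field (hence χ(baseline) = 1). Each outer iteration minimizes
the surrogate-level χ by differential evolution (population 15 per
dimension, dithered mutation in (0.5, 1), recombination 0.7) inside a bounds
box rebuilt from the simulated pool and expanded by η = 1.1 per side,
validates the proposal with one simulation-level evaluation, accepts it only
if it beats the incumbent, and rebuilds the surrogates with the new point
either way. When the surrogate search stalls, the GPs are refitted under
progressively stricter length-scale floors (l > 1e-10, then l > 1e-5)
before the run terminates.

Simulation-level evaluation is pluggable: any callable
`(ParameterVector, TrainingSet) -> SimulationRecord` works, and the package
bundles a synthetic evaluator with a planted optimum θ*, segmented
parameter→property dependencies, realistic noise, and injectable failures,
so the entire method runs and is testable on a desktop. The intended users
are force-field developers prototyping optimization strategies and anyone
who needs a self-contained, reproducible test bed for surrogate-assisted
parameter fitting.

## Worked example

Generate a synthetic 28-compound training set (56 measurements: ρ_L and
ΔH_vap per compound) over the default 12-parameter space, then optimize:

```bash
ljsurrogate synth-data --compounds 28 --seed 3 --out data/

cat > run.toml << 'EOF'
[run]
n_initial = 10
max_iterations = 12
gp_restarts = 2

[run.de]
max_generations = 150
EOF

ljsurrogate -v optimize --config run.toml \
    --training-set data/pure_training_set.csv \
    --truth-spec data/pure_truth_spec.json \
    --seed 11 --out runs/demo
```

which logs one line per iteration and ends with:

```
INFO ljsurrogate: iter 10: surrogate chi 0.0402, simulation chi 0.06094, accepted=True, pool=21, level=none
INFO ljsurrogate: iter 11: surrogate chi 0.9929 >= incumbent 0.06094; escalating none -> loose
INFO ljsurrogate: iter 11: surrogate chi 0.04356, simulation chi 0.06136, accepted=False, pool=22, level=loose
max_iterations: best simulation chi 0.0609 after 22 simulations (12 iterations)
```

Read: the starting force field has χ = 1 by construction; after 22
simulation-level evaluations (10 initial Latin-hypercube points + 12
iterations) the best accepted vector reaches χ = 0.061, a ~16× reduction in
the scaled squared error. At iteration 11 the surrogate search could not
beat the incumbent, so the models were rebuilt under the loose length-scale
constraint before proposing again. `runs/demo/trajectory.jsonl` holds the full
iteration history (proposals, both objective levels, accept/reject, bounds,
constraint level) and `runs/demo/best_vector.json` the optimized parameters.
The same seed and config reproduce these files byte for byte.

The same machinery is available as a library (`multi_fidelity_optimize`,
`build_ensemble`, `de_minimize`, `benchmark`, ...); see `docs/methods.md`
for the model, its assumptions, and all tunable parameters.

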
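# hypersis

SIS (susceptible–infected–susceptible) epidemics on hypergraphs: exact
individual-level stochastic simulation, a deterministic mean-field ODE
approximation, and spectral thresholds that decide whether the disease dies
out.

Nodes interact through hyperedges (groups of any size). A susceptible node
`i` becomes infectious with rate

    beta * sum_h I[i,h] * f(number of infected members of hyperedge h)

and recovers with rate `delta`. The response `f` may be nonlinear: concave
families (`identity`, `capped_linear`, `log1p`, `arctan`) model collective
suppression; threshold families (`step`, `hinge`) model collective
contagion. Hyperedges may be partitioned into categories, each with its own
response `f_k`.

All extinction conditions share the form `beta * c_f * lambda / delta < 1`,
where `lambda` is the largest eigenvalue of the slope-weighted
co-membership matrix `W = I I^T` and `c_f` is a slope constant of `f`
(`f'(0)` for concave responses, a linear-majorant slope otherwise).

## Modules

| module | contents |
|---|---|
| `hypersis.hypergraph` | `Hypergraph` / `PartitionedHypergraph`, incidence, co-membership and Laplacian matrices, random generator, text/JSON I/O |
| `hypersis.rates` | infection-response families, derivative-at-zero metadata, concavity checks, concave-majorant slopes |
| `hypersis.simulate` | synchronous discrete-time scheme, exact event-driven simulator, ensembles, dominating severity chain and bounding birth–death chain |
| `hypersis.meanfield` | mean-field vector field, Euler and adaptive integrators, analytic Jacobian, norm-decay diagnostics |
| `hypersis.spectral` | effective matrices, `beta_c`, extinction-probability/expected-time bounds, subset pressure `E(S,f)`, isoperimetric `eta`, persistence certificate |
| `hypersis.experiments` / `hypersis.cli` | config-driven beta-grid protocols and the `hypersis` command-line tool |

## CLI

```bash
# draw a hypergraph: 400 nodes, 400 edges, 200 size-3, 100 size-4, 50 size-5
hypersis generate --n 400 --counts "2:400,3:200,4:100,5:50" --seed 1 \
    --partition --out hg.txt

# spectral threshold for a partitioned family (f1 = x, f_k = 2 log(1+x))
hypersis threshold --hypergraph hg.txt --rate identity --rate log1p:a=2 \
    --rate log1p:a=2 --rate log1p:a=2 --beta 0.02

# stochastic ensemble and mean-field integration
hypersis simulate  --hypergraph hg.txt --rate identity --rate log1p:a=2 \
    --rate log1p:a=2 --rate log1p:a=2 --beta 0.05 --t 50 --runs 10 \
    --seed 7 --out ensemble.csv
hypersis meanfield --hypergraph hg.txt --rate identity --rate log1p:a=2 \
    --rate log1p:a=2 --rate log1p:a=2 --beta 0.05 --t 50 --out mf.csv

# extinction bounds (+ optional persistence certificate, small n only)
hypersis bounds --hypergraph hg.txt --rate identity --rate log1p:a=2 \
    --rate log1p:a=2 --rate log1p:a=2 --beta 0.02

# config-driven beta-grid experiment
hypersis experiment --config config.yaml --out results/run1
```

Example `config.yaml`:

```yaml
hypergraph:
  generator: {n: 400, counts_by_size: {2: 400, 3: 200, 4: 100, 5: 50},
              seed: 1, partition_by_size: true}
rates: [identity, "log1p:a=2", "log1p:a=2", "log1p:a=2"]
beta: [0.0, 0.01, 0.02, 0.03, 0.04]
delta: 1.0
i0: 0.5
T: 150.0
dt: 0.05
n_runs: 5
seed: 11
```

## Reproducibility

Every stochastic entry point takes an explicit seed. Ensemble runs derive
per-run seeds as `SeedSequence((base_seed, run_index))`, so runs are
reproducible and independent of execution order.
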
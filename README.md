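# spreadrank

Tools for studying how the choice of node-importance metric shapes epidemic
spreading and immunization on complex networks. The package implements
heterogeneous mean-field (HMF) SIS models parameterized by any of four
centrality metrics — degree *k*, H-index *h*, coreness *s*, and (unnormalized)
betweenness *b* — together with their epidemic thresholds, a stochastic SIS
simulator, and uniform vs. metric-targeted immunization experiments on
Barabási–Albert (BA) scale-free networks or user-supplied graphs.

It is aimed at network epidemiologists and network scientists comparing
"influential spreader" rankings: which metric predicts the widest spread,
the smallest epidemic threshold, and the cheapest targeted vaccination.

## Model

Group the nodes of an undirected simple graph into classes by the value *x*
of a metric, with empirical distribution P(x). Assuming annealed,
uncorrelated mixing, the infected fraction ρ<sub>x</sub>(t) of class *x*
obeys the SIS equations

```
dρ_x/dt = −ρ_x + λ x (1 − ρ_x) Θ,     Θ = (1/⟨x⟩) Σ_x x P(x) ρ_x ,
```

with spreading rate λ per contact and recovery rate μ = 1. The endemic
stationary state solves the scalar self-consistency equation

```
Θ = (1/⟨x⟩) Σ_x x P(x) · λxΘ / (1 + λxΘ),
```

whose nonzero root exists iff λ exceeds the epidemic threshold

```
λ_c = ⟨x⟩ / ⟨x²⟩ .
```

With x = k this is the classical degree-based HMF SIS model; substituting
h, s, or b yields the H-index, coreness, and betweenness models. Because
betweenness fluctuates most (largest second moment relative to its mean),
the betweenness model has the smallest threshold and the highest prevalence;
coreness, the most homogeneous metric, sits at the other end.

A discrete-time stochastic SIS simulator (synchronous updates with time step
dt; recovery probability μ·dt, per-contact transmission probability λ·dt)
provides the Monte Carlo baseline, and the immunization module removes the
top-g fraction of nodes under each metric (or a uniform random fraction)
before simulating, reporting ρ_g/ρ_0 curves and the immunization threshold
g_c at which prevalence is driven to zero.

## Worked example

```python
from spreadrank import (BAParams, barabasi_albert, build_classes,
                        compute_metric, epidemic_threshold,
                        stationary_prevalence)

net = barabasi_albert(BAParams(n_nodes=2000, m=5, seed=1))
for metric in ("betweenness", "degree", "h_index", "coreness"):
    classes = build_classes(compute_metric(net, metric))
    lc = epidemic_threshold(classes)
    rho = stationary_prevalence(classes, 0.15).rho
    print(f"{metric:12s}  lambda_c = {lc:.5f}   rho(0.15) = {rho:.3f}")
```

prints

```
betweenness   lambda_c = 0.00003   rho(0.15) = 0.984
degree        lambda_c = 0.04405   rho(0.15) = 0.374
h_index       lambda_c = 0.13602   rho(0.15) = 0.069
coreness      lambda_c = 0.20000   rho(0.15) = 0.000
```

— the four thresholds order λ_c^b < λ_c^k < λ_c^h < λ_c^s. At λ = 0.15 the
betweenness model is deep in its supercritical regime (betweenness values
span several orders of magnitude, so ⟨b²⟩ dwarfs ⟨b⟩ and λ_c^b is tiny)
and predicts near-total infection, while the coreness model — the most
homogeneous metric — is still below its threshold and predicts extinction.

A shell interface mirrors the library:

```
spreadrank generate ba --n 2000 --m 5 --seed 1 -o edges.txt
spreadrank centrality edges.txt --metric betweenness -o b.tsv
spreadrank hmf edges.txt --metric degree --lambda-grid 0:0.3:0.02
spreadrank immunize edges.txt --strategy degree --lam 0.15 --runs 50 --seed 1
spreadrank run config.yaml
```

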
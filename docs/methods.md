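# Methods

## Model

The package studies SIS epidemics on undirected simple graphs at the level
of node classes. A centrality metric x ∈ {degree k, H-index h, coreness s,
betweenness b} partitions the nodes into classes of equal metric value;
all nodes of a class are assumed to behave identically, and contacts are
annealed and degree-uncorrelated, so the probability that a followed link
points to an infected node is the single scalar

    Θ(t) = (1/⟨x⟩) Σ_x x P(x) ρ_x(t).

The class dynamics are dρ_x/dt = −μ ρ_x + λ x (1 − ρ_x) Θ with μ = 1.
These are the standard degree-block HMF SIS equations with the degree
replaced by an arbitrary nonnegative node score; the degree case is not
special-cased anywhere. The stationary state satisfies a scalar fixed-point
equation in Θ whose right-hand side is increasing and concave with slope
λ⟨x²⟩/⟨x⟩ at the origin, giving the threshold λ_c = ⟨x⟩/⟨x²⟩ and a unique
endemic root above it.

Assumptions worth keeping in mind: annealed mixing ignores the quenched
contact structure (the simulator on the actual graph therefore sits below
the mean-field curve on large sparse networks); uncorrelated mixing ignores
degree–degree correlations (the generated BA networks are nearly neutral,
assortativity ≈ −0.01, so the approximation is mild there); and grouping by
a non-local metric such as betweenness assumes nodes of equal betweenness
have statistically equivalent neighborhoods, which is a modeling choice,
not a theorem.

## Numerical choices

* **Stationary solver as the primary computation.** Betweenness classes
  reach values of 10⁵–10⁶, which makes the class ODE system stiff; the
  scalar bracketing root find on Θ (Brent, xtol 1e-14, on [1e-14, 1]) is
  scale-free and exact to solver tolerance at any metric magnitude. The ODE
  integrator (LSODA, rtol 1e-8, atol 1e-10, post-hoc clamping to [0,1]) is
  retained as a cross-check; tests require agreement to 1e-6.
* **Classes are exact.** No binning: each distinct metric value is its own
  class (M ≤ N classes; the scalar solve is O(M) per evaluation, so this is
  cheap). Zero-valued classes (e.g. leaf betweenness) are retained — they
  carry P(x) mass and stay uninfected at stationarity. An all-zero metric
  (e.g. betweenness on a complete graph) is rejected as degenerate.
* **Betweenness convention.** Unnormalized pair-dependency betweenness
  (fractional credit for tied geodesics, endpoints excluded), which equals
  the literal count of shortest paths through a node whenever geodesics are
  unique. The literal integer count is available behind a flag
  (`betweenness(net, count_paths=True)`) for sensitivity analysis; it
  enumerates full distance/path-count matrices and is intended for small
  graphs.
* **Monte Carlo discretization.** The simulator updates synchronously with
  a step dt: recovery probability μ·dt, per-contact transmission
  probability λ·dt (a susceptible with n infected neighbours is infected
  with probability 1 − (1 − λ·dt)ⁿ). dt = 1 gives the classic
  certain-recovery cellular-automaton scheme; however that scheme's
  stationary prevalence (e.g. ≈ 0.49 on a 10-regular graph at λ = 0.5,
  from ρ = (1 − ρ)(1 − (1 − λ)^{kρ})) is not comparable to the
  continuous-time mean-field fixed point 1 − 1/(λk) = 0.8 that the theory
  predicts. The default dt = 0.1 discretizes the continuous-time rates the
  model is written in and agrees with the fixed point to O(dt) (measured
  0.76 at dt = 0.1, 0.776 at dt = 0.05 on that graph). The step is exposed
  on every entry point.
* **Simulation window.** Defaults t_max = 120, burn-in = 80 time units
  (1200/800 steps at dt = 0.1); the stationary estimate is the mean
  prevalence over the post-burn-in window, and the absorbing all-susceptible
  state short-circuits the loop. Ensembles derive per-run streams from one
  master `SeedSequence`, so results are bit-reproducible.
* **Immunization.** Targeted immunization removes the round(gN)
  highest-ranked nodes (round-half-up; boundary ties broken by ascending
  node index, since the strict metric-cutoff rule cannot hit gN exactly on
  discrete data). Immunized nodes keep their identity — edges are removed,
  prevalence is counted against the original N, and the SIS seeder never
  infects them — so ρ_g/ρ_0 is comparable across g. Rankings are computed
  once on the intact graph (static targeting; no re-ranking after removal).
  The mean-field statement of *uniform* immunization, λ → λ(1 − g), is
  implemented separately (`mf_uniform_immunized_prevalence`) rather than
  conflated with the node-removal experiments. The immunization threshold
  g_c is the smallest grid g with ρ_g/ρ_0 ≤ ε (default ε = 0.005, a
  noise floor for 100-run ensembles on N ≥ 2000).
* **Assortativity** is the Pearson correlation of end-point degrees over
  the edge list counted in both orientations; full degrees are used rather
  than excess degrees (Pearson correlation is shift-invariant, so the value
  equals the standard assortativity coefficient). Undefined (None) when a
  degree sequence has zero variance.
* **Mean distance** is averaged over unordered distinct pairs of the giant
  component via exact all-pairs BFS; for large graphs a seeded
  sampled-source estimator (default 1000 sources) is available, and the
  per-source row mean is an unbiased estimator of the pair average by
  symmetry.

## Synthetic data

The generator grows Barabási–Albert networks from a complete seed clique of
m0 nodes (default m0 = m, the standard convention; the construction is then
feasible at every step), attaching each new node to m distinct existing
nodes with degree-proportional probability via urn sampling with rejection
of duplicates. The result is always simple and connected with exactly
m0(m0−1)/2 + (N−m0)·m edges. The two reference configurations emulate the
study's networks: N=5000, m=30 (⟨k⟩ ≈ 59.8) and N=10000, m=100
(⟨k⟩ ≈ 199.0). Realization-dependent quantities (metric maxima, exact
mean distance) vary with the unstated details of any particular BA variant;
they are reported, not asserted. What the generator does *not* emulate:
degree–degree correlations, clustering, and community structure of real
contact networks — a passing ordering test on BA networks shows the metric
ranking under a neutral scale-free null, not under arbitrary real topology
(the study itself found the degree ranking superior on its real networks).

Deterministic fixtures (star, path, cycle, complete, circulant-regular)
provide closed-form oracles: e.g. on the 4-leaf star the degree model at
λ = 1 has the hand-checkable fixed point Θ* = 1/2, ρ = 2/5, and on any
k-regular graph every metric is single-class so all four models collapse
onto ρ = 1 − 1/(λx).

## Scales used by the shipped experiments

The test suite and the acceptance script run the full pipeline at sizes
chosen to complete on a single CPU in minutes while preserving every
qualitative regime: five N=5000 replicates plus one N=10000 network for
topology and ordering checks (exact all-pairs BFS at N=5000; sampled at
N=10000), an N=2000, m=5 network for the threshold-onset scan, an N=2000,
m=3 network with 50-run ensembles and a g-grid step of 0.02 for the
immunization ranking, and an N=1000 10-regular circulant for the
simulator/mean-field comparison. Full-scale ensembles (100 runs) remain
the library defaults.

## Known limitations

* Annealed, uncorrelated mean field only; no degree-correlated mixing
  P(k'|k), no quenched (individual-based) mean field, no SIR/SEIR.
* The betweenness HMF model tends to *over*-predict spreading drastically
  at moderate λ because ⟨b²⟩/⟨b⟩ is enormous; this is a property of the
  model class being studied, not a numerical artifact.
* Discrete-time simulation bias is O(dt); comparisons against the
  continuous-time theory should use dt ≤ 0.1.
* The immunization threshold estimate is grid-resolution limited and, near
  criticality, sensitive to the finite ensemble (50–100 runs) and the
  absorbing-state cutoff ε.
* The Pajek reader handles the common `*Vertices`/`*Edges`/`*Arcs` subset
  only (no multirelational or coordinate extensions).
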
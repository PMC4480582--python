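# unpbn — unmixing cell subpopulations with mixtures of Gaussian Bayesian networks

Single-cell snapshot measurements (flow/mass cytometry, multiplexed imaging)
observe a handful of proteins per cell out of a much larger biochemical
system.  When the sampled population contains qualitatively distinct
subpopulations — different cell fates, mutants, stimulation histories — the
statistical relations among the *measured* proteins differ between
subpopulations, and fitting a single network to the pooled data yields an
uninformative average.  `unpbn` addresses this by treating the data as a
mixture of Gaussian Bayesian networks (GBNs) with an *unknown* number of
components: it simultaneously infers how many distinct subpopulations are
present, which cells belong to which, and the network of statistical
relations among the measured proteins within each subpopulation.

## The model

An observation is a vector x ∈ R^d of protein levels in one cell.  Within a
subpopulation the data follow a GBN: a DAG `G` plus linear-Gaussian
conditionals

    x_j | pa_G(x_j) ~ N( μ_j + Σ_{k∈K_j} β_{j,k}(x_k − μ_k), σ_j² ).

The population is a mixture p(x) = Σ_{h=1}^N w_h p(x | μ_h, σ_h, B_h, G_h).
Component parameters (μ, σ, B) and the weights w are integrated out
analytically — the former through the conjugate Normal–Wishart prior (zero
prior mean, identity precision-scale matrix, d+2 degrees of freedom), giving
the closed-form BGe marginal likelihood L(G|X); the latter through a
symmetric Dirichlet(α=1), giving a Dirichlet-multinomial prior over the
allocation vector l.  With a truncated Poisson(λ=1) prior on N and a
parent-set-cardinality prior p(G), the sampler targets

    p(l, G₁..G_N, N | X) ∝ Π_h [ L(G_h | X_{I_h}) p(G_h) ] · p_N(l|N) · p(N).

A trans-dimensional MCMC (single-edge structure moves, collapsed Gibbs
reallocation, and allocation-sampler eject/absorb moves on N) explores this
posterior.  Traces are summarized by posterior edge probabilities
(pep_ij = Σ_s a_ij^s / r), a label-switching-resolved consensus allocation
(maximizing the posterior-expected adjusted Rand index), and the accuracy
metric *pco* (percentage of correctly allocated observations).  k-means and
Ward hierarchical clustering plus average-silhouette-width (ASW) model-size
selection are included as the proximity-based reference methods.

A built-in reduced EGF/NGF MAPK cascade (Raf–Mek–Erk with EGF-transient /
NGF-sustained Erk dynamics and Normal expression noise on total protein
levels, σ = μ·fd) generates benchmark snapshot data; a published kinetic
model in SBML form can be substituted via `unpbn.load_sbml_model`.

## Worked example

```python
import numpy as np
from unpbn import (two_component_gbn_spec, generate_gbn_mixture,
                   McmcConfig, run_mcmc, consensus_allocation, pco,
                   per_component_edge_probabilities, symmetrize_pep)

spec = two_component_gbn_spec(n_cells=200)      # v-structure vs chain, d=3
data, truth = generate_gbn_mixture(spec, np.random.default_rng(1))

trace = run_mcmc(data, config=McmcConfig(
    n_iterations=2000, burn_in=1000, thinning=5, seed=11))

print(trace.n_components_counts())
cons = consensus_allocation(trace)
print(cons.n_components, round(pco(cons.labels, truth), 1))
pep = per_component_edge_probabilities(trace, cons)[0]
print(np.round(symmetrize_pep(pep), 2))
```

Output:

```
{2: 142, 3: 58}
2 100.0
[[0.   0.21 0.95]
 [0.21 0.   0.93]
 [0.95 0.93 0.  ]]
```

The chain spends most retained samples at N=2 components (the truth), the
consensus allocation recovers the two subpopulations perfectly
(pco = 100%), and the first component's undirected posterior edge
probabilities put ~0.93–0.95 on the two connections of its generating
v-structure (x1→x3←x2) and much lower mass (0.21) on the absent x1–x2
connection (the flat parent-set-cardinality prior keeps absent-edge mass
non-negligible at this sample size; see `docs/methods.md`).

The same workflow is available from the shell:

```bash
unpbn simulate --fd 0.5 --time-point 120 --seed 7 --out data/
unpbn unmix --data data/mixture_t120.csv --seed 7 --iterations 2000 \
      --burn-in 1000 --thinning 5 --truth data/truth_t120.csv --pco --out run/
unpbn benchmark --fd-levels 0.1,0.7 --time-points 120,540 --cells 50 \
      --seed 7 --out bench/
```

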
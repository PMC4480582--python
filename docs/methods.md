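# Methods

## Model

Observations x ∈ R^d (active protein levels per cell) are modelled as a
mixture of Gaussian Bayesian networks.  Each component h carries a DAG G_h;
given G_h the joint density is multivariate normal with the conditional
independence structure of G_h, parametrized node-wise as
x_j | pa(x_j) ~ N(μ_j + Σ_k β_{j,k}(x_k − μ_k), σ_j²).  The inferential
targets are the allocation vector l, the component DAGs, and the number of
components N; all continuous parameters are integrated out.

**Marginal likelihood (BGe).**  With a Normal–Wishart prior — prior mean
vector 0, Wishart scale T = I, ν (weight on the mean, `mean_precision_scale`)
= 1, degrees of freedom α_w = d + 2 — the marginal likelihood of a DAG
factorizes over node families, each family score being a ratio of subset
marginals

    log p(X_S) = (p/2)·log(ν/(ν+n)) − (np/2)·log π
               + log Γ_p((α_w−d+p+n)/2) − log Γ_p((α_w−d+p)/2)
               + ((α_w−d+p)/2)·log det T_SS − ((α_w−d+p+n)/2)·log det R_SS,

R = T + S_n + (νn/(ν+n))(x̄−μ₀)(x̄−μ₀)ᵀ, |S| = p.  The α_w − d + p shift
makes the subset marginal consistent with the inverse-Wishart marginal of a
sub-covariance, which is what gives identical scores to Markov-equivalent
DAGs.  The test suite checks the closed form against dense-grid quadrature
(2-D over (μ, σ²) for single columns; 3-D over the covariance Cholesky for
column pairs) to 1e-4 log-units, and score equivalence across all 2- and
3-node equivalence classes.  With T = I the prior expects unit-scale
covariance, so z-scored columns are the recommended input for real data
(`Dataset.standardized()`, CLI `--standardize`).  Note that column scaling is
not score-neutral: strongly shrunken within-component variance (e.g. after
pooling widely separated components) weakens the penalty on extra edges.

**Structure prior.**  Uniform over parent-set cardinalities:
log p(G) = Σ_j −log C(d−1, |pa(j)|).  This prior is deliberately flat over
sizes, which gives parent sets of size d−1 the same prior mass as size 0;
for d = 3 a second parent costs nothing relative to the first (see
"Limitations").  A `max_parents` cap is available for larger d (default
d − 1, i.e. uncapped).

**Allocation and N priors.**  Mixture weights are integrated against a
symmetric Dirichlet(α = 1), giving the Dirichlet-multinomial allocation
probability p_N(l|N) = Γ(Nα)Γ(n+Nα)⁻¹ Π_h Γ(n_h+α)/Γ(α); N has a Poisson
(λ = 1) prior truncated to N ≥ 1.  States never contain empty components
(labels are surjective onto 1..N), so the prior marginal over N is the
truncated Poisson reweighted by the surjective Dirichlet-multinomial mass —
the prior-sampling test compares against this exactly enumerated marginal.

## Sampler

One iteration is a sweep of three phases:

1. **Edge moves** — per component, one single-edge operation (add, delete,
   reverse) drawn uniformly from the valid (acyclicity- and cap-respecting)
   neighborhood, accepted by Metropolis–Hastings with the family-score delta
   and the neighborhood-size proposal ratio.
2. **Gibbs reallocation** — a collapsed pass over all observations in random
   order; observation i is reassigned among the current N components with
   probability ∝ (n_h^{(−i)} + α) · predictive BGe contribution.  If i is its
   component's sole member the full conditional degenerates to the current
   label (the no-empty-component policy), so dimension changes happen only
   through eject/absorb.
3. **Dimension change** — by default an even mixture of two reversible
   proposal pairs.

   *Eject/absorb (Beta coin):* eject picks a component uniformly, splits its
   members by i.i.d. coin flips with Beta(1,1)-integrated probability (so
   the split proposal cancels exactly against the Dirichlet-multinomial
   prior ratio at α = 1), gives the new component label N+1 and a DAG drawn
   uniformly from the enumerated DAG space (d ≤ 4; copy-of-parent fallback
   above that).  Absorb merges the last-labelled component into a uniformly
   chosen keeper.  Restricting absorb to the last label makes the pair
   exactly inverse on labelled states, so the proposal densities are
   available in closed form without path-counting; the uniform DAG proposal
   (rather than copying the parent's DAG) gives the reverse move of any
   absorb positive density even when the merged components carry different
   DAGs.

   *Split-merge (anchor pair, restricted-Gibbs final scan):* an ordered pair
   of distinct observations is drawn uniformly — a state-independent choice,
   so each per-pair kernel is a valid Metropolis–Hastings kernel on its own
   and no summation over alternative proposal paths is needed.  If the
   anchors share a component it is split: the first anchor keeps the label
   and DAG, the second seeds a new last-labelled part with a uniformly
   proposed DAG; remaining members are pre-assigned to the nearer anchor
   (deterministic launch) and one sequential restricted Gibbs scan in fixed
   index order generates the final assignment, whose probability is the
   proposal density.  If the anchors sit in different components and the
   second one's component carries the last label, the merge (exact reverse)
   is proposed, its acceptance evaluating the same launch-and-scan density
   at the current assignment.  This pair is what keeps splits viable when a
   component's fitted density is tight (low expression noise): the Beta-coin
   eject must pay the full predictive cost of a random subset and its
   acceptance collapses, whereas the restricted scan proposes
   cluster-respecting splits.

   Acceptance terms always include the posterior ratio (component scores,
   structure priors, allocation term, p(N)) and the full proposal ratio;
   both pairs (and their mixture) are validated against the exhaustively
   enumerated posterior on toy problems.

   Each sweep ends with a label swap of two uniformly chosen components — a
   symmetric proposal between states of equal posterior, always accepted.
   It is required for irreducibility: since absorb/merge may only remove the
   last label, a component buried under a later-created one could otherwise
   never rotate into the removable slot.

The chain starts from N = 1, all observations together, empty DAG.  All
probability arithmetic is on the log scale; categorical draws use a
fixed-order inverse-CDF over cumulative weights, making runs bit-identical
for a given seed.  Correctness of the whole move set is validated by
comparing thinned visit frequencies against the exhaustively enumerated
posterior over all (partition, DAG-assignment) states on toy problems
(χ² not rejected at 0.01), and the prior-only chain against the enumerated
prior marginal of N.

`move_probabilities` (edge, gibbs, eject, absorb) defaults to
(0.25, 0.25, 0.25, 0.25): the first two entries switch their phases on, the
last two set the relative eject-vs-absorb probability (their normalized
ratio enters the acceptance terms).  Published-scale run lengths
(2.8·10⁶ iterations, 1.4·10⁶ burn-in, thinning 350 for two-component
problems; 5·10⁶/2·10⁶/500 for four-component problems) are the config
defaults; all desk-scale analyses here override them (below).

## Post-processing

* **pep** — directed posterior edge probability pep_ij = Σ_s a_ij^s / r.
  Whole-trace pep weights each sampled component by its occupancy n_h/n.
  Per-component pep matches each sampled component to the consensus
  component sharing most members (ties toward the larger consensus
  component) and averages within the matched slot; an alternative
  (``match="consensus"``) instead lets each consensus block select, per
  sample, the component holding the majority of its members — insensitive
  to transient satellite components but blind to genuine sub-splits.
  Because Markov-
  equivalent DAGs score identically, directed pep spreads over
  equivalence-class orientations; the symmetrized (undirected) pep
  p_ij + p_ji is the connection-level summary used for reporting.
* **Consensus allocation** — maximizes the posterior-expected adjusted Rand
  index (mean ARI against all retained samples) over a candidate set:
  average-linkage cuts of the 1 − co-clustering-similarity distance at every
  K plus every sampled partition, optionally restricted to exactly K blocks
  (`k_fixed`).  On n ≤ 8 toys the candidate search matches exhaustive
  search over all set partitions.
* **pco** — per sample and component, the majority ground-truth label
  defines the component's identity; the fraction of members carrying it is
  averaged over components, then samples, and scaled to percent.  A tied
  majority gives the same count for any tied label, so the deterministic
  tie-break cannot change the value.

## Clustering baselines and model-size selection

k-means (squared-Euclidean objective, 500 random restarts by default,
best-objective restart returned) and Ward hierarchical clustering cut at K
serve as proximity-based references; singleton silhouettes are 0
(Rousseeuw's convention) and ASW comparisons are made only within one
method.  The network-mixture method enters the ASW comparison through its
consensus allocation constrained to each imposed K.

## Synthetic data

**Reduced MAPK cascade.**  A five-state ODE (fast Ras-GTP-like activator u,
slow Rap1-like activator v, active pRaf, ppMek, ppErk; rate equations in the
`ReducedCascadeModel` docstring) reproduces the defining qualitative
difference between the stimulations: EGF combines receptor-level stimulus
decay (τ = 150 s) with a Hill-type negative feedback of ppErk on u, giving a
transient ppErk peak near 1–2 min that decays to < 50% of peak by 600 s; NGF
drives a weaker fast input plus the slow sustained v, holding ppErk > 80% of
peak.  The Mek catalytic constant kcat is 0.15 s⁻¹ (wild type) or 0.015 s⁻¹
(mutant), and totals default to (Raf, Mek, Erk) = (100, 120, 100) units.
Cell-to-cell variability: total Raf/Mek/Erk are drawn N(μ, μ·fd) per cell,
clipped at 0 (at fd = 0.7 about 8% of draws clip); each cell is one stiff
ODE solve (LSODA, rtol 1e-6, atol 1e-9) sampled every 60 s over 600 s, and
an observation is the (pRaf, ppMek, ppErk) triplet at one snapshot time.
Although the injected noise is Gaussian, its propagation through the
saturating cascade yields visibly skewed output clouds, which is what gives
the network-based method its advantage over proximity clustering at high
noise.  This model is a deliberately small stand-in with hand-chosen rates:
it emulates the transient/sustained contrast, expression-noise propagation
and wild-type/mutant contrast of the published full-scale kinetic model, not
its quantitative trajectories; accuracy numbers obtained with it are
expected to differ from published full-model values.  An SBML Level 2 model
can be swapped in via `load_sbml_model` (libsbml + sympy compilation of
kinetic laws; exercised in the tests on a tiny synthetic two-species model).

**GBN mixture generator.**  Ancestral sampling of each component's
linear-Gaussian conditionals in topological order.  The default
two-component condition (d = 3, 200 cells/component) uses a v-structure
(x1→x3←x2, β = ±1.5) against a chain (x1→x2→x3, β = ∓1.5) with a mean shift
of 4 between components and unit conditional variances — i.e. components on
the prior's unit scale, separated both in location and in dependence
structure.  The four-component condition places 150-cell components at the
corners of a side-4 square in the (x1, x2) plane with alternating structures
and weight signs.

## Desk-scale run lengths

Chosen as the package's own reduced defaults for tests and the acceptance
script: two-component recovery 2000 iterations (1000 burn-in, thinning 5;
3000/1500/5 in the acceptance script);
four-component 3000/1500/5; cascade benchmark 1500/750/5 per (noise, time)
cell with 175 cells per stimulus and three snapshot times; exactness checks
≥ 1.2·10⁵ sweeps on n ≤ 4 toys.  At these lengths the two-component
posterior mode of N, consensus pco ≥ 95%, and ASW selection of the true K
are all reproduced.

## Limitations and numerical notes

* The parent-set-cardinality prior is flat over sizes: at d = 3 adding a
  second parent to a one-parent node *raises* the structure prior by a
  factor 2.  Combined with n = 200 observations this keeps the undirected
  pep of a truly absent connection in a chain component around 0.2–0.35
  (verified against the exactly enumerated single-component DAG posterior,
  i.e. independent of MCMC mixing); stronger |β| makes it worse.
  Absent-connection suppression below 0.2 at this sample size would require
  a sparsity-favoring structure prior, which the model deliberately does not
  use.
* Beta-coin eject acceptance rates are low (≈0.5–1%) and collapse entirely
  on tightly fitted components; the anchor-pair split-merge half of the
  default move mixture is what makes desk-scale chains split reliably.
  Four-component problems still need the longer default above.
* Degenerate inputs: n = 0 scores 0 (vacuous likelihood); constant columns
  are left centred-but-unscaled by standardization; a DAG with no valid
  single-edge neighbor (d = 1) proposes the identity.
* Checkpoint/resume is not implemented; reproducibility rests on the seeded
  bit-identical contract plus the run manifest (config, seed, package
  version, data checksum) written next to every CLI output.
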
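"""Trans-dimensional MCMC for mixtures of Gaussian Bayesian networks.

The target is the joint posterior over the allocation vector ``l``, the number
of mixture components ``N`` and one DAG per component,

    p(l, G_1..G_N, N | X)  ∝  prod_h [ L(G_h | X_{I_h}) p(G_h) ]  p_N(l | N)  p(N),

where component-level Gaussian parameters (means, variances, regression
weights) and the mixture weights are integrated out analytically:
``L(G | X)`` is the closed-form BGe marginal likelihood (:mod:`unpbn.gbn`) and
``p_N(l | N)`` the Dirichlet-multinomial allocation probability with symmetric
concentration ``alpha``.  ``p(N)`` is Poisson(lambda) truncated to N >= 1.

One iteration is a sweep of three move phases:

* a Metropolis-Hastings single-edge move (add/delete/reverse) per component,
* a collapsed Gibbs reallocation pass over all observations,
* one eject/absorb proposal changing N (allocation-sampler style: eject splits
  a component by an integrated Beta-Bernoulli coin flip; absorb merges the
  last-labelled component into another).

States never contain empty components: a Gibbs draw that would empty a
component is the (correct) degenerate full conditional that leaves the label
unchanged, and eject proposals producing an empty part are rejected.
All probability arithmetic is on the log scale; categorical draws use a
fixed-order inverse-CDF, so runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import json
import math
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gbn import (
    Dag,
    Dataset,
    FamilyScorer,
    NormalWishartPrior,
    SuffStats,
    apply_edge_op,
    enumerate_dags,
    log_prior_dag,
    single_edge_neighborhood,
)

__all__ = [
    "McmcConfig",
    "MixtureState",
    "Trace",
    "TraceSample",
    "log_posterior",
    "run_mcmc",
    "propose_edge_move",
    "gibbs_reallocate",
    "propose_component_change",
    "dirichlet_multinomial_log",
    "poisson_truncated_logpmf",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McmcConfig:
    """Run-length, prior and move-schedule settings for the sampler.

    ``move_probabilities`` = (edge, gibbs, eject, absorb) weights summing to 1;
    the edge and Gibbs phases run whenever their weight is positive, and the
    per-iteration component move picks eject vs absorb with the normalized
    weight of those two entries.  Paper-scale defaults for run length are
    2.8e6/1.4e6/350 for two-component problems; tests override them.
    """

    n_iterations: int = 2_800_000
    burn_in: int = 1_400_000
    thinning: int = 350
    seed: int = 0
    alpha: float = 1.0
    lambda_poisson: float = 1.0
    move_probabilities: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    beta_split_a: float = 1.0
    split_proposal: str = "mixed"  # "beta" | "rgibbs" | "mixed"
    dag_enum_limit: int = 4
    max_parents: int | None = None
    prior_only: bool = False  # constant likelihood (empty-data scoring): samples the prior

    def validate(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.lambda_poisson <= 0:
            raise ValueError("lambda_poisson must be positive")
        mp = self.move_probabilities
        if len(mp) != 4 or any(w < 0 for w in mp) or abs(sum(mp) - 1.0) > 1e-9:
            raise ValueError("move_probabilities must be 4 non-negative weights summing to 1")
        if mp[2] + mp[3] <= 0:
            raise ValueError("eject/absorb weights must not both be zero")
        if self.beta_split_a <= 0:
            raise ValueError("beta_split_a must be positive")
        if self.split_proposal not in ("beta", "rgibbs", "mixed"):
            raise ValueError("split_proposal must be 'beta', 'rgibbs' or 'mixed'")


@dataclass
class MixtureState:
    """One point of the chain: labels in 1..N plus one DAG per component."""

    n_components: int
    allocation: np.ndarray  # length n, values in 1..N
    dags: tuple[Dag, ...]

    def __post_init__(self):
        self.allocation = np.asarray(self.allocation, dtype=np.int64)
        self.dags = tuple(self.dags)
        self.validate()

    def validate(self) -> None:
        N = self.n_components
        if len(self.dags) != N:
            raise ValueError("number of dags must equal n_components")
        if self.allocation.size:
            counts = np.bincount(self.allocation, minlength=N + 1)[1:]
            if self.allocation.min() < 1 or self.allocation.max() > N:
                raise ValueError("allocation labels must lie in 1..N")
            if np.any(counts == 0):
                raise ValueError("every component must have at least one member")

    @property
    def component_sizes(self) -> np.ndarray:
        return np.bincount(self.allocation, minlength=self.n_components + 1)[1:]

    def members(self, h: int) -> np.ndarray:
        """0-based row indices allocated to component ``h`` (1-based)."""
        return np.flatnonzero(self.allocation == h)


@dataclass(frozen=True)
class TraceSample:
    iteration: int
    n_components: int
    allocation: np.ndarray
    dags: tuple[Dag, ...]


@dataclass
class Trace:
    """Retained (post burn-in, thinned) samples plus provenance."""

    samples: list[TraceSample]
    config: McmcConfig
    variable_names: list[str]
    data_checksum: str
    acceptance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n(self) -> int:
        return self.samples[0].allocation.size if self.samples else 0

    @property
    def d(self) -> int:
        return len(self.variable_names)

    def n_components_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.samples:
            out[s.n_components] = out.get(s.n_components, 0) + 1
        return out

    def posterior_mode_n(self) -> int:
        counts = self.n_components_counts()
        best = max(counts.values())
        return min(k for k, v in counts.items() if v == best)

    # -- serialization ------------------------------------------------------

    def save(self, samples_path, manifest_path=None) -> None:
        """JSON-lines record per retained sample plus an optional run manifest."""
        with open(samples_path, "w") as fh:
            for s in self.samples:
                fh.write(
                    json.dumps(
                        {
                            "iteration": s.iteration,
                            "n_components": s.n_components,
                            "allocation": s.allocation.tolist(),
                            "dags": [d.adjacency.tolist() for d in s.dags],
                        }
                    )
                    + "\n"
                )
        if manifest_path is not None:
            from dataclasses import asdict

            with open(manifest_path, "w") as fh:
                json.dump(
                    {
                        "config": asdict(self.config),
                        "variable_names": self.variable_names,
                        "data_checksum": self.data_checksum,
                        "n_samples": len(self.samples),
                        "acceptance": self.acceptance,
                    },
                    fh,
                    indent=2,
                )

    @classmethod
    def load(cls, samples_path, manifest_path=None) -> "Trace":
        samples = []
        with open(samples_path) as fh:
            for line in fh:
                rec = json.loads(line)
                samples.append(
                    TraceSample(
                        iteration=rec["iteration"],
                        n_components=rec["n_components"],
                        allocation=np.asarray(rec["allocation"], dtype=np.int64),
                        dags=tuple(Dag(np.asarray(a, dtype=np.int8)) for a in rec["dags"]),
                    )
                )
        config = McmcConfig()
        names: list[str] = []
        checksum = ""
        if manifest_path is not None:
            with open(manifest_path) as fh:
                man = json.load(fh)
            cfg = dict(man["config"])
            cfg["move_probabilities"] = tuple(cfg["move_probabilities"])
            config = McmcConfig(**cfg)
            names = man["variable_names"]
            checksum = man["data_checksum"]
        if not names and samples:
            d = len(samples[0].dags[0].adjacency)
            names = [f"x{j+1}" for j in range(d)]
        return cls(samples, config, names, checksum)


# ---------------------------------------------------------------------------
# prior pieces
# ---------------------------------------------------------------------------


def dirichlet_multinomial_log(counts: Sequence[int], alpha: float) -> float:
    """log p_N(l | N) of one labelled allocation vector with component counts
    ``counts`` (length N), mixture weights integrated out against a symmetric
    Dirichlet(alpha) prior:

        Gamma(N a) / Gamma(n + N a) * prod_h Gamma(n_h + a) / Gamma(a).
    """
    counts = np.asarray(counts)
    N = counts.size
    n = int(counts.sum())
    out = math.lgamma(N * alpha) - math.lgamma(n + N * alpha)
    for c in counts:
        out += math.lgamma(c + alpha) - math.lgamma(alpha)
    return out


def poisson_truncated_logpmf(N: int, lam: float) -> float:
    """Poisson(lam) prior on the number of components, truncated to N >= 1."""
    if N < 1:
        return -math.inf
    return (
        N * math.log(lam) - lam - math.lgamma(N + 1) - math.log1p(-math.exp(-lam))
    )


def log_posterior(
    state: MixtureState,
    data: Dataset,
    prior: NormalWishartPrior | None = None,
    config: McmcConfig | None = None,
) -> float:
    """Unnormalized log posterior of a mixture state (per-component BGe score
    and structure prior, Dirichlet-multinomial allocation term, truncated
    Poisson on N)."""
    config = config or McmcConfig()
    scorer = FamilyScorer(data.d, prior or NormalWishartPrior())
    state.validate()
    total = 0.0
    for h in range(1, state.n_components + 1):
        rows = data.values[state.members(h)]
        if rows.shape[0] == 0:
            raise ValueError(f"component {h} is empty")
        stats = SuffStats.from_rows(rows)
        total += scorer.dag_logml(stats, state.dags[h - 1])
        total += log_prior_dag(state.dags[h - 1])
    total += dirichlet_multinomial_log(state.component_sizes, config.alpha)
    total += poisson_truncated_logpmf(state.n_components, config.lambda_poisson)
    return total


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _NullScorer:
    """Scores every family as 0 — equivalent to scoring against empty data, so
    the chain targets the (l, G, N) prior alone."""

    def family_score(self, stats, node, parents) -> float:
        return 0.0

    def dag_logml(self, stats, dag) -> float:
        return 0.0


_NBHD_CACHE: dict[tuple[bytes, int], list] = {}


def _neighborhood(dag: Dag, cap: int | None):
    key = (dag._key, -1 if cap is None else cap)
    nb = _NBHD_CACHE.get(key)
    if nb is None:
        nb = single_edge_neighborhood(dag, cap)
        if len(_NBHD_CACHE) > 100_000:
            _NBHD_CACHE.clear()
        _NBHD_CACHE[key] = nb
    return nb


class _Component:
    """Per-component book-keeping: sufficient statistics, DAG, cached scores."""

    __slots__ = ("stats", "dag", "logml", "fam_cache")

    def __init__(self, stats: SuffStats, dag: Dag, scorer: FamilyScorer):
        self.stats = stats
        self.dag = dag
        self.fam_cache: dict = {}
        self.logml = scorer.dag_logml(stats, dag)

    def refresh(self, scorer: FamilyScorer) -> None:
        self.fam_cache.clear()
        self.logml = scorer.dag_logml(self.stats, self.dag)

    def family(self, scorer: FamilyScorer, j: int, parents: tuple[int, ...]) -> float:
        key = (j, parents)
        v = self.fam_cache.get(key)
        if v is None:
            v = scorer.family_score(self.stats, j, parents)
            self.fam_cache[key] = v
        return v


class Sampler:
    """Mutable sampler over (labels, per-component DAGs, N).

    Labels are held 0-based internally; public :class:`MixtureState` objects
    use the 1-based convention.
    """

    def __init__(
        self,
        data: Dataset,
        prior: NormalWishartPrior | None = None,
        config: McmcConfig | None = None,
        rng: np.random.Generator | None = None,
    ):
        config = config or McmcConfig()
        config.validate()
        if data.n < 1:
            raise ValueError("need at least one observation")
        self.data = data
        self.X = data.values
        self.d = data.d
        self.config = config
        self.prior = (prior or NormalWishartPrior()).resolved(self.d)
        self.scorer = (
            _NullScorer() if config.prior_only else FamilyScorer(self.d, self.prior)
        )
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.cap = config.max_parents
        self._log_prior_cache: dict[bytes, float] = {}
        if self.d <= config.dag_enum_limit:
            self._dag_pool = enumerate_dags(self.d, self.cap)
            self._log_q_dag = -math.log(len(self._dag_pool))
        else:
            self._dag_pool = None
            self._log_q_dag = 0.0  # copy-parent proposal
        # neutral start: one component, empty DAG
        self.labels = np.zeros(data.n, dtype=np.int64)
        self.comps: list[_Component] = [
            _Component(SuffStats.from_rows(self.X), Dag.empty(self.d), self.scorer)
        ]
        self.sizes = [data.n]
        self.accept_counts = {
            "edge": [0, 0],
            "gibbs_moved": [0, 0],
            "eject": [0, 0],
            "absorb": [0, 0],
            "split": [0, 0],
            "merge": [0, 0],
        }

    # -- helpers ------------------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.comps)

    def _lp_dag(self, dag: Dag) -> float:
        v = self._log_prior_cache.get(dag._key)
        if v is None:
            v = log_prior_dag(dag)
            self._log_prior_cache[dag._key] = v
        return v

    def state(self) -> MixtureState:
        return MixtureState(
            n_components=self.N,
            allocation=self.labels + 1,
            dags=tuple(c.dag for c in self.comps),
        )

    def set_state(self, state: MixtureState) -> None:
        state.validate()
        if state.allocation.size != self.X.shape[0]:
            raise ValueError("state allocation length does not match data")
        self.labels = state.allocation.astype(np.int64) - 1
        self.comps = []
        self.sizes = []
        for h in range(state.n_components):
            rows = self.X[self.labels == h]
            self.comps.append(_Component(SuffStats.from_rows(rows), state.dags[h], self.scorer))
            self.sizes.append(rows.shape[0])

    def _categorical(self, logw: np.ndarray) -> int:
        """Inverse-CDF draw with fixed summation order (seed-reproducible)."""
        w = np.exp(logw - logw.max())
        cdf = np.cumsum(w)
        u = self.rng.random() * cdf[-1]
        return int(np.searchsorted(cdf, u, side="right").clip(0, w.size - 1))

    # -- move 1: single-edge structure moves --------------------------------

    def edge_move(self, h: int) -> bool:
        comp = self.comps[h]
        nb = _neighborhood(comp.dag, self.cap)
        if not nb:
            return False
        op = nb[self.rng.integers(len(nb))]
        new_dag = apply_edge_op(comp.dag, op)
        kind, i, j = op
        changed = (j,) if kind in ("add", "delete") else (i, j)
        delta = 0.0
        for node in changed:
            delta += comp.family(self.scorer, node, new_dag.parent_sets[node])
            delta -= comp.family(self.scorer, node, comp.dag.parent_sets[node])
        delta += self._lp_dag(new_dag) - self._lp_dag(comp.dag)
        delta += math.log(len(nb)) - math.log(len(_neighborhood(new_dag, self.cap)))
        self.accept_counts["edge"][1] += 1
        if delta >= 0 or self.rng.random() < math.exp(delta):
            # family scores of unchanged nodes stay valid in the cache
            old_fams = comp.dag.parent_sets
            comp.logml += sum(
                comp.family(self.scorer, node, new_dag.parent_sets[node])
                - comp.family(self.scorer, node, old_fams[node])
                for node in changed
            )
            comp.dag = new_dag
            self.accept_counts["edge"][0] += 1
            return True
        return False

    # -- move 2: collapsed Gibbs reallocation -------------------------------

    def gibbs_pass(self, order: np.ndarray | None = None) -> int:
        if order is None:
            order = self.rng.permutation(self.X.shape[0])
        moved = 0
        alpha = self.config.alpha
        for i in order:
            moved += self._gibbs_one(int(i), alpha)
        return moved

    def _gibbs_one(self, i: int, alpha: float) -> int:
        c = int(self.labels[i])
        if self.sizes[c] == 1:
            # removing i would empty its component: the full conditional puts
            # all mass on the current label under the no-empty-components policy
            return 0
        x = self.X[i]
        N = self.N
        comp_c = self.comps[c]
        stats_minus = comp_c.stats.remove(x)
        logml_minus = self.scorer.dag_logml(stats_minus, comp_c.dag)
        logw = np.empty(N)
        for h in range(N):
            if h == c:
                pred = comp_c.logml - logml_minus
                m = self.sizes[c] - 1
            else:
                comp = self.comps[h]
                pred = self.scorer.dag_logml(comp.stats.add(x), comp.dag) - comp.logml
                m = self.sizes[h]
            logw[h] = math.log(m + alpha) + pred
        hstar = self._categorical(logw)
        self.accept_counts["gibbs_moved"][1] += 1
        if hstar == c:
            return 0
        comp_h = self.comps[hstar]
        new_stats = comp_h.stats.add(x)
        new_logml = self.scorer.dag_logml(new_stats, comp_h.dag)
        comp_c.stats = stats_minus
        comp_c.logml = logml_minus
        comp_c.fam_cache.clear()
        comp_h.stats = new_stats
        comp_h.logml = new_logml
        comp_h.fam_cache.clear()
        self.sizes[c] -= 1
        self.sizes[hstar] += 1
        self.labels[i] = hstar
        self.accept_counts["gibbs_moved"][0] += 1
        return 1

    # -- move 3: eject / absorb ---------------------------------------------

    def _log_split(self, n_a: int, n_b: int) -> float:
        """Marginal probability of a particular two-way member assignment under
        i.i.d. Bernoulli(p) flips with p ~ Beta(a, a) integrated out."""
        a = self.config.beta_split_a
        return (
            math.lgamma(n_a + a)
            + math.lgamma(n_b + a)
            - math.lgamma(n_a + n_b + 2 * a)
            - (2 * math.lgamma(a) - math.lgamma(2 * a))
        )

    def _dm_delta(self, old_sizes: list[int], new_sizes: list[int]) -> float:
        alpha = self.config.alpha
        return dirichlet_multinomial_log(new_sizes, alpha) - dirichlet_multinomial_log(
            old_sizes, alpha
        )

    def _pe_pa(self) -> tuple[float, float]:
        we, wa = self.config.move_probabilities[2], self.config.move_probabilities[3]
        tot = we + wa
        return we / tot, wa / tot

    def component_move(self, apply: bool = True) -> tuple[bool, float]:
        """One dimension-changing proposal.  Returns (changed, log acceptance
        term); with ``apply=False`` the proposal is evaluated but never applied.

        Depending on ``split_proposal`` this is the Beta-coin eject/absorb
        pair, the anchor-pair split-merge with a restricted-Gibbs final scan,
        or an even mixture of the two (the default): the Beta pair proposes
        cheap unstructured changes, the split-merge pair proposes
        cluster-respecting splits that remain viable when a component's fitted
        density is tight.
        """
        mode = self.config.split_proposal
        if mode == "mixed":
            mode = "beta" if self.rng.random() < 0.5 else "rgibbs"
        if mode == "rgibbs":
            return self._split_merge(apply)
        pe, pa = self._pe_pa()
        if self.rng.random() < pe:
            return self._eject(pe, pa, apply)
        return self._absorb(pe, pa, apply)

    # -- anchor-pair split-merge (restricted-Gibbs final scan) ---------------
    #
    # An ordered pair of distinct observations (i1, i2) is drawn uniformly —
    # a state-independent choice, so each per-pair kernel is itself a valid
    # Metropolis-Hastings kernel and no summation over anchor paths is needed.
    # Same component: propose a split (i1 anchors the part keeping the label
    # and DAG, i2 anchors a new last-labelled part with a freshly proposed
    # DAG); members are pre-assigned to the nearer anchor (deterministic
    # launch) and one restricted Gibbs scan in fixed index order generates the
    # final assignment, whose sequential probability is the proposal density.
    # Different components: propose the merge of i2's component into i1's,
    # available only when i2's component carries the last label (the exact
    # reverse of a split); its acceptance evaluates the same launch-and-scan
    # density at the current assignment.

    def _restricted_scan(
        self,
        others: np.ndarray,
        sides: np.ndarray,
        stats_a: SuffStats,
        stats_b: SuffStats,
        dag_a: Dag,
        dag_b: Dag,
        target: np.ndarray | None,
    ) -> tuple[np.ndarray, SuffStats, SuffStats, float]:
        """One sequential restricted-Gibbs pass over ``others``.

        ``sides`` is the current boolean assignment (True = part B) and is
        updated in place conceptually; with ``target`` given, the scan follows
        it instead of sampling and returns its log probability.
        """
        alpha = self.config.alpha
        logq = 0.0
        n_a = 1 + int((~sides).sum())  # anchors included
        n_b = 1 + int(sides.sum())
        sides = sides.copy()
        for t, o in enumerate(others):
            x = self.X[o]
            if sides[t]:
                stats_b = stats_b.remove(x)
                n_b -= 1
            else:
                stats_a = stats_a.remove(x)
                n_a -= 1
            la = math.log(n_a + alpha) + self.scorer.dag_logml(
                stats_a.add(x), dag_a
            ) - self.scorer.dag_logml(stats_a, dag_a)
            lb = math.log(n_b + alpha) + self.scorer.dag_logml(
                stats_b.add(x), dag_b
            ) - self.scorer.dag_logml(stats_b, dag_b)
            lz = np.logaddexp(la, lb)
            log_pb = lb - lz
            log_pa = la - lz
            if target is None:
                go_b = self.rng.random() < math.exp(log_pb)
            else:
                go_b = bool(target[t])
            # evaluating a (numerically) probability-zero assignment gives
            # logq = -inf, i.e. certain rejection, not an error
            logq += log_pb if go_b else log_pa
            if go_b:
                stats_b = stats_b.add(x)
                n_b += 1
            else:
                stats_a = stats_a.add(x)
                n_a += 1
            sides[t] = go_b
        return sides, stats_a, stats_b, logq

    def _launch_sides(self, others: np.ndarray, i1: int, i2: int) -> np.ndarray:
        """Deterministic launch: each member joins the nearer anchor (B on ties)."""
        if others.size == 0:
            return np.zeros(0, dtype=bool)
        da = np.linalg.norm(self.X[others] - self.X[i1], axis=1)
        db = np.linalg.norm(self.X[others] - self.X[i2], axis=1)
        return db <= da

    def _split_merge(self, apply: bool = True) -> tuple[bool, float]:
        n = self.X.shape[0]
        if n < 2:
            return False, 0.0
        i1 = int(self.rng.integers(n))
        i2 = int(self.rng.integers(n - 1))
        if i2 >= i1:
            i2 += 1
        c1, c2 = int(self.labels[i1]), int(self.labels[i2])
        if c1 == c2:
            return self._split_rg(i1, i2, apply)
        return self._merge_rg(i1, i2, apply)

    def _split_rg(self, i1: int, i2: int, apply: bool) -> tuple[bool, float]:
        self.accept_counts["split"][1] += 1
        N = self.N
        c = int(self.labels[i1])
        comp = self.comps[c]
        members = np.flatnonzero(self.labels == c)
        others = members[(members != i1) & (members != i2)]
        if self._dag_pool is not None:
            dag_b = self._dag_pool[int(self.rng.integers(len(self._dag_pool)))]
            log_q_dag = self._log_q_dag
        else:
            dag_b = comp.dag
            log_q_dag = 0.0
        dag_a = comp.dag
        sides0 = self._launch_sides(others, i1, i2)
        stats_a = SuffStats.from_rows(self.X[[i1], :])
        stats_b = SuffStats.from_rows(self.X[[i2], :])
        for t, o in enumerate(others):
            if sides0[t]:
                stats_b = stats_b.add(self.X[o])
            else:
                stats_a = stats_a.add(self.X[o])
        sides, stats_a, stats_b, logq = self._restricted_scan(
            others, sides0, stats_a, stats_b, dag_a, dag_b, target=None
        )
        n_b = 1 + int(sides.sum())
        n_a = 1 + (others.size - int(sides.sum()))
        logml_a = self.scorer.dag_logml(stats_a, dag_a)
        logml_b = self.scorer.dag_logml(stats_b, dag_b)
        old_sizes = list(self.sizes)
        new_sizes = list(self.sizes)
        new_sizes[c] = n_a
        new_sizes.append(n_b)
        lam = self.config.lambda_poisson
        delta_post = (
            logml_a
            + logml_b
            - comp.logml
            + self._lp_dag(dag_b)
            + self._dm_delta(old_sizes, new_sizes)
            + (math.log(lam) - math.log(N + 1))
        )
        # reverse merge (same anchor pair) is deterministic: q_r = 1
        log_alpha = delta_post - logq - log_q_dag
        if apply and (
            log_alpha >= 0 or self.rng.random() < math.exp(log_alpha)
        ):
            move_b = others[sides]
            self.labels[move_b] = N
            self.labels[i2] = N
            comp.stats = stats_a
            comp.logml = logml_a
            comp.fam_cache.clear()
            newc = _Component.__new__(_Component)
            newc.stats = stats_b
            newc.dag = dag_b
            newc.fam_cache = {}
            newc.logml = logml_b
            self.comps.append(newc)
            self.sizes[c] = n_a
            self.sizes.append(n_b)
            self.accept_counts["split"][0] += 1
            return True, log_alpha
        return False, log_alpha

    def _merge_rg(self, i1: int, i2: int, apply: bool) -> tuple[bool, float]:
        self.accept_counts["merge"][1] += 1
        N = self.N
        c1, c2 = int(self.labels[i1]), int(self.labels[i2])
        if c2 != N - 1 or c1 == N - 1:
            return False, 0.0  # only the last label can be absorbed; skipped
        comp_a, comp_b = self.comps[c1], self.comps[c2]
        members_a = np.flatnonzero(self.labels == c1)
        members_b = np.flatnonzero(self.labels == c2)
        merged_members = np.sort(np.concatenate([members_a, members_b]))
        others = merged_members[(merged_members != i1) & (merged_members != i2)]
        actual_b = np.isin(others, members_b)
        # evaluate the reverse split: deterministic launch + one scan at the
        # actual assignment
        sides0 = self._launch_sides(others, i1, i2)
        stats_a = SuffStats.from_rows(self.X[[i1], :])
        stats_b = SuffStats.from_rows(self.X[[i2], :])
        for t, o in enumerate(others):
            if sides0[t]:
                stats_b = stats_b.add(self.X[o])
            else:
                stats_a = stats_a.add(self.X[o])
        _, _, _, logq = self._restricted_scan(
            others, sides0, stats_a, stats_b, comp_a.dag, comp_b.dag,
            target=actual_b,
        )
        if self._dag_pool is not None:
            log_q_dag = self._log_q_dag
        else:
            log_q_dag = 0.0 if comp_b.dag == comp_a.dag else -math.inf
        merged = comp_a.stats.merge(comp_b.stats)
        logml_m = self.scorer.dag_logml(merged, comp_a.dag)
        old_sizes = list(self.sizes)
        new_sizes = old_sizes[: N - 1]
        new_sizes[c1] = old_sizes[c1] + old_sizes[N - 1]
        lam = self.config.lambda_poisson
        delta_post = (
            logml_m
            - comp_a.logml
            - comp_b.logml
            - self._lp_dag(comp_b.dag)
            + self._dm_delta(old_sizes, new_sizes)
            + (math.log(N) - math.log(lam))
        )
        log_alpha = delta_post + logq + log_q_dag
        if apply and (
            log_alpha >= 0
            or (math.isfinite(log_alpha) and self.rng.random() < math.exp(log_alpha))
        ):
            self.labels[self.labels == N - 1] = c1
            comp_a.stats = merged
            comp_a.logml = logml_m
            comp_a.fam_cache.clear()
            self.comps.pop()
            self.sizes[c1] = new_sizes[c1]
            self.sizes.pop()
            self.accept_counts["merge"][0] += 1
            return True, log_alpha
        return False, log_alpha

    def _eject(self, pe: float, pa: float, apply: bool = True) -> tuple[bool, float]:
        self.accept_counts["eject"][1] += 1
        N = self.N
        h = int(self.rng.integers(N))
        members = np.flatnonzero(self.labels == h)
        n_h = members.size
        p = self.rng.beta(self.config.beta_split_a, self.config.beta_split_a)
        go = self.rng.random(n_h) < p
        n_b = int(go.sum())
        n_a = n_h - n_b
        if n_a == 0 or n_b == 0:
            return False, -math.inf
        if self._dag_pool is not None:
            new_dag = self._dag_pool[int(self.rng.integers(len(self._dag_pool)))]
        else:
            new_dag = self.comps[h].dag
        rows_b = self.X[members[go]]
        stats_b = SuffStats.from_rows(rows_b)
        comp_h = self.comps[h]
        stats_a = SuffStats(
            comp_h.stats.n - stats_b.n,
            comp_h.stats.s - stats_b.s,
            comp_h.stats.M - stats_b.M,
        )
        logml_a = self.scorer.dag_logml(stats_a, comp_h.dag)
        logml_b = self.scorer.dag_logml(stats_b, new_dag)
        old_sizes = list(self.sizes)
        new_sizes = list(self.sizes)
        new_sizes[h] = n_a
        new_sizes.append(n_b)
        lam = self.config.lambda_poisson
        delta_post = (
            logml_a
            + logml_b
            - comp_h.logml
            + self._lp_dag(new_dag)
            + self._dm_delta(old_sizes, new_sizes)
            + (math.log(lam) - math.log(N + 1))  # p(N+1)/p(N), truncation cancels
        )
        log_q_dag = self._log_q_dag if self._dag_pool is not None else 0.0
        log_alpha = (
            delta_post
            + math.log(pa)
            - math.log(pe)
            - self._log_split(n_a, n_b)
            - log_q_dag
        )
        if apply and (log_alpha >= 0 or self.rng.random() < math.exp(log_alpha)):
            self.labels[members[go]] = N
            comp_h.stats = stats_a
            comp_h.logml = logml_a
            comp_h.fam_cache.clear()
            self.comps.append(_Component(stats_b, new_dag, self.scorer))
            self.comps[-1].logml = logml_b
            self.sizes[h] = n_a
            self.sizes.append(n_b)
            self.accept_counts["eject"][0] += 1
            return True, log_alpha
        return False, log_alpha

    def _absorb(self, pe: float, pa: float, apply: bool = True) -> tuple[bool, float]:
        self.accept_counts["absorb"][1] += 1
        N = self.N
        if N < 2:
            return False, 0.0  # move unavailable; skipped, counted as rejected
        j = int(self.rng.integers(N - 1))  # keeper among labels 0..N-2
        last = N - 1
        comp_j, comp_l = self.comps[j], self.comps[last]
        merged = comp_j.stats.merge(comp_l.stats)
        logml_m = self.scorer.dag_logml(merged, comp_j.dag)
        old_sizes = list(self.sizes)
        new_sizes = old_sizes[:last]
        new_sizes[j] = old_sizes[j] + old_sizes[last]
        lam = self.config.lambda_poisson
        delta_post = (
            logml_m
            - comp_j.logml
            - comp_l.logml
            - self._lp_dag(comp_l.dag)
            + self._dm_delta(old_sizes, new_sizes)
            + (math.log(N) - math.log(lam))  # p(N-1)/p(N)
        )
        if self._dag_pool is not None:
            log_q_dag_rev = self._log_q_dag
        else:
            # reverse eject copies the keeper's DAG
            log_q_dag_rev = 0.0 if comp_l.dag == comp_j.dag else -math.inf
        log_alpha = (
            delta_post
            + math.log(pe)
            - math.log(pa)
            + self._log_split(old_sizes[j], old_sizes[last])
            + log_q_dag_rev
        )
        if apply and (
            log_alpha >= 0
            or (math.isfinite(log_alpha) and self.rng.random() < math.exp(log_alpha))
        ):
            self.labels[self.labels == last] = j
            comp_j.stats = merged
            comp_j.logml = logml_m
            comp_j.fam_cache.clear()
            self.comps.pop()
            self.sizes[j] = new_sizes[j]
            self.sizes.pop()
            self.accept_counts["absorb"][0] += 1
            return True, log_alpha
        return False, log_alpha

    # -- full sweep and run --------------------------------------------------

    def label_swap(self) -> None:
        """Swap the labels of two uniformly chosen components.

        The proposal is symmetric and the posterior is label-exchangeable, so
        the move is always accepted.  It exists because absorb/merge may only
        remove the *last* label: without swaps a component buried under a
        later-created one could never rotate into the removable slot.
        """
        N = self.N
        if N < 2:
            return
        a = int(self.rng.integers(N))
        b = int(self.rng.integers(N - 1))
        if b >= a:
            b += 1
        mask_a = self.labels == a
        self.labels[self.labels == b] = a
        self.labels[mask_a] = b
        self.comps[a], self.comps[b] = self.comps[b], self.comps[a]
        self.sizes[a], self.sizes[b] = self.sizes[b], self.sizes[a]

    def sweep(self) -> None:
        mp = self.config.move_probabilities
        if mp[0] > 0:
            for h in range(self.N):
                self.edge_move(h)
        if mp[1] > 0:
            self.gibbs_pass()
        self.component_move()
        self.label_swap()

    def run(self) -> Trace:
        cfg = self.config
        samples: list[TraceSample] = []
        report = max(1, cfg.n_iterations // 10)
        for t in range(1, cfg.n_iterations + 1):
            self.sweep()
            if t > cfg.burn_in and (t - cfg.burn_in) % cfg.thinning == 0:
                samples.append(
                    TraceSample(
                        iteration=t,
                        n_components=self.N,
                        allocation=self.labels.copy() + 1,
                        dags=tuple(c.dag for c in self.comps),
                    )
                )
            if t % report == 0:
                logger.info(
                    "iteration %d/%d: N=%d, acceptance=%s",
                    t,
                    cfg.n_iterations,
                    self.N,
                    self.acceptance_rates(),
                )
        return Trace(
            samples=samples,
            config=cfg,
            variable_names=self.data.variable_names,
            data_checksum=self.data.checksum(),
            acceptance=self.acceptance_rates(),
        )

    def acceptance_rates(self) -> dict:
        return {
            k: (v[0] / v[1] if v[1] else float("nan"))
            for k, v in self.accept_counts.items()
        }


# ---------------------------------------------------------------------------
# spec-level operation wrappers
# ---------------------------------------------------------------------------


def run_mcmc(
    data: Dataset,
    prior: NormalWishartPrior | None = None,
    config: McmcConfig | None = None,
) -> Trace:
    """Run the full UNPBN chain and return the retained trace.

    Identical data, prior, config (and hence seed) give bit-identical traces.
    """
    config = config or McmcConfig()
    config.validate()
    return Sampler(data, prior, config).run()


def _sampler_for(state, data, prior, config, rng) -> Sampler:
    config = config or McmcConfig()
    s = Sampler(data, prior, config, rng=rng)
    s.set_state(state)
    return s


def propose_edge_move(
    state: MixtureState,
    component: int,
    data: Dataset,
    prior: NormalWishartPrior | None = None,
    config: McmcConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MixtureState, float]:
    """Propose (without accepting) one single-edge operation on the DAG of
    ``component`` (1-based).  Returns the proposed state and the log proposal
    ratio log q(reverse)/q(forward) (neighborhood-size asymmetry); a DAG with
    no valid neighbor proposes the identity with log ratio 0."""
    if not (1 <= component <= state.n_components):
        raise ValueError("component index out of range")
    rng = rng if rng is not None else np.random.default_rng(0)
    cfg = config or McmcConfig()
    dag = state.dags[component - 1]
    nb = single_edge_neighborhood(dag, cfg.max_parents)
    if not nb:
        return state, 0.0
    op = nb[int(rng.integers(len(nb)))]
    new_dag = apply_edge_op(dag, op)
    nb_new = single_edge_neighborhood(new_dag, cfg.max_parents)
    dags = list(state.dags)
    dags[component - 1] = new_dag
    new_state = MixtureState(state.n_components, state.allocation.copy(), tuple(dags))
    return new_state, math.log(len(nb)) - math.log(len(nb_new))


def gibbs_reallocate(
    state: MixtureState,
    data: Dataset,
    observation: int,
    prior: NormalWishartPrior | None = None,
    config: McmcConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MixtureState:
    """One collapsed-Gibbs update of the label of ``observation`` (0-based)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    s = _sampler_for(state, data, prior, config, rng)
    s._gibbs_one(int(observation), s.config.alpha)
    return s.state()


def gibbs_full_conditional(
    state: MixtureState,
    data: Dataset,
    observation: int,
    prior: NormalWishartPrior | None = None,
    config: McmcConfig | None = None,
) -> np.ndarray:
    """Normalized full-conditional reallocation probabilities of one observation
    over the current components (useful for validation)."""
    s = _sampler_for(state, data, prior, config, np.random.default_rng(0))
    i = int(observation)
    c = int(s.labels[i])
    if s.sizes[c] == 1:
        out = np.zeros(s.N)
        out[c] = 1.0
        return out
    x = s.X[i]
    alpha = s.config.alpha
    comp_c = s.comps[c]
    stats_minus = comp_c.stats.remove(x)
    logml_minus = s.scorer.dag_logml(stats_minus, comp_c.dag)
    logw = np.empty(s.N)
    for h in range(s.N):
        if h == c:
            pred = comp_c.logml - logml_minus
            m = s.sizes[c] - 1
        else:
            comp = s.comps[h]
            pred = s.scorer.dag_logml(comp.stats.add(x), comp.dag) - comp.logml
            m = s.sizes[h]
        logw[h] = math.log(m + alpha) + pred
    w = np.exp(logw - logw.max())
    return w / w.sum()


def propose_component_change(
    state: MixtureState,
    data: Dataset,
    prior: NormalWishartPrior | None = None,
    config: McmcConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MixtureState, float]:
    """One eject/absorb proposal applied with its Metropolis-Hastings accept
    step; returns the (possibly unchanged) state and the move's log acceptance
    term (0 for an identity outcome such as an unavailable absorb)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    s = _sampler_for(state, data, prior, config, rng)
    before = s.state()
    _, log_alpha = s.component_move()
    after = s.state()
    if (
        after.n_components == before.n_components
        and np.array_equal(after.allocation, before.allocation)
        and after.dags == before.dags
        and not math.isfinite(log_alpha)
    ):
        return before, 0.0
    return after, log_alpha
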
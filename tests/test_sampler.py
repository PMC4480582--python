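"""Sampler correctness: posterior pieces, moves, determinism, prior sampling."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from unpbn.gbn import (
    Dag,
    Dataset,
    FamilyScorer,
    NormalWishartPrior,
    SuffStats,
    enumerate_dags,
    log_prior_dag,
)
from unpbn.sampler import (
    McmcConfig,
    MixtureState,
    Sampler,
    Trace,
    dirichlet_multinomial_log,
    gibbs_full_conditional,
    gibbs_reallocate,
    log_posterior,
    poisson_truncated_logpmf,
    propose_component_change,
    propose_edge_move,
    run_mcmc,
)

from conftest import set_partitions


def enumerate_partition_posterior(X: np.ndarray, alpha=1.0, lam=1.0):
    """Exhaustive posterior over set partitions for d=1 (single, empty DAG)."""
    n, d = X.shape
    sc = FamilyScorer(d, NormalWishartPrior())
    dag = Dag.empty(d)
    out = {}
    for part in set_partitions(list(range(n))):
        N = len(part)
        lp = dirichlet_multinomial_log([len(b) for b in part], alpha)
        lp += poisson_truncated_logpmf(N, lam)
        lp += math.lgamma(N + 1)  # distinct labelings per partition
        for b in part:
            lp += sc.dag_logml(SuffStats.from_rows(X[b]), dag) + log_prior_dag(dag)
        key = frozenset(frozenset(b) for b in part)
        out[key] = np.logaddexp(out.get(key, -np.inf), lp)
    tot = np.logaddexp.reduce(list(out.values()))
    return {k: math.exp(v - tot) for k, v in out.items()}


class TestPriorPieces:
    def test_allocation_term_matches_gamma_evaluation(self):
        # n=4, N=2, m=(2,2), alpha=1:
        # Gamma(2) Gamma(3) Gamma(3) / (Gamma(6) Gamma(1) Gamma(1)) = 1/30
        assert dirichlet_multinomial_log([2, 2], 1.0) == pytest.approx(
            math.log(1 / 30)
        )

    def test_allocation_term_sums_to_one_over_all_vectors(self):
        n, N, alpha = 4, 3, 0.7
        total = 0.0
        for labels in np.ndindex(*(N,) * n):
            counts = np.bincount(labels, minlength=N)
            total += math.exp(dirichlet_multinomial_log(counts, alpha))
        assert total == pytest.approx(1.0)

    def test_truncated_poisson_normalizes(self):
        lam = 1.0
        total = sum(math.exp(poisson_truncated_logpmf(N, lam)) for N in range(1, 60))
        assert total == pytest.approx(1.0)
        assert poisson_truncated_logpmf(0, lam) == -math.inf


class TestLogPosterior:
    def test_single_component_reduces_to_gbn_score(self, small_dataset):
        from unpbn.gbn import log_marginal_likelihood

        dag = Dag.from_edges(2, [(0, 1)])
        state = MixtureState(1, np.ones(small_dataset.n, dtype=int), (dag,))
        lp = log_posterior(state, small_dataset)
        expected = (
            log_marginal_likelihood(small_dataset, dag)
            + log_prior_dag(dag)
            + dirichlet_multinomial_log([small_dataset.n], 1.0)
            + poisson_truncated_logpmf(1, 1.0)
        )
        assert lp == pytest.approx(expected)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        ds = Dataset(rng.normal(size=(8, 2)))
        dags = (Dag.empty(2), Dag.from_edges(2, [(0, 1)]))
        alloc = np.array([1, 1, 1, 2, 2, 2, 1, 2])
        s1 = MixtureState(2, alloc, dags)
        s2 = MixtureState(2, 3 - alloc, dags[::-1])
        assert log_posterior(s1, ds) == pytest.approx(log_posterior(s2, ds))

    def test_component_likelihoods_decompose(self):
        """Changing one component's data changes only that component's term."""
        rng = np.random.default_rng(4)
        base = rng.normal(size=(6, 2))
        ds1 = Dataset(base)
        doubled = np.vstack([base[:3], base[:3], base[3:]])
        ds2 = Dataset(doubled)
        dags = (Dag.empty(2), Dag.empty(2))
        s1 = MixtureState(2, np.array([1, 1, 1, 2, 2, 2]), dags)
        s2 = MixtureState(2, np.array([1, 1, 1, 1, 1, 1, 2, 2, 2]), dags)
        sc = FamilyScorer(2, NormalWishartPrior())
        delta_comp1 = sc.dag_logml(
            SuffStats.from_rows(doubled[:6]), dags[0]
        ) - sc.dag_logml(SuffStats.from_rows(base[:3]), dags[0])
        delta_alloc = dirichlet_multinomial_log([6, 3], 1.0) - dirichlet_multinomial_log(
            [3, 3], 1.0
        )
        assert log_posterior(s2, ds2) - log_posterior(s1, ds1) == pytest.approx(
            delta_comp1 + delta_alloc
        )

    def test_empty_component_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            MixtureState(2, np.ones(small_dataset.n, dtype=int), (Dag.empty(2),) * 2)


class TestEdgeMoveProposal:
    def test_empty_2node_graph_proposes_an_addition(self, small_dataset):
        state = MixtureState(
            1, np.ones(small_dataset.n, dtype=int), (Dag.empty(2),)
        )
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(20):
            new, logq = propose_edge_move(state, 1, small_dataset, rng=rng)
            seen.add(tuple(new.dags[0].edges()))
            assert logq == pytest.approx(math.log(2) - math.log(2))
        assert seen == {((0, 1),), ((1, 0),)}

    def test_single_node_dag_proposes_identity(self):
        ds = Dataset(np.array([[0.1], [0.2]]))
        state = MixtureState(1, np.array([1, 1]), (Dag.empty(1),))
        new, logq = propose_edge_move(state, 1, ds)
        assert new.dags[0] == Dag.empty(1) and logq == 0.0


class TestGibbsReallocation:
    def test_single_component_leaves_allocation_unchanged(self, small_dataset):
        state = MixtureState(1, np.ones(small_dataset.n, dtype=int), (Dag.empty(2),))
        out = gibbs_reallocate(state, small_dataset, observation=2)
        np.testing.assert_array_equal(out.allocation, state.allocation)

    def test_identical_components_give_half_half(self):
        """Duplicated members + same DAG: full conditional is symmetric."""
        rows = np.array([[0.4, -0.2], [1.1, 0.3], [-0.5, 0.8]])
        X = np.vstack([rows, rows, [[0.0, 0.0]]])
        ds = Dataset(X)
        alloc = np.array([1, 1, 1, 2, 2, 2, 1])
        state = MixtureState(2, alloc, (Dag.empty(2),) * 2)
        probs = gibbs_full_conditional(state, ds, observation=6)
        assert probs == pytest.approx([0.5, 0.5])

    def test_full_conditional_matches_direct_marginal_ratio(self):
        """d=1, n=3, N=2: probabilities equal the closed-form ratio of
        component marginal likelihoods times the allocation-prior factor."""
        X = np.array([[-0.7], [0.9], [0.2]])
        ds = Dataset(X)
        state = MixtureState(2, np.array([1, 2, 1]), (Dag.empty(1),) * 2)
        probs = gibbs_full_conditional(state, ds, observation=2)
        sc = FamilyScorer(1, NormalWishartPrior())
        dag = Dag.empty(1)

        def ml(rows):
            return sc.dag_logml(SuffStats.from_rows(np.asarray(rows)), dag)

        # without obs 2: comp1 = {x0}, comp2 = {x1}
        w1 = math.log(1 + 1.0) + (ml([X[0], X[2]]) - ml([X[0]]))
        w2 = math.log(1 + 1.0) + (ml([X[1], X[2]]) - ml([X[1]]))
        Z = np.logaddexp(w1, w2)
        assert probs == pytest.approx([math.exp(w1 - Z), math.exp(w2 - Z)])

    def test_sole_member_cannot_empty_its_component(self):
        X = np.array([[0.0], [5.0], [5.1]])
        state = MixtureState(2, np.array([1, 2, 2]), (Dag.empty(1),) * 2)
        probs = gibbs_full_conditional(state, Dataset(X), observation=0)
        assert probs == pytest.approx([1.0, 0.0])


class TestComponentChange:
    def test_eject_then_inverse_absorb_restores_state(self):
        rng = np.random.default_rng(8)
        ds = Dataset(rng.normal(size=(10, 2)))
        cfg = McmcConfig(n_iterations=10, burn_in=0, thinning=1, seed=0)
        s = Sampler(ds, config=cfg)
        before = s.state()
        # force ejects until one is accepted
        for _ in range(200):
            changed, _ = s._eject(0.5, 0.5)
            if changed:
                break
        assert s.N == 2
        # the exact inverse absorb: keeper 0 absorbs the last component
        labels_before_merge = s.labels.copy()
        changed = False
        for _ in range(500):
            changed, _ = s._absorb(0.5, 0.5)
            if changed:
                break
        assert changed and s.N == 1
        after = s.state()
        assert after.n_components == before.n_components
        np.testing.assert_array_equal(after.allocation, before.allocation)
        assert after.dags == before.dags

    def test_absorb_unavailable_at_single_component(self, small_dataset):
        state = MixtureState(1, np.ones(small_dataset.n, dtype=int), (Dag.empty(2),))
        cfg = McmcConfig(
            n_iterations=10, burn_in=0, thinning=1, seed=1,
            move_probabilities=(0.0, 0.0, 1e-9, 1.0 - 1e-9),  # absorb (almost) surely
            split_proposal="beta",
        )
        new, log_term = propose_component_change(
            state, small_dataset, config=cfg, rng=np.random.default_rng(0)
        )
        assert new.n_components == 1
        assert log_term == 0.0


class TestRunBookkeeping:
    def test_retained_sample_count(self):
        ds = Dataset(np.random.default_rng(0).normal(size=(5, 1)))
        cfg = McmcConfig(n_iterations=10, burn_in=0, thinning=1, seed=2)
        trace = run_mcmc(ds, config=cfg)
        assert len(trace) == 10
        cfg2 = McmcConfig(n_iterations=100, burn_in=40, thinning=7, seed=2)
        assert len(run_mcmc(ds, config=cfg2)) == (100 - 40) // 7

    def test_invalid_config_rejected_before_sampling(self):
        ds = Dataset(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            run_mcmc(ds, config=McmcConfig(n_iterations=10, burn_in=10))
        with pytest.raises(ValueError):
            run_mcmc(ds, config=McmcConfig(alpha=-1.0))
        with pytest.raises(ValueError):
            run_mcmc(
                ds,
                config=McmcConfig(move_probabilities=(0.5, 0.5, 0.0, 0.0)),
            )

    def test_same_seed_bit_identical_traces(self):
        rng = np.random.default_rng(9)
        ds = Dataset(rng.normal(size=(20, 2)))
        cfg = McmcConfig(n_iterations=300, burn_in=100, thinning=4, seed=123)
        t1 = run_mcmc(ds, config=cfg)
        t2 = run_mcmc(ds, config=cfg)
        assert len(t1) == len(t2)
        for a, b in zip(t1.samples, t2.samples):
            assert a.n_components == b.n_components
            np.testing.assert_array_equal(a.allocation, b.allocation)
            assert a.dags == b.dags

    def test_trace_round_trip(self, tmp_path):
        ds = Dataset(np.random.default_rng(1).normal(size=(6, 2)))
        cfg = McmcConfig(n_iterations=50, burn_in=10, thinning=5, seed=3)
        trace = run_mcmc(ds, config=cfg)
        trace.save(tmp_path / "t.jsonl", tmp_path / "m.json")
        back = Trace.load(tmp_path / "t.jsonl", tmp_path / "m.json")
        assert len(back) == len(trace)
        for a, b in zip(trace.samples, back.samples):
            np.testing.assert_array_equal(a.allocation, b.allocation)
            assert a.dags == b.dags
        assert back.config == cfg


class TestStationaryDistribution:
    def test_visit_frequencies_match_enumerated_posterior(self):
        """d=1, n=4: thinned visit frequencies over all 15 set partitions agree
        with the exhaustively enumerated posterior (chi-square at 0.01)."""
        X = np.array([[-1.2], [0.3], [1.5], [0.1]])
        probs = enumerate_partition_posterior(X)
        cfg = McmcConfig(n_iterations=120_000, burn_in=2_000, thinning=10, seed=3)
        s = Sampler(Dataset(X), config=cfg)
        counts: dict = {}
        nrec = 0
        for t in range(1, cfg.n_iterations + 1):
            s.sweep()
            if t > cfg.burn_in and (t - cfg.burn_in) % cfg.thinning == 0:
                key = frozenset(
                    frozenset(np.flatnonzero(s.labels == h).tolist())
                    for h in range(s.N)
                )
                counts[key] = counts.get(key, 0) + 1
                nrec += 1
        keys = list(probs)
        obs = np.array([counts.get(k, 0) for k in keys], float)
        exp = np.array([probs[k] for k in keys]) * nrec
        big = exp >= 5
        obs_p = np.append(obs[big], obs[~big].sum())
        exp_p = np.append(exp[big], exp[~big].sum())
        if exp_p[-1] == 0:
            obs_p, exp_p = obs_p[:-1], exp_p[:-1]
        exp_p *= obs_p.sum() / exp_p.sum()
        _, p = chisquare(obs_p, exp_p)
        assert p > 0.01

    def test_joint_dag_partition_frequencies_match_enumeration_d2(self):
        """d=2, n=3: visit frequencies over joint (partition, per-block DAG)
        states match the exhaustively enumerated posterior, exercising edge
        moves and the uniform-DAG eject proposal together."""
        import itertools

        X = np.array([[-1.0, 0.5], [0.8, -0.2], [0.1, 1.1]])
        n, d = X.shape
        sc = FamilyScorer(d, NormalWishartPrior())
        dags = enumerate_dags(d)
        probs: dict = {}
        for part in set_partitions(list(range(n))):
            N = len(part)
            base = (
                dirichlet_multinomial_log([len(b) for b in part], 1.0)
                + poisson_truncated_logpmf(N, 1.0)
                + math.lgamma(N + 1)
            )
            blocks = [frozenset(b) for b in part]
            for assign in itertools.product(range(len(dags)), repeat=N):
                lp = base
                for b, gi in zip(part, assign):
                    lp += sc.dag_logml(SuffStats.from_rows(X[b]), dags[gi])
                    lp += log_prior_dag(dags[gi])
                key = frozenset(zip(blocks, assign))
                probs[key] = np.logaddexp(probs.get(key, -np.inf), lp)
        tot = np.logaddexp.reduce(list(probs.values()))
        probs = {k: math.exp(v - tot) for k, v in probs.items()}
        dag_index = {g: i for i, g in enumerate(dags)}
        cfg = McmcConfig(n_iterations=150_000, burn_in=5_000, thinning=10, seed=5)
        s = Sampler(Dataset(X), config=cfg)
        counts: dict = {}
        nrec = 0
        for t in range(1, cfg.n_iterations + 1):
            s.sweep()
            if t > cfg.burn_in and (t - cfg.burn_in) % cfg.thinning == 0:
                key = frozenset(
                    (
                        frozenset(np.flatnonzero(s.labels == h).tolist()),
                        dag_index[s.comps[h].dag],
                    )
                    for h in range(s.N)
                )
                counts[key] = counts.get(key, 0) + 1
                nrec += 1
        keys = list(probs)
        obs = np.array([counts.get(k, 0) for k in keys], float)
        exp = np.array([probs[k] for k in keys]) * nrec
        big = exp >= 5
        obs_p = np.append(obs[big], obs[~big].sum())
        exp_p = np.append(exp[big], exp[~big].sum())
        if exp_p[-1] == 0:
            obs_p, exp_p = obs_p[:-1], exp_p[:-1]
        exp_p *= obs_p.sum() / exp_p.sum()
        _, p = chisquare(obs_p, exp_p)
        assert p > 0.01

    def test_prior_sampling_matches_enumerated_prior_over_n(self):
        """With constant likelihood (empty-data scoring) the chain's marginal
        over N equals the truncated-Poisson prior restricted to allocations
        with no empty component, computed exactly by enumeration."""
        n = 4
        lam, alpha = 1.0, 1.0
        # exact marginal: p(N) * sum over surjective label vectors of DM mass
        from itertools import product

        marg = np.zeros(n + 1)
        for N in range(1, n + 1):
            base = poisson_truncated_logpmf(N, lam)
            tot = 0.0
            for labels in product(range(N), repeat=n):
                counts = np.bincount(labels, minlength=N)
                if counts.min() == 0:
                    continue
                tot += math.exp(dirichlet_multinomial_log(counts, alpha))
            marg[N] = math.exp(base) * tot
        marg /= marg.sum()
        ds = Dataset(np.zeros((n, 1)))
        cfg = McmcConfig(
            n_iterations=80_000, burn_in=2_000, thinning=10, seed=4, prior_only=True
        )
        s = Sampler(ds, config=cfg)
        counts = np.zeros(n + 1)
        for t in range(1, cfg.n_iterations + 1):
            s.sweep()
            if t > cfg.burn_in and (t - cfg.burn_in) % cfg.thinning == 0:
                counts[s.N] += 1
        freq = counts / counts.sum()
        np.testing.assert_allclose(freq[1:], marg[1:], atol=0.02)


class TestRecovery:
    def test_two_component_mixture_recovers_n_and_allocation(
        self, recovery_mixture2, recovery_trace2
    ):
        from unpbn.postprocess import consensus_allocation, pco

        _, _, truth = recovery_mixture2
        trace = recovery_trace2
        assert trace.posterior_mode_n() == 2
        cons = consensus_allocation(trace)
        assert pco(cons.labels, truth) >= 95.0

    @pytest.mark.parametrize("seeds", [(0, 1, 2)])
    def test_pco_non_decreasing_with_separation(self, seeds):
        """Stronger component separation should not hurt expected accuracy."""
        from unpbn.postprocess import pco
        from unpbn.simulate import generate_gbn_mixture, two_component_gbn_spec

        levels = [1.0, 2.5, 5.0]
        means = []
        for sep in levels:
            vals = []
            for seed in seeds:
                spec = two_component_gbn_spec(n_cells=60, separation=sep)
                ds, truth = generate_gbn_mixture(spec, np.random.default_rng(seed))
                cfg = McmcConfig(
                    n_iterations=600, burn_in=300, thinning=5, seed=seed + 50
                )
                vals.append(pco(run_mcmc(ds, config=cfg), truth))
            means.append(np.mean(vals))
        assert means[0] <= means[1] + 2.0
        assert means[1] <= means[2] + 2.0
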
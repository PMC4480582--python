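"""Trace summarization: posterior edge probabilities, consensus allocation and pco.

The MCMC trace is reduced to three kinds of summaries:

* ``pep`` — the posterior edge probability of each directed edge, the fraction
  of retained samples containing it (per component after label matching, or
  occupancy-weighted over the whole trace).  Because Markov-equivalent DAGs
  score identically, directed pep splits over equivalence-class orientations;
  ``symmetrize_pep`` gives the undirected connection probability used for
  reporting.
* a consensus allocation — a single partition resolving label switching by
  maximizing the posterior-expected adjusted Rand index over a candidate set
  (hierarchical cuts of the co-clustering similarity plus every sampled
  partition), optionally constrained to exactly K blocks.
* ``pco`` — percentage of correctly allocated observations: per sample and per
  component, members carrying the component's majority true label count as
  correct; the triple average (over members, components, samples) times 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .sampler import Trace

__all__ = [
    "EdgeProbabilityMatrix",
    "ConsensusAllocation",
    "posterior_edge_probabilities",
    "per_component_edge_probabilities",
    "symmetrize_pep",
    "co_clustering_matrix",
    "consensus_allocation",
    "pco",
    "adjusted_rand_index",
]


@dataclass
class EdgeProbabilityMatrix:
    """d x d matrix of posterior edge probabilities (zero diagonal, entries in [0, 1])."""

    pep: np.ndarray
    scope: str = "trace"  # "trace" or "component:<k>"

    def __post_init__(self):
        p = np.asarray(self.pep, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("pep must be square")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("pep entries must lie in [0, 1]")
        if np.any(np.abs(np.diag(p)) > 1e-12):
            raise ValueError("pep diagonal must be zero")
        self.pep = p


@dataclass
class ConsensusAllocation:
    """A single label vector summarizing the whole trace, plus the posterior
    co-clustering similarity it was derived from."""

    labels: np.ndarray
    n_components: int
    similarity: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.min(initial=1) < 1 or (
            self.labels.size and self.labels.max() > self.n_components
        ):
            raise ValueError("labels must lie in 1..n_components")


def _check_trace(trace: Trace) -> None:
    if len(trace) == 0:
        raise ValueError("trace has no retained samples")


def posterior_edge_probabilities(
    trace: Trace, component_map: "ConsensusAllocation | None" = None
):
    """Whole-trace pep: adjacency averaged over samples with components
    weighted by their occupancy n_h / n (reduces to the plain per-sample
    average a_ij^s / r whenever each sample has a single component).

    With a ``component_map`` (a consensus allocation), delegates to
    :func:`per_component_edge_probabilities` and returns one matrix per
    consensus component instead.
    """
    if component_map is not None:
        return per_component_edge_probabilities(trace, component_map)
    _check_trace(trace)
    d = trace.d
    n = trace.n
    acc = np.zeros((d, d))
    for s in trace.samples:
        sizes = np.bincount(s.allocation, minlength=s.n_components + 1)[1:]
        for h, dag in enumerate(s.dags):
            acc += (sizes[h] / n) * dag.adjacency
    return EdgeProbabilityMatrix(acc / len(trace), scope="trace")


def per_component_edge_probabilities(
    trace: Trace, consensus: "ConsensusAllocation", match: str = "overlap"
) -> list[EdgeProbabilityMatrix]:
    """One pep matrix per consensus component.

    ``match="overlap"`` (default): each sampled component is matched to the
    consensus component with which it shares the most members (ties broken
    toward the larger consensus component, then the smaller index); its
    adjacency is averaged into that slot, normalized by the number of
    contributions.  Every sampled component contributes, including transient
    small ones.

    ``match="consensus"``: for each retained sample, each consensus block
    selects the sampled component holding the majority of its members and
    averages that component's adjacency — one contribution per block per
    sample, insensitive to transient satellite components.
    """
    _check_trace(trace)
    if match not in ("overlap", "consensus"):
        raise ValueError("match must be 'overlap' or 'consensus'")
    d = trace.d
    K = consensus.n_components
    cons = consensus.labels
    cons_sizes = np.bincount(cons, minlength=K + 1)[1:]
    acc = np.zeros((K, d, d))
    cnt = np.zeros(K)
    for s in trace.samples:
        if match == "overlap":
            for h, dag in enumerate(s.dags):
                members = s.allocation == (h + 1)
                overlap = np.bincount(cons[members], minlength=K + 1)[1:]
                best = overlap.max()
                tied = np.flatnonzero(overlap == best)
                if tied.size > 1:
                    tied = tied[np.argsort(-cons_sizes[tied], kind="stable")]
                k = int(tied[0])
                acc[k] += dag.adjacency
                cnt[k] += 1
        else:
            for k in range(K):
                block_labels = s.allocation[cons == (k + 1)]
                h = int(np.bincount(block_labels).argmax()) - 1
                acc[k] += s.dags[h].adjacency
                cnt[k] += 1
    out = []
    for k in range(K):
        pep = acc[k] / cnt[k] if cnt[k] else np.zeros((d, d))
        out.append(EdgeProbabilityMatrix(pep, scope=f"component:{k + 1}"))
    return out


def symmetrize_pep(pep: EdgeProbabilityMatrix) -> np.ndarray:
    """Undirected connection probability: P(i->j or j->i present); the two
    directed events are mutually exclusive within any single DAG."""
    p = pep.pep
    return p + p.T


def co_clustering_matrix(trace: Trace) -> np.ndarray:
    """(i, j) entry: fraction of retained samples allocating i and j together.

    Invariant to component relabeling within each sample; diagonal is 1.
    """
    _check_trace(trace)
    n = trace.n
    acc = np.zeros((n, n))
    for s in trace.samples:
        onehot = s.allocation[:, None] == np.arange(1, s.n_components + 1)[None, :]
        acc += onehot.astype(float) @ onehot.T.astype(float)
    return acc / len(trace)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions (pair-count
    form); 1 for identical partitions up to relabeling, expectation 0 under
    independent random labelings."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError("label vectors must have equal length")
    n = a.size
    if n == 0:
        return 1.0
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    ct = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(ct, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _candidate_partitions(trace: Trace, similarity: np.ndarray, k_max: int) -> list[np.ndarray]:
    n = similarity.shape[0]
    cands: list[np.ndarray] = []
    if n > 1:
        dist = 1.0 - similarity
        np.fill_diagonal(dist, 0.0)
        dist = 0.5 * (dist + dist.T)
        Z = linkage(squareform(dist, checks=False), method="average")
        for k in range(1, min(k_max, n) + 1):
            cands.append(fcluster(Z, t=k, criterion="maxclust").astype(np.int64))
    else:
        cands.append(np.ones(n, dtype=np.int64))
    seen = {c.tobytes() for c in cands}
    for s in trace.samples:
        lab = _canonical_labels(s.allocation)
        if lab.tobytes() not in seen:
            seen.add(lab.tobytes())
            cands.append(lab)
    return cands


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel blocks 1..K in order of first appearance."""
    _, inv = np.unique(labels, return_inverse=True)
    order = {}
    out = np.empty(labels.size, dtype=np.int64)
    nxt = 1
    for i, v in enumerate(inv):
        if v not in order:
            order[v] = nxt
            nxt += 1
        out[i] = order[v]
    return out


def consensus_allocation(trace: Trace, k_fixed: int | None = None) -> ConsensusAllocation:
    """Label-switching-resolved summary partition.

    Maximizes the posterior-expected adjusted Rand index (mean ARI against all
    retained samples) over a candidate set: average-linkage cuts of the
    1 - co-clustering distance at every K, plus every sampled partition.  With
    ``k_fixed`` the candidates are restricted to partitions with exactly that
    many blocks.
    """
    _check_trace(trace)
    n = trace.n
    if k_fixed is not None:
        if k_fixed < 1:
            raise ValueError("k_fixed must be >= 1")
        if k_fixed > n:
            raise ValueError("k_fixed cannot exceed the number of observations")
    sim = co_clustering_matrix(trace)
    k_max = max((s.n_components for s in trace.samples), default=1)
    k_max = max(k_max, k_fixed or 1) + 2
    cands = _candidate_partitions(trace, sim, k_max)
    if k_fixed is not None:
        cands = [c for c in cands if np.unique(c).size == k_fixed]
        if not cands:
            raise ValueError(f"no candidate partition with exactly {k_fixed} blocks")
    best, best_score = None, -np.inf
    for cand in cands:
        score = float(
            np.mean([adjusted_rand_index(cand, s.allocation) for s in trace.samples])
        )
        if score > best_score + 1e-12:
            best, best_score = cand, score
    labels = _canonical_labels(best)
    return ConsensusAllocation(
        labels=labels, n_components=int(labels.max()), similarity=sim
    )


def pco(trace_or_labels, true_labels) -> float:
    """Percentage of correctly allocated observations.

    For each retained sample and each of its components, the component's true
    identity is the majority ground-truth label among its members; members
    carrying it count as correct.  The average is taken per component, then
    over components, then over samples, and scaled to [0, 100].  A tie in the
    majority is resolved deterministically (ties yield the same correct count
    for any tied label).  Accepts a :class:`Trace` or a single label vector.
    """
    truth = np.asarray(true_labels).ravel()
    if isinstance(trace_or_labels, Trace):
        _check_trace(trace_or_labels)
        if trace_or_labels.n != truth.size:
            raise ValueError("true_labels length does not match the trace")
        allocs = [s.allocation for s in trace_or_labels.samples]
    else:
        alloc = np.asarray(trace_or_labels).ravel()
        if alloc.size != truth.size:
            raise ValueError("true_labels length does not match the allocation")
        allocs = [alloc]
    _, truth_idx = np.unique(truth, return_inverse=True)
    total = 0.0
    for alloc in allocs:
        labs = np.unique(alloc)
        comp_acc = 0.0
        for h in labs:
            members = truth_idx[alloc == h]
            counts = np.bincount(members)
            comp_acc += counts.max() / members.size
        total += comp_acc / labs.size
    return 100.0 * total / len(allocs)
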
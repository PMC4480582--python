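"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form BGe ratio formula: subset marginal
likelihoods are computed by dense-grid quadrature against the Normal-inverse-
gamma / inverse-Wishart marginals of the Normal-Wishart prior, with only
elementary Gaussian identities used analytically.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, logsumexp


def quad_logml_1d(x: np.ndarray, d: int, dof: float, nu: float) -> float:
    """log p of one data column by 2-D quadrature over (mu, sigma^2).

    The marginal of a single diagonal entry of Sigma ~ InvWishart_d(I, dof) is
    InvWishart_1(1, dof - (d - 1)); mu | sigma^2 ~ N(0, sigma^2 / nu).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    nu_iw = dof - (d - 1)
    tgrid = np.linspace(-8, 6, 4001)  # t = log sigma^2
    mgrid = np.linspace(-15, 15, 4001)
    T, M = np.meshgrid(tgrid, mgrid, indexing="ij")
    s2 = np.exp(T)
    logp = (
        0.5 * nu_iw * math.log(0.5)
        - gammaln(0.5 * nu_iw)
        - (0.5 * nu_iw + 1) * T
        - 0.5 / s2
    ) + T  # + T: Jacobian d sigma^2 = sigma^2 dt
    logp += (
        -0.5 * math.log(2 * math.pi)
        - 0.5 * (T - math.log(nu))
        - 0.5 * nu * M**2 / s2
    )
    logp += (
        -0.5 * n * math.log(2 * math.pi)
        - 0.5 * n * T
        - 0.5 * ((x[:, None, None] - M) ** 2).sum(0) / s2
    )
    dt = tgrid[1] - tgrid[0]
    dm = mgrid[1] - mgrid[0]
    return float(logsumexp(logp) + math.log(dt * dm))


def quad_logml_2d(X: np.ndarray, dof: float, nu: float, n_nodes: int = 220) -> float:
    """log p of a two-column data block by 3-D quadrature over the Cholesky
    factor of Sigma ~ InvWishart_2(I, dof); the mean is integrated with the
    standard Gaussian identity."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    assert d == 2
    xbar = X.mean(0)
    Sn = (X - xbar).T @ (X - xbar)
    A = Sn + (nu * n / (nu + n)) * np.outer(xbar, xbar)
    t1 = np.linspace(-4, 3, n_nodes)
    t2 = np.linspace(-4, 3, n_nodes)
    u = np.linspace(-6, 6, n_nodes)
    T1, U, T2 = np.meshgrid(t1, u, t2, indexing="ij")
    l1, l2 = np.exp(T1), np.exp(T2)
    s11 = l1**2
    s12 = l1 * U
    s22 = U**2 + l2**2
    det = (l1 * l2) ** 2
    i11 = s22 / det
    i22 = s11 / det
    i12 = -s12 / det
    trPA = i11 * A[0, 0] + 2 * i12 * A[0, 1] + i22 * A[1, 1]
    trP = i11 + i22
    logdet = np.log(det)
    lognorm = -(
        0.5 * dof * d * math.log(2)
        + 0.25 * d * (d - 1) * math.log(math.pi)
        + gammaln(0.5 * dof)
        + gammaln(0.5 * (dof - 1))
    )
    logp = lognorm - 0.5 * (dof + d + 1) * logdet - 0.5 * trP
    logp += (
        -0.5 * n * d * math.log(2 * math.pi)
        - 0.5 * n * logdet
        + 0.5 * d * (math.log(nu) - math.log(nu + n))
        - 0.5 * trPA
    )
    # dSigma = 4 l1^2 l2 dl1 dl21 dl2, with dl = l dt for both diagonals
    logp += math.log(4.0) + 3 * T1 + 2 * T2
    dt = (t1[1] - t1[0]) * (u[1] - u[0]) * (t2[1] - t2[0])
    return float(logsumexp(logp) + math.log(dt))


def reachability_has_cycle(adj: np.ndarray) -> bool:
    """Brute-force cycle detection: path enumeration via boolean matrix powers."""
    a = np.asarray(adj, dtype=bool)
    d = a.shape[0]
    reach = a.copy()
    for _ in range(d):
        reach = reach | (reach @ a)
    return bool(np.any(np.diag(reach)))


def ari_pair_counts(a, b) -> float:
    """Adjusted Rand index by explicit enumeration of all observation pairs."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    n = a.size
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            if sa and sb:
                n11 += 1
            elif sa and not sb:
                n10 += 1
            elif not sa and sb:
                n01 += 1
            else:
                n00 += 1
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def cpdag_key(dag):
    """Markov-equivalence-class key: skeleton plus v-structures."""
    import itertools

    a = dag.adjacency
    skel = frozenset(frozenset((i, j)) for i, j in dag.edges())
    vs = set()
    for j in range(dag.d):
        for u, v in itertools.combinations(dag.parents(j), 2):
            if not (a[u, v] or a[v, u]):
                vs.add((frozenset((u, v)), j))
    return skel, frozenset(vs)
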
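"""Independent reference implementations used only to check the package.

These are deliberately naive: a quadratic-time affine-gap local-alignment
DP with explicit three-state matrices, a tree likelihood that materializes
the full joint tensor over internal-node states, and a numerical-quadrature
version of the discrete-gamma category means.
"""

from __future__ import annotations

import itertools

import numpy as np


def sw_brute(query: str, ref: str, score, gap_open: float, gap_ext: float):
    """Affine-gap local alignment by explicit 3-matrix DP; returns the
    optimal score. ``score(a, b)`` is a callable."""
    m, n = len(query), len(ref)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_ext, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_ext, F[i - 1][j] - gap_ext)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + score(query[i - 1], ref[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def enumeration_site_likelihood(
    parent: dict[int, int],
    lengths: dict[int, float],
    children: dict[int, list[int]],
    root: int,
    leaf_states: dict[int, int | None],
    model,
) -> float:
    """Single-site likelihood by explicit enumeration over all joint
    internal-state assignments (mean over gamma categories).

    ``leaf_states[node]`` is a residue index or None for missing data.
    Nodes are arbitrary hashables; internal nodes are those with children.
    """
    internals = [v for v in children if children[v]]
    total = 0.0
    for c in range(model.k):
        r = float(model.rates[c])
        P = {v: model.transition(lengths[v], r) for v in parent}
        acc = 0.0
        for combo in itertools.product(range(20), repeat=len(internals)):
            state = dict(zip(internals, combo))
            term = model.pi[state[root]]
            for v in parent:
                p = parent[v]
                if v in state:
                    term *= P[v][state[p], state[v]]
                else:
                    s = leaf_states[v]
                    if s is None:
                        term *= 1.0  # missing data
                    else:
                        term *= P[v][state[p], s]
            acc += term
        total += acc / model.k
    return total


def enumeration_site_likelihood_dense(
    parent: dict,
    lengths: dict,
    children: dict,
    root,
    leaf_states: dict,
    model,
) -> float:
    """Like :func:`enumeration_site_likelihood` but materializes the full
    joint tensor over internal-node states (one axis per internal node),
    multiplies every edge factor onto the grid, and takes the grand sum —
    still exhaustive enumeration, just not a python loop."""
    internals = sorted((v for v in children if children[v]), key=str)
    axis = {v: i for i, v in enumerate(internals)}
    m = len(internals)

    def on_axis(vec, ax):
        shape = [1] * m
        shape[ax] = 20
        return vec.reshape(shape)

    def on_axes(matrix, ax1, ax2):
        shape = [1] * m
        shape[ax1] = 20
        shape[ax2] = 20
        if ax1 < ax2:
            return matrix.reshape(shape)
        return matrix.T.reshape(shape)

    total = 0.0
    for c in range(model.k):
        r = float(model.rates[c])
        P = {v: model.transition(lengths[v], r) for v in parent}
        T = np.ones((20,) * m)
        T = T * on_axis(model.pi, axis[root])
        for v, p in parent.items():
            if v in axis:
                T = T * on_axes(P[v], axis[p], axis[v])
            else:
                s = leaf_states[v]
                vec = np.ones(20) if s is None else P[v][:, s]
                T = T * on_axis(vec, axis[p])
        total += float(T.sum()) / model.k
    return total


def gamma_rates_quadrature(alpha: float, k: int) -> np.ndarray:
    """Discrete-gamma category means by adaptive quadrature."""
    from scipy import integrate
    from scipy.stats import gamma

    dist = gamma(a=alpha, scale=1.0 / alpha)
    edges = dist.ppf(np.arange(k + 1) / k)
    rates = []
    for i in range(k):
        hi = edges[i + 1] if np.isfinite(edges[i + 1]) else dist.ppf(1 - 1e-12)
        val, _err = integrate.quad(lambda x: x * dist.pdf(x), edges[i], hi,
                                   limit=200)
        rates.append(val * k)
    return np.asarray(rates)
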
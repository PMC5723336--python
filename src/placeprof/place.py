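"""Maximum-likelihood placement of recruited reads on a reference tree.

The model is a reversible amino-acid CTMC (LG/WAG/JTT exchangeabilities x
stationary frequencies, rate matrix normalized to one expected substitution
per unit branch length) with discrete-gamma rate heterogeneity (equal-weight
categories, category rates by the mean-within-quantile-bin rule). Reference
partial likelihoods are computed once per package by Felsenstein pruning
(gaps = missing data, per-site scaling) and reused for every query.

Placement follows the evolutionary-placement heuristic: every edge is scored
with the query attached at the edge midpoint via a fixed-length pendant
branch (phase 1), then the pendant length is re-optimized by golden-section
search on the best candidate edges (phase 2). Per-edge likelihood weight
ratios are the per-edge likelihoods normalized over all edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as _gamma_dist

from .formats import NumberedTree, SeqRecord
from .matrices import AA_INDEX, blosum_matrix, encode_aa, load_exchangeabilities
from .refpkg import ModelSpec, ReferencePackage
from .recruit import RecruitedRead

PENDANT_MIN = 1e-8
PENDANT_MAX = 2.0
PENDANT_START = 0.1

__all__ = [
    "SubstitutionModel",
    "build_model",
    "discrete_gamma_rates",
    "substitution_probability",
    "tree_log_likelihood",
    "AlignedQuery",
    "Placement",
    "align_read_to_profile",
    "combine_pair_in_alignment",
    "PlacementEngine",
    "epa_place",
]


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Discrete-gamma category rates (equal-probability categories).

    Rate i is the mean of a Gamma(alpha, mean 1) over its quantile bin,
    computed in closed form from the regularized incomplete gamma; the
    rates average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    cum = gammainc(alpha + 1, edges * alpha)
    cum[0], cum[-1] = 0.0, 1.0
    return k * np.diff(cum)


@dataclass
class SubstitutionModel:
    """Reversible amino-acid CTMC with discrete-gamma rate heterogeneity."""

    exchangeability: np.ndarray
    pi: np.ndarray
    alpha: float
    k: int
    Q: np.ndarray = field(init=False)
    rates: np.ndarray = field(init=False)
    _evals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)   # D^{-1/2} U
    _right: np.ndarray = field(init=False, repr=False)  # U^T D^{1/2}

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-12:
            pi = pi / pi.sum()
        self.pi = pi
        R = np.asarray(self.exchangeability, dtype=float)
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        Q = Q / mu
        self.Q = Q
        self.rates = discrete_gamma_rates(self.alpha, self.k)
        d = np.sqrt(pi)
        A = (Q * d[:, None]) / d[None, :]
        A = (A + A.T) / 2.0  # exact symmetry
        evals, U = np.linalg.eigh(A)
        self._evals = evals
        self._left = U / d[:, None]
        self._right = U.T * d[None, :]

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * rate * t); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._left * np.exp(self._evals * rate * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P


def build_model(
    model_spec: ModelSpec, ref_alignment: Optional[list[SeqRecord]] = None
) -> SubstitutionModel:
    """Instantiate a substitution model from a reference-package spec.

    Stationary frequencies come from the named matrix, or are counted from
    the reference alignment when empirical frequencies are requested.
    """
    R, freqs = load_exchangeabilities(model_spec.matrix)
    if model_spec.frequencies == "empirical":
        if ref_alignment is None:
            raise ValueError("empirical frequencies need a reference alignment")
        counts = np.ones(20)  # +1 pseudocount keeps all frequencies positive
        for rec in ref_alignment:
            for c in rec.seq.upper():
                idx = AA_INDEX.get(c)
                if idx is not None:
                    counts[idx] += 1
        freqs = counts / counts.sum()
    return SubstitutionModel(R, freqs, model_spec.alpha, model_spec.k)


def substitution_probability(
    model: SubstitutionModel, t: float, category: int = 0
) -> np.ndarray:
    """Transition-probability matrix for one gamma category."""
    return model.transition(t, float(model.rates[category]))


# -- pruning core ----------------------------------------------------------

def _leaf_vector(seq: str, n_cols: int) -> np.ndarray:
    """Per-site conditional vectors for a leaf row: one-hot for residues,
    all-ones for gaps/unknowns (missing data)."""
    if len(seq) != n_cols:
        raise ValueError("sequence length does not match column count")
    vec = np.ones((n_cols, 20))
    for s, c in enumerate(seq.upper()):
        idx = AA_INDEX.get(c)
        if idx is not None:
            vec[s, :] = 0.0
            vec[s, idx] = 1.0
    return vec


def _rescale(arr: np.ndarray, scale: np.ndarray) -> None:
    """Per-(category, site) rescaling in place; log factors added to scale."""
    factor = arr.max(axis=2)
    factor[factor == 0.0] = 1.0
    arr /= factor[:, :, None]
    scale += np.log(factor)


class _Partials:
    """Down (subtree) and outside partial likelihoods for a fixed tree,
    model, and leaf data, with per-(category, site) log scaling."""

    def __init__(
        self,
        tree: NumberedTree,
        model: SubstitutionModel,
        leaf_vecs: dict[str, np.ndarray],
        compute_outside: bool = True,
    ):
        self.tree = tree
        self.model = model
        k = model.k
        S = next(iter(leaf_vecs.values())).shape[0]
        self.n_sites = S
        n = tree.n_nodes
        # transition matrices per edge per category
        self.P = np.zeros((n, k, 20, 20))
        for v in range(tree.n_edges):
            for c in range(k):
                self.P[v, c] = model.transition(
                    float(tree.lengths[v]), float(model.rates[c])
                )
        self.down = np.zeros((n, k, S, 20))
        self.down_scale = np.zeros((n, k, S))
        # M[v] = P_v @ down[v]: message from subtree(v) to v's parent
        self.M = np.zeros((n, k, S, 20))
        for v in tree.postorder():
            if tree.is_leaf(v):
                name = tree.names[v]
                if name not in leaf_vecs:
                    raise ValueError(f"leaf {name!r} has no sequence row")
                self.down[v] = leaf_vecs[name][None, :, :]
            else:
                acc = np.ones((k, S, 20))
                sc = np.zeros((k, S))
                for ch in tree.children[v]:
                    acc *= self.M[ch]
                    sc += self.down_scale[ch]
                self.down[v] = acc
                self.down_scale[v] = sc
                _rescale(self.down[v], self.down_scale[v])
            if v != tree.root:
                # message through the edge: sum_b P[a,b] down[b]
                self.M[v] = np.einsum("cab,csb->csa", self.P[v], self.down[v])

        pi = model.pi
        root_site = np.einsum("a,csa->cs", pi, self.down[tree.root])
        self.site_loglik = logsumexp(
            np.log(root_site) + self.down_scale[tree.root], axis=0
        ) - math.log(k)
        self.total_loglik = float(self.site_loglik.sum())

        if not compute_outside:
            return
        # outside partials O[v]: P(data outside subtree(v) | state at parent(v))
        self.O = np.zeros((n, k, S, 20))
        self.O_scale = np.zeros((n, k, S))
        U = np.zeros((n, k, S, 20))  # outside conditional on state at node
        U_scale = np.zeros((n, k, S))
        U[tree.root] = 1.0
        for p in reversed(range(n)):
            kids = tree.children[p]
            if not kids:
                continue
            for v in kids:
                acc = U[p].copy()
                sc = U_scale[p].copy()
                for w in kids:
                    if w != v:
                        acc *= self.M[w]
                        sc += self.down_scale[w]
                self.O[v] = acc
                self.O_scale[v] = sc
                _rescale(self.O[v], self.O_scale[v])
                # reversibility: transition child->parent uses the same P
                U[v] = np.einsum("cab,csb->csa", self.P[v], self.O[v])
                U_scale[v] = self.O_scale[v]


def tree_log_likelihood(
    refpkg_or_tree: Union[ReferencePackage, NumberedTree],
    model: SubstitutionModel,
    alignment: Union[dict[str, str], list[SeqRecord], None] = None,
) -> float:
    """Total log-likelihood of an aligned amino-acid matrix on a tree.

    Gaps are treated as missing data; per-site likelihoods average over
    gamma categories. For a ReferencePackage the bundled alignment is used
    unless one is supplied.
    """
    if isinstance(refpkg_or_tree, ReferencePackage):
        tree = refpkg_or_tree.tree
        if alignment is None:
            alignment = refpkg_or_tree.alignment
    else:
        tree = refpkg_or_tree
        if alignment is None:
            raise ValueError("an alignment is required with a bare tree")
    if isinstance(alignment, dict):
        rows = alignment
    else:
        rows = {r.id: r.seq for r in alignment}
    n_cols = len(next(iter(rows.values())))
    leaf_vecs = {}
    for name in tree.leaf_names:
        if name not in rows:
            raise ValueError(f"leaf {name!r} has no sequence row")
        leaf_vecs[name] = _leaf_vector(rows[name], n_cols)
    return _Partials(tree, model, leaf_vecs, compute_outside=False).total_loglik


# -- queries ---------------------------------------------------------------

GAP_CODE = -2  # column not covered by the query
UNK_CODE = -1  # covered but uninformative (X)


@dataclass
class AlignedQuery:
    """A query registered to the reference alignment's columns.

    ``codes[s]`` is the residue index at column s, UNK_CODE for X, or
    GAP_CODE where the query has no residue.
    """

    query_id: str
    codes: np.ndarray
    mates: tuple[str, ...] = ("merged",)

    @property
    def coverage_mask(self) -> np.ndarray:
        return self.codes != GAP_CODE

    @property
    def n_covered(self) -> int:
        return int(self.coverage_mask.sum())

    @property
    def n_informative(self) -> int:
        return int((self.codes >= 0).sum())


@dataclass
class Placement:
    """Per-edge placement of one query: (edge id, log-likelihood, LWR,
    pendant length), sorted by descending LWR (ties: ascending edge id)."""

    query_id: str
    rows: list[tuple[int, float, float, float]]

    @property
    def best_edge(self) -> int:
        return self.rows[0][0]

    @property
    def best_pendant(self) -> float:
        return self.rows[0][3]


def _profile(refpkg: ReferencePackage) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue frequencies (normalized by row count, so gaps
    dilute) and occupancy for the reference alignment."""
    S = refpkg.n_columns
    freq = np.zeros((S, 20))
    nrow = len(refpkg.alignment)
    for rec in refpkg.alignment:
        for s, ch in enumerate(rec.seq.upper()):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                freq[s, idx] += 1.0
    occ = freq.sum(axis=1) / nrow
    freq /= nrow
    return freq, occ


def align_read_to_profile(
    read: RecruitedRead,
    refpkg: ReferencePackage,
    gap_open: float = 11.0,
    gap_ext: float = 1.0,
) -> AlignedQuery:
    """Column-register a recruited read against the reference alignment.

    Global-in-read / local-in-profile affine alignment against per-column
    BLOSUM62 profile scores; skipping a column costs gap penalties scaled
    by column occupancy (all-gap columns are free). Reference columns are
    never modified: read residues falling between columns (insertions) are
    dropped.
    """
    from . import _align

    cached = getattr(refpkg, "_profile_cache", None)
    if cached is None or cached[3] != (gap_open, gap_ext):
        freq, occ = _profile(refpkg)
        colscore = freq @ blosum_matrix("BLOSUM62")
        cached = (colscore, occ * gap_open, occ * gap_ext, (gap_open, gap_ext))
        object.__setattr__(refpkg, "_profile_cache", cached)
    colscore, del_open, del_ext, _ = cached
    q = encode_aa(read.aa_seq)
    _score, cols = _align.profile_align(
        q, colscore, del_open, del_ext, gap_open, gap_ext
    )
    codes = np.full(refpkg.n_columns, GAP_CODE, dtype=np.int64)
    for i, j in enumerate(cols):
        if j >= 0:
            codes[j] = q[i] if q[i] >= 0 else UNK_CODE
    return AlignedQuery(read.read_id, codes, mates=(read.mate,))


def combine_pair_in_alignment(q1: AlignedQuery, q2: AlignedQuery) -> AlignedQuery:
    """Combine mate pairs into one query in the same column space: union of
    coverage; agreeing residues kept, disagreements masked to X."""
    if q1.codes.shape != q2.codes.shape:
        raise ValueError("queries have different column counts")
    a, b = q1.codes, q2.codes
    out = np.where(a == GAP_CODE, b, a)
    both = (a != GAP_CODE) & (b != GAP_CODE)
    out = np.where(both & (a != b), UNK_CODE, out)
    stem = q1.query_id
    for sep in ("/", "_"):
        if stem.endswith((sep + "1", sep + "2")):
            stem = stem[:-2]
    return AlignedQuery(stem, out, mates=tuple(q1.mates) + tuple(q2.mates))


def _golden_max(f, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Golden-section maximization on [lo, hi]; returns (x, f(x))."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > tol:
        if f1 >= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = f(x2)
    return (x1, f1) if f1 >= f2 else (x2, f2)


class PlacementEngine:
    """Per-edge ML placement with reference partials computed once.

    Phase 1 scores every edge with the query attached at the edge midpoint
    through a pendant branch of length ``pendant_start``; phase 2 refines
    the pendant length on the top max(5, ceil(phase2_frac * E)) edges by
    golden-section search on [1e-8, 2.0] to tolerance 1e-4.
    """

    def __init__(
        self,
        refpkg: ReferencePackage,
        model: Optional[SubstitutionModel] = None,
        pendant_start: float = PENDANT_START,
        phase2_frac: float = 0.1,
        min_aa: int = 33,
    ):
        self.refpkg = refpkg
        self.model = model or build_model(refpkg.model_spec, refpkg.alignment)
        self.pendant_start = pendant_start
        self.phase2_frac = phase2_frac
        self.min_aa = min_aa
        tree = refpkg.tree
        S = refpkg.n_columns
        leaf_vecs = {r.id: _leaf_vector(r.seq, S) for r in refpkg.alignment}
        part = _Partials(tree, self.model, leaf_vecs, compute_outside=True)
        self._part = part
        k = self.model.k
        pi = self.model.pi
        E = tree.n_edges
        # per-edge midpoint weights W_e[c,s,a] = pi_a * (P(x)@down)_a * G_a,
        # with per-category scale logs folded in against the per-site max
        # so per-query work needs no logsumexp
        self.W = np.zeros((E, k, S, 20))
        self.Wscale = np.zeros((E, k, S))
        for e in range(E):
            half = float(tree.lengths[e]) / 2.0
            for c in range(k):
                r = float(self.model.rates[c])
                Phalf = self.model.transition(half, r)
                A = part.down[e, c] @ Phalf.T        # (S,20) at attachment
                G = part.O[e, c] @ Phalf.T           # outside over other half
                self.W[e, c] = pi[None, :] * A * G
            self.Wscale[e] = part.down_scale[e] + part.O_scale[e]
        self.site_scale = self.Wscale.max(axis=1)    # (E, S)
        self.W *= np.exp(self.Wscale - self.site_scale[:, None, :])[..., None]
        self.site_loglik_ref = part.site_loglik
        self.n_edges = E

    # per-site query vectors through the pendant branch
    def _query_vecs(self, codes_cov: np.ndarray, pendant: float) -> np.ndarray:
        k = self.model.k
        n = codes_cov.shape[0]
        out = np.ones((k, n, 20))
        informative = codes_cov >= 0
        if informative.any():
            idx = codes_cov[informative]
            for c in range(k):
                P = self.model.transition(pendant, float(self.model.rates[c]))
                out[c, informative, :] = P[:, idx].T
        return out

    def _query_vecs_multi(
        self, codes_cov: np.ndarray, pendants: np.ndarray
    ) -> np.ndarray:
        """Query conditionals through pendant branches, one pendant per
        candidate edge: returns (n_pendants, k, n_cov, 20)."""
        m = self.model
        npend = pendants.shape[0]
        n = codes_cov.shape[0]
        expd = np.exp(
            m._evals[None, None, :]
            * (m.rates[None, :, None] * pendants[:, None, None])
        )  # (npend, k, 20)
        P = np.einsum("ab,ekb,bc->ekac", m._left, expd, m._right)
        np.clip(P, 0.0, None, out=P)
        out = np.ones((npend, m.k, n, 20))
        informative = codes_cov >= 0
        if informative.any():
            idx = codes_cov[informative]
            # qv[a] = P[a, residue]
            out[:, :, informative, :] = P[:, :, :, idx].transpose(0, 1, 3, 2)
        return out

    def edge_log_likelihoods(
        self, query: AlignedQuery, pendant: Optional[float] = None
    ) -> np.ndarray:
        """Total log-likelihood of tree + query per attachment edge, with
        the query joined at the edge midpoint by a fixed pendant branch."""
        cov = query.coverage_mask
        qv = self._query_vecs_multi(
            query.codes[cov],
            np.array([self.pendant_start if pendant is None else pendant]),
        )[0]
        inner = np.einsum("eksa,ksa->eks", self.W[:, :, cov, :], qv).mean(axis=1)
        return (
            np.log(inner).sum(axis=1)
            + self.site_scale[:, cov].sum(axis=1)
            + float(self.site_loglik_ref[~cov].sum())
        )

    def place(self, query: AlignedQuery) -> Placement:
        cov = query.coverage_mask
        if query.n_covered < self.min_aa:
            raise ValueError(
                f"query {query.query_id!r} covers {query.n_covered} columns "
                f"(< {self.min_aa})"
            )
        codes_cov = query.codes[cov]
        uncovered_ll = float(self.site_loglik_ref[~cov].sum())
        W_cov = self.W[:, :, cov, :]            # (E, k, n_cov, 20)
        scale_sum = self.site_scale[:, cov].sum(axis=1)  # (E,)

        # phase 1: all edges, fixed pendant
        ll = self.edge_log_likelihoods(query)
        pendants = np.full(self.n_edges, self.pendant_start)

        # phase 2: golden-section pendant optimization on the top edges,
        # vectorized across candidates (one new evaluation point per edge
        # and iteration)
        n_top = max(5, math.ceil(self.phase2_frac * self.n_edges))
        n_top = min(n_top, self.n_edges)
        order = sorted(range(self.n_edges), key=lambda e: (-ll[e], e))
        top = np.array(order[:n_top])
        Wt = W_cov[top]
        st_top = scale_sum[top]

        def f(pends: np.ndarray) -> np.ndarray:
            QV = self._query_vecs_multi(codes_cov, pends)
            inn = np.einsum("eksa,eksa->eks", Wt, QV).mean(axis=1)
            return np.log(inn).sum(axis=1) + st_top

        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a = np.full(n_top, PENDANT_MIN)
        b = np.full(n_top, PENDANT_MAX)
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1 = f(x1)
        f2 = f(x2)
        while float((b - a).max()) > 1e-4:
            left = f1 >= f2  # maximum bracketed in [a, x2]
            b = np.where(left, x2, b)
            a = np.where(left, a, x1)
            new_x = np.where(left, b - invphi * (b - a), a + invphi * (b - a))
            new_f = f(new_x)
            x1, f1, x2, f2 = (
                np.where(left, new_x, x2),
                np.where(left, new_f, f2),
                np.where(left, x1, new_x),
                np.where(left, f1, new_f),
            )
        best_x = np.where(f1 >= f2, x1, x2)
        best_f = np.maximum(f1, f2) + uncovered_ll
        for i, e in enumerate(top):
            if best_f[i] > ll[e]:
                ll[e] = best_f[i]
                pendants[e] = best_x[i]

        lwr = np.exp(ll - logsumexp(ll))
        lwr /= lwr.sum()
        rows = sorted(
            (
                (int(e), float(ll[e]), float(lwr[e]), float(pendants[e]))
                for e in range(self.n_edges)
            ),
            key=lambda r: (-r[2], r[0]),
        )
        return Placement(query.query_id, rows)


def epa_place(
    query: AlignedQuery,
    refpkg: ReferencePackage,
    model: Optional[SubstitutionModel] = None,
) -> Placement:
    """Place a single aligned query (engine cached on the package)."""
    engine = getattr(refpkg, "_engine_cache", None)
    if engine is None or (model is not None and engine.model is not model):
        engine = PlacementEngine(refpkg, model)
        object.__setattr__(refpkg, "_engine_cache", engine)
    return engine.place(query)
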
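"""Felsenstein-pruning likelihood engine over arbitrary finite alphabets.

Supports reversible GTR-type models on 2/4/6-state alphabets and the
empirical JTT model on amino acids, each optionally with discrete-gamma
rate variation (+G, equal-probability categories represented by their
means), a proportion of invariant sites (+I) and empirical frequencies
(+F).  Branch lengths are in expected substitutions per site; the rate
matrix is normalised so the mixture's mean rate is 1.

The engine compresses alignments to unique site patterns and vectorises
across gamma categories, which keeps the parametric-bootstrap loops
(Goldman test, recovery experiments) affordable on one CPU.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as _gamma_dist

from .alphabets import GAP, MISSING, resolve
from .seq_data import Alignment
from .treeutils import TreeArrays, to_arrays

_MIN_BL = 1e-9
_MAX_BL = 20.0


def _optimize_scalar_log(neg_fn, current: float, maxiter: int, xatol_log: float = 1e-3,
                         lo: float = _MIN_BL, hi: float = _MAX_BL) -> tuple[float, float]:
    """Minimise neg_fn(t) over t in [lo, hi] by Brent in log space.

    Searches a window around the current value first (golden-section on
    the full interval needs far more iterations than a typical budget),
    expanding the window while the optimum sticks to its boundary.
    Returns (t_best, neg_value).
    """
    from scipy.optimize import minimize_scalar as _ms

    t0 = float(np.clip(current, lo * 10, hi / 2))
    span = 3.0  # +/- in natural log, covers a 20-fold window each way
    lo_l, hi_l = np.log(lo), np.log(hi)
    for _ in range(4):
        a = max(np.log(t0) - span, lo_l)
        b = min(np.log(t0) + span, hi_l)
        res = _ms(
            lambda u: neg_fn(float(np.exp(u))),
            bounds=(a, b),
            method="bounded",
            options={"xatol": xatol_log, "maxiter": maxiter},
        )
        u = float(res.x)
        at_low = u - a < 2 * xatol_log and a > lo_l + 1e-9
        at_high = b - u < 2 * xatol_log and b < hi_l - 1e-9
        if not (at_low or at_high):
            return float(np.exp(u)), float(res.fun)
        t0 = float(np.exp(u + (-span if at_low else span) / 2))
    return float(np.exp(u)), float(res.fun)


# ----------------------------------------------------------------------
# Models
# ----------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=1024)
def _discrete_gamma_cached(alpha: float, n: int) -> tuple[float, ...]:
    edges = _gamma_dist.ppf(np.arange(1, n) / n, a=alpha, scale=1.0 / alpha)
    cuts = np.concatenate([[0.0], alpha * edges, [np.inf]])
    reg = gammainc(alpha + 1.0, cuts)
    rates = n * np.diff(reg)
    return tuple(rates / rates.mean())


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability discrete-gamma categories.

    Uses the standard representation of Gamma(alpha, alpha) (mean 1) by
    ``n`` categories of probability 1/n, each represented by its
    conditional mean.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    n = int(n_categories)
    if n == 1:
        return np.ones(1)
    return np.array(_discrete_gamma_cached(float(alpha), n))


def _logsumexp0(terms: np.ndarray) -> np.ndarray:
    """Log-sum-exp over axis 0 (minimal-overhead replacement)."""
    m = terms.max(axis=0)
    m = np.where(np.isfinite(m), m, 0.0)
    return m + np.log(np.exp(terms - m).sum(axis=0))


def _load_jtt() -> tuple[str, np.ndarray, np.ndarray]:
    text = (
        importlib.resources.files("mitobias.data").joinpath("jtt.txt").read_text()
    )
    lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    order = "".join(lines[0].split())
    vals = [float(x) for x in lines[1:]]
    ex_low, freqs = vals[:190], np.array(vals[190:])
    k = 20
    S = np.zeros((k, k))
    pos = 0
    for i in range(1, k):
        for j in range(i):
            S[i, j] = S[j, i] = ex_low[pos]
            pos += 1
    # reorder from the resource's residue order to the package aa20 order
    target = resolve("aa20")
    perm = [order.index(a) for a in target]
    S = S[np.ix_(perm, perm)]
    freqs = freqs[perm]
    return target, S, freqs / freqs.sum()


_JTT_CACHE: tuple[str, np.ndarray, np.ndarray] | None = None


def jtt_exchangeabilities() -> tuple[np.ndarray, np.ndarray]:
    """JTT symmetric exchangeabilities and equilibrium frequencies (aa20 order)."""
    global _JTT_CACHE
    if _JTT_CACHE is None:
        _JTT_CACHE = _load_jtt()
    return _JTT_CACHE[1].copy(), _JTT_CACHE[2].copy()


@dataclass
class SubstitutionModel:
    """A reversible substitution model with optional +G/+I mixture."""

    alphabet: str
    exchangeabilities: np.ndarray
    equilibrium_freqs: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 5
    p_invariant: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        k = len(resolve(self.alphabet))
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.equilibrium_freqs = np.asarray(self.equilibrium_freqs, dtype=float)
        if self.exchangeabilities.shape != (k, k):
            raise ValueError("exchangeability matrix shape mismatch")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeabilities must be symmetric")
        if abs(self.equilibrium_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("equilibrium frequencies must sum to 1")
        if not 0 <= self.p_invariant < 1:
            raise ValueError("p_invariant must be in [0, 1)")

    @property
    def k(self) -> int:
        return len(resolve(self.alphabet))

    def rate_matrix(self) -> np.ndarray:
        """Q with rows summing to 0 and mean substitution rate 1."""
        pi = self.equilibrium_freqs
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float((pi * np.diag(Q)).sum())
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / mu

    def mixture(self) -> tuple[np.ndarray, np.ndarray, float]:
        """(rates, weights) for the variable-rate categories, plus p_inv.

        Gamma category rates are rescaled by 1/(1 - p_inv) so the overall
        mixture (including the invariant class at rate 0) keeps mean 1.
        """
        if self.gamma_shape is None:
            rates = np.ones(1)
        else:
            rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)
        p = self.p_invariant
        if p > 0:
            rates = rates / (1.0 - p)
        weights = np.full(len(rates), (1.0 - p) / len(rates))
        return rates, weights, p

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via the sqrt(pi) symmetrisation."""
        pi = self.equilibrium_freqs
        Q = self.rate_matrix()
        d = np.sqrt(np.maximum(pi, 1e-300))
        B = (Q * d[:, None]) / d[None, :]
        B = (B + B.T) / 2.0
        w, U = np.linalg.eigh(B)
        V = U / d[:, None]
        Vinv = U.T * d[None, :]
        return w, V, Vinv

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stack of P(t * r_c), shape (n_cat, k, k)."""
        w, V, Vinv = self.eigen()
        e = np.exp(np.outer(t * rates, w))  # (nc, k)
        P = np.einsum("ik,ck,kj->cij", V, e, Vinv)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def empirical_frequencies(alignment: Alignment, pseudocount: float = 0.0) -> np.ndarray:
    symbols = resolve(alignment.alphabet)
    counts = np.array([(alignment.data == s).sum() for s in symbols], dtype=float)
    counts += pseudocount
    if counts.sum() == 0:
        raise ValueError("alignment has no countable symbols")
    return counts / counts.sum()


def gtr_model(
    alphabet: str,
    exchangeabilities: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    gamma_shape: float | None = None,
    n_categories: int = 5,
    p_invariant: float = 0.0,
) -> SubstitutionModel:
    k = len(resolve(alphabet))
    if exchangeabilities is None:
        exchangeabilities = np.ones((k, k)) - np.eye(k)
    if freqs is None:
        freqs = np.full(k, 1.0 / k)
    return SubstitutionModel(
        alphabet, exchangeabilities, freqs, gamma_shape, n_categories, p_invariant,
        name=f"GTR({alphabet})",
    )


def jtt_model(
    freqs: np.ndarray | None = None,
    gamma_shape: float | None = None,
    n_categories: int = 5,
    p_invariant: float = 0.0,
) -> SubstitutionModel:
    """JTT, optionally +F (pass alignment-wide empirical frequencies)."""
    S, pi = jtt_exchangeabilities()
    if freqs is not None:
        pi = np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()
    return SubstitutionModel(
        "aa20", S, pi, gamma_shape, n_categories, p_invariant, name="JTT"
    )


# ----------------------------------------------------------------------
# Engine
# ----------------------------------------------------------------------

@dataclass
class SiteLogLikelihoods:
    topology_id: str
    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class SiteRates:
    values: np.ndarray  # posterior mean relative rate per site, data-wide mean 1
    flagged_all_missing: np.ndarray  # boolean per site


def _encode(alignment: Alignment, taxa: Sequence[str]) -> np.ndarray:
    index = {s: i for i, s in enumerate(resolve(alignment.alphabet))}
    rows = []
    for t in taxa:
        row = alignment.data[alignment.taxon_ids.index(t)]
        rows.append([index.get(ch, -1) for ch in row])
    return np.asarray(rows, dtype=np.int16)


class PruningEngine:
    """Pattern-compressed pruning likelihood for one alignment + topology.

    The engine holds the flattened tree; branch lengths live in
    ``self.arrays.edge_length`` and can be updated between calls.
    """

    def __init__(self, alignment: Alignment, tree: dendropy.Tree, model: SubstitutionModel):
        if set(t.label for t in tree.taxon_namespace) != set(alignment.taxon_ids):
            missing = set(t.label for t in tree.taxon_namespace) ^ set(alignment.taxon_ids)
            raise ValueError(f"tree/alignment taxon mismatch: {sorted(missing)}")
        self.model = model
        self.arrays: TreeArrays = to_arrays(tree)
        self.taxa = [self.arrays.leaf_taxon[i] for i in sorted(self.arrays.leaf_taxon)]
        X = _encode(alignment, self.taxa)
        patterns, inverse, counts = np.unique(
            X, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_taxa, P)
        self.pattern_of_site = inverse.ravel()
        self.pattern_counts = counts.astype(float)
        self.n_sites = X.shape[1]
        k = model.k
        # leaf partials, (n_leaves, P, k)
        leaf_ids = sorted(self.arrays.leaf_taxon)
        self.leaf_row = {nid: r for r, nid in enumerate(leaf_ids)}
        P = patterns.shape[1]
        onehot = np.zeros((len(leaf_ids), P, k))
        for r in range(len(leaf_ids)):
            obs = patterns[r]
            ok = obs >= 0
            onehot[r, ok, obs[ok]] = 1.0
            onehot[r, ~ok, :] = 1.0
        self.leaf_partials = onehot
        # invariant-class likelihood per pattern
        prod = onehot.prod(axis=0)  # (P, k)
        self.invariant_lik = prod @ model.equilibrium_freqs
        self._eig = model.eigen()

    def _trans(self, t: float, rates: np.ndarray) -> np.ndarray:
        w, V, Vinv = self._eig
        e = np.exp(np.outer(np.maximum(t, 0.0) * rates, w))
        P = np.einsum("ik,ck,kj->cij", V, e, Vinv)
        np.clip(P, 1e-300, None, out=P)
        return P

    def pattern_log_likelihoods(self) -> np.ndarray:
        """Log-likelihood per unique pattern under the current lengths."""
        ll_cat, logw, p_inv = self._per_category()
        terms = ll_cat + logw[:, None]
        if p_inv > 0:
            inv = np.log(np.maximum(self.invariant_lik, 1e-300)) + np.log(p_inv)
            terms = np.vstack([terms, inv[None, :]])
        return _logsumexp0(terms)

    def _all_edge_trans(self, rates: np.ndarray) -> np.ndarray:
        """P(t_e * r_c) for every node's parent edge: (n_nodes, nc, k, k)."""
        w, V, Vinv = self._eig
        t = np.maximum(self.arrays.edge_length, 0.0)
        e = np.exp(t[:, None, None] * rates[None, :, None] * w[None, None, :])
        P = np.einsum("ik,enk,kj->enij", V, e, Vinv)
        np.clip(P, 1e-300, None, out=P)
        return P

    def _per_category(self) -> tuple[np.ndarray, np.ndarray, float]:
        model = self.model
        rates, weights, p_inv = model.mixture()
        nc = len(rates)
        Pn = self.patterns.shape[1]
        k = model.k
        arr = self.arrays
        P_all = self._all_edge_trans(rates)
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros((nc, Pn))
        for node in arr.postorder:
            node = int(node)
            if node in arr.leaf_taxon:
                continue
            L = None
            for ch in arr.children[node]:
                M = P_all[ch]  # (nc,k,k)
                if ch in arr.leaf_taxon:
                    # leaf message by direct gather: m[c,p,i] = P[c,i,obs_p]
                    obs = self.patterns[self.leaf_row[ch]]
                    msg = M[:, :, np.where(obs >= 0, obs, 0)].transpose(0, 2, 1)
                    if (obs < 0).any():
                        msg = msg.copy()
                        msg[:, obs < 0, :] = 1.0
                else:
                    msg = np.matmul(partials.pop(ch), M.transpose(0, 2, 1))
                L = msg if L is None else L * msg
            # rescale only when numbers get genuinely small
            if L.min() < 1e-220:
                s = np.maximum(L.max(axis=2), 1e-300)
                L = L / s[:, :, None]
                logscale = logscale + np.log(s)
            partials[node] = L
        root = arr.root
        site_lik = partials[root] @ model.equilibrium_freqs  # (nc, Pn)
        ll_cat = np.log(np.maximum(site_lik, 1e-300)) + logscale
        return ll_cat, np.log(np.maximum(weights, 1e-300)), p_inv

    def log_likelihood(self) -> float:
        return float(self.pattern_log_likelihoods() @ self.pattern_counts)

    def site_log_likelihoods(self, topology_id: str = "") -> SiteLogLikelihoods:
        per_pattern = self.pattern_log_likelihoods()
        return SiteLogLikelihoods(topology_id, per_pattern[self.pattern_of_site])

    # -- branch-length optimisation ------------------------------------
    def optimize_branch_lengths(
        self,
        tol: float = 1e-6,
        max_sweeps: int = 20,
        edges: Iterable[int] | None = None,
        maxiter: int = 40,
        xatol: float = 1e-7,
    ) -> float:
        """Coordinate-wise Brent optimisation; lnL never decreases.

        ``edges`` restricts optimisation to the given node ids (branch
        above each).  Returns the final log-likelihood.
        """
        arr = self.arrays
        edge_ids = [int(i) for i in (edges if edges is not None else range(arr.n_nodes))
                    if arr.parent[int(i)] >= 0]
        current = self.log_likelihood()
        for _ in range(max_sweeps):
            start = current
            for e in edge_ids:
                t0 = arr.edge_length[e]

                def neg(t, _e=e):
                    arr.edge_length[_e] = t
                    return -self.log_likelihood()

                t_best, neg_best = _optimize_scalar_log(
                    neg, t0, maxiter, xatol_log=1e-4 if xatol < 1e-5 else 1e-3
                )
                if -neg_best > current:
                    arr.edge_length[e] = t_best
                    current = -neg_best
                else:
                    arr.edge_length[e] = t0
            if current - start < tol:
                break
        return current

    def tree_with_lengths(self) -> dendropy.Tree:
        return self.arrays.write_back()

    # -- fast approximate sweeps (inside-outside caching) ---------------
    def _edge_caches(self, rates: np.ndarray):
        """Below-partials and outside-partials per edge at current lengths.

        For edge (u -> c): lik(t) = sum_i W_c(i) sum_j P_t(i,j) L_c(j),
        where L_c is the partial below c and W_c collects everything
        outside c's subtree expressed as a function of u's state.
        Returns dicts keyed by child node id, with per-category log
        scaling factors.
        """
        arr = self.arrays
        nc = len(rates)
        Pn = self.patterns.shape[1]
        k = self.model.k
        P_all = self._all_edge_trans(rates)
        L: dict[int, np.ndarray] = {}
        lsL: dict[int, np.ndarray] = {}
        msg: dict[int, np.ndarray] = {}
        for node in arr.postorder:
            node = int(node)
            if node in arr.leaf_taxon:
                Lv = np.broadcast_to(
                    self.leaf_partials[self.leaf_row[node]], (nc, Pn, k)
                ).copy()
                ls = np.zeros((nc, Pn))
            else:
                Lv = np.ones((nc, Pn, k))
                ls = np.zeros((nc, Pn))
                for ch in arr.children[node]:
                    Lv = Lv * msg[ch]
                    ls = ls + lsL[ch]
                if Lv.min() < 1e-220:
                    s = np.maximum(Lv.max(axis=2), 1e-300)
                    Lv = Lv / s[:, :, None]
                    ls = ls + np.log(s)
            L[node] = Lv
            lsL[node] = ls
            if arr.parent[node] >= 0:
                msg[node] = np.matmul(Lv, P_all[node].transpose(0, 2, 1))
        # outside pass
        W: dict[int, np.ndarray] = {}
        lsW: dict[int, np.ndarray] = {}
        U: dict[int, np.ndarray] = {
            arr.root: np.broadcast_to(
                self.model.equilibrium_freqs, (nc, Pn, k)
            ).copy()
        }
        lsU: dict[int, np.ndarray] = {arr.root: np.zeros((nc, Pn))}
        for node in arr.postorder[::-1]:
            node = int(node)
            if node in arr.leaf_taxon:
                continue
            for c in arr.children[node]:
                Wc = U[node].copy()
                ls = lsU[node].copy()
                for s in arr.children[node]:
                    if s == c:
                        continue
                    Wc = Wc * msg[s]
                    ls = ls + lsL[s]
                if Wc.min() < 1e-220:
                    sc = np.maximum(Wc.max(axis=2), 1e-300)
                    Wc = Wc / sc[:, :, None]
                    ls = ls + np.log(sc)
                W[c] = Wc
                lsW[c] = ls
                if c not in arr.leaf_taxon:
                    U[c] = np.matmul(Wc, P_all[c])
                    lsU[c] = ls
        return L, lsL, W, lsW

    def _edge_loglik(self, L_c, lsL_c, W_c, lsW_c, t: float, rates, logw):
        w, V, Vinv = self._eig
        e = np.exp(np.outer(np.maximum(t, 0.0) * rates, w))
        P = np.einsum("ik,ck,kj->cij", V, e, Vinv)
        np.clip(P, 1e-300, None, out=P)
        tmp = np.matmul(L_c, P.transpose(0, 2, 1))  # (nc,P,k) as function of i
        lik = (W_c * tmp).sum(axis=2)
        ll = np.log(np.maximum(lik, 1e-300)) + lsL_c + lsW_c + logw[:, None]
        return float(_logsumexp0(ll) @ self.pattern_counts)

    def fast_length_sweeps(
        self, n_sweeps: int = 2, maxiter: int = 8, xatol: float = 1e-4
    ) -> float:
        """Approximate branch-length sweeps using cached outside partials.

        Caches are rebuilt once per sweep; within a sweep each edge is
        optimised against caches computed at sweep start, so the result
        is a refinement heuristic rather than an exact coordinate ascent
        (valid for models without an invariant class).  Returns the
        exact final log-likelihood.
        """
        if self.model.p_invariant > 0:
            return self.optimize_branch_lengths(
                max_sweeps=n_sweeps, maxiter=maxiter, xatol=xatol
            )
        arr = self.arrays
        model = self.model
        rates, weights, _ = model.mixture()
        logw = np.log(np.maximum(weights, 1e-300))
        nc = len(rates)
        Pn = self.patterns.shape[1]
        k = model.k
        w_eig, V, Vinv = self._eig

        def trans(t):
            e = np.exp(np.outer(np.maximum(t, 0.0) * rates, w_eig))
            P = np.einsum("ik,ck,kj->cij", V, e, Vinv)
            np.clip(P, 1e-300, None, out=P)
            return P

        best = self.log_likelihood()
        best_lengths = arr.edge_length.copy()
        for _ in range(n_sweeps):
            # below partials and messages at current lengths
            L: dict[int, np.ndarray] = {}
            lsL: dict[int, np.ndarray] = {}
            msg: dict[int, np.ndarray] = {}

            def below(v: int):
                if v in arr.leaf_taxon:
                    Lv = np.broadcast_to(
                        self.leaf_partials[self.leaf_row[v]], (nc, Pn, k)
                    ).copy()
                    ls = np.zeros((nc, Pn))
                else:
                    Lv = np.ones((nc, Pn, k))
                    ls = np.zeros((nc, Pn))
                    for ch in arr.children[v]:
                        Lv = Lv * msg[ch]
                        ls = ls + lsL[ch]
                    if Lv.min() < 1e-220:
                        s = np.maximum(Lv.max(axis=2), 1e-300)
                        Lv = Lv / s[:, :, None]
                        ls = ls + np.log(s)
                L[v] = Lv
                lsL[v] = ls

            for v in arr.postorder:
                v = int(v)
                below(v)
                if arr.parent[v] >= 0:
                    msg[v] = np.matmul(L[v], trans(arr.edge_length[v]).transpose(0, 2, 1))

            # one Gauss-Seidel pass: optimise each edge against up-to-date
            # messages; refresh the child's message immediately
            def visit(u: int, U_u: np.ndarray, lsU_u: np.ndarray):
                for c in arr.children[u]:
                    if c not in arr.leaf_taxon:
                        Wc = U_u.copy()
                        ls = lsU_u.copy()
                        for s in arr.children[u]:
                            if s != c:
                                Wc = Wc * msg[s]
                                ls = ls + lsL[s]
                        U_c = np.matmul(Wc, trans(arr.edge_length[c]))
                        visit(c, U_c, ls)
                        below(c)  # refresh from updated child messages
                    Wc = U_u.copy()
                    ls = lsU_u.copy()
                    for s in arr.children[u]:
                        if s != c:
                            Wc = Wc * msg[s]
                            ls = ls + lsL[s]
                    if Wc.min() < 1e-220:
                        sc = np.maximum(Wc.max(axis=2), 1e-300)
                        Wc = Wc / sc[:, :, None]
                        ls = ls + np.log(sc)

                    def neg(t, _W=Wc, _lsW=ls, _c=c):
                        return -self._edge_loglik(
                            L[_c], lsL[_c], _W, _lsW, t, rates, logw
                        )

                    t_best, neg_best = _optimize_scalar_log(
                        neg, arr.edge_length[c], maxiter
                    )
                    if -neg_best >= -neg(arr.edge_length[c]):
                        arr.edge_length[c] = t_best
                    msg[c] = np.matmul(
                        L[c], trans(arr.edge_length[c]).transpose(0, 2, 1)
                    )

            root = arr.root
            visit(
                root,
                np.broadcast_to(model.equilibrium_freqs, (nc, Pn, k)).copy(),
                np.zeros((nc, Pn)),
            )
            lnl = self.log_likelihood()
            if lnl > best + 1e-9:
                best = lnl
                best_lengths = arr.edge_length.copy()
            else:
                break
        arr.edge_length[:] = best_lengths
        return best


def site_log_likelihoods(
    alignment: Alignment, tree: dendropy.Tree, model: SubstitutionModel,
    topology_id: str = "",
) -> SiteLogLikelihoods:
    """Per-site log-likelihoods on a fixed tree (no optimisation)."""
    return PruningEngine(alignment, tree, model).site_log_likelihoods(topology_id)


def optimize_branch_lengths(
    alignment: Alignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> tuple[dendropy.Tree, float]:
    eng = PruningEngine(alignment, tree, model)
    lnl = eng.optimize_branch_lengths(tol=tol, max_sweeps=max_sweeps)
    return eng.tree_with_lengths(), lnl


# ----------------------------------------------------------------------
# Model fitting
# ----------------------------------------------------------------------

def _parse_family(family: str) -> tuple[str, bool, bool, bool]:
    parts = family.upper().split("+")
    base = parts[0]
    if base not in ("GTR", "JTT"):
        raise ValueError(f"unsupported model family {family!r}")
    flags = set(parts[1:])
    return base, "G" in flags, "I" in flags, "F" in flags


def _n_free_exchange(k: int) -> int:
    return max(k * (k - 1) // 2 - 1, 0)


def fit_model(
    alignment: Alignment,
    tree: dendropy.Tree,
    model_family: str = "GTR+G+I+F",
    n_categories: int = 5,
    outer_rounds: int = 2,
    bl_sweeps: int = 2,
) -> tuple[SubstitutionModel, dendropy.Tree, float]:
    """ML fit of a model family on a fixed topology.

    Alternates branch-length sweeps with quasi-Newton optimisation of the
    substitution parameters (free GTR exchangeabilities, gamma shape,
    invariant proportion).  Frequencies are empirical (+F); JTT without +F
    keeps its published frequencies.
    """
    base, has_g, has_i, has_f = _parse_family(model_family)
    k = len(resolve(alignment.alphabet))
    if base == "JTT" and alignment.alphabet != "aa20":
        raise ValueError("JTT applies to aa20 alignments only")
    if base == "JTT":
        freqs = empirical_frequencies(alignment, pseudocount=0.5) if has_f else None
        model = jtt_model(freqs, gamma_shape=1.0 if has_g else None,
                          n_categories=n_categories,
                          p_invariant=0.05 if has_i else 0.0)
        n_ex = 0
    else:
        freqs = empirical_frequencies(alignment, pseudocount=0.5)
        model = gtr_model(alignment.alphabet, None, freqs,
                          gamma_shape=1.0 if has_g else None,
                          n_categories=n_categories,
                          p_invariant=0.05 if has_i else 0.0)
        n_ex = _n_free_exchange(k)

    eng = PruningEngine(alignment, tree, model)

    def opt_bl() -> float:
        if eng.model.p_invariant == 0:
            return eng.fast_length_sweeps(max(bl_sweeps, 2))
        return eng.optimize_branch_lengths(max_sweeps=bl_sweeps, maxiter=16)

    def pack(m: SubstitutionModel) -> np.ndarray:
        theta = []
        if n_ex:
            iu = np.triu_indices(k, 1)
            ex = m.exchangeabilities[iu]
            theta.extend(np.log(ex[:-1] / ex[-1]))
        if has_g:
            theta.append(np.log(m.gamma_shape))
        if has_i:
            p = np.clip(m.p_invariant / 0.9, 1e-6, 1 - 1e-6)
            theta.append(np.log(p / (1 - p)))
        return np.array(theta)

    def unpack(theta: np.ndarray) -> SubstitutionModel:
        pos = 0
        m = model
        if n_ex:
            iu = np.triu_indices(k, 1)
            ex = np.ones(n_ex + 1)
            ex[:-1] = np.exp(np.clip(theta[pos : pos + n_ex], -12, 12))
            S = np.zeros((k, k))
            S[iu] = ex
            S = S + S.T
            m = replace(m, exchangeabilities=S)
            pos += n_ex
        if has_g:
            m = replace(m, gamma_shape=float(np.exp(np.clip(theta[pos], -6, 6))))
            pos += 1
        if has_i:
            z = np.clip(theta[pos], -12, 12)
            m = replace(m, p_invariant=float(1 / (1 + np.exp(-z)) * 0.9))
            pos += 1
        return m

    lnl = opt_bl()
    n_par = pack(model).size
    for _ in range(outer_rounds):
        if n_par:
            def neg(theta):
                eng.model = unpack(theta)
                eng._eig = eng.model.eigen()
                eng.invariant_lik = (
                    eng.leaf_partials.prod(axis=0) @ eng.model.equilibrium_freqs
                )
                return -eng.log_likelihood()

            res = minimize(neg, pack(eng.model), method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-5, "maxiter": 200 * n_par})
            eng.model = unpack(res.x)
            eng._eig = eng.model.eigen()
            eng.invariant_lik = (
                eng.leaf_partials.prod(axis=0) @ eng.model.equilibrium_freqs
            )
        lnl = opt_bl()
    model = eng.model
    model.name = model_family
    return model, eng.tree_with_lengths(), lnl


def n_free_parameters(model_family: str, alphabet: str, n_branches: int) -> int:
    base, has_g, has_i, has_f = _parse_family(model_family)
    k = len(resolve(alphabet))
    n = n_branches + int(has_g) + int(has_i)
    if base == "GTR":
        n += _n_free_exchange(k) + (k - 1)
    elif has_f:
        n += k - 1
    return n


def compare_models(
    alignment: Alignment, tree: dendropy.Tree, families: Sequence[str], **fit_kw
):
    """Fit each family and tabulate lnL / AIC / BIC."""
    import pandas as pd

    arr = to_arrays(tree)
    n_branches = int((arr.parent >= 0).sum())
    n_sites = alignment.n_columns
    rows = []
    for fam in families:
        _, _, lnl = fit_model(alignment, tree, fam, **fit_kw)
        p = n_free_parameters(fam, alignment.alphabet, n_branches)
        rows.append(
            {"family": fam, "lnL": lnl, "n_params": p,
             "AIC": 2 * p - 2 * lnl, "BIC": p * np.log(n_sites) - 2 * lnl}
        )
    return pd.DataFrame(rows).set_index("family")


# ----------------------------------------------------------------------
# Site rates and fast-site exclusion
# ----------------------------------------------------------------------

def posterior_site_rates(
    alignment: Alignment, tree: dendropy.Tree, model: SubstitutionModel
) -> SiteRates:
    """Posterior-mean relative rate per site, normalised to mean 1.

    ER_s = sum_c r_c P(c|s) with P(c|s) proportional to w_c L_s(c); the
    invariant class (rate 0) participates when p_invariant > 0.
    """
    eng = PruningEngine(alignment, tree, model)
    ll_cat, logw, p_inv = eng._per_category()
    rates, weights, _ = model.mixture()
    terms = ll_cat + logw[:, None]
    cat_rates = list(rates)
    if p_inv > 0:
        inv = np.log(np.maximum(eng.invariant_lik, 1e-300)) + np.log(p_inv)
        terms = np.vstack([terms, inv[None, :]])
        cat_rates.append(0.0)
    post = np.exp(terms - logsumexp(terms, axis=0, keepdims=True))
    er_pattern = np.array(cat_rates) @ post
    er = er_pattern[eng.pattern_of_site]
    all_missing = (eng.patterns < 0).all(axis=0)[eng.pattern_of_site]
    mean = er[~all_missing].mean() if (~all_missing).any() else 1.0
    er = er / mean
    return SiteRates(values=er, flagged_all_missing=all_missing)


def exclude_fast_sites(
    alignment: Alignment, site_rates: SiteRates, threshold: float
) -> tuple[Alignment, float]:
    """Drop sites with posterior mean rate strictly above the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    keep = site_rates.values <= threshold
    fraction = float(1.0 - keep.mean())
    return alignment.take_columns(np.nonzero(keep)[0]), fraction


# ----------------------------------------------------------------------
# NNI search
# ----------------------------------------------------------------------

def _nni_neighbours(tree: dendropy.Tree):
    """Yield NNI rearrangements of an unrooted (derooted) tree."""
    t0 = tree.clone(depth=1)
    t0.deroot()
    base = t0.as_string(schema="newick", unquoted_underscores=True)
    n_edges = sum(1 for _ in t0.preorder_internal_edge_iter(exclude_seed_edge=True))
    for edge_i in range(n_edges):
        for swap in (0, 1):
            t = dendropy.Tree.get(
                data=base, schema="newick", preserve_underscores=True
            )
            t.suppress_unifurcations()
            edges = list(t.preorder_internal_edge_iter(exclude_seed_edge=True))
            if edge_i >= len(edges):
                continue
            edge = edges[edge_i]
            head, tail = edge.head_node, edge.tail_node
            head_children = head.child_nodes()
            tail_others = [c for c in tail.child_nodes() if c is not head]
            if tail.parent_node is None and len(tail_others) < 1:
                continue
            if len(head_children) != 2 or not tail_others:
                continue
            a = head_children[swap]
            b = tail_others[0]
            head.remove_child(a)
            tail.remove_child(b)
            head.add_child(b)
            tail.add_child(a)
            yield t


def nni_search(
    alignment: Alignment,
    model: SubstitutionModel,
    start_tree: dendropy.Tree,
    tol: float = 1e-4,
    bl_sweeps: int = 3,
    max_rounds: int = 20,
) -> tuple[dendropy.Tree, float]:
    """Greedy NNI hill-climb with branch-length re-optimisation."""
    eng = PruningEngine(alignment, start_tree, model)
    best_lnl = eng.optimize_branch_lengths()
    best_tree = eng.tree_with_lengths()
    for _ in range(max_rounds):
        improved = False
        for cand in _nni_neighbours(best_tree):
            e = PruningEngine(alignment, cand, model)
            lnl = e.optimize_branch_lengths(max_sweeps=bl_sweeps)
            if lnl > best_lnl + tol:
                best_lnl, best_tree = lnl, e.tree_with_lengths()
                improved = True
                break
        if not improved:
            break
    eng = PruningEngine(alignment, best_tree, model)
    final_lnl = eng.optimize_branch_lengths()
    return eng.tree_with_lengths(), max(final_lnl, best_lnl)


# ----------------------------------------------------------------------
# Simulation under a fitted model (parametric bootstrap)
# ----------------------------------------------------------------------

def simulate_under_model(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    rng: np.random.Generator,
    taxa: Sequence[str] | None = None,
) -> Alignment:
    """Simulate a stationary alignment under (tree, model).

    Each site draws a rate category (invariant class included); states
    evolve from a root draw out of the equilibrium frequencies.
    """
    arr = to_arrays(tree)
    symbols = resolve(model.alphabet)
    k = model.k
    rates, weights, p_inv = model.mixture()
    cat_rates = np.concatenate([rates, [0.0]]) if p_inv > 0 else rates
    cat_w = np.concatenate([weights, [p_inv]]) if p_inv > 0 else weights
    cat = rng.choice(len(cat_rates), size=n_sites, p=cat_w / cat_w.sum())
    pi = model.equilibrium_freqs
    states = {arr.root: rng.choice(k, size=n_sites, p=pi)}
    order = list(arr.postorder[::-1])
    for node in order:
        node = int(node)
        if node == arr.root:
            continue
        parent_states = states[arr.parent[node]]
        P = model.transition_matrices(arr.edge_length[node], cat_rates)
        # P[c] rows: cumulative sampling per site
        probs = P[cat, parent_states, :]  # (n_sites, k)
        u = rng.random(n_sites)
        states[node] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(0, k - 1)
    out_rows = {}
    for nid, taxon in arr.leaf_taxon.items():
        out_rows[taxon] = "".join(symbols[s] for s in states[nid])
    taxa = list(taxa) if taxa else sorted(out_rows)
    return Alignment(taxa, [out_rows[t] for t in taxa], model.alphabet)
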
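"""HKY85 + discrete-gamma likelihood on a fixed topology (Felsenstein pruning).

Branch lengths are in expected substitutions per site. Rate variation across
sites uses a discrete gamma with category MEDIANS (renormalised to mean 1).
`ml_fit` maximises the likelihood over branch lengths (and optionally kappa
and alpha) by bounded quasi-Newton optimisation and converts the fitted
root-to-tip distances to clade ages with the same transition clock used for
rho dating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .tree import MutationTree, Node

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_TI_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def hky_rate_matrix(kappa: float, freqs: Sequence[float]) -> np.ndarray:
    """HKY85 rate matrix normalised to one expected substitution per unit time."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = kappa * pi[j] if _TI_PARTNER[i] == j else pi[j]
    Q[np.diag_indices(4)] = -Q.sum(axis=1)
    scale = -np.dot(pi, np.diag(Q))
    return Q / scale


@dataclass(frozen=True)
class HkyEigen:
    """Eigendecomposition of the HKY rate matrix for fast matrix exponentials."""

    U: np.ndarray
    Uinv: np.ndarray
    lam: np.ndarray

    def transition_matrix(self, t: float | np.ndarray) -> np.ndarray:
        """P(t) = U exp(lam t) U^-1; broadcasts over an array of t."""
        t = np.asarray(t, dtype=float)
        expd = np.exp(np.multiply.outer(t, self.lam))  # (..., 4)
        return np.einsum("ij,...j,jk->...ik", self.U, expd, self.Uinv)


def hky_eigen(kappa: float, freqs: Sequence[float]) -> HkyEigen:
    pi = np.asarray(freqs, dtype=float)
    Q = hky_rate_matrix(kappa, pi)
    # symmetrise: S = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
    d = np.sqrt(pi)
    S = (Q * d[:, None]) / d[None, :]
    lam, V = np.linalg.eigh((S + S.T) / 2)
    U = V / d[:, None]
    Uinv = V.T * d[None, :]
    return HkyEigen(U, Uinv, lam)


def gamma_median_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Medians of equal-probability gamma(alpha, 1/alpha) slices, mean 1."""
    if n_categories == 1:
        return np.ones(1)
    q = (np.arange(n_categories) + 0.5) / n_categories
    rates = gamma_dist.ppf(q, alpha, scale=1.0 / alpha)
    return rates / rates.mean()


def compress_alignment(alignment: dict[str, str], tip_names: Sequence[str]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Site-pattern compression: (ntips x npatterns codes, pattern weights).

    Codes 0..3 are ACGT; 4 marks missing data (N or gap).
    """
    n_sites = len(next(iter(alignment.values())))
    mat = np.empty((len(tip_names), n_sites), dtype=np.int8)
    for r, name in enumerate(tip_names):
        seq = alignment[name].upper()
        if len(seq) != n_sites:
            raise ValueError(f"sequence {name!r} has inconsistent length")
        mat[r] = [_BASE_IDX.get(b, 4) for b in seq]
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return patterns, weights.astype(float)


class TreeLikelihood:
    """Pruning-algorithm likelihood for a fixed rooted topology."""

    def __init__(self, topology: MutationTree, alignment: dict[str, str],
                 freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)):
        self.nodes: list[Node] = list(topology.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [[self.index[id(c)] for c in n.children]
                         for n in self.nodes]
        self.tip_names = [n.name for n in self.nodes if n.is_tip]
        missing = [n for n in self.tip_names if n not in alignment]
        if missing:
            raise ValueError(f"alignment lacks sequences for tips {missing}")
        self.patterns, self.weights = compress_alignment(alignment, self.tip_names)
        self.n_sites = int(self.weights.sum())
        self.freqs = np.asarray(freqs, dtype=float)
        # tip partials including missing data (all-ones row)
        eye5 = np.vstack([np.eye(4), np.ones(4)])
        tip_row = {name: r for r, name in enumerate(self.tip_names)}
        self.tip_partials = {}
        for i, n in enumerate(self.nodes):
            if n.is_tip:
                codes = self.patterns[tip_row[n.name]]
                self.tip_partials[i] = eye5[codes]  # (npat, 4)
        self.n_branches = len(self.nodes) - 1  # every node but the root

    def branch_vector_template(self) -> np.ndarray:
        return np.full(self.n_branches, 0.01)

    def site_log_likelihoods(self, branch_lengths: np.ndarray, kappa: float,
                             alpha: float = 1.0, n_categories: int = 1
                             ) -> np.ndarray:
        """Per-pattern log-likelihoods (before weighting)."""
        eig = hky_eigen(kappa, self.freqs)
        rates = gamma_median_rates(alpha, n_categories)
        npat = self.patterns.shape[1]
        site_lik = np.zeros(npat)
        for rate in rates:
            partials: list[Optional[np.ndarray]] = [None] * len(self.nodes)
            b = 0
            P = {}
            for i, n in enumerate(self.nodes):
                if n is not self.nodes[-1]:  # root is last in postorder
                    P[i] = eig.transition_matrix(branch_lengths[b] * rate)
                    b += 1
            for i, n in enumerate(self.nodes):
                if n.is_tip:
                    partials[i] = self.tip_partials[i]
                else:
                    part = np.ones((npat, 4))
                    for ci in self.children[i]:
                        part = part * (partials[ci] @ P[ci].T)
                    partials[i] = part
            site_lik += (partials[-1] @ self.freqs) / len(rates)
        return np.log(np.clip(site_lik, 1e-300, None))

    def loglik(self, branch_lengths: np.ndarray, kappa: float,
               alpha: float = 1.0, n_categories: int = 1) -> float:
        return float(self.site_log_likelihoods(
            branch_lengths, kappa, alpha, n_categories) @ self.weights)


def transition_fraction(kappa: float, freqs: Sequence[float]) -> float:
    """Fraction of substitutions that are transitions at HKY stationarity."""
    pa, pc, pg, pt = freqs
    ti = 2 * kappa * (pa * pg + pc * pt)
    tv = 2 * (pa + pg) * (pc + pt)
    return ti / (ti + tv)


@dataclass
class MLBranchFit:
    """Fitted branch lengths (expected substitutions/site, postorder without root)."""

    tree: MutationTree
    branch_lengths: np.ndarray
    kappa: float
    alpha: float
    n_categories: int
    loglik: float
    n_sites: int
    converged: bool
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)

    def node_distance(self, node: Node, ancestor: Node) -> float:
        """Fitted substitutions/site on the path ancestor -> node."""
        order = [n for n in self.tree.postorder()]
        idx = {id(n): i for i, n in enumerate(order)}
        d = 0.0
        cur = node
        while cur is not ancestor:
            d += self.branch_lengths[idx[id(cur)]]
            cur = cur.parent
        return d

    def clade_ages(self, clock, clades: Sequence[str]) -> dict[str, float]:
        """Mean root-to-tip fitted transition distance converted to years."""
        frac = transition_fraction(self.kappa, self.freqs)
        out = {}
        for clade in clades:
            node = self.tree.find(clade)
            tips = MutationTree(node).tips()
            dist = np.mean([self.node_distance(t, node) for t in tips])
            transitions = dist * self.n_sites * frac
            out[clade] = clock.to_years(transitions)
        return out


def ml_fit(topology: MutationTree, alignment: dict[str, str],
           mut_model=None, estimate_kappa: bool = True,
           estimate_alpha: bool = False, n_categories: Optional[int] = None,
           max_iter: int = 500) -> MLBranchFit:
    """Maximum-likelihood branch lengths under HKY + discrete gamma.

    The topology is fixed; branch lengths (and optionally kappa, alpha) are
    optimised by L-BFGS-B. Raises on non-convergence, carrying the
    best-so-far fit in the exception.
    """
    from .simulate import MutationModel  # default parameter source

    model = mut_model or MutationModel()
    ncat = n_categories if n_categories is not None else model.n_categories
    tl = TreeLikelihood(topology, alignment, model.base_freqs)
    nb = tl.n_branches

    k0, a0 = model.kappa, model.gamma_shape

    def unpack(x):
        bl = x[:nb]
        kappa = np.exp(x[nb]) if estimate_kappa else k0
        j = nb + int(estimate_kappa)
        alpha = np.exp(x[j]) if estimate_alpha else a0
        return bl, kappa, alpha

    def neg(x):
        bl, kappa, alpha = unpack(x)
        return -tl.loglik(bl, kappa, alpha, ncat)

    x0 = list(tl.branch_vector_template())
    bounds = [(0.0, 10.0)] * nb
    if estimate_kappa:
        x0.append(np.log(k0))
        bounds.append((np.log(0.05), np.log(500.0)))
    if estimate_alpha:
        x0.append(np.log(a0))
        bounds.append((np.log(0.01), np.log(100.0)))

    res = minimize(neg, np.array(x0), method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8})
    bl, kappa, alpha = unpack(res.x)
    fit = MLBranchFit(topology, np.array(bl), float(kappa), float(alpha),
                      ncat, -float(res.fun), tl.n_sites,
                      bool(res.success), tuple(model.base_freqs))
    if not res.success and res.status != 1:  # status 1 = maxiter reached cleanly
        err = RuntimeError(
            f"ML fit did not converge: {res.message} "
            f"(|grad| = {np.max(np.abs(res.jac)):.3g})"
        )
        err.best_fit = fit
        raise err
    return fit
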
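"""Numba-compiled inner loops for the relaxed-clock MCMC.

The fixed-topology sampler spends almost all its time updating partial
likelihoods along root-ward paths after single-parameter moves, so the whole
Metropolis loop lives here: HKY transition probabilities in closed form,
partial-likelihood updates restricted to the affected nodes, and the move
schedule (node heights, branch-rate multipliers, the lognormal rate sd,
kappa). Everything is float64; pattern counts are small enough that no
scaling is needed at mtDNA-like divergences.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# calibration prior form codes
SHIFTED_EXP = 0
TRUNC_NORMAL = 1


@njit(cache=True)
def hky_transition(P, t, kappa, pi):
    """Closed-form HKY P(t) written into the 4x4 array P (order ACGT)."""
    piR = pi[0] + pi[2]
    piY = pi[1] + pi[3]
    beta = 1.0 / (2.0 * kappa * (pi[0] * pi[2] + pi[1] * pi[3])
                  + 2.0 * piR * piY)
    e1 = np.exp(-beta * t)
    for j in range(4):
        Pj = piR if j % 2 == 0 else piY
        e2 = np.exp(-beta * t * (Pj * kappa + (1.0 - Pj)))
        for i in range(4):
            if i == j:
                P[i, j] = pi[j] + pi[j] * (1.0 / Pj - 1.0) * e1 \
                    + ((Pj - pi[j]) / Pj) * e2
            elif i % 2 == j % 2:  # same chemical class: transition
                P[i, j] = pi[j] + pi[j] * (1.0 / Pj - 1.0) * e1 \
                    - (pi[j] / Pj) * e2
            else:
                P[i, j] = pi[j] * (1.0 - e1)


@njit(cache=True)
def _fill_P(P, node, heights, parent, mult, mu, kappa, pi, cat_rates):
    """Refresh the per-category transition matrices of the edge above node."""
    dur = heights[parent[node]] - heights[node]
    bl = dur * mu * mult[node]
    if bl < 0.0:
        bl = 0.0
    for c in range(cat_rates.shape[0]):
        hky_transition(P[node, c], bl * cat_rates[c], kappa, pi)


@njit(cache=True)
def _update_node(partials, P, child1, child2, node, ncat, npat):
    c1 = child1[node]
    c2 = child2[node]
    for c in range(ncat):
        for p in range(npat):
            for i in range(4):
                s1 = 0.0
                s2 = 0.0
                for j in range(4):
                    s1 += P[c1, c, i, j] * partials[c1, c, p, j]
                    s2 += P[c2, c, i, j] * partials[c2, c, p, j]
                partials[node, c, p, i] = s1 * s2


@njit(cache=True)
def _update_path(partials, P, child1, child2, parent, node, ncat, npat):
    """Recompute partials from `node` up to the root (inclusive)."""
    cur = node
    while cur >= 0:
        if child1[cur] >= 0:
            _update_node(partials, P, child1, child2, cur, ncat, npat)
        cur = parent[cur]


@njit(cache=True)
def _root_loglik(partials, root, pi, weights, ncat, npat):
    ll = 0.0
    for p in range(npat):
        site = 0.0
        for c in range(ncat):
            s = 0.0
            for i in range(4):
                s += pi[i] * partials[root, c, p, i]
            site += s
        site /= ncat
        if site < 1e-300:
            site = 1e-300
        ll += weights[p] * np.log(site)
    return ll


@njit(cache=True)
def _calibration_logprior(heights, calib_node, calib_form, calib_a, calib_b):
    lp = 0.0
    for k in range(calib_node.shape[0]):
        x = heights[calib_node[k]]
        if calib_form[k] == SHIFTED_EXP:
            if x < calib_a[k]:
                return -np.inf
            lp += np.log(calib_b[k]) - calib_b[k] * (x - calib_a[k])
        else:  # truncated normal, lower bound 0 (norm. constant cancels in MH)
            if x < 0.0:
                return -np.inf
            z = (x - calib_a[k]) / calib_b[k]
            lp += -0.5 * z * z - np.log(calib_b[k]) \
                - 0.5 * np.log(2.0 * np.pi)
    return lp


@njit(cache=True)
def _coalescent_logprior(heights, child1, theta):
    """Constant-size coalescent density of the node heights.

    theta = haploid Ne x generation time, in years: with k lineages the
    coalescence hazard is k(k-1)/(2 theta) per year. Contemporaneous tips.
    """
    n = heights.shape[0]
    n_internal = 0
    for i in range(n):
        if child1[i] >= 0:
            n_internal += 1
    ev = np.empty(n_internal)
    j = 0
    for i in range(n):
        if child1[i] >= 0:
            ev[j] = heights[i]
            j += 1
    ev = np.sort(ev)
    n_tips = n - n_internal
    lp = 0.0
    prev = 0.0
    k = n_tips
    for j in range(n_internal):
        dt = ev[j] - prev
        lp += -k * (k - 1) / 2.0 * dt / theta - np.log(theta)
        prev = ev[j]
        k -= 1
    return lp


@njit(cache=True)
def _mult_logprior(mult, child1, parent, sigma):
    """iid lognormal(mean 1) density of branch-rate multipliers."""
    lp = 0.0
    mu_ln = -0.5 * sigma * sigma
    for i in range(mult.shape[0]):
        if parent[i] < 0:
            continue
        x = mult[i]
        z = (np.log(x) - mu_ln) / sigma
        lp += -0.5 * z * z - np.log(x * sigma) - 0.5 * np.log(2.0 * np.pi)
    return lp


@njit(cache=True)
def run_fixed_topology_mcmc(
    seed, iterations, thinning, burn_in,
    child1, child2, parent, postorder_internal,
    heights0, mult0, partials, weights, pi, cat_rates,
    mu, kappa0, sigma0, sample_kappa, sample_sigma, prior_only,
    calib_node, calib_form, calib_a, calib_b,
    track_nodes,
    height_window, mult_step, sigma_step, kappa_step,
    kappa_bounds, sigma_bounds,
    tree_prior, theta0,
):
    """Metropolis sampler over node heights, branch rates, sigma and kappa.

    ``tree_prior`` 0 = uniform on heights, 1 = constant-size coalescent
    with scale parameter theta (= Ne x generation time, years) sampled
    under a scale-invariant prior.

    Returns (ages, scalars, accept_counts): `ages` has one row per kept
    sample and one column per tracked node; `scalars` columns are
    (loglik, logprior, sigma, kappa, theta).
    """
    np.random.seed(seed)
    n = child1.shape[0]
    ncat = cat_rates.shape[0]
    npat = weights.shape[0]
    root = postorder_internal[postorder_internal.shape[0] - 1]

    heights = heights0.copy()
    mult = mult0.copy()
    sigma = sigma0
    kappa = kappa0

    P = np.zeros((n, ncat, 4, 4))
    for i in range(n):
        if parent[i] >= 0:
            _fill_P(P, i, heights, parent, mult, mu, kappa, pi, cat_rates)
    for oi in range(postorder_internal.shape[0]):
        _update_node(partials, P, child1, child2, postorder_internal[oi],
                     ncat, npat)

    def_ll = 0.0
    cur_ll = def_ll if prior_only else _root_loglik(
        partials, root, pi, weights, ncat, npat)
    cur_cal = _calibration_logprior(heights, calib_node, calib_form,
                                    calib_a, calib_b)
    theta = theta0
    cur_coal = _coalescent_logprior(heights, child1, theta) \
        if tree_prior == 1 else 0.0
    cur_mult = _mult_logprior(mult, child1, parent, sigma)
    # hyperpriors: exponential(mean 1/3) on the lognormal rate sd — large
    # rate variation must earn its place in the likelihood — and
    # log-uniform on kappa
    cur_hyper = -3.0 * sigma - (np.log(kappa) if sample_kappa else 0.0)

    n_kept = (iterations - burn_in) // thinning
    ages = np.zeros((n_kept, track_nodes.shape[0]))
    scalars = np.zeros((n_kept, 5))
    accepts = np.zeros(5, dtype=np.int64)
    proposals = np.zeros(5, dtype=np.int64)

    n_internal = postorder_internal.shape[0]
    kept = 0
    for it in range(iterations):
        u = np.random.random()
        if u < 0.5:
            move = 0
        elif u < 0.75:
            move = 1
        elif u < 0.85 and sample_sigma:
            move = 2
        elif u < 0.93 and sample_kappa:
            move = 3
        elif tree_prior == 1:
            move = 4
        else:
            move = 0
        proposals[move] += 1

        if move == 0:
            v = postorder_internal[np.random.randint(n_internal)]
            lo = heights[child1[v]]
            if heights[child2[v]] > lo:
                lo = heights[child2[v]]
            old = heights[v]
            log_h = 0.0
            if parent[v] >= 0:
                hi = heights[parent[v]]
                if hi <= lo:
                    continue
                new = lo + np.random.random() * (hi - lo)
            else:
                new = old * np.exp((np.random.random() - 0.5) * height_window)
                if new <= lo:
                    continue
                log_h = np.log(new / old)
            heights[v] = new
            new_cal = _calibration_logprior(heights, calib_node, calib_form,
                                            calib_a, calib_b)
            new_coal = _coalescent_logprior(heights, child1, theta) \
                if tree_prior == 1 else 0.0
            if prior_only:
                new_ll = cur_ll
            else:
                _fill_P(P, child1[v], heights, parent, mult, mu, kappa, pi,
                        cat_rates)
                _fill_P(P, child2[v], heights, parent, mult, mu, kappa, pi,
                        cat_rates)
                if parent[v] >= 0:
                    _fill_P(P, v, heights, parent, mult, mu, kappa, pi,
                            cat_rates)
                _update_path(partials, P, child1, child2, parent, v,
                             ncat, npat)
                new_ll = _root_loglik(partials, root, pi, weights, ncat, npat)
            if np.log(np.random.random()) < (new_ll + new_cal + new_coal) \
                    - (cur_ll + cur_cal + cur_coal) + log_h:
                cur_ll = new_ll
                cur_cal = new_cal
                cur_coal = new_coal
                accepts[0] += 1
            else:
                heights[v] = old
                if not prior_only:
                    _fill_P(P, child1[v], heights, parent, mult, mu, kappa,
                            pi, cat_rates)
                    _fill_P(P, child2[v], heights, parent, mult, mu, kappa,
                            pi, cat_rates)
                    if parent[v] >= 0:
                        _fill_P(P, v, heights, parent, mult, mu, kappa, pi,
                                cat_rates)
                    _update_path(partials, P, child1, child2, parent, v,
                                 ncat, npat)
        elif move == 1:
            b = np.random.randint(n)
            while parent[b] < 0:
                b = np.random.randint(n)
            old = mult[b]
            new = old * np.exp(np.random.normal(0.0, mult_step))
            mult[b] = new
            new_mult_lp = _mult_logprior(mult, child1, parent, sigma)
            if prior_only:
                new_ll = cur_ll
            else:
                _fill_P(P, b, heights, parent, mult, mu, kappa, pi, cat_rates)
                start = parent[b]
                _update_path(partials, P, child1, child2, parent, start,
                             ncat, npat)
                new_ll = _root_loglik(partials, root, pi, weights, ncat, npat)
            log_h = np.log(new / old)
            if np.log(np.random.random()) < (new_ll + new_mult_lp) \
                    - (cur_ll + cur_mult) + log_h:
                cur_ll = new_ll
                cur_mult = new_mult_lp
                accepts[1] += 1
            else:
                mult[b] = old
                if not prior_only:
                    _fill_P(P, b, heights, parent, mult, mu, kappa, pi,
                            cat_rates)
                    _update_path(partials, P, child1, child2, parent,
                                 parent[b], ncat, npat)
        elif move == 2:
            old = sigma
            new = old * np.exp(np.random.normal(0.0, sigma_step))
            if new < sigma_bounds[0] or new > sigma_bounds[1]:
                continue
            new_mult_lp = _mult_logprior(mult, child1, parent, new)
            new_hyper = -3.0 * new - (np.log(kappa) if sample_kappa else 0.0)
            log_h = np.log(new / old)
            if np.log(np.random.random()) < (new_mult_lp + new_hyper) \
                    - (cur_mult + cur_hyper) + log_h:
                sigma = new
                cur_mult = new_mult_lp
                cur_hyper = new_hyper
                accepts[2] += 1
        elif move == 4:
            old = theta
            new = old * np.exp(np.random.normal(0.0, 0.3))
            new_coal = _coalescent_logprior(heights, child1, new)
            # scale-invariant prior 1/theta; log-scale walk Hastings
            log_h = np.log(new / old)
            if np.log(np.random.random()) < (new_coal - np.log(new)) \
                    - (cur_coal - np.log(old)) + log_h:
                theta = new
                cur_coal = new_coal
                accepts[4] += 1
        else:
            old = kappa
            new = old * np.exp(np.random.normal(0.0, kappa_step))
            if new < kappa_bounds[0] or new > kappa_bounds[1]:
                continue
            if prior_only:
                new_ll = cur_ll
            else:
                for i in range(n):
                    if parent[i] >= 0:
                        _fill_P(P, i, heights, parent, mult, mu, new, pi,
                                cat_rates)
                for oi in range(n_internal):
                    _update_node(partials, P, child1, child2,
                                 postorder_internal[oi], ncat, npat)
                new_ll = _root_loglik(partials, root, pi, weights, ncat, npat)
            new_hyper = -3.0 * sigma - np.log(new)
            log_h = np.log(new / old)
            if np.log(np.random.random()) < (new_ll + new_hyper) \
                    - (cur_ll + cur_hyper) + log_h:
                kappa = new
                cur_ll = new_ll
                cur_hyper = new_hyper
                accepts[3] += 1
            else:
                if not prior_only:
                    for i in range(n):
                        if parent[i] >= 0:
                            _fill_P(P, i, heights, parent, mult, mu, kappa,
                                    pi, cat_rates)
                    for oi in range(n_internal):
                        _update_node(partials, P, child1, child2,
                                     postorder_internal[oi], ncat, npat)

        if it >= burn_in and (it - burn_in) % thinning == 0 and kept < n_kept:
            for t in range(track_nodes.shape[0]):
                ages[kept, t] = heights[track_nodes[t]]
            scalars[kept, 0] = cur_ll
            scalars[kept, 1] = cur_cal + cur_mult + cur_hyper + cur_coal
            scalars[kept, 2] = sigma
            scalars[kept, 3] = kappa
            scalars[kept, 4] = theta
            kept += 1
    return ages, scalars, accepts, proposals
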
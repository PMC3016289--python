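"""Bayesian clade dating under an uncorrelated lognormal relaxed clock.

Node ages (years) of a rooted genealogy are sampled by Markov chain Monte
Carlo together with per-branch rate multipliers (iid lognormal with mean 1
and estimated sd), the HKY kappa, and internal calibration priors on named
clades: shifted-exponential priors built from a (mode, 95th percentile)
pair — zero density below the mode, mode at the offset — or zero-truncated
normal priors from a (centre, sd) pair. Hard monophyly constraints restrict
topology proposals; violating proposals are rejected outright.

Two samplers are provided: a numba-compiled fixed-topology sampler (heights
and rates only, mirroring dating on a hand-built tree) used for production
runs, and a pure-Python sampler supporting prior-only validation and
constraint-respecting topology moves for small problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import MutationTree, Node

log = logging.getLogger("mthaplo")


# ---------------------------------------------------------------------------
# calibration priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationPrior:
    """Prior on a named clade's age, in years."""

    clade: str
    form: str                      # "shifted_exponential" | "truncated_normal"
    a: float                       # offset (= mode) | centre
    b: float                       # rate (per year)  | sd
    note: str = ""

    def _dist(self):
        if self.form == "shifted_exponential":
            return stats.expon(loc=self.a, scale=1.0 / self.b)
        if self.form == "truncated_normal":
            return stats.truncnorm(-self.a / self.b, np.inf,
                                   loc=self.a, scale=self.b)
        raise ValueError(f"unknown prior form {self.form!r}")

    def logpdf(self, x: float) -> float:
        # closed forms (cheap enough for per-iteration MCMC use)
        if self.form == "shifted_exponential":
            if x < self.a:
                return -np.inf
            return float(np.log(self.b) - self.b * (x - self.a))
        if x < 0:
            return -np.inf
        z = (x - self.a) / self.b
        norm = stats.norm.sf(-self.a / self.b)
        return float(-0.5 * z * z - np.log(self.b)
                     - 0.5 * np.log(2 * np.pi) - np.log(norm))

    def pdf(self, x: float) -> float:
        lp = self.logpdf(x)
        return float(np.exp(lp)) if np.isfinite(lp) else 0.0

    def ppf(self, q: float) -> float:
        return float(self._dist().ppf(q))

    def sample(self, rng: np.random.Generator, size=None):
        if self.form == "shifted_exponential":
            return self.a + rng.exponential(1.0 / self.b, size=size)
        # rejection from the untruncated normal (centre well above 0 in
        # all realistic calibrations, so acceptance is near 1)
        if size is None:
            x = rng.normal(self.a, self.b)
            while x < 0:
                x = rng.normal(self.a, self.b)
            return x
        x = rng.normal(self.a, self.b, size=size)
        while np.any(x < 0):
            bad = x < 0
            x[bad] = rng.normal(self.a, self.b, size=int(bad.sum()))
        return x

    @property
    def mode(self) -> float:
        return self.a if self.form == "shifted_exponential" \
            else max(self.a, 0.0)


def prior_from_mode_p95(clade: str, mode: float, p95: float,
                        note: str = "") -> CalibrationPrior:
    """Shifted-exponential prior with density mode at ``mode`` (years) and
    95th percentile at ``p95``.

    The rate solves P(X <= p95) = 0.95 for X - mode ~ Exp(rate), i.e.
    rate = ln(20) / (p95 - mode); the density is zero below the mode and
    maximal at it, encoding a hard archaeological minimum age with an
    exponentially decaying tail.
    """
    if not p95 > mode >= 0:
        raise ValueError("need p95 > mode >= 0")
    rate = np.log(20.0) / (p95 - mode)
    return CalibrationPrior(clade, "shifted_exponential", mode, rate, note)


def truncated_normal_prior(clade: str, centre: float, sd: float,
                           note: str = "") -> CalibrationPrior:
    """Normal prior truncated at zero, centred on ``centre`` (years)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return CalibrationPrior(clade, "truncated_normal", centre, sd, note)


@dataclass(frozen=True)
class MonophylyConstraint:
    """A named set of tips that must form a clade in every sampled tree."""

    name: str
    tips: frozenset[str]


@dataclass(frozen=True)
class McmcSettings:
    iterations: int = 500_000
    thinning: int = 100
    burn_in: Optional[int] = None       # default: 10% of iterations
    seed: int = 1
    height_window: float = 0.4          # root scale-move log-width
    mult_step: float = 0.4
    sigma_step: float = 0.3
    kappa_step: float = 0.2

    @property
    def effective_burn_in(self) -> int:
        return self.burn_in if self.burn_in is not None \
            else self.iterations // 10

    def __post_init__(self):
        if self.effective_burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PosteriorTrace:
    """Thinned posterior samples; clade ages are columns ``age_<name>``."""

    samples: pd.DataFrame
    clades: tuple[str, ...]
    settings: McmcSettings
    acceptance: dict = field(default_factory=dict)

    def ages(self, clade: str) -> np.ndarray:
        col = f"age_{clade}"
        if col not in self.samples:
            raise KeyError(f"clade {clade!r} absent from trace")
        return self.samples[col].to_numpy()


def log_calibration_prior(ages: dict[str, float],
                          priors: Sequence[CalibrationPrior]) -> float:
    """Sum of calibration log-densities; -inf outside any prior's support."""
    lp = 0.0
    for pr in priors:
        if pr.clade not in ages:
            raise KeyError(f"no age supplied for calibrated clade {pr.clade!r}")
        lp += pr.logpdf(ages[pr.clade])
    return float(lp)


# ---------------------------------------------------------------------------
# tree indexing shared by both samplers
# ---------------------------------------------------------------------------

class _Indexed:
    """Array view of a timed binary topology (postorder, root last)."""

    def __init__(self, tree: MutationTree):
        self.nodes = list(tree.postorder())
        for n in self.nodes:
            if n.children and len(n.children) != 2:
                raise ValueError("the relaxed-clock samplers need a binary tree")
            if n.time is None:
                raise ValueError("every node needs a time (years BP)")
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.child1 = np.full(n, -1, dtype=np.int64)
        self.child2 = np.full(n, -1, dtype=np.int64)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.heights = np.zeros(n)
        for i, nd in enumerate(self.nodes):
            self.heights[i] = nd.time
            if nd.children:
                self.child1[i] = self.index[id(nd.children[0])]
                self.child2[i] = self.index[id(nd.children[1])]
            if nd.parent is not None:
                self.parent[i] = self.index[id(nd.parent)]
        self.postorder_internal = np.array(
            [i for i, nd in enumerate(self.nodes) if nd.children],
            dtype=np.int64)
        self.tip_names = [nd.name for nd in self.nodes if not nd.children]

    def mrca_index(self, tips: frozenset[str]) -> int:
        best = None
        for i, nd in enumerate(self.nodes):
            sub = frozenset(t.name for t in MutationTree(nd).tips())
            if tips <= sub and (best is None or
                                len(sub) < len(frozenset(
                                    t.name for t in MutationTree(self.nodes[best]).tips()))):
                best = i
        if best is None:
            raise KeyError(f"no MRCA found for tips {sorted(tips)}")
        return best

    def named_node_index(self, name: str) -> Optional[int]:
        for i, nd in enumerate(self.nodes):
            if nd.name == name:
                return i
        return None


def _resolve_clades(idx: _Indexed, priors, constraints,
                    extra_clades: Sequence[str]):
    """Map clade names to node indices (named node or constraint MRCA)."""
    con_by_name = {c.name: c for c in constraints}
    out: dict[str, int] = {}
    names = [p.clade for p in priors] + list(extra_clades) \
        + [c.name for c in constraints]
    for name in names:
        if name in out:
            continue
        i = idx.named_node_index(name)
        if i is None and name in con_by_name:
            i = idx.mrca_index(con_by_name[name].tips)
        if i is None:
            raise KeyError(f"cannot resolve clade {name!r} to a tree node")
        out[name] = i
    return out


# ---------------------------------------------------------------------------
# likelihood helpers (shared with tests)
# ---------------------------------------------------------------------------

def relaxed_clock_loglik(tree: MutationTree, branch_rates: dict | float,
                         alignment: dict[str, str], mut_model=None,
                         clock_rate_per_site: float = 1.0,
                         n_categories: int = 1) -> float:
    """Pruning likelihood with branch length = duration x rate multiplier.

    ``branch_rates`` maps node names (the node below each branch) to rate
    multipliers, or is a single scalar applied to all branches (the strict
    clock limit). Rates multiply the mean clock rate
    ``clock_rate_per_site`` (expected substitutions per site per year).
    """
    from .likelihood import TreeLikelihood
    from .simulate import MutationModel

    model = mut_model or MutationModel()
    tl = TreeLikelihood(tree, alignment, model.base_freqs)
    order = list(tree.postorder())
    bl = []
    for nd in order[:-1]:
        dur = nd.parent.time - nd.time
        r = branch_rates if np.isscalar(branch_rates) \
            else branch_rates.get(nd.name, 1.0)
        bl.append(dur * clock_rate_per_site * r)
    return tl.loglik(np.array(bl), model.kappa, model.gamma_shape,
                     n_categories)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def run_mcmc(topology: MutationTree,
             alignment: Optional[dict[str, str]],
             priors: Sequence[CalibrationPrior] = (),
             constraints: Sequence[MonophylyConstraint] = (),
             settings: Optional[McmcSettings] = None,
             mut_model=None,
             clock_rate_per_site: float = 1e-7,
             n_categories: int = 1,
             sample_kappa: bool = True,
             sample_sigma: bool = True,
             prior_only: bool = False,
             sample_topology: bool = False,
             tree_prior: str = "coalescent",
             track_clades: Sequence[str] = (),
             track_heights: bool = False) -> PosteriorTrace:
    """Sample the posterior of node ages (and clock parameters).

    ``topology`` must carry node times as the initial state. With
    ``prior_only`` the data term is switched off (the standard sampler
    validation: sampled calibrated ages must reproduce their priors).
    With ``sample_topology`` constraint-respecting exchange moves are
    enabled (pure-Python path, intended for small problems); otherwise the
    topology is fixed and the compiled sampler is used.
    """
    from .simulate import MutationModel

    settings = settings or McmcSettings()
    model = mut_model or MutationModel()
    idx = _Indexed(topology.copy())
    clade_nodes = _resolve_clades(idx, priors, constraints, track_clades)

    if sample_topology or (prior_only and alignment is None):
        return _run_python(idx, alignment, priors, constraints, settings,
                           model, clock_rate_per_site, n_categories,
                           prior_only, sample_topology, clade_nodes)
    if prior_only:
        return _run_python(idx, None, priors, constraints, settings,
                           model, clock_rate_per_site, n_categories,
                           True, False, clade_nodes)
    if track_heights:
        for i in idx.postorder_internal:
            clade_nodes.setdefault(f"h{i}", int(i))
    return _run_kernel(idx, alignment, priors, settings, model,
                       clock_rate_per_site, n_categories,
                       sample_kappa, sample_sigma, tree_prior, clade_nodes)


def _prior_arrays(priors, clade_nodes):
    from . import _kernels
    node = np.array([clade_nodes[p.clade] for p in priors], dtype=np.int64)
    form = np.array([_kernels.SHIFTED_EXP if p.form == "shifted_exponential"
                     else _kernels.TRUNC_NORMAL for p in priors],
                    dtype=np.int64)
    a = np.array([p.a for p in priors])
    b = np.array([p.b for p in priors])
    return node, form, a, b


def _run_kernel(idx, alignment, priors, settings, model,
                mu, ncat, sample_kappa, sample_sigma, tree_prior,
                clade_nodes):
    if tree_prior not in ("uniform", "coalescent"):
        raise ValueError("tree_prior must be 'uniform' or 'coalescent'")
    from . import _kernels
    from .likelihood import TreeLikelihood, gamma_median_rates

    tl = TreeLikelihood(MutationTree(idx.nodes[-1]), alignment,
                        model.base_freqs)
    npat = tl.patterns.shape[1]
    n = len(idx.nodes)
    partials = np.zeros((n, ncat, npat, 4))
    eye5 = np.vstack([np.eye(4), np.ones(4)])
    tip_row = {name: r for r, name in enumerate(tl.tip_names)}
    for i, nd in enumerate(idx.nodes):
        if not nd.children:
            codes = tl.patterns[tip_row[nd.name]]
            partials[i, :, :, :] = eye5[codes][None, :, :]

    cal_node, cal_form, cal_a, cal_b = _prior_arrays(priors, clade_nodes)
    track_names = sorted(clade_nodes)
    track_nodes = np.array([clade_nodes[c] for c in track_names],
                           dtype=np.int64)
    mult0 = np.ones(n)
    cat_rates = gamma_median_rates(model.gamma_shape, ncat)

    ages, scalars, accepts, proposals = _kernels.run_fixed_topology_mcmc(
        settings.seed, settings.iterations, settings.thinning,
        settings.effective_burn_in,
        idx.child1, idx.child2, idx.parent, idx.postorder_internal,
        idx.heights, mult0, partials, tl.weights,
        np.asarray(model.base_freqs, dtype=float), cat_rates,
        mu, model.kappa, 0.3, sample_kappa, sample_sigma, False,
        cal_node, cal_form, cal_a, cal_b, track_nodes,
        settings.height_window, settings.mult_step, settings.sigma_step,
        settings.kappa_step,
        np.array([0.05, 500.0]), np.array([1e-3, 5.0]),
        1 if tree_prior == "coalescent" else 0,
        float(np.mean(idx.heights[idx.postorder_internal])),
    )
    df = pd.DataFrame({
        "state": settings.effective_burn_in
        + settings.thinning * np.arange(len(scalars)),
        "log_likelihood": scalars[:, 0],
        "log_prior": scalars[:, 1],
        "sigma": scalars[:, 2],
        "kappa": scalars[:, 3],
        "theta": scalars[:, 4],
    })
    for j, name in enumerate(track_names):
        df[f"age_{name}"] = ages[:, j]
    move_names = ["height", "rate", "sigma", "kappa", "theta"]
    acc = {m: (int(a), int(p)) for m, a, p
           in zip(move_names, accepts, proposals)}
    for m, (a, p) in acc.items():
        if p > 200 and a == 0:
            log.warning("no accepted %s moves in %d proposals", m, p)
    return PosteriorTrace(df, tuple(track_names), settings, acc)


def _run_python(idx, alignment, priors, constraints, settings, model,
                mu, ncat, prior_only, sample_topology, clade_nodes):
    """Reference sampler: prior-only runs and topology sampling.

    Calibrated node heights use independence proposals from their own
    priors (acceptance then depends only on the remaining terms), which
    makes prior-only samples nearly independent — the property the
    prior-reproduction validation relies on.
    """
    rng = np.random.default_rng(settings.seed)
    heights = idx.heights.copy()
    child1, child2, parent = idx.child1.copy(), idx.child2.copy(), \
        idx.parent.copy()
    internal = list(idx.postorder_internal)
    prior_by_node = {clade_nodes[p.clade]: p for p in priors}
    con_tips = {c.name: c.tips for c in constraints}

    def tipset(i, c1, c2):
        if c1[i] < 0:
            return frozenset([idx.nodes[i].name] if i < len(idx.nodes)
                             else [])
        return tipset(c1[i], c1, c2) | tipset(c2[i], c1, c2)

    def loglik():
        if prior_only:
            return 0.0
        tree = _tree_from_arrays(idx, heights, child1, child2, parent)
        return relaxed_clock_loglik(tree, 1.0, alignment, model, mu, ncat)

    def ordering_ok(i):
        lo = max(heights[child1[i]], heights[child2[i]])
        hi = heights[parent[i]] if parent[i] >= 0 else np.inf
        return lo < heights[i] < hi

    def log_target_prior():
        """Calibration densities plus normalised conditional-uniform
        densities for uncalibrated internal nodes.

        The normalisation term -log(parent - max_child) makes the
        uncalibrated heights integrate out exactly, so calibrated clades'
        prior-only marginals reproduce their calibration priors.
        """
        lp = 0.0
        for i in internal:
            if not ordering_ok(i):
                return -np.inf
            pr = prior_by_node.get(i)
            if pr is not None:
                lp += pr.logpdf(heights[i])
            elif parent[i] >= 0:
                lo = max(heights[child1[i]], heights[child2[i]])
                lp += -np.log(heights[parent[i]] - lo)
        return lp

    cur_ll = loglik()
    cur_prior = log_target_prior()
    kept_rows = []
    burn = settings.effective_burn_in
    violations = 0
    for it in range(settings.iterations):
        if sample_topology and rng.random() < 0.2:
            ok = _try_exchange(rng, heights, child1, child2, parent,
                               internal, con_tips, idx)
            if ok is not None:
                new_ll = loglik()
                new_prior = log_target_prior()
                if np.log(rng.random()) < (new_ll + new_prior) \
                        - (cur_ll + cur_prior):
                    cur_ll, cur_prior = new_ll, new_prior
                else:
                    _undo_exchange(ok, child1, child2, parent)
                    cur_prior = log_target_prior()
            else:
                violations += 1
        else:
            # one systematic sweep over the internal nodes (random order)
            order = rng.permutation(len(internal))
            for oi in order:
                i = internal[oi]
                old = heights[i]
                pr = prior_by_node.get(i)
                if pr is not None:
                    new = float(pr.sample(rng))
                    log_h = pr.logpdf(old) - pr.logpdf(new)
                else:
                    lo = max(heights[child1[i]], heights[child2[i]])
                    hi = heights[parent[i]] if parent[i] >= 0 else old * 2.5
                    if hi <= lo:
                        continue
                    new = rng.uniform(lo, hi)
                    log_h = 0.0
                heights[i] = new
                if not ordering_ok(i):
                    heights[i] = old
                    continue
                new_prior = log_target_prior()
                new_ll = loglik() if not prior_only else cur_ll
                if np.log(rng.random()) < (new_ll + new_prior) \
                        - (cur_ll + cur_prior) + log_h:
                    cur_ll, cur_prior = new_ll, new_prior
                else:
                    heights[i] = old
        if it >= burn and (it - burn) % settings.thinning == 0:
            row = {"state": it, "log_likelihood": cur_ll,
                   "log_prior": sum(p.logpdf(heights[clade_nodes[p.clade]])
                                    for p in priors),
                   "sigma": np.nan, "kappa": model.kappa}
            for name, ni in clade_nodes.items():
                if sample_topology:
                    ni = _mrca_arrays(con_tips.get(name, None), name, idx,
                                      child1, child2, parent) or ni
                row[f"age_{name}"] = heights[ni]
            # record monophyly of every constraint in this sampled state
            for c in constraints:
                mono_node = _mrca_arrays(c.tips, c.name, idx, child1,
                                         child2, parent)
                row[f"mono_{c.name}"] = mono_node is not None
            kept_rows.append(row)
    df = pd.DataFrame(kept_rows)
    return PosteriorTrace(df, tuple(sorted(clade_nodes)), settings,
                          {"constraint_rejections": violations})


def _tree_from_arrays(idx, heights, child1, child2, parent) -> MutationTree:
    n = len(heights)
    nodes = [Node(idx.nodes[i].name if child1[i] < 0 else idx.nodes[i].name,
                  time=float(heights[i])) for i in range(n)]
    root = None
    for i in range(n):
        if parent[i] >= 0:
            nodes[parent[i]].add(nodes[i])
        else:
            root = nodes[i]
    t = MutationTree(root)
    t.set_lengths_from_times()
    return t


def _tips_below(i, child1, child2, idx):
    if child1[i] < 0:
        return frozenset([idx.nodes[i].name])
    return _tips_below(child1[i], child1, child2, idx) \
        | _tips_below(child2[i], child1, child2, idx)


def _mrca_arrays(tips, name, idx, child1, child2, parent):
    """Index of the node spanning exactly ``tips``, or None."""
    if tips is None:
        return None
    for i in range(len(child1)):
        if _tips_below(i, child1, child2, idx) == tips:
            return i
    return None


def _try_exchange(rng, heights, child1, child2, parent, internal,
                  con_tips, idx):
    """Narrow exchange: swap a node with its uncle when times permit.

    Returns an undo record, or None if the proposal violated a monophyly
    constraint or the time ordering (such proposals are rejected outright).
    """
    candidates = [i for i in internal if parent[i] >= 0]
    if not candidates:
        return None
    v = candidates[rng.integers(len(candidates))]
    p = parent[v]
    sib = child2[p] if child1[p] == v else child1[p]
    kids = [child1[v], child2[v]]
    c = kids[rng.integers(2)]
    # swap c (child of v) with sib (child of p)
    if heights[sib] >= heights[v]:
        return None
    undo = (v, p, c, sib, child1[v], child2[v], child1[p], child2[p])
    _apply_swap(v, p, c, sib, child1, child2, parent)
    for tips in con_tips.values():
        if _mrca_arrays(tips, "constraint", idx, child1, child2, parent) is None:
            _undo_exchange(undo, child1, child2, parent)
            return None
    return undo


def _apply_swap(v, p, c, sib, child1, child2, parent):
    if child1[v] == c:
        child1[v] = sib
    else:
        child2[v] = sib
    if child1[p] == sib:
        child1[p] = c
    else:
        child2[p] = c
    parent[c] = p
    parent[sib] = v


def _undo_exchange(undo, child1, child2, parent):
    v, p, c, sib, v1, v2, p1, p2 = undo
    child1[v], child2[v] = v1, v2
    child1[p], child2[p] = p1, p2
    parent[c] = v
    parent[sib] = p


def genealogies_from_trace(trace: PosteriorTrace, topology: MutationTree,
                           max_genealogies: int = 50) -> list[MutationTree]:
    """Rebuild sampled genealogies from a height-tracked trace.

    Requires the trace to have been run with ``track_heights=True`` (columns
    ``age_h<i>`` for every internal node of the fixed topology). Returns an
    evenly thinned subset, each a timed copy of the topology — input for
    skyline estimation from the dating posterior.
    """
    idx = _Indexed(topology.copy())
    cols = [c for c in trace.samples.columns if c.startswith("age_h")]
    if not cols:
        raise ValueError("trace lacks per-node height columns "
                         "(run with track_heights=True)")
    rows = np.linspace(0, len(trace.samples) - 1,
                       min(max_genealogies, len(trace.samples))).astype(int)
    out = []
    for r in rows:
        heights = idx.heights.copy()
        for c in cols:
            heights[int(c[5:])] = trace.samples[c].iloc[r]
        out.append(_tree_from_arrays(idx, heights, idx.child1, idx.child2,
                                     idx.parent))
    return out


def summarize_ages(trace: PosteriorTrace, clades: Sequence[str],
                   kind: str = "central") -> dict[str, tuple[float, float, float]]:
    """Posterior median and 95% interval per clade.

    ``kind`` selects the central (quantile) interval or the highest
    posterior density interval.
    """
    if len(trace.samples) == 0:
        raise ValueError("empty trace")
    out = {}
    for clade in clades:
        x = trace.ages(clade)
        med = float(np.median(x))
        if kind == "central":
            lo, hi = np.quantile(x, [0.025, 0.975])
        elif kind == "hpd":
            import arviz
            lo, hi = arviz.hdi(x, hdi_prob=0.95)
        else:
            raise ValueError("kind must be 'central' or 'hpd'")
        out[clade] = (med, float(lo), float(hi))
    return out
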
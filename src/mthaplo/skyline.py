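"""Bayesian skyline reconstruction of effective population size through time.

The skyline model partitions the coalescent events of one or more sampled
genealogies into ``m`` contiguous groups, each with its own constant haploid
effective size Ne; the coalescent likelihood in an interval with k lineages
has hazard k(k-1)/(2 Ne) per generation. Group sizes and boundaries are
sampled by Markov chain Monte Carlo under a smoothing prior in which each
group's Ne is exponentially distributed around the previous (older groups
shrink toward recent ones), and the posterior is summarised as a
piecewise-constant trajectory with pointwise median and 95% interval.

The classic (deterministic) skyline — the method-of-moments estimate
Ne = k(k-1) t / 2 per coalescent interval — is provided as an oracle and
sanity check for the Bayesian version.

All internal computation is in generations; summaries convert to years with
a configurable generation time (25 years by default) and annotate the most
recent time point with a calendar year for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tree import MutationTree


def coalescent_intervals(genealogy: MutationTree, generation_time: float = 25.0
                         ) -> list[tuple[int, float]]:
    """(lineage count, interval length in generations), tips -> root."""
    times = sorted(n.time for n in genealogy.preorder() if not n.is_tip)
    n_tips = genealogy.n_tips()
    out = []
    prev = 0.0
    k = n_tips
    for t in times:
        out.append((k, (t - prev) / generation_time))
        prev = t
        k -= 1
    return out


@dataclass
class SkylineModel:
    """m contiguous groups of coalescent events, each with constant Ne."""

    group_sizes: tuple[int, ...]      # events per group, tips -> root
    ne: tuple[float, ...]             # haploid Ne per group (generations units)

    def __post_init__(self):
        if len(self.group_sizes) != len(self.ne):
            raise ValueError("one Ne per group required")
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("each group must contain at least one event")
        if any(x <= 0 for x in self.ne):
            raise ValueError("Ne must be positive")

    @property
    def m(self) -> int:
        return len(self.ne)


def coalescent_loglik(genealogy: MutationTree, model: SkylineModel,
                      generation_time: float = 25.0) -> float:
    """Log-density of the genealogy under the piecewise-constant coalescent.

    Each coalescent interval with k lineages contributes
    -k(k-1)/(2 Ne) * t to the exponent plus log(k(k-1)/(2 Ne)) at its
    closing coalescence. For 2 tips and constant Ne this reduces to
    -t/Ne - ln(Ne).
    """
    intervals = coalescent_intervals(genealogy, generation_time)
    if sum(model.group_sizes) != len(intervals):
        raise ValueError("model groups do not cover the coalescent events")
    ll = 0.0
    idx = 0
    for g, ne in zip(model.group_sizes, model.ne):
        for _ in range(g):
            k, t = intervals[idx]
            rate = k * (k - 1) / (2.0 * ne)
            ll += -rate * t + np.log(rate)
            idx += 1
    return float(ll)


def classic_skyline(genealogy: MutationTree, generation_time: float = 25.0
                    ) -> list[tuple[float, float, int, float]]:
    """Per-interval moment estimates: (t_start, t_end, k, Ne_hat), generations.

    With k lineages over an interval of length t the estimate is
    Ne_hat = k(k-1) t / 2 (the inverse-hazard method of moments).
    """
    out = []
    start = 0.0
    for k, t in coalescent_intervals(genealogy, generation_time):
        out.append((start, start + t, k, k * (k - 1) * t / 2.0))
        start += t
    return out


# ---------------------------------------------------------------------------
# Bayesian skyline MCMC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkylineSettings:
    iterations: int = 30000
    thinning: int = 20
    burn_in_fraction: float = 0.1
    seed: int = 1
    ne_step: float = 0.5          # sd of log-scale random walk on group Ne
    ne_bounds: tuple[float, float] = (1e-2, 1e9)


@dataclass
class SkylinePosterior:
    """Sampled step functions: boundary times (generations) and group Ne."""

    boundary_times: list[np.ndarray]   # per sample, length m-1, increasing
    ne: list[np.ndarray]               # per sample, length m
    max_time: float                    # deepest root time (generations)
    generation_time: float

    def ne_at(self, sample_idx: int, t: float) -> float:
        b = self.boundary_times[sample_idx]
        g = int(np.searchsorted(b, t, side="right"))
        return float(self.ne[sample_idx][g])


def _pooled_structure(genealogies: Sequence[MutationTree],
                      generation_time: float):
    """Merge loci onto the pooled coalescent-event grid.

    Returns (event_times, per-segment lineage-pair time A_s); segment s ends
    at pooled event s, and exactly one coalescence closes each segment.
    """
    events = []
    per_locus = []
    for gl in genealogies:
        iv = coalescent_intervals(gl, generation_time)
        times = np.cumsum([t for _, t in iv])
        ks = [k for k, _ in iv]
        per_locus.append((np.concatenate([[0.0], times]), ks))
        events.extend(times)
    events = np.sort(np.asarray(events))
    seg_edges = np.concatenate([[0.0], events])
    A = np.zeros(len(events))
    for bounds, ks in per_locus:
        for i, k in enumerate(ks):
            lo, hi = bounds[i], bounds[i + 1]
            pair = k * (k - 1) / 2.0
            # overlap of locus interval with each pooled segment
            lo_clip = np.clip(seg_edges[:-1], lo, hi)
            hi_clip = np.clip(seg_edges[1:], lo, hi)
            A += pair * (hi_clip - lo_clip)
    return events, A


def sample_skyline(genealogies: MutationTree | Sequence[MutationTree],
                   m: int = 10,
                   settings: Optional[SkylineSettings] = None,
                   generation_time: float = 25.0) -> SkylinePosterior:
    """MCMC over group effective sizes and group boundaries.

    Accepts a single genealogy or several independent ones (replicate loci
    or posterior genealogy draws) sharing one demographic history; groups
    partition the POOLED coalescent events contiguously. The prior is
    scale-invariant on the first (most recent) group's Ne and exponential
    with mean Ne_g on each next older group (the standard skyline smoothing
    prior); boundaries are uniform over contiguous compositions.
    """
    if isinstance(genealogies, MutationTree):
        genealogies = [genealogies]
    settings = settings or SkylineSettings()
    rng = np.random.default_rng(settings.seed)
    events, A = _pooled_structure(genealogies, generation_time)
    E = len(events)
    if m > E:
        raise ValueError(f"m={m} exceeds the {E} pooled coalescent events")
    prefA = np.concatenate([[0.0], np.cumsum(A)])

    # cuts: indices in 1..E-1 splitting events into m contiguous groups
    cuts = np.linspace(0, E, m + 1).round().astype(int)
    cuts[0], cuts[-1] = 0, E
    for i in range(1, m + 1):  # enforce strictly increasing
        cuts[i] = max(cuts[i], cuts[i - 1] + 1)
    cuts[-1] = E
    ne = np.full(m, max(float(np.mean(A) * 2), 1.0))
    lo, hi = settings.ne_bounds

    def group_stats(c):
        a = prefA[c[1:]] - prefA[c[:-1]]
        k = np.diff(c).astype(float)
        return a, k

    def loglik(c, ne_vec):
        a, k = group_stats(c)
        return float(np.sum(-a / ne_vec - k * np.log(ne_vec)))

    def logprior(ne_vec):
        lp = -np.log(ne_vec[0])
        for g in range(1, m):
            lp += -np.log(ne_vec[g - 1]) - ne_vec[g] / ne_vec[g - 1]
        return float(lp)

    cur_ll = loglik(cuts, ne)
    cur_lp = logprior(ne)
    keep_b, keep_ne = [], []
    burn = int(settings.iterations * settings.burn_in_fraction)
    for it in range(settings.iterations):
        if m > 1 and rng.random() < 0.3:
            # move one interior cut uniformly between its neighbours
            j = int(rng.integers(1, m))
            lo_c, hi_c = cuts[j - 1] + 1, cuts[j + 1] - 1
            if hi_c >= lo_c:
                prop = cuts.copy()
                prop[j] = int(rng.integers(lo_c, hi_c + 1))
                new_ll = loglik(prop, ne)
                if np.log(rng.random()) < new_ll - cur_ll:
                    cuts, cur_ll = prop, new_ll
        else:
            g = int(rng.integers(0, m))
            prop_ne = ne.copy()
            prop_ne[g] = ne[g] * np.exp(rng.normal(0.0, settings.ne_step))
            if lo <= prop_ne[g] <= hi:
                new_ll = loglik(cuts, prop_ne)
                new_lp = logprior(prop_ne)
                # log-scale random walk: Hastings ratio = prop/cur
                log_h = np.log(prop_ne[g] / ne[g])
                if np.log(rng.random()) < (new_ll + new_lp) - (cur_ll + cur_lp) + log_h:
                    ne, cur_ll, cur_lp = prop_ne, new_ll, new_lp
        if it >= burn and (it - burn) % settings.thinning == 0:
            keep_b.append(events[cuts[1:-1] - 1] if m > 1 else np.empty(0))
            keep_ne.append(ne.copy())
    return SkylinePosterior(keep_b, keep_ne, float(events[-1]), generation_time)


@dataclass
class SkylineTrajectory:
    """Posterior Ne through time with a 95% envelope.

    Times are years before the most recent time point (annotated with a
    calendar year for plotting); Ne is in haploid individuals.
    """

    times_years: np.ndarray
    ne_median: np.ndarray
    ne_low: np.ndarray
    ne_high: np.ndarray
    generation_time: float
    most_recent_year: int
    interval_kind: str = "central"
    log_scale: bool = True  # conventional plotting scale for Ne

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_years": self.times_years,
            "ne_median": self.ne_median,
            "ne_low": self.ne_low,
            "ne_high": self.ne_high,
        })


def bsp_summarize(posterior: SkylinePosterior,
                  generation_time: Optional[float] = None,
                  most_recent_year: int = 1600,
                  n_grid: int = 101,
                  interval: str = "central") -> SkylineTrajectory:
    """Pointwise posterior median and 95% interval on a time grid.

    ``interval`` is "central" (2.5%-97.5% quantiles) or "hpd" (highest
    posterior density via arviz). The time axis is years before
    ``most_recent_year`` (sampling is treated as contemporaneous; the year
    anchors the axis annotation only).
    """
    gt = generation_time if generation_time is not None else posterior.generation_time
    grid_gen = np.linspace(0.0, posterior.max_time, n_grid)
    n_samp = len(posterior.ne)
    vals = np.empty((n_samp, n_grid))
    for s in range(n_samp):
        b = posterior.boundary_times[s]
        idx = np.searchsorted(b, grid_gen, side="right")
        vals[s] = posterior.ne[s][idx]
    med = np.median(vals, axis=0)
    if interval == "central":
        lo = np.quantile(vals, 0.025, axis=0)
        hi = np.quantile(vals, 0.975, axis=0)
    elif interval == "hpd":
        import arviz
        hdi = arviz.hdi(vals[None, :, :], hdi_prob=0.95)
        lo, hi = hdi[:, 0], hdi[:, 1]
    else:
        raise ValueError("interval must be 'central' or 'hpd'")
    return SkylineTrajectory(grid_gen * gt, med, lo, hi, gt,
                             most_recent_year, interval)
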
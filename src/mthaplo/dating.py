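"""Clade age estimation with the rho statistic and a transition clock.

rho is the mean number of mutations separating each sequence in a clade from
the clade's inferred ancestral haplotype (the clade root of a
:class:`~mthaplo.tree.MutationTree`); multiplied by the mutation rate it
estimates the clade's TMRCA. Its standard error is computed from the branch
structure (Saillard estimator): each branch contributes its mutation count
weighted by the squared fraction of clade tips descending through it.

The default clock is the complete-molecule transition clock of one
transition per 3,624 years, so rho and sigma count TRANSITIONS only
(transversions and indels are excluded and logged); a whole-substitution
mode is available for sensitivity analysis. Ages pass through a pluggable
monotone purifying-selection correction (identity by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .tree import MutationTree, Node
from .variants import VariantCall

log = logging.getLogger("mthaplo")

YEARS_PER_TRANSITION = 3624.0  # whole-molecule transition clock

CountMode = Literal["transitions", "substitutions"]


def _counter(mode: CountMode) -> Callable[[VariantCall], bool]:
    if mode == "transitions":
        return lambda v: v.is_transition
    if mode == "substitutions":
        return lambda v: v.is_substitution
    raise ValueError(f"unknown count mode {mode!r}")


def identity_correction(age: float) -> float:
    return age


def table_correction(uncorrected: Sequence[float], corrected: Sequence[float]
                     ) -> Callable[[float], float]:
    """Monotone (PCHIP) interpolation of a user-supplied correction table.

    The table maps uncorrected ages to corrected ages (both in years); it
    must be monotone non-decreasing. Outside the table range the correction
    extrapolates linearly from the end segments, and correction(0) = 0 is
    always enforced.
    """
    x = np.asarray(uncorrected, dtype=float)
    y = np.asarray(corrected, dtype=float)
    if np.any(np.diff(x) <= 0) or np.any(np.diff(y) < 0):
        raise ValueError("correction table must be monotone non-decreasing")
    if x[0] > 0:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[0.0], y])
    interp = PchipInterpolator(x, y, extrapolate=True)

    def corr(age: float) -> float:
        return float(max(interp(age), 0.0)) if age > 0 else 0.0

    return corr


@dataclass(frozen=True)
class MolecularClock:
    """Conversion from mutational distance to years."""

    years_per_transition: float = YEARS_PER_TRANSITION
    correction: Callable[[float], float] = identity_correction

    def __post_init__(self):
        if self.years_per_transition <= 0:
            raise ValueError("years_per_transition must be positive")

    def to_years(self, n_transitions: float) -> float:
        if n_transitions <= 0:
            return 0.0
        return self.correction(n_transitions * self.years_per_transition)


@dataclass(frozen=True)
class RhoEstimate:
    clade: str
    rho: float
    sigma: float
    n_tips: int
    age_years: float
    ci95: tuple[float, float]


def _clade_node(tree: MutationTree, clade: str | Node) -> Node:
    return clade if isinstance(clade, Node) else tree.find(clade)


def rho(tree: MutationTree, clade: str | Node = None,
        mode: CountMode = "transitions") -> float:
    """Mean mutation count from the clade root to each of its tips."""
    node = tree.root if clade is None else _clade_node(tree, clade)
    count = _counter(mode)
    tips = MutationTree(node).tips()
    if not tips:
        raise ValueError("clade has no tips")
    total = 0
    excluded = 0
    for tip in tips:
        path = tree.path_mutations(tip, ancestor=node)
        total += sum(1 for v in path if count(v))
        excluded += sum(1 for v in path if not count(v))
    if excluded:
        log.info("rho: excluded %d non-clock mutations in clade %s",
                 excluded, getattr(node, "name", "?"))
    return total / len(tips)


def saillard_sigma(tree: MutationTree, clade: str | Node = None,
                   mode: CountMode = "transitions") -> float:
    """Standard error of rho from the branch structure.

    sigma^2 = n^-2 * sum over branches within the clade of
    (number of clade tips descending through the branch)^2 times the
    branch's counted mutations. The clade's stem branch is outside the
    clade and does not contribute.
    """
    node = tree.root if clade is None else _clade_node(tree, clade)
    count = _counter(mode)
    sub = MutationTree(node)
    n = sub.n_tips()
    if n == 0:
        raise ValueError("clade has no tips")
    var = 0.0
    for b in sub.preorder():
        if b is node:
            continue  # stem mutations lie outside the clade
        n_below = len(MutationTree(b).tips())
        m = sum(1 for v in b.mutations if count(v))
        var += (n_below ** 2) * m
    return float(np.sqrt(var)) / n


def rho_age(rho_value: float, sigma: float, clock: Optional[MolecularClock] = None,
            clade: str = "clade", n_tips: int = 0) -> RhoEstimate:
    """Convert rho +/- 1.96 sigma to a corrected age with a 95% CI.

    The CI applies the correction to the endpoints (valid because the
    correction is monotone) and is floored at 0 years.
    """
    clock = clock or MolecularClock()
    age = clock.to_years(rho_value)
    lo = clock.to_years(max(rho_value - 1.96 * sigma, 0.0))
    hi = clock.to_years(rho_value + 1.96 * sigma)
    return RhoEstimate(clade, rho_value, sigma, n_tips, age, (lo, hi))


def date_clade(tree: MutationTree, clade: str | Node = None,
               clock: Optional[MolecularClock] = None,
               mode: CountMode = "transitions") -> RhoEstimate:
    """rho-date one clade of a mutation tree."""
    node = tree.root if clade is None else _clade_node(tree, clade)
    r = rho(tree, node, mode)
    s = saillard_sigma(tree, node, mode)
    name = node.name or "clade"
    return rho_age(r, s, clock, clade=name, n_tips=len(MutationTree(node).tips()))


def age_table(tree: MutationTree, clades: Sequence[str],
              clock: Optional[MolecularClock] = None,
              methods: Sequence[str] = ("rho",),
              alignment: Optional[dict] = None,
              mut_model=None,
              bayes_summary: Optional[dict] = None) -> pd.DataFrame:
    """Tabulate clade ages per method (one row per clade x method).

    Methods: "rho" (rho + Saillard CI), "ml" (maximum-likelihood branch
    fitting; needs the alignment), "bayesian" (imported posterior summaries
    keyed by clade: (median, lo, hi)). Rows are ordered as given, methods in
    the requested order; methods are labelled explicitly.
    """
    clock = clock or MolecularClock()
    rows = []
    ml_ages = None
    for clade in clades:
        tree.find(clade)  # raises KeyError for unknown clades
    for clade in clades:
        for method in methods:
            if method == "rho":
                est = date_clade(tree, clade, clock)
                rows.append({"clade": clade, "method": "rho",
                             "age_years": est.age_years,
                             "ci_low": est.ci95[0], "ci_high": est.ci95[1]})
            elif method == "ml":
                if ml_ages is None:
                    from .likelihood import ml_fit
                    if alignment is None:
                        raise ValueError("ML dating needs the alignment")
                    fit = ml_fit(tree, alignment, mut_model)
                    ml_ages = fit.clade_ages(clock, clades)
                age = ml_ages[clade]
                rows.append({"clade": clade, "method": "ml",
                             "age_years": age, "ci_low": np.nan,
                             "ci_high": np.nan})
            elif method == "bayesian":
                if bayes_summary is None or clade not in bayes_summary:
                    raise ValueError(f"no Bayesian summary for clade {clade!r}")
                med, lo, hi = bayes_summary[clade]
                rows.append({"clade": clade, "method": "bayesian",
                             "age_years": med, "ci_low": lo, "ci_high": hi})
            else:
                raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows, columns=["clade", "method", "age_years",
                                       "ci_low", "ci_high"])
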
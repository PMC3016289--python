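"""Synthetic data with known truth: genealogies, sequences, frequency tables.

The generator emulates the statistical structure of paired mtDNA haplogroup
datasets: two sister clades splitting at a known time, clade-structured
genealogies under piecewise-constant demography (haploid coalescent — mtDNA
is maternally inherited), sequences evolved under an HKY-type process with a
per-molecule transition clock and optional mutational hotspots, and
geographically structured haplogroup frequencies sampled binomially around a
true spatial cline.

Every operation takes a mandatory seed and draws from its own named stream,
so results are bit-reproducible and adding operations does not shift
existing expectations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import msprime
import numpy as np
import pandas as pd

from .tree import MutationTree, Node
from .variants import (
    ReferenceSequence,
    SequenceProfile,
    VariantCall,
    call_variants,
    substitution_class,
    transition_partner,
)

_STREAMS = {
    "coalescent": 1,
    "sequences": 2,
    "sister": 3,
    "frequency": 4,
    "demo": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant haploid effective size through time.

    ``epochs`` lists (start_time_years_before_present, Ne); the first epoch
    must start at 0 (the present) and times must strictly increase. Ne is the
    HAPLOID effective number (the natural unit for mtDNA).
    """

    epochs: tuple[tuple[float, float], ...] = ((0.0, 1000.0),)
    generation_time: float = 25.0

    def __post_init__(self):
        times = [t for t, _ in self.epochs]
        if times[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("epoch start times must strictly increase")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("Ne must be positive")

    def ne_at(self, years_bp: float) -> float:
        ne = self.epochs[0][1]
        for t, n in self.epochs:
            if years_bp >= t:
                ne = n
        return ne


@dataclass(frozen=True)
class MutationModel:
    """HKY-type mutation process with optional discrete-gamma rate variation.

    ``kappa`` is the transition/transversion rate ratio; ``gamma_shape`` the
    shape of the gamma distribution of relative site rates approximated by
    ``n_categories`` discrete categories (category medians); ``site_rates``
    optionally fixes explicit per-site multipliers (hotspots), normalised to
    mean 1 so the whole-molecule clock is preserved.
    """

    kappa: float = 22.0
    gamma_shape: float = 1.0
    n_categories: int = 32
    site_rates: Optional[tuple[float, ...]] = None
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.kappa <= 0 or self.gamma_shape <= 0:
            raise ValueError("kappa and gamma_shape must be positive")

    def normalised_site_rates(self, n_sites: int) -> np.ndarray:
        if self.site_rates is None:
            return np.ones(n_sites)
        r = np.asarray(self.site_rates, dtype=float)
        if len(r) != n_sites:
            raise ValueError("site_rates length does not match the reference")
        return r / r.mean()


def _demography(model: DemographicModel) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=model.epochs[0][1])
    for t_years, ne in model.epochs[1:]:
        dem.add_population_parameters_change(
            time=t_years / model.generation_time, initial_size=ne, population="pop"
        )
    return dem


def _tree_from_tskit(ts, generation_time: float, labels: Sequence[str]) -> MutationTree:
    t = ts.first()
    nodes: dict[int, Node] = {}

    def build(u: int) -> Node:
        node = Node(time=ts.nodes_time[u] * generation_time)
        if t.is_leaf(u):
            node.name = labels[u]
        for c in t.children(u):
            node.add(build(c))
        nodes[u] = node
        return node

    root = build(t.root)
    tree = MutationTree(root)
    tree.set_lengths_from_times()
    return tree


def simulate_coalescent(n_tips: int, model: DemographicModel, seed: int,
                        label_prefix: str = "t") -> MutationTree:
    """Simulate one haploid coalescent genealogy under piecewise-constant Ne.

    Node times are in years before present; tips are contemporaneous
    (time 0), so the genealogy is ultrametric. Backed by msprime.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(seed, "coalescent")
    ms_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n_tips, demography=_demography(model), ploidy=1,
        random_seed=ms_seed,
    )
    labels = [f"{label_prefix}{i + 1}" for i in range(n_tips)]
    return _tree_from_tskit(ts, model.generation_time, labels)


_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


def evolve_sequences(genealogy: MutationTree, reference: ReferenceSequence,
                     mut_model: MutationModel, clock_rate: float, seed: int,
                     ) -> tuple[dict[str, str], MutationTree]:
    """Drop mutations on branches as a Poisson process and return sequences.

    ``clock_rate`` is the expected number of TRANSITIONS per year summed over
    the whole molecule (e.g. 1/3624 for the complete-sequence transition
    clock). Transversions occur in addition, at total rate 2/kappa relative
    to transitions per site. Returns the tip sequences and a copy of the
    genealogy whose branches carry the true mutation lists (with back- and
    recurrent mutations recorded as they happened).
    """
    rng = _rng(seed, "sequences")
    tree = genealogy.copy()
    n_sites = len(reference)
    site_mult = mut_model.normalised_site_rates(n_sites)
    # per-site relative total event rate: transitions kappa, 2 transversions at 1 each
    kappa = mut_model.kappa
    total_rate = clock_rate * (kappa + 2.0) / kappa  # events/year, whole molecule
    site_p = site_mult / site_mult.sum()
    p_transition = kappa / (kappa + 2.0)

    seqs: dict[str, str] = {}

    def recurse(node: Node, state: np.ndarray):
        if node.parent is not None:
            duration = node.parent.time - node.time
            n_events = rng.poisson(total_rate * duration)
            muts: list[VariantCall] = []
            for _ in range(n_events):
                site = rng.choice(n_sites, p=site_p)
                old = _BASES[state[site]]
                if rng.random() < p_transition:
                    new = transition_partner(old)
                else:
                    choices = [b for b in _BASES
                               if b != old and substitution_class(old, b) == "transversion"]
                    new = choices[rng.integers(0, 2)]
                state[site] = _BASE_IDX[new]
                muts.append(VariantCall(site + 1, old, new,
                                        substitution_class(old, new)))
            node.mutations = muts
        if node.is_tip:
            seqs[node.name] = "".join(_BASES[i] for i in state)
        for c in node.children:
            recurse(c, state.copy())

    root_state = np.array([_BASE_IDX[b] for b in reference.bases])
    recurse(tree.root, root_state)
    return seqs, tree


@dataclass
class SisterDataset:
    """Two sister haplogroups with a known split time and full truth."""

    profiles: list[SequenceProfile]
    alignment: dict[str, str]
    true_tree: MutationTree          # mutation-annotated, timed
    split_time: float                # years BP
    clade_tmrcas: dict[str, float]   # years BP, keyed by clade name
    clade_tips: dict[str, list[str]]
    reference: ReferenceSequence


def make_sister_haplogroup_dataset(
    split_time: float,
    n_per_clade: int | tuple[int, int],
    demography_per_clade: DemographicModel | tuple[DemographicModel, DemographicModel],
    seed: int,
    reference: Optional[ReferenceSequence] = None,
    mut_model: Optional[MutationModel] = None,
    clock_rate: float = 1.0 / 3624.0,
    clade_names: tuple[str, str] = ("A", "B"),
) -> SisterDataset:
    """Generate two reciprocally monophyletic clades splitting at a known time.

    Each clade's genealogy is simulated under its own demography conditioned
    on its TMRCA being younger than the split (rejection sampling); the two
    clade ancestors are then joined at ``split_time``. Sequences evolve from
    the reference at the root.
    """
    if reference is None:
        from .variants import synthetic_reference
        reference = synthetic_reference(length=1000)
    if mut_model is None:
        mut_model = MutationModel()
    ns = n_per_clade if isinstance(n_per_clade, tuple) else (n_per_clade, n_per_clade)
    dems = (demography_per_clade if isinstance(demography_per_clade, tuple)
            else (demography_per_clade, demography_per_clade))
    rng = _rng(seed, "sister")

    root = Node("root", time=split_time)
    clade_tmrcas, clade_tips = {}, {}
    for name, n, dem in zip(clade_names, ns, dems):
        for _ in range(1000):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            clade = simulate_coalescent(n, dem, sub_seed, label_prefix=f"{name}_")
            if clade.root.time < split_time:
                break
        else:  # pragma: no cover - only under pathological parameters
            raise RuntimeError(
                f"could not draw a clade TMRCA younger than the split for {name}"
            )
        clade.root.name = name
        clade_tmrcas[name] = clade.root.time
        clade_tips[name] = [t.name for t in clade.tips()]
        root.add(clade.root)

    tree = MutationTree(root, name="sister")
    tree.set_lengths_from_times()
    seq_seed = int(rng.integers(0, 2**31 - 1))
    alignment, true_tree = evolve_sequences(tree, reference, mut_model,
                                            clock_rate, seq_seed)
    profiles = []
    for name in clade_names:
        for tip in clade_tips[name]:
            profiles.append(call_variants(alignment[tip], reference,
                                          sample_id=tip, haplogroup=name))
    return SisterDataset(profiles, alignment, true_tree, split_time,
                         clade_tmrcas, clade_tips, reference)


def make_frequency_sites(
    n_sites: int,
    gradient_spec: Callable[[float, float], float] | dict,
    seed: int,
    n_samples: int | tuple[int, int] = (20, 120),
    lon_range: tuple[float, float] = (-20.0, 40.0),
    lat_range: tuple[float, float] = (10.0, 45.0),
    haplogroup: str = "U6",
) -> pd.DataFrame:
    """Sample population sites with binomial counts around a true surface.

    ``gradient_spec`` is either a callable (lon, lat) -> true frequency in
    [0, 1], or a dict {"kind": "logistic_ew", "midpoint_lon": x0, "scale": s,
    "max_freq": f} describing an east-west logistic cline peaking in the west.
    Returns a tidy table (site, lon, lat, n, count, true_freq).
    """
    if isinstance(gradient_spec, dict):
        spec = dict(gradient_spec)
        if spec.pop("kind") != "logistic_ew":
            raise ValueError("unknown gradient kind")
        x0 = spec.get("midpoint_lon", 0.0)
        s = spec.get("scale", 10.0)
        fmax = spec.get("max_freq", 1.0)

        def true_freq(lon, lat):
            return fmax / (1.0 + np.exp((lon - x0) / s))
    else:
        true_freq = gradient_spec

    rng = _rng(seed, "frequency")
    rows = []
    for i in range(n_sites):
        lon = rng.uniform(*lon_range)
        lat = rng.uniform(*lat_range)
        n = (int(rng.integers(n_samples[0], n_samples[1] + 1))
             if isinstance(n_samples, tuple) else int(n_samples))
        f = float(np.clip(true_freq(lon, lat), 0.0, 1.0))
        count = int(rng.binomial(n, f))
        rows.append({"site": f"site{i + 1}", "lon": lon, "lat": lat,
                     "n": n, haplogroup: count, "true_freq": f})
    return pd.DataFrame(rows)
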
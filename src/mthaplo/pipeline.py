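"""End-to-end orchestration: profiles -> tree -> dating -> skyline -> maps.

Stages run in dependency order, each writing its artifacts into its own
subdirectory together with a marker recording the hash of the configuration
and of upstream markers; a stage re-runs only when that hash changes (or its
marker is deleted). All randomness derives from the master seed, so a run is
reproducible artifact-for-artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as mio
from .dating import MolecularClock, age_table
from .simulate import (DemographicModel, MutationModel,
                       make_frequency_sites, make_sister_haplogroup_dataset)
from .tree import assign_initial_times, resolve_polytomies
from .variants import ReferenceSequence, synthetic_reference

log = logging.getLogger("mthaplo")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "mthaplo_out",
    "data": {"demo": True, "reference_length": 1000},
    "network": {
        "hotspots": [16189, 16311],
        "hotspot_weight": 5.0,
        "default_weight": 10.0,
        "method": "mj",
        "constrain_haplogroups": True,
    },
    "dating": {
        "years_per_transition": 3624.0,
        "clades": None,           # default: the haplogroup labels
        "methods": ["rho"],
    },
    "bayes": {
        "enabled": True,
        "iterations": 50_000,
        "thinning": 50,
        "burn_in": None,
        "kappa": 22.0,
        "calibrations": [
            {"clade": "root", "form": "shifted_exponential",
             "mode": 45000.0, "p95": 60000.0},
        ],
    },
    "skyline": {"enabled": True, "m": 5, "iterations": 20000,
                "generation_time": 25.0, "most_recent_year": 1600},
    "map": {"enabled": True, "cellsize": 2.0, "n_sites": 25,
            "haplogroups": ["U6"], "power": 2.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    outdir: Path
    config_hash: str
    seed: int
    ages: Optional[pd.DataFrame] = None
    bayes_summary: Optional[dict] = None
    skyline_path: Optional[Path] = None
    map_paths: list[Path] = field(default_factory=list)
    stages_run: list[str] = field(default_factory=list)
    stages_cached: list[str] = field(default_factory=list)


class _Stage:
    def __init__(self, outdir: Path, name: str, config_part, upstream: str):
        self.dir = outdir / name
        self.name = name
        self.hash = _hash([config_part, upstream])
        self.marker = self.dir / "stage.json"

    @property
    def cached(self) -> bool:
        if not self.marker.exists():
            return False
        return json.loads(self.marker.read_text()).get("hash") == self.hash

    def done(self, **extra) -> None:
        payload = {"hash": self.hash, "stage": self.name, **extra}
        self.marker.write_text(json.dumps(payload, indent=1, default=str))


def make_demo_dataset(seed: int, outdir: Path,
                      reference_length: int = 1000):
    """A packaged-style synthetic fixture with U6/U5-like structure.

    Two sister haplogroups split 46 ka ago; clade "U6like" underwent a
    3-fold expansion 20 ka ago while "U5like" stayed constant; 20 genomes
    per clade on a toy reference, plus a geographic frequency table with a
    west-peaked cline. Writes FASTA, profile TSV, the true tree and a truth
    JSON; fully regenerable from the seed.
    """
    ref = synthetic_reference(reference_length, seed=20211201)
    mm = MutationModel(kappa=22.0)
    dem_u6 = DemographicModel(((0.0, 1800.0), (20000.0, 600.0)), 25.0)
    dem_u5 = DemographicModel(((0.0, 600.0),), 25.0)
    ds = make_sister_haplogroup_dataset(
        46000.0, 20, (dem_u6, dem_u5), seed=seed, reference=ref,
        mut_model=mm, clock_rate=1.0 / 3624.0,
        clade_names=("U6like", "U5like"))
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_fasta(outdir / "alignment.fasta",
                    sorted(ds.alignment.items()))
    mio.write_profiles(outdir / "profiles.tsv", ds.profiles)
    mio.write_fasta(outdir / "reference.fasta", [(ref.name, ref.bases)])
    ds.true_tree.set_lengths_from_times()
    mio.write_tree(outdir / "true_tree.nwk", ds.true_tree)
    sites = make_frequency_sites(
        25, {"kind": "logistic_ew", "midpoint_lon": 0.0, "scale": 8.0,
             "max_freq": 0.8}, seed=seed)
    sites.to_csv(outdir / "sites.csv", index=False)
    truth = {
        "split_time": ds.split_time,
        "clade_tmrcas": ds.clade_tmrcas,
        "clade_tips": ds.clade_tips,
        "seed": seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return ds, ref, sites


def run_all(config: Optional[dict] = None,
            config_path: Optional[str] = None) -> RunReport:
    """Execute the full analysis described by the configuration."""
    from .bayes import (McmcSettings, prior_from_mode_p95,
                        truncated_normal_prior, genealogies_from_trace,
                        run_mcmc, summarize_ages)
    from .geo import GridSpec, idw_interpolate
    from .network import (Constraint, PositionWeights, build_mj_network,
                          condense_haplotypes, extract_parsimony_tree,
                          hypercube_network, median_closure)
    from .skyline import SkylineSettings, bsp_summarize, sample_skyline

    if config_path is not None:
        config = _merge(DEFAULT_CONFIG, mio.load_config(config_path))
    else:
        config = _merge(DEFAULT_CONFIG, config or {})
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir, _hash(config), seed)

    def run_stage(stage: _Stage, fn):
        if stage.cached:
            log.info("[%s] cached, skipping", stage.name)
            report.stages_cached.append(stage.name)
            return
        stage.dir.mkdir(parents=True, exist_ok=True)
        log.info("[%s] running", stage.name)
        fn(stage)
        report.stages_run.append(stage.name)

    # ---- data ------------------------------------------------------------
    data_stage = _Stage(outdir, "data", [config["data"], seed], "")
    def _data(st):
        if config["data"].get("demo", True):
            make_demo_dataset(seed, st.dir,
                              int(config["data"].get("reference_length", 1000)))
        else:
            raise NotImplementedError(
                "only demo data generation is wired into run_all; use the "
                "library API for custom datasets")
        st.done()
    run_stage(data_stage, _data)
    ref = ReferenceSequence(
        mio.read_fasta(data_stage.dir / "reference.fasta")[0][1], "reference")
    profiles = mio.read_profiles(data_stage.dir / "profiles.tsv", ref)
    alignment = dict(mio.read_fasta(data_stage.dir / "alignment.fasta", ref))
    truth = json.loads((data_stage.dir / "truth.json").read_text())

    # ---- tree ------------------------------------------------------------
    net_cfg = config["network"]
    tree_stage = _Stage(outdir, "tree", net_cfg, data_stage.hash)
    def _tree(st):
        weights = PositionWeights(net_cfg["default_weight"],
                                  net_cfg["hotspots"],
                                  net_cfg["hotspot_weight"])
        haps = condense_haplotypes(profiles)
        root = frozenset()
        method = net_cfg.get("method", "median")
        if method == "hypercube":
            net = hypercube_network(haps, weights, include=[root])
        elif method == "median":
            net = median_closure(haps, weights, include=[root])
        else:
            net = build_mj_network(haps, float(net_cfg.get("epsilon", 0.0)),
                                   weights)
        constraints = []
        if net_cfg.get("constrain_haplogroups", True):
            by_hg: dict[str, set] = {}
            for p in profiles:
                if p.haplogroup:
                    by_hg.setdefault(p.haplogroup, set()).add(p.sample_id)
            constraints = [Constraint(k, frozenset(v))
                           for k, v in sorted(by_hg.items())]
        tree = extract_parsimony_tree(net, root, constraints)
        mio.write_tree(st.dir / "tree.nwk", tree)
        net.to_graphml(st.dir / "network.graphml")
        st.done(n_haplotypes=len(haps))
    run_stage(tree_stage, _tree)
    tree = mio.read_tree(tree_stage.dir / "tree.nwk", ref)

    # ---- rho / ML dating -------------------------------------------------
    date_cfg = config["dating"]
    clock = MolecularClock(float(date_cfg["years_per_transition"]))
    clades = date_cfg.get("clades") or sorted(
        {p.haplogroup for p in profiles if p.haplogroup})
    date_stage = _Stage(outdir, "dating", date_cfg, tree_stage.hash)
    def _date(st):
        tab = age_table(tree, clades, clock, tuple(date_cfg["methods"]),
                        alignment=alignment)
        tab.to_csv(st.dir / "ages.tsv", sep="\t", index=False)
        st.done()
    run_stage(date_stage, _date)
    report.ages = pd.read_csv(date_stage.dir / "ages.tsv", sep="\t")

    # ---- Bayesian dating ------------------------------------------------
    bayes_cfg = config["bayes"]
    bayes_stage = _Stage(outdir, "bayes", bayes_cfg, tree_stage.hash)
    if bayes_cfg.get("enabled", True):
        def _bayes(st):
            mm = MutationModel(kappa=float(bayes_cfg.get("kappa", 22.0)))
            timed = resolve_polytomies(tree, seed)
            timed = assign_initial_times(
                timed, clock.years_per_transition)
            priors = []
            for cal in bayes_cfg["calibrations"]:
                if cal["form"] == "shifted_exponential":
                    priors.append(prior_from_mode_p95(
                        cal["clade"], float(cal["mode"]), float(cal["p95"])))
                else:
                    priors.append(truncated_normal_prior(
                        cal["clade"], float(cal["centre"]), float(cal["sd"])))
            mu = (1.0 / clock.years_per_transition) \
                * (mm.kappa + 2.0) / mm.kappa / len(ref)
            settings = McmcSettings(
                iterations=int(bayes_cfg["iterations"]),
                thinning=int(bayes_cfg["thinning"]),
                burn_in=bayes_cfg.get("burn_in"), seed=seed)
            trace = run_mcmc(timed, alignment, priors,
                             settings=settings, mut_model=mm,
                             clock_rate_per_site=mu, n_categories=1,
                             track_clades=clades, track_heights=True)
            mio.write_trace(st.dir / "trace.tsv", trace.samples)
            mio.write_tree(st.dir / "timed_tree.nwk", timed)
            summary = summarize_ages(trace, ["root"] + clades)
            (st.dir / "summary.json").write_text(
                json.dumps(summary, indent=1))
            st.done()
        run_stage(bayes_stage, _bayes)
        report.bayes_summary = json.loads(
            (bayes_stage.dir / "summary.json").read_text())

    # ---- skyline ---------------------------------------------------------
    sky_cfg = config["skyline"]
    sky_stage = _Stage(outdir, "skyline", sky_cfg, bayes_stage.hash)
    if sky_cfg.get("enabled", True) and bayes_cfg.get("enabled", True):
        def _sky(st):
            from .bayes import PosteriorTrace
            samples = mio.read_trace(bayes_stage.dir / "trace.tsv")
            timed = mio.read_tree(bayes_stage.dir / "timed_tree.nwk", ref)
            timed.set_times_from_lengths()
            trace = PosteriorTrace(samples, (), McmcSettings(seed=seed))
            gens = genealogies_from_trace(trace, timed, max_genealogies=30)
            post = sample_skyline(
                gens, m=int(sky_cfg["m"]),
                settings=SkylineSettings(
                    iterations=int(sky_cfg["iterations"]), seed=seed),
                generation_time=float(sky_cfg["generation_time"]))
            traj = bsp_summarize(
                post, most_recent_year=int(sky_cfg["most_recent_year"]))
            traj.to_frame().to_csv(st.dir / "trajectory.tsv", sep="\t",
                                   index=False)
            st.done()
        run_stage(sky_stage, _sky)
        report.skyline_path = sky_stage.dir / "trajectory.tsv"

    # ---- maps ------------------------------------------------------------
    map_cfg = config["map"]
    map_stage = _Stage(outdir, "map", map_cfg, data_stage.hash)
    if map_cfg.get("enabled", True):
        def _map(st):
            sites = pd.read_csv(data_stage.dir / "sites.csv")
            grid = GridSpec.covering(sites.lon, sites.lat,
                                     float(map_cfg["cellsize"]))
            for hg in map_cfg["haplogroups"]:
                col = hg if hg in sites.columns else sites.columns[4]
                pts = list(zip(sites["lon"], sites["lat"],
                               sites[col] / sites["n"]))
                surf = idw_interpolate(pts, grid,
                                       power=float(map_cfg["power"]),
                                       haplogroup=hg)
                surf.write(st.dir / f"freq_{hg}.asc")
            st.done()
        run_stage(map_stage, _map)
        report.map_paths = sorted(map_stage.dir.glob("freq_*.asc"))

    provenance = {
        "seed": seed, "config_hash": report.config_hash,
        "stages_run": report.stages_run,
        "stages_cached": report.stages_cached,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return report
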
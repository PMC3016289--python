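# mthaplo

Chronology and demography of mitochondrial DNA haplogroups from complete
mtDNA variant profiles: haplotype networks and parsimony trees, clade dating
by the ρ statistic, maximum likelihood and a Bayesian relaxed clock with
internal calibrations, Bayesian skyline plots of effective population size,
and inverse-distance-weighted haplogroup frequency maps. A synthetic-data
module generates coalescent datasets with known truth, so every estimator in
the package can be validated end-to-end.

The package is aimed at population geneticists working with human (or other
non-recombining) mitochondrial data who want the classical haplogroup
toolkit — rho dating, median networks, BEAST-style relaxed-clock
calibration, skyline plots, frequency surfaces — as one scriptable,
reproducible Python library.

## The statistics at the core

**ρ dating.** For a clade with *n* sampled sequences, ρ is the mean number
of transitions separating each sequence from the clade's ancestral
haplotype along the tree:
ρ = n⁻¹ Σᵢ mᵢ, where mᵢ counts transitions on the root-to-tip path.
Its standard error follows from the branch structure (Saillard estimator):
σ² = n⁻² Σ_b n_b² m_b over branches *b* inside the clade, with n_b tips
below branch *b* and m_b transitions on it. Ages use the whole-molecule
transition clock of **one transition per 3,624 years**, through a pluggable
monotone purifying-selection correction (identity by default):
age = correction(ρ × 3624), with the 95 % CI from ρ ± 1.96 σ, floored at 0.

**Maximum likelihood.** Branch lengths on a fixed topology are fitted under
HKY85 with discrete-gamma rate variation (32 category medians by default)
via Felsenstein pruning and bounded quasi-Newton optimisation; mean fitted
root-to-tip transition distance converts to years with the same clock.

**Bayesian relaxed clock.** Node ages are sampled by MCMC under an
uncorrelated lognormal relaxed clock (per-branch rate multipliers, iid
lognormal with mean 1 and estimated sd), HKY mutation, a constant-size
coalescent tree prior, hard monophyly constraints (violating proposals are
rejected outright), and internal calibration priors: shifted exponentials
built from a (mode, 95th-percentile) pair — density zero below the mode,
rate λ = ln 20 / (p95 − mode) — or a zero-truncated normal from
(centre, sd).

**Bayesian skyline.** Coalescent events of one or more genealogies are
partitioned into *m* contiguous groups with constant haploid Ne each
(hazard k(k−1)/(2Ne) per generation for k lineages); group sizes and
boundaries are sampled by MCMC under an exponential smoothing prior, and
the posterior trajectory is summarised pointwise (median, 95 % envelope) on
a time axis in years (generation time 25 y, most recent point 1600 AD by
convention). The classic per-interval estimate Ne = k(k−1)t/2 is included
as a deterministic oracle.

**Networks and maps.** Haplotypes condense into a median-joining network
(hotspots such as 16189/16311 down-weighted); a rooted most-parsimonious
tree embeddable in the network is extracted by an exact minimum Steiner-tree
search (Dreyfus–Wagner) with monophyly constraints, replacing the
traditional hand construction (a user-supplied branching order is honoured
exactly when given). HV-I haplotypes classify into U6 subclades by their
diagnostic motifs, and per-population frequencies interpolate onto a grid
by inverse distance weighting with power two.

## Worked example

`examples/04_bayesian_split_dating.py` simulates two sister haplogroups
splitting 46,000 years ago (20 genomes each), then dates the split under
the relaxed clock with a shifted-exponential calibration (mode 45 ka,
p95 60 ka):

```
root  posterior median    46912 y   95% interval [45072 - 54970]
A     posterior median    25988 y   95% interval [16986 - 37680]
B     posterior median    23688 y   95% interval [14641 - 34434]
truth: split 46000, A 28555, B 24140
```

The split posterior brackets the true 46 ka; clade ages are informed
jointly by the sequences, the calibration and the coalescent prior.
`examples/05_skyline_expansion.py` reconstructs a simulated 3-fold
expansion (`recovered fold-change: 3.14 (truth 3.0)`), and the other
examples cover variant notation, network/tree building, ρ dating and
frequency surfaces — each prints its numbers with a line on what they mean.

The same analyses run from the shell:

```bash
mthaplo demo --seed 1 --outdir demo      # synthetic dataset + truth
mthaplo run --seed 1 --outdir demo_run   # full pipeline with caching
mthaplo date rho --tree demo/true_tree.nwk --clade U6like
mthaplo map build --sites demo/sites.csv --haplogroup U6
```

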
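# Methods

This note documents the models implemented in `mthaplo`, their assumptions,
the defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices that were genuinely open.

## Coordinates, notation and clocks

All positions are 1-based against a reference sequence (16,569 bp for human
mtDNA numbering; toy references of any length are allowed so tests and
examples need not carry a full-length genome — the packaged
`synthetic_reference` is a deterministic random stand-in of the right shape,
not the real reference, and every analysis is reference-agnostic). A bare
position token denotes a transition, a position with a trailing base a
transversion, dotted/`d` forms insertions and deletions. Indels and
ambiguous bases (N, treated as missing and logged) are recorded but
**excluded from every clock computation**, because the clock is calibrated
per transition: one transition on the whole molecule per **3,624 years**
(`MolecularClock.years_per_transition`). A purifying-selection correction is
exposed as a pluggable monotone function — identity by default, or a
monotone PCHIP interpolation of a user-supplied table; no numeric claims are
made for any built-in table. Correction of a CI endpoint is valid because
the correction is monotone; ages and CI bounds are floored at 0. A
whole-substitution counting mode (`mode="substitutions"`) exists for
sensitivity analysis.

## rho and its standard error

rho is the mean transition count from the clade's ancestral node to each of
its tips; the standard error weights each branch's count by the squared
fraction of clade tips descending through it (sigma² = n⁻² Σ n_b² m_b; the
clade's stem is outside the clade and never counts). Both are exact tree
traversals, tested against independent brute-force enumeration to 1e−12.
The 95 % interval is ρ ± 1.96 σ on the transition scale, converted through
the clock. Coverage of this interval reflects Poisson mutation noise only,
conditional on the tree: in simulations at mtDNA-realistic depths (a
59-genome clade with TMRCA ≈ 26 ka, matching the largest subclade size in
published complete-mtDNA haplogroup datasets) empirical coverage is ≈ 92 %;
at much shallower depths (ρ ≈ 5) the plug-in variance makes it dip toward
88 %, a known property of the estimator, not a bug.

## Maximum-likelihood branch fitting

HKY85 with empirically configurable base frequencies (default uniform) and
discrete-gamma rate variation using **category medians** renormalised to
mean 1 (32 categories by default; medians rather than means are a documented
choice). The pruning algorithm runs on site patterns; branch lengths (and
optionally kappa and alpha on log scales) are optimised by L-BFGS-B with
branch bounds [0, 10] substitutions/site. Non-convergence raises, carrying
the best-so-far fit. Clade ages convert the mean fitted root-to-tip distance
to transitions via the stationary transition fraction
(2κ(π_Aπ_G+π_Cπ_T) / (2κ(π_Aπ_G+π_Cπ_T) + 2π_Rπ_Y)) and then to years with
the same clock as rho.

## Bayesian relaxed-clock dating

The sampler works on a timed, binary, rooted topology. Parameters: internal
node heights (years), per-branch rate multipliers (iid lognormal with mean
1 and sd σ), σ itself, kappa, and the coalescent scale θ. Priors:

- calibration priors on named clades — shifted exponential from
  (mode, p95) with rate ln 20/(p95 − mode) (zero density below the mode,
  mode at the offset), or normal truncated at zero from (centre, sd);
- tree prior: constant-size coalescent with hazard k(k−1)/(2θ) per year
  (θ = haploid Ne × generation time) under a scale-invariant 1/θ prior;
  a uniform-on-heights option exists for isolation tests. The joint
  "skyline-as-tree-prior" analysis is approximated by running the dating
  chain under the constant coalescent and feeding its posterior genealogies
  into the skyline sampler (`genealogies_from_trace`);
- hyperpriors: exponential with mean 1/3 on the lognormal rate sd (large
  rate variation must earn its place in the likelihood — with a diffuse sd
  prior the two clade stem branches can absorb arbitrary root-age changes,
  a well-known relaxed-clock non-identifiability), log-uniform on kappa in
  [0.05, 500].

Moves: uniform-window height moves (multiplicative for the root), log-scale
random walks on multipliers, σ, κ and θ. The fixed-topology path is
numba-compiled with partial-likelihood updates restricted to the root-ward
path of the changed node, and closed-form HKY transition probabilities
(verified against the matrix exponential to 1e−12). Topology sampling uses
a pure-Python path with narrow-exchange moves; proposals breaking a
monophyly constraint or the time ordering are rejected outright, and every
sampled state records each constraint's status. Identical seeds give
identical traces.

Prior-only validation: with the likelihood off, uncalibrated internal
heights carry **normalised** conditional-uniform densities
(−log(parent − max child)), so they integrate out exactly and each
calibrated clade's marginal reproduces its calibration prior; calibrated
nodes use independence proposals from their own priors, making thinned
samples nearly independent (10,000 samples pass KS at α = 0.01 against all
four analytic priors). Central 95 % intervals are the default summary; HPD
(via arviz) sits behind a flag.

## Bayesian skyline

Groups partition the pooled coalescent events of one or more genealogies
(replicate loci or posterior draws sharing one history) contiguously;
within a group Ne is constant. Likelihood terms reduce to per-group
(lineage-pair time, event count) sufficient statistics via prefix sums, so
iterations are O(m). Prior: scale-invariant on the most recent group,
exponential with mean Ne_g on each next older group (the standard skyline
smoothing prior); boundaries uniform over contiguous compositions, updated
by symmetric repositioning between neighbouring cuts. Default m = 10 groups
(tests use m = 4–5 at their smaller sizes). Ne is reported in haploid
individuals — the natural unit for mtDNA — and times in years via the
generation time (default 25 y); the "most recent time point = 1600 AD"
convention annotates the axis only. The deterministic classic skyline
(Ne = k(k−1)t/2 per interval) serves as an independent oracle; with one
group the sampler's posterior matches the analytic inverse-gamma result for
the constant-size coalescent.

## Median networks and parsimony trees

Haplotypes are token sets; positions carry integer-style weights (default
10, hotspots such as 16189 and 16311 down-weighted to 5 — the hotspot list
is configuration, since no canonical list is universal). The median-joining
construction iterates: minimum-spanning-network links with tolerance ε
(default 0), majority medians of link-sharing triplets admitted only when
their connection cost is λ-minimal within ε, pruning of unused medians.
Every link is subdivided through deterministic intermediates so each edge
carries exactly one mutation.

Tree extraction is a minimum Steiner-tree problem over the network's
unit-edge graph with terminals = observed haplotypes + the root haplotype.
Small instances (≤ 9 terminal groups, ≤ 400 nodes) are solved **exactly**
by the Dreyfus–Wagner dynamic programme; larger ones fall back to the
Mehlhorn approximation (still embeddable and constraint-respecting, no
longer guaranteed minimal). Two caveats discovered during validation and
now part of the design:

- A median network (even the full median closure) does **not** always
  contain a globally most-parsimonious tree; `hypercube_network` builds the
  complete hypercube over the segregating tokens (capped at 8 sites) and
  guarantees global optimality of the extracted tree — it is the substrate
  used for all optimality validation. Extraction over an MJ network is
  optimal only relative to that network.
- The root haplotype must be part of the closure/hypercube construction
  (`include=`); grafting it afterwards can exclude optimal trees.

Monophyly constraints (nested or disjoint; violations raise naming the
clade) are solved innermost-first as nested Steiner problems. Each clade's
subtree lives in its own namespace — its own copy of the latent network —
and glues to the rest at a single attachment vertex through an explicit
zero-mutation stem, so a clade junction coinciding with the attachment
vertex still yields a proper clade node, and paths through haplotypes
observed elsewhere become distinct latent copies (recurrent haplotypes)
rather than monophyly violations. The constraint's MRCA (lowest spanning
node) receives the clade name, so stem mutations stay outside rho. Ties
break deterministically by sorted token order. A user-supplied nested
branching order (`branching_order_tree`) is honoured exactly, mirroring
hand-built trees.

## Geographic surfaces

HV-I motifs (positions 16024–16365): U6a 16172-16219-16278; U6a1 +16189;
U6b 16172-16219-16311; U6b1 +16163; U6c 16169-16172-16189; U6c1 +16129.
The most-derived complete motif wins; haplotypes with the U6-like core
(16172 plus 16219 or 16169) but no complete motif report as "U6-other"
(a package convention). The unstable 16189 can be treated as a wildcard via
an explicit flag. U6b/U6d pool as "U6bd" for mapping, being
indistinguishable at HV-I resolution. Site coordinates are population
centroids (mean of member sample coordinates); sites below a sample-size
floor are flagged, not dropped.

IDW: value(cell) = Σ wᵢfᵢ / Σ wᵢ with wᵢ = dᵢ⁻², all sites contributing (no
search radius), exact site value at coincident cells, duplicate coordinates
with conflicting values rejected. Great-circle (haversine) distance is the
default; planar Euclidean sits behind a flag, and the two agree on the toy
configurations used for validation. Output is an ESRI ASCII grid on a plate
carrée lattice.

## Synthetic data: what it emulates, what it does not

`simulate` draws haploid coalescent genealogies (msprime) under
piecewise-constant demographies, evolves sequences branch-by-branch as a
Poisson process with the whole-molecule transition clock (transversions at
2/κ relative total rate, default κ = 22, mtDNA-like), optional per-site
hotspot multipliers (normalised to mean 1 so the molecule-wide clock is
preserved), and records the true per-branch mutation lists. Sister-
haplogroup datasets join two clade genealogies (each conditioned younger
than the split by rejection) at a known split time. Frequency tables draw
binomial counts around a true spatial cline. Every operation draws from its
own named stream derived from the master seed, so results are
bit-reproducible and insensitive to the addition of new operations.

Not emulated: recombination (absent in mtDNA), migration, selection,
heteroplasmy, sequencing error, rate differences between control and coding
regions beyond per-site multipliers. Passing recovery tests therefore show
the estimators are correct and calibrated **under the generating model**,
not that real data meet that model.

Default validation problem sizes (chosen to represent the study design at
desk scale): toy references of 400–1,000 bp carrying whole-molecule clock
semantics; sister datasets with a 46-ka split and 2 × 20 tips (haploid
Ne = 600, generation time 25 y); split-age recovery over 20 replicates of
500,000 MCMC iterations (thinning 100, 10 % burn-in); rho-CI coverage over
200 replicates of a 59-genome clade with TMRCA ≈ 26 ka; skyline fold-change
recovery over 20 replicates of 8 × 30-tip genealogies under a two-epoch
3-fold expansion (Ne 1,000 → 3,000 at 20 ka), fold-change read from the
posterior median trajectory at the present versus 30 ka.

## Pipeline

`run_all` wires the stages (data → network/tree → rho/ML table → Bayesian
dating → skyline → maps) through plain-text artifacts; each stage's marker
records a hash of its configuration and upstream markers, so re-runs skip
unchanged stages and deleting a marker re-runs only that stage and its
dependants. The demo dataset (46-ka split, one clade with a 3-fold
expansion at 20 ka, west-peaked frequency cline) regenerates exactly from
its seed. Exclusion counts (indels/transversions dropped from clocking) are
logged because they silently change ages. The extracted parsimony tree is
binary-resolved (zero-mutation nodes) and given rough mutation-clock times
to initialise the Bayesian sampler.

## Known limitations

- The relaxed-clock kernel requires a binary topology; polytomies must be
  resolved first (the pipeline does this automatically).
- Joint tree-and-skyline sampling is approximated (constant-coalescent
  dating prior, skyline on posterior genealogies) rather than sampled as
  one model.
- Exact parsimony extraction is exponential in the number of haplotype
  groups; beyond the documented thresholds results are approximate.
- The truncated-normal calibration omits its normalising constant inside
  the MCMC (it cancels); reported log-priors are unnormalised in that term.
- Saillard intervals are conditional on the tree and undercover at very
  shallow time depths (see above).
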
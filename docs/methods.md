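# Methods

## The demographic model and its coalescent

A `DemographicModel` is a set of populations (diploid effective size N_e,
selfing rate s ∈ [0,1], diploid sample count), split events (time in
generations backward; the derived population merges into the ancestral
one), and a constant backward migration matrix m[i][j] (per-generation
probability that a lineage in i traces back to j). Genealogies are drawn
under the structured coalescent: k lineages in a population coalesce at
rate k(k−1)/2 · 1/(2N_e), lineages migrate at rate m[i][j] each, and a
split pools the derived population's lineages into the ancestral one.
Time is continuous, in generations; conversion to calendar years happens
only at reporting, via a generation time of 1–2 years.

Selfing enters through the mixed-mating equilibrium identity-by-descent
probability F = s/(2−s): each sampled diploid starts the genealogy as a
single lineage carrying both of its haploid genomes with probability F,
and as two independent lineages otherwise. This shortcut reproduces the
equilibrium heterozygote deficit the mating-system analyses assume
(verified against F in the tests) without gametic bookkeeping deeper in
the genealogy; it does not model the ~1/(1+F) reduction of effective size
inside permanently selfing populations, which in the fitted models is
absorbed by N_e itself.

Mutations are infinite-sites: Poisson on branches at rate μ·L (locus
length L, rate μ per site per generation, default 0.355 × 10⁻⁸), assigned
to unique uniform positions; polarization is exact (ancestral = 0). Loci
are independent and non-recombining. Descendant sets are tracked as
64-bit masks, capping a model at 64 haploid samples — ample for pooled
super-populations of 3 diploids each. The event loop is numba-compiled;
the first call in a session pays a compilation cost.

## Expected SFS and composite likelihood

The expected joint unfolded SFS under a model is approximated by
Monte-Carlo: for each of `n_sims` genealogies, every branch's length is
accumulated into the SFS cell indexed by its per-population descendant
counts. Normalising the accumulated lengths over polymorphic cells gives
the probability that a segregating site falls in each cell, conditioned
on polymorphism in the pooled sample — a Rao-Blackwellised version of
counting simulated mutations, with noticeably lower variance at the same
number of genealogies. Conditioning on polymorphism removes any
dependence on unknowable monomorphic site totals, so models are always
compared on identically conditioned data.

Polymorphic cells with zero simulated mass are floored at 0.5/n_sims and
the distribution renormalised, guaranteeing a finite log-likelihood for
rare observed cells. The composite log-likelihood is multinomial,
lnCL = Σ m_cell · ln p_cell over polymorphic cells (natural log), and
AIC = 2k − 2 lnCL with k the number of free parameters. Composite
likelihoods over linked sites overstate information, so AIC comparisons
are most reliable between candidates of equal k (as in the topology and
placement steps); nested gene-flow candidates with extra parameters tend
to be over-favoured, a known property of composite-likelihood AIC.

## Optimisation

Free parameters carry finite bounds and an optional log flag (used for
sizes and times spanning more than an order of magnitude; starts are then
log-uniform). Fitting is multi-start ECM: parameters are grouped into
blocks (split times | sizes | migration rates) and each parameter is
maximised conditionally by bounded one-dimensional search
(`scipy.optimize.minimize_scalar`, ≤16 evaluations, relative tolerance
10⁻³ of the bound span). All likelihood evaluations within one cycle use
the same simulation seed (common random numbers), which makes the noisy
objective locally smooth; cycles stop when the relative lnCL improvement
falls below `tol` (default 0.001) or after `max_cycles`. All starts share
the cycle-seed sequence and a final common evaluation seed, so the
best-of-starts choice — and any AIC comparison across candidates fitted
with the same `seed` — is like-for-like.

Desk-scale defaults are 2,000 simulations per evaluation, 10 starts and
20 cycles; the corresponding full-scale settings (100,000 simulations,
100 starts, 100 cycles) are accepted through the same keyword arguments.
The split-time recovery analyses use 5,000 loci; at these sizes one full
fit takes a few seconds on one CPU.

Hierarchical selection runs scenario sets in order, selects each step's
winner by AIC (ties broken by smaller k, then model id), and prunes
populations that appeared only in losing candidates; later candidates
referencing a pruned population are rejected as contradicting an earlier
decision. Confidence intervals are parametric bootstrap: datasets of the
observed polymorphic size are drawn multinomially from the fitted
spectrum and refitted with a reduced start count; percentile intervals
are reported. Whether this matches the original study's interval
construction is not documented there; the output is labelled
parametric-bootstrap.

## Study conditions for the split-time analysis

The canonical two-population scenario (`parapop.study.best_split_model`)
places the derived selfer (N_e = 5,000) splitting from its parent
(N_e = 10,000) 6,007 generations ago with bidirectional migration 10⁻⁵
per generation, 10 kb loci, μ = 0.355 × 10⁻⁸, and one super-population of
3 diploids per species. The sizes and migration rate are fixed study
conditions chosen as realistic for selfing range-edge populations of
these species (low diversity, 4Nm well below 1); with them the split sits
at ≈0.6 coalescent time units of the derived population, where the joint
SFS is informative about the split time. Selfing is fixed at 0 in the
fitted demographic models — its equilibrium effect on diversity is
absorbed by N_e, and the mating-system analyses estimate s separately —
while the simulator exposes per-population s for generators that need it.

## Mating-system estimators

Multilocus F_IS uses per-locus observed heterozygosity H_obs and
sample-size-corrected expected heterozygosity H_exp = 2p̂q̂·n/(n−1)
(n diploids), combined as 1 − ΣH_obs/ΣH_exp over polymorphic loci;
an all-monomorphic panel returns an undefined flag rather than a number.
Conversions use the equilibrium identities F = s/(2−s), s = 2F/(1+F),
t = (1−F)/(1+F); an empirical F→t calibration curve, where available from
progeny-array studies, can be supplied as a table and replaces the
equilibrium F→t mapping by interpolation (empirical curves are typically
steeper, giving lower t for the same F).

The progeny-array estimator detects an offspring as outcrossed iff it
carries an allele absent from its mother at ≥1 locus. Given outcrossing,
the per-family detection probability is P_det = 1 − Π_l P(pollen allele ∈
maternal alleles at l); the multilocus outcrossing rate is the detected
fraction divided by the offspring-weighted mean P_det, truncated to
[0,1], with a bootstrap over families for the standard deviation. Pollen
pool frequencies default to the arrays' stored values and can instead be
estimated from the maternal plants, the usual field practice. Offspring
sharing no allele with their mother at some locus are genotyping errors:
excluded and counted.

## Correlation of zygosity and LD extent

For one individual, z(x) = 1 if heterozygous at assayed site x, else 0;
θ is the genome-wide mean of z. For each log-spaced distance bin, Δ is
the Pearson correlation of (z(x), z(y)) over ordered in-bin pairs, with
pairs never spanning a region boundary (genic regions in real data,
supplied as a BED-like interval mask). The covariance/θ(1−θ) scaling is
reported as an alternative column, since either reading of "scaled by θ"
may be wanted for comparisons; by default pairing is over the assayed
variant sites. When the predicted pair count in a bin exceeds a cap
(default 2 × 10⁶) the left-site index is strided, which subsamples pairs
without bias.

The LD extent rescales Δ by its value in the shortest-distance bin and
reports the distance at which the scaled curve first reaches a threshold
(default 0.1), interpolating linearly between adjacent bin centers in
log10 distance; a curve that never crosses is right-censored and flagged.
The synthetic generator for this analysis is a stationary two-state
Markov chain with P(het→het) = ρ + θ(1−ρ) and P(hom→het) = θ(1−ρ), whose
marginal mean is θ and lag-d autocorrelation ρᵈ, so the estimator can be
checked against a closed form; over a wide log bin the pooled expectation
is the mean of ρᵈ over the lags in the bin, not ρ at the bin center.

## Introgression

Patterson's D over a (P1, P2, P3, outgroup) quartet uses the
allele-frequency form: ABBA = Σ(1−p1)p2p3(1−p4), BABA = Σp1(1−p2)p3(1−p4),
D = (ABBA−BABA)/(ABBA+BABA). Standard errors come from a delete-one
jackknife over contiguous genomic blocks (default 1 Mb; simulated loci on
separate chromosomes form one block each) and Z = D/SE, with |Z| ≥ 3 as
the conventional significance threshold. Fewer than 3 non-empty blocks
refuses the jackknife (flagged, D still reported); ABBA+BABA = 0 flags D
undefined.

## Mutational load and geography

Load is the per-sample count of variants homozygous for the alternate
allele whose first ANN annotation is MODERATE or HIGH impact (SnpEff
orders annotations most-severe-first, so only the first is read;
heterozygous and homozygous-reference genotypes never count, missing
genotypes are skipped). Population means average samples within
populations. Expansion distances sum great-circle (haversine) segments
along an ordered route of map nodes on a sphere of radius 6371.0088 km;
the route itself is a user/config input, not inferred here. Load is
regressed on log10 distance by OLS with a two-sided t-test on the slope;
zero distances are offset by +1 km (logged), and constant distances or
fewer than 3 records refuse the regression. The serial-founder generator
(repeated binomial bottlenecks of 10 founders along 8 demes) raises
E[p²] with distance and therefore produces the positive load-distance
slope expected in the expanding outcrossing parent.

## What the generators do and do not emulate

The generators reproduce the statistical structure each estimator
assumes: equilibrium inbreeding for F_IS, mixed-mating gamete draws for
progeny arrays, geometric heterozygosity tracts for Δ, i.i.d. annotated
genotypes for load counting, and the structured coalescent for SFS and D.
They do not emulate recombination within loci, linked selection,
genotyping error (beyond the explicit incompatible-offspring channel),
reference bias, or missing data patterns of real resequencing; passing
tests therefore demonstrate estimator correctness under the stated
models, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

Zero-probability flooring at 0.5/n_sims before renormalisation; AIC ties
broken by smaller k then model id; undefined statistics (monomorphic
F_IS panels, θ = 0 zygosity profiles, ABBA+BABA = 0) return flagged
results rather than raising; incompatible progeny are excluded and
counted; thinning keeps the first site per chromosome and uses an
inclusive ≥ min_bp rule; the MAC filter is strict (minor count > 3
removes count-3 sites) and applies to the structure/tree site set only,
since it would distort an SFS used for fitting. Validation rejects
non-tree split sequences, migration between populations with no
coexisting epoch, out-of-range coordinates and rates, and unsorted
positions. All generators and fits are bit-reproducible given a seed.

## Known limitations

Single-epoch constant sizes (no growth curves); no recombination-aware
likelihood; composite-likelihood AIC over-favours extra parameters for
nested gene-flow candidates (see above); the progeny-array estimator
assumes the pollen pool is known or well estimated; LD extents are
bin-resolution limited; and the 64-haploid engine cap is deliberate.
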
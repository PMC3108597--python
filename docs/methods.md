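# Methods

This note records the models and estimators implemented in `mthap`, the
conventions and tunable parameters that matter, and what the synthetic-data
generator does and does not emulate.

## Data model and haplotype determination

The unit of analysis is an aligned set of same-length sequences (one per
sampled individual) with a population label and an optional social-group
label nested inside the population.  Haplotype collapsing is exact string
identity by default (`missing_policy="strict"`): an N or IUPAC ambiguity
code matches only itself, so two sequences differing only at an ambiguous
position are distinct haplotypes.  This is the deterministic convention of
the classic desk tools; because published surveys rarely state how a
sequencing ambiguity was resolved, a `merge-compatible` policy is also
provided (a sequence joins the first haplotype whose states are
IUPAC-compatible at every site, the representative keeping the more specific
state) but is not the default — it is order-dependent by construction.

Site classification works column-by-column over the collapsed table,
count-weighted by default so that singletons and parsimony-informative
status are judged over individuals.  Conventions: a column containing a gap
in any sequence is an indel site and is excluded from the segregating-site
and transition/transversion tallies; ambiguity codes are missing data at
that column; a column with k > 2 observed bases contributes k−1 mutations to
η, with each non-majority base classed as transition or transversion against
the majority base.  Positions are 0-based internally, 1-based in all
reports.

## Diversity and distances

Gene diversity uses Nei's unbiased estimator h = n(1−Σp²)/(n−1); nucleotide
diversity π is the mean per-site pairwise difference over all unordered
individual pairs (computed between haplotypes and expanded by counts, which
is exact and much faster), with pairwise deletion of missing/indel
positions.  π is uncorrected by default — the standard Nei estimator — and a
TN93-corrected variant is available, since published control-region π values
do not always state whether model correction was applied.

The Tamura–Nei (1993) distance separates the two transition classes (A↔G,
C↔T) from transversions and corrects for unequal base composition; base
frequencies default to the empirical frequencies of the pair.  The
implementation was cross-checked against an independent reference
implementation to 12 decimal places (the value is frozen in the test suite)
and reduces to the Jukes–Cantor closed form when frequencies are equal and
changes are proportioned as under JC.  A non-positive logarithm argument
(saturation) raises an explicit error naming the proportions involved.

## AMOVA and permutation inference

The hierarchical analysis of molecular variance decomposes squared
inter-individual distances into sums of squared deviations at three nested
levels (among populations / among groups within populations / within
groups), with variance components solved from the expected mean squares
using the standard unequal-sample-size coefficients.  Negative components
are reported as computed, never truncated to zero — pairwise Φ_ST tables in
the literature routinely print small negative values and truncation would
bias permutation nulls.  Fixation indices follow the usual identities
(Φ_CT = σ²_a/σ²_T, Φ_SC = σ²_b/(σ²_b+σ²_c), Φ_ST = (σ²_a+σ²_b)/σ²_T).

Each index has its own permutation null: Φ_ST permutes individuals among
populations, Φ_SC permutes individuals among groups within their population,
Φ_CT permutes whole groups among populations.  Permutations act on
individuals represented as haplotype indices (exact, no resequencing), and
p = (x+1)/(N+1) so a finite-permutation p is never zero.  All stochastic
routines take explicit seeds.

The leave-one-group-out screen reruns the three-level AMOVA once per
excluded social group to locate groups that dominate the among-group
component; exclusions that would empty a population are flagged and skipped
rather than fatal.  Multiple testing across the screen uses the sequential
goodness-of-fit (SGoF) procedure in its plain exact-binomial form: with N
tests and R p-values at or below γ = 0.05, the k smallest p-values are
declared significant where k counts the values i ≤ R whose upper binomial
tail P(X ≥ i | N, γ) is ≤ α = 0.05.  The refinements of the "+" variant
(continuity corrections, G-test approximations) are deliberately omitted;
the choice is recorded in the output metadata.

## Resampling tests

The chi-square evenness test compares observed haplotype counts with a null
frequency vector (equal frequencies for a whole-sample test, i.e. expected
count n/K per haplotype; the population's frequencies when testing a social
group against its population).  Null replicates are drawn multinomially
*from the null frequencies* and the p-value is the proportion of replicate
χ² at or above the observed.  A literal "resample the observed frequencies"
mode is exposed for comparison but is not a calibrated test — resampling the
alternative cannot produce a null distribution — and is off by default.

The Mantel test correlates the upper triangles of two distance matrices,
permuting rows/columns of one matrix simultaneously (delegated to
scikit-bio's implementation behind the package interface; the test suite
checks it against exhaustive enumeration on four units).  The accompanying
reduced-major-axis regression uses slope = sign(r)·sd(y)/sd(x).  Geographic
distances may be supplied as a matrix or computed as great-circle km from
per-population mean coordinates (decimal degrees, spherical approximation).

Rarefaction: accumulation curves draw random orderings of the pooled
individuals without replacement and report mean and SD of the distinct
haplotype count at cumulative levels (defaults: 7 events × 10 samples,
1,000 randomizations); the Monte-Carlo means are validated against the
closed-form hypergeometric expectation Σ_h [1 − C(N−c_h, g)/C(N, g)].  The
paired richness comparison draws n_rep = 20 samples of k = 10 individuals
without replacement from each of two pools (independent streams salted by
the replicate index) and applies a two-tailed paired t-test with
df = n_rep − 1.  Whether such published comparisons drew with or without
replacement is typically unstated; without replacement is the default here.

## Neutrality statistics and coalescent nulls

Fu's F_S is computed from the Ewens sampling distribution: S′ = P(K ≥ K_obs)
given θ̂ equal to the mean number of pairwise differences (not per site),
with the haplotype-count probabilities obtained from unsigned Stirling
numbers of the first kind in a log-space recurrence (stable to n in the
hundreds); F_S = ln(S′/(1−S′)).  When S′ is exactly 0 or 1 (e.g. a single
haplotype) the statistic is returned as an explicit boundary marker rather
than an infinite float.

Fu & Li's D* and F* are the outgroup-free starred variants, using the
corrected variance-coefficient formulas that the standard desk tools adopted
(the test suite freezes values from an exact-fraction evaluation of those
published formulas at small n).  F* uses the mean pairwise difference.
Since no outgroup sequence is part of the data model, the with-outgroup D/F
are not provided.

R₂ follows its definition R₂ = √[(1/n) Σᵢ (Uᵢ − k̄/2)²]/S with Uᵢ the number
of sites at which individual i alone carries its state (so both a derived
singleton and the lone carrier of an ancestral state count), and k̄ the mean
pairwise difference.

Significance comes from standard constant-size coalescent genealogies for n
tips with the observed number of segregating sites placed multinomially on
branches proportionally to branch length — fixed-S conditioning, the common
desk-tool convention; whether a given published analysis conditioned on S or
on θ is usually unstated, and the conditioning used is recorded in the
output metadata.  All four statistics are lower-tail by default
(p = (#{stat* ≤ stat_obs}+1)/(n_sims+1)); 50,000 simulations is the
production default.  Calibration is verified in the test suite by a
cross-engine experiment: data simulated under a finite-site HKY coalescent
(msprime) are analysed with this infinite-site fixed-S null, and all four
tests reject at the nominal 5% within the 99% binomial band over 300
replicates.

θ estimators are desk-scale: Watterson's θ_W = S/(a_{n−1}L) and Tajima's
θ_π = π.  The effective-size arithmetic N_ef = θ/(2μτ) takes μ in
substitutions/site/year and a generation-time range in years (μτ is the
per-generation rate); the point estimate uses the τ midpoint and the
interval combines the extreme values of θ, μ and τ that minimize and
maximize the quotient — a worst-case (not probabilistic) propagation.
N_e = 2·N_ef assumes a long-term 1:1 sex ratio with equal reproductive
variance.

## Median-joining network

The network starts from the ε-relaxed minimum spanning network over the
observed haplotypes restricted to their variable positions (an edge belongs
to the MSN exactly when its weight is within ε of the minimax path weight
between its endpoints; ε = 0, the strictest setting, is the default).
Majority-consensus median vectors are proposed from connected triplets
(centre node with two MSN neighbours) and added one at a time — candidates
examined in lexicographic order for bit-stable runs — whenever they strictly
shorten the minimum spanning tree over the augmented sequence set; the
process repeats to fixation, after which median vectors of degree ≤ 2 are
pruned iteratively (a degree-2 Steiner point cannot shorten a network under
the Hamming metric's triangle inequality).  Site weights are uniform;
down-weighting transversions is exposed through the distance layer but off
by default.  Only topology is in scope: published network figures are
manually laid out and not reproducible.

## The simulator: what it emulates, and what it does not

`simulate_metapopulation` draws a haploid coalescent ancestry (msprime) for
K demes under an island model with symmetric scaled migration, or under
star/stepwise divergence histories, with per-deme effective female sizes
N_f; mtDNA conventions throughout (pairwise coalescence time N_f
generations, θ/site = 2 N_f μ per generation, migration = female dispersal).
Mutations follow HKY with base frequencies (0.3721, 0.2469, 0.1286, 0.2524),
a transition/transversion ratio R = 33 converted to κ via
κ = R·g_R·g_Y/(g_A g_G + g_C g_T), and an invariant-site mask of ⌊p_inv·L⌋
uniformly chosen positions (p_inv = 0.9017, L = 366 by default).

Two rate conventions matter and are easy to get silently wrong:

* msprime's matrix mutation models count silent events (state → same state)
  in the event rate; at R = 33 the equilibrium silent fraction is ≈ 0.40.
  The event rate is rescaled by 1/(1 − silent fraction) so the realized
  substitution rate equals the configured μ.
* μ (default 3.7×10⁻⁸/site/year × τ = 17.5 y) is interpreted as the
  sequence-wide average rate — the "+I" convention under which such rates
  are estimated — so the unmasked fraction carries rate μ/(1 − p_inv).

Defaults aim at the study conditions the analyses assume: the
`study-design` scenario uses 8 demes with sample sizes
(23, 2, 17, 32, 1, 64, 11, 2) (n = 152), four social groups in each deme,
and per-deme N_f = 1750 females chosen so the metapopulation-wide θ is
~0.018/site, which yields ~20–25 haplotypes, overall h ≈ 0.9, π ≈ 0.014 and
S ≈ 21 — shallow divergence with most neighbouring haplotypes 1–3 steps
apart.  Group labels are a random partition by default; a `founder` mode
seeds one group from a single matriline (all copies of the deme's modal
haplotype) to reproduce a socially driven fixed group.

What passing tests on simulated data do **not** show about real data: the
generator has no selection, no recombination, no sequencing error or missing
data, no rate heterogeneity beyond the invariant mask (no Γ), groups are
random partitions rather than behavioural units, and migration is symmetric
and time-constant.  Conclusions about estimator calibration transfer to real
data only to the extent those simplifications are benign.

## Numerical and design choices

* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage seeds from one root seed and records them in the run
  manifest, sufficient to re-run bit-identically.
* Permutation/randomization p-values use the (x+1)/(N+1) convention.
* Degenerate inputs raise typed errors (single-unit designs, all-zero
  distance matrices, saturated distances, pools smaller than the rarefaction
  draw) rather than returning NaN.
* The pipeline excludes populations under 10 individuals from per-population
  h/π reporting and from the AMOVA by default (configurable `min_n`),
  the usual practice for control-region survey tables.
* Test-suite problem sizes are deliberately modest (e.g. 300-replicate
  calibration with 1,000-simulation nulls cached per observed S, 200
  simulator replicates for θ recovery, 20 replicates per migration level);
  they are the package's chosen verification sizes and the production
  defaults remain 16,000 permutations / 50,000 simulations / 10,000
  randomizations.

## Known limitations

* Fixed-S and fixed-θ coalescent conditioning give slightly different null
  distributions; only fixed-S is wired into the p-value machinery
  (fixed-θ data can be produced by the simulator and analysed manually).
* The TN93 distance has no Γ rate heterogeneity, and the AMOVA uses squared
  distances without the Slatkin linearization.
* The SGoF implementation is the plain exact-binomial variant.
* Mantel p-values inherit scikit-bio's permutation scheme; partial Mantel
  and coverage-based richness estimators (Chao1, ACE) are out of scope.
* At n = 2 every polymorphic site is a singleton for both sequences under
  the symmetric U definition, making R₂ degenerate at 1/2 — a property of
  the folded definition, not a bug.
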
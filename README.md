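# mthap

Single-locus population-genetic analysis for mitochondrial haplotype data,
with a coalescent metapopulation simulator.

`mthap` is built for studies of the kind conservation geneticists run on a
maternally inherited marker — a few hundred bases of the mtDNA control region
sequenced in tens to hundreds of individuals sampled across fragmented
populations and, where known, their social groups.  It answers the standard
questions end-to-end: how much haplotype and nucleotide diversity each
population holds, how genetic variance partitions across the social
hierarchy, whether richness differences survive rarefaction, whether the
data bear the footprint of expansion or decline, and how large the long-term
female effective population was.

## What it computes

* **Haplotype collapsing and site classification** — distinct sequences with
  per-(population, group) counts; segregating sites *S*, mutations η,
  singletons η_s, transition/transversion classes, parsimony-informative
  sites.
* **Diversity** — Nei's unbiased gene diversity
  *h* = *n*(1 − Σ*p*²)/(*n* − 1), nucleotide diversity π, and Tamura–Nei
  (TN93) model-corrected pairwise distances.
* **Hierarchical AMOVA** — variance components σ²_a (among populations),
  σ²_b (among groups within populations), σ²_c (within groups) from squared
  TN93 distances with unequal-sample-size coefficients, and the fixation
  indices Φ_CT = σ²_a/σ²_T, Φ_SC = σ²_b/(σ²_b+σ²_c),
  Φ_ST = (σ²_a+σ²_b)/σ²_T, each with its own permutation scheme
  (*p* = (*x*+1)/(*N*+1)).  Pairwise Φ_ST matrices, a leave-one-group-out
  screen, and sequential-goodness-of-fit (SGoF) multiple-test correction.
* **Resampling tests** — randomization chi-square tests of
  haplotype-frequency evenness, Mantel tests of isolation by distance with
  reduced-major-axis regression, sample-based accumulation curves and paired
  *t*-tests of rarefied haplotype richness.
* **Neutrality/demography** — Fu's *F*_S (Ewens sampling probabilities via
  Stirling numbers), Fu & Li's outgroup-free *D** and *F**, Ramos-Onsins &
  Rozas' *R*₂, each with significance from constant-size coalescent
  simulations conditioned on the observed *S*; Watterson and Tajima θ
  estimators; effective size *N*_ef = θ/(2μτ) with worst-case interval
  propagation and *N*_e = 2 *N*_ef under a 1:1 sex ratio.
* **Median-joining haplotype network** — minimum-spanning network plus
  consensus median (Steiner) vectors, edges annotated with per-site changes
  and transition/transversion class.
* **Simulator** — haploid island-model or split-history coalescent
  (via msprime) with HKY mutations, a fixed invariant-site mask, extreme
  transition bias, social-group labels, and a ground-truth record for
  parameter-recovery testing.

## Worked example

Simulate a study-like dataset — 8 populations with sample sizes
(23, 2, 17, 32, 1, 64, 11, 2), 366 bp under HKY+I with ts/tv = 33 — and run
the full analysis:

```bash
mthap simulate --scenario study-design --out study --seed 42
# n=152 L=366 populations=8
mthap run study.fasta study.tsv --out report --seed 1 --n-perm 1000 --n-sims 2000
```

`report/diversity.tsv` (populations with n < 10 get haplotype counts only):

```
population  n    haplotypes  unique_haplotypes  h      pi      s
pop0        23   14          4.0                0.945  0.013   18.0
pop5        64   13          1.0                0.902  0.0115  19.0
...
overall     152  26                             0.928  0.012   22.0
```

Here 26 distinct haplotypes, overall gene diversity 0.928 and nucleotide
diversity 0.012 mean almost every pair of individuals carries different
haplotypes that nevertheless differ at only ~1% of sites — the
high-*h*/low-π signature typical of control-region surveys.
`report/demography.json` holds the neutrality suite
(e.g. `"R2": 0.0998, "p_R2": 0.73` — no evidence of expansion) and θ
estimates; `report/amova.tsv` the variance components and Φ indices with
permutation *p*-values; `report/network_edges.tsv` the median-joining
topology with per-edge mutation labels such as `238T>C(tr)`.

The effective-size arithmetic is also exposed directly:

```bash
mthap ne --theta 0.01803 --mu 3.7e-8 \
      --theta-low 0.0091 --theta-high 0.0285 \
      --mu-low 2.1e-8 --mu-high 6.0e-8 --tau 15 20
# N_ef point: 13923 females
# N_ef interval: 3792 - 45238 females
# N_e (1:1 sex ratio): 27846 individuals
```

i.e. a mutation-scaled diversity of θ = 0.01803 at a rate of
3.7×10⁻⁸ substitutions/site/year and a 15–20-year generation time implies
roughly 14,000 breeding females long-term, with an order-of-magnitude
uncertainty band once the rate and θ intervals are propagated.

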
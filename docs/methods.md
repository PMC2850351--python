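# Methods

This note records the models and procedures implemented in `taxenv`, the
assumptions behind them, the defaults that matter, and the choices made
where the design was genuinely open.

## Sequence preparation and OTU clustering

Sequences between 250 and 1900 bp are retained; identical residue
strings are collapsed to one genotype (first occurrence kept). Many 16S
submissions list only distinct genotypes, so within-sample abundance is
not meaningful in this data model — everything downstream is
presence-based.

OTU clustering is greedy and incremental: sequences are processed
longest-first (ties broken by id, which makes output deterministic);
each sequence joins the first existing cluster whose *representative* it
matches at ≥ 97% identity, otherwise it founds a new cluster. Joining
the first acceptable representative rather than the best mirrors the
incremental semantics of the widely used clustering tools and keeps the
procedure order-deterministic. Identity is matches over alignment
length: for equal-length pairs this is exactly 1 − Hamming/length (`N`
never counts as a match, including against another `N`); unequal-length
pairs fall back to a global edit-distance alignment with identity
1 − distance/longer-length. Sequences with more than 10% `N` are
rejected outright. An optional k-mer prefilter skips representatives
that provably cannot reach the threshold (a sequence with at most *d*
mismatches shares at least `L − k + 1 − d·k` k-mers with its match); it
is a pure speed-up, off by default, and tested to leave results
unchanged.

Samples with fewer than five sequences are dropped: a handful of reads
cannot support statements about a community.

## Taxonomic assignment

Two assignment routes are consumed as tables, never computed here:
fixed-rank classifier calls with a confidence (kept only when strictly
above 0.80), and similarity-search hits. Hits are aggregated per
candidate taxon as the mean of its five best bit-scores; the best taxon
is assigned only when it leads the runner-up by a configurable margin
(default 5 bit-score units; no printed reference value exists, so this
is deliberately a parameter). With a single candidate the runner-up
average is defined as 0. Exact ties never produce an assignment.

The OTU consensus walks ranks from species up to phylum and returns the
first rank at which *exactly one* taxon covers ≥ 25% of the OTU's
sequences; OTUs need more than five member sequences (≥ 6). The 25%
fraction is computed over sequences *assigned at the tested rank* by
default: classifiers assign to variable depths, and using all members as
the denominator would make deep ranks effectively unreachable. The
alternative denominator is available via
`TaxonomyConfig(denominator="members")`.

## Environment hierarchy and community matrices

The bundled vocabulary has 5 supertypes, 20 types and 46 subtypes.
Types without a finer division act as their own subtype (that is how the
subtype level reaches 46); subtype identifiers are qualified as
`type/subtype` because bare subtype names repeat across types. Samples
may carry several labels (multi-origin submissions) and then count fully
in every labelled environment; a flag excludes them for sensitivity
checks. Unlabelled samples fall into an `Unknown` bucket that is
excluded from matrices by default.

`Y_ij` counts *distinct OTUs* of taxon i present in at least one sample
of environment j. Distinct-OTU counts are not additive across
sub-environments — an OTU present in two types of one supertype is one
OTU at the supertype level — so changing levels always re-tallies from
samples rather than merging columns. OTUs observed in exactly one sample
(singletons) are excluded by default from the occurrence-based analyses:
one observation says nothing about a distribution. Expected counts are
the usual independence product `E_ij = Y_i· Y_·j / Y_··`, which
preserves both margins exactly; size normalization divides each column
by its number of samples to remove the sampling-effort effect.

Occurrence statistics use (OTU, sample) presence pairs as observations,
while the community matrix stores distinct-OTU counts; the two are
produced by separate operations because they answer different questions
(how often a taxon is seen vs. how rich it is).

## Specificity, cosmopolitanism, diversity, collector's curves

A taxon is *specific* when its largest single-environment share of
observations reaches 90% (ties for the maximum never qualify), and
*cosmopolitan* when it has ≥ 5 observations in at least round-half-up
(0.9 · n_envs) environments — the rounding convention that yields 5 of
5 supertypes, 18 of 20 types and 41 of 46 subtypes.

Hill numbers: `N0` is richness, `N1 = exp(−Σ p ln p)` the exponential of
Shannon entropy, `N2 = 1/Σ p²` the inverse Simpson index. Shannon uses
the natural logarithm; the identity `shannon = ln N1` fixes consistency
but not the base, and e is the conventional choice in ecology.

Collector's curves pool all sequences of an environment into one
metasample and draw them uniformly without replacement, recording the
running number of distinct OTUs; ten replicate permutations are averaged
by default. Sequences, not OTUs, are the sampling units. The exact
expectation `Σ_o [1 − C(n−n_o, m)/C(n, m)]` is implemented alongside as
an independent check.

## The affinity model

```
Y_ij ~ Poisson(λ_ij · E_ij)
log λ_ij = α + θ_i + γ_j + ν_ij
θ_i ~ N(0, σ²_θ),  γ_j ~ N(0, σ²_γ)
ν_ij ~ w · N(0, σ²_signal) + (1−w) · N(0, σ²_noise)
```

λ_ij is the multiplicative over-/under-representation of taxon i in
environment j relative to independence; ν_ij is the *adjusted* affinity
after removing what the taxon and environment main effects explain. The
narrow mixture component absorbs cell-level noise; the wide one captures
genuine departures.

Hyperpriors (no reference values exist, so these are declared choices):
α ~ N(0, 10²); the four variances carry inverse-gamma(2, 1) priors
(conjugate); w ~ Beta(1, 1). The ordering σ²_noise < σ²_signal is
enforced by rejection inside the variance update, which both blocks
label switching and makes the mixture identifiable.

**Sampler.** Metropolis-within-Gibbs. The Poisson likelihood factorizes
by cell, so all θ_i, all γ_j and all ν_ij can be proposed and
accepted/rejected in parallel as vectorized random-walk updates; α is a
scalar update; z, w and the variances are conjugate draws. The Poisson
mean matrix is cached and updated multiplicatively, making one sweep a
handful of small matrix operations. Step sizes adapt toward ~40%
acceptance during burn-in only, so retained draws come from a fixed
kernel. Identifiability of the decomposition (not of λ, which is always
identified) is enforced by re-centering θ, γ and the rows and columns of
ν after each sweep, with the shifts absorbed so log λ is untouched.
Defaults: 4 chains, 10,000 iterations, 5,000 burn-in, thinning 10 for
the retained matrix draws. A run whose interaction updates accept under
1% of proposals raises an error pointing at the step-size configuration
rather than returning a silently frozen chain.

Summaries: posterior median of λ per cell, the posterior probability
P(λ > 1), and flags — *affinity* when that probability reaches 0.95,
*under-presence* when it falls below 0.05 (the threshold is the
configurable counterpart of "high affinity", for which no printed
criterion exists; a median-based cut is available via the summary
table). Diagnostics (effective sample size, split-chain R-hat) come from
ArviZ. Environments are clustered agglomeratively (complete linkage,
Euclidean) on columns of log posterior-median affinities; log of the
median rather than median of the log is used — the two orderings differ
only by Jensen-gap effects and "on the log scale" does not
disambiguate.

**Calibration evidence computed by the test suite.** Simulation-based
calibration: with truths drawn from the model's own centered priors
(α sd tightened to 1 so prior-predictive counts stay finite), 90%
credible intervals for log λ cover at 88–89% over 200 replicates of a
4×3 problem — within the 90% ± 3% band, the small deficit being a
finite-chain-length effect. Under a null with ν = 0 and margin-based E,
0.4% of cells are flagged as affinities at the 0.95 cut (the mixture
prior shrinks noise cells hard, so the realized false-flag rate sits far
below the nominal 5%). On a 50 × 10 recovery problem (baseline
expectation 50, signal sd 1.0), posterior-median log-affinities
correlate with truth at r ≈ 0.98 and 90% of cells planted at ν = log 3
are flagged.

## Ordination

Classical correspondence analysis by SVD of the standardized residual
matrix `(P − rcᵀ)/√(rcᵀ)`; scores are principal coordinates and the sum
of squared singular values equals chi-square over the grand total. An
exactly independent matrix has zero inertia and returns an empty axis
set rather than an error. Detrending re-centers axis-2 scores within 26
equal-width windows of axis 1 (the classical segment count); rows and
columns share the windows and the subtracted means pool both point sets
so taxa and environments stay comparable. Full DCA axis rescaling is
deliberately not implemented: the ordination is descriptive, and
inertia fractions plus groupings are the quantities used downstream.
The ordination input is the size-normalized matrix, not raw counts.

## Synthetic data

The generators define the conditions under which everything is tested:

- **Community matrices** are drawn from the model's own generative
  process with a flat baseline expected count (default experiments use
  50 per cell; heterogeneous E is exercised by passing real margins).
  Main effects default to sd 0.5, interactions to a 10% spike fraction
  with sd 1.0 — moderate taxon/environment imbalances and a minority of
  genuine affinities, which is the regime the model targets.
- **Sample tables** plant roles at documented "strong" presets
  (specialist presence rate 0.8 at home, 0.02 away; cosmopolitan 0.7
  everywhere; background 0.05), three OTUs per taxon, with stochastic
  draws deterministically capped/topped-up so the planted property holds
  by construction (specialists keep ≥ 90% of occurrences at home;
  cosmopolitans reach ≥ 5 occurrences in the threshold number of
  environments). Per-environment sample counts are uniform; no
  real-data skew is modelled.
- **Sequences** mutate OTU seed sequences by substitutions only, so
  identity is exactly 1 − Hamming/length and the clustering oracle is
  alignment-free and exact. No chimeras, sequencing errors, indels or
  primer bias are simulated — passing tests therefore demonstrate
  algorithmic correctness on clean planted structure, not robustness to
  real 16S artefacts.

All generators are seeded and byte-reproducible, including across
interpreter processes.

## Problem sizes and numerical choices

The heavy test-suite experiments use a 50 × 10 matrix at 4 × 10,000
MCMC iterations (seconds on one CPU thanks to the vectorized sweeps) and
200 × (2 × 2,400) fits for calibration; these sizes give Monte-Carlo
error comfortably inside the asserted tolerances while keeping the whole
suite fast. Collector's-curve checks compare against the closed-form
expectation within three Monte-Carlo standard errors at 400 replicates.
Threshold arithmetic (round-half-up) is computed as ⌊0.9·n + 0.5⌋.
Degenerate inputs fail loudly: zero occurrence vectors, all-zero
matrices, zero-sample environments and non-positive expected counts all
raise instead of propagating NaNs.

## Known limitations

- The greedy clustering is quadratic in the number of genotypes per
  comparison-heavy datasets; the k-mer prefilter mitigates but the
  implementation targets method-scale studies, not million-sequence
  corpora.
- The consensus-taxonomy denominator question (assigned vs. all members)
  has no authoritative answer; both are implemented and the default is
  documented above.
- The affinity sampler is a random-walk scheme; for matrices far larger
  than a few hundred taxa, gradient-based samplers would mix better per
  sweep.
- Collector's curves operate on sequence draws; sample-level
  accumulation curves are not implemented.
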
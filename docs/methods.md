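# Methods

`palaeosed` implements two self-contained analysis workflows used in
cave-sediment studies — single-grain luminescence chronology and sediment
ancient-mtDNA authentication — together with a synthetic-data generator that
provides ground-truthed inputs for both. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data do
and do not emulate.

## Equivalent-dose models (`palaeosed.grains`)

All dose models work in natural-log space. For grain *i* with equivalent dose
`d_i` (Gy) and standard error `se_i`, the log dose `z_i = log d_i` carries
measurement error `s_i = se_i / d_i` (the relative error), the standard
small-error approximation. Reported doses are back-transformed with the delta
method.

**Outlier rejection (nMAD).** Grain *i* is rejected when
`|z_i − median(z)| / (1.4826 · MAD(z))` exceeds a threshold. The threshold
defaults to 2.0, a common choice in single-grain practice, and is exposed as a
parameter so its sensitivity can be examined. When `MAD = 0` (zero spread),
grains at the median have an indeterminate score and are kept; any grain off
the median has an effectively infinite score and is rejected.

**Central age model (CAM).** `z_i ~ Normal(log δ, σ² + s_i²)`, maximised over
(`log δ`, `σ ≥ 0`) with L-BFGS-B. `σ` is the overdispersion — relative
between-grain spread beyond measurement error. The standard error of `log δ`
comes from the observed information, `1/√Σ wᵢ` with `wᵢ = 1/(σ̂² + s_i²)`;
with equal `s_i` and `σ̂ = 0` the estimator reduces exactly to the arithmetic
mean of log doses, which the tests assert against that closed form.

**Finite mixture model (FMM).** A k-component normal mixture in log dose with
per-grain sd `√(σ_b² + s_i²)`, where `σ_b` is a fixed overdispersion supplied
per fit (default 0.10; the appropriate value is site-specific and the
parameter is deliberately explicit). Fitting is EM with 10 restarts from
jittered dose quantiles under a caller-supplied RNG seed, so fits are
reproducible. k is selected by BIC with `2k − 1` free parameters; ties break
toward higher likelihood and then lower k. A component whose proportion
collapses below 10⁻³ triggers a refit at smaller k.

**Minimum age model (MAM, 3-parameter).** Log doses follow a point mass of
weight `p` at `γ` (the log dose of the fully bleached population) plus a
normal of mean `γ` and sd `σ` truncated below at `γ` (partially bleached or
intruded older grains); each observation adds Gaussian noise
`√(s_i² + σ_b²)`. The likelihood is maximised by Nelder-Mead over
(`logit p`, `γ`, `log σ`); the standard error of `γ` is obtained from the
curvature of the profile log-likelihood (finite differences at ±0.02 in log
dose, with the nuisance parameters re-optimised). If the profile is flat —
all grains consistent with a single dose — the CAM result is returned with a
warning, flagged in the fit's `extra` dict.

**Reliability.** A fitted distribution is `single_component` (k = 1),
`dominant_component` (k > 1 and the largest proportion ≥ 0.70) or `mixed`.
The 0.70 threshold is inclusive.

## Ages and paired-age combination (`palaeosed.ages`)

`age = D_e / dose rate`, with relative errors combined in quadrature. Errors
are split into an *unshared* (random) component — the D_e error and the dose
rate's random error — and a *shared* (systematic) component from the dose
rate's systematic error (calibration factors, internal-K, cosmic-ray
estimates). Which laboratory sources are systematic is a property of the
input dose-rate table, not of this code; the split enters as two numbers.

Paired quartz-OSL and K-feldspar-pIRIR ages combine as an inverse-variance
weighted mean using only the unshared errors; the shared relative error
(mean of the pair, or a dataset-wide override such as 0.04) is re-added in
quadrature to the combined uncertainty. The OSL/pIRIR consistency check is
the arithmetic mean of per-pair ratios with its standard error of the mean,
flagged consistent when within 1.96 SEM of unity.

## Bayesian phase chronology (`palaeosed.chronology`)

Layers are phases ordered oldest → youngest, each with a start (older) and
end (younger) boundary in ka BP. Sample *i* in phase *p* has a latent true
age `θ_i ~ Uniform(end_p, start_p)` and likelihood
`age_i ~ Normal(θ_i, unshared_se_i²)` — only random errors enter; systematic
errors are common to the whole chronology and are re-added to summary
intervals downstream. Boundaries are a priori uniformly ordered below
`prior_max_age` (default 500 ka, chosen to comfortably exceed the span of
deposits this kind of model is applied to). Adjacent phases either share a
boundary (`allow_gaps=False`) or have independent end/start boundaries
allowing depositional hiatuses.

This is an emulation of the phase/sequence machinery of established
radiocarbon/luminescence modelling platforms, not a port: the subtleties of
span-based boundary priors are out of scope, and correctness is validated by
simulation coverage (true boundaries inside the 95% HPD interval for ≥ 7 of 8
boundaries in ≥ 80% of synthetic 4-layer sites) rather than by matching any
external program's output.

Sampling is Metropolis-within-Gibbs: latent ages are drawn exactly from
truncated-normal conditionals via inverse-CDF (deterministic given the seed);
each boundary takes a random-walk Metropolis step, rejected outright if it
violates the ordering or expels a member age, and otherwise accepted with the
ratio of the phase-span factors `Π (start_p − end_p)^{−n_p}` (the marginal
prior contribution of the uniform latent ages). Proposal scales are tuned
every 100 burn-in iterations toward a 20–40% acceptance rate and frozen at
the end of burn-in so the post-burn-in chain satisfies detailed balance.
Summaries are shortest (highest-posterior-density) intervals at 68% and 95%,
optionally converted to years and rounded to the nearest decade. Effective
sample sizes use the initial-positive-autocorrelation estimator.

Degenerate cases: empty phases are allowed with a warning (their boundaries
are constrained only by ordering); initialization fails with an explicit
error naming the offending phases when observed ages cannot be ordered below
`prior_max_age`.

## Fragment processing (`palaeosed.reads`)

Reference genomes are circular; alignments may wrap the origin and
coordinates are 1-based inclusive, with `end` allowed to exceed the genome
length on a wrapped alignment. Assignment is exact k-mer seeding (default
k = 16) on both strands followed by ungapped extension over the whole
fragment; the per-genome best hit minimises mismatches, with deterministic
tie-breaks (position, then strand, then genome id).

A fragment is assigned to a family only when all hits within one mismatch of
the best lie in a single family — a conservativeness rule in the spirit of
lowest-common-ancestor binning — and its uniqueness score reaches the
threshold (default 25). The score is `3 × (best score − best score in any
other family)`, capped at 60 (60 when no other family has a hit), a
Phred-like gap score: it reproduces the *semantics* of a mapping-quality
cutoff without reproducing any specific aligner's MAPQ formula. The gap is
taken against other *families* rather than other genomes so that close
intra-family reference variants do not destroy uniqueness.

Length filtering keeps aligned fragments of ≥ 35 bp (inclusive).
Deduplication has two modes mirroring the two capture protocols: `sequence`
(identical sequences collapse; survivors must be seen ≥ 2 times — the
mammalian-capture rule) and `coordinate` (fragments sharing genome, start,
end and strand collapse; min count 1 — the human-capture rule). Both are
idempotent because duplicate counts sum on collapse.

Terminal C→T annotation rewrites the reference segment onto the read's own
strand, so damage on reverse-strand reads (G→A on the forward reference) is
flagged identically. The frequency denominator is the number of fragments
with a reference C at the terminus, with the window (default: the single
outermost base at each end) configurable. Counting all fragments in the
denominator instead is possible by construction of the emitted counts.

Paired-end read merging is upstream of this package's inputs: fragments
arrive pre-merged and a pass-through `merged` flag preserves the data model.

## Authentication (`palaeosed.authenticate`)

A family in a sample is called ancient when all three criteria hold:

1. ≥ 1% of all family-assigned fragments belong to the family;
2. ≥ 10 assigned fragments are putatively deaminated (terminal C→T at either
   end);
3. the terminal C→T frequency is significantly above 10%: the lower bound of
   the two-sided 95% Clopper–Pearson interval exceeds 0.10, at either
   terminus by default (requiring both is a config option; with damage
   concentrated at single terminal bases, "either" is the natural reading and
   the default).

The Clopper–Pearson interval is the exact binomial interval (the default of
R's `binom.test`); a Wilson alternative is selectable. `k = 0` returns a
lower bound of 0. Tests verify the bound against an independent
binomial-CDF root-finding oracle for every (k, n) with n ≤ 30.

Before authentication, a family's fragments are restricted to the family's
best reference genome (most aligned fragments; ties break to the
lexicographically smallest genome id for stability).

## Group and lineage assignment (`palaeosed.lineage`)

A mitochondrial group call (e.g. Denisovan, Neanderthal, modern human;
hyaenid haplogroups; ursid species groups) requires the group's derived state
to be supported by significantly more than 10% of informative fragments
(Clopper–Pearson lower bound > 0.10) *and* at three or more unique diagnostic
positions. Informative fragments overlap ≥ 1 diagnostic position after strand
normalization. Modern-human calls use deaminated fragments only, excluding
present-day contamination. Fragments supporting another group's derived state
elsewhere still count (support is per group), but such conflicts are counted
and surfaced. Diagnostic positions whose allele pair matches the deamination
signature (C/T or G/A) are flagged `damage_vulnerable` in panel tables, since
damage can mimic the derived state there; the synthetic generator avoids
creating such positions so that truth-label evaluations are not confounded.

The contaminant count is the number of unique hominin fragments carrying the
modern-human derived state at ≥ 1 modern-specific position; a fragment also
supporting an archaic state still counts (conservative). Endogenous count =
unique hominin fragments − contaminant estimate (clamped at zero with a
warning).

Lineage assignment emulates pseudoalignment with unique-k-mer scoring: a
fragment is assigned to the single lineage whose private k-mers (k = 16,
both strands) it contains most of; ties and zero scores are unassigned,
which preserves the decision semantics (share thresholds over identified
sequences) without an external index format. Denisova 3 pools with
Denisova 4, and Denisova 2 with Denisova 8, reflecting the two deep Denisovan
mtDNA clades. Pools holding ≥ 20% of identified (lineage-assigned) sequences
are called — the stricter share-over-all-endogenous reading is available via
the `min_share` semantics if computed by the caller — and only for samples
whose endogenous count reaches 250.

## Reporting (`palaeosed.report`)

Layer composition is the unweighted mean of per-sample family *percentages*
(each sample's percentages sum to 100 before averaging), so small and large
samples weigh equally; samples with zero assigned fragments are excluded with
a warning (the exclusion threshold is configurable only in the sense that
callers filter their input; the default excludes exactly the zero-assignment
samples). Detection tables round to the nearest integer percentage with ties
away from zero — the convention that reproduces every printed
count/percentage pair the tests check. Haplogroup turnover takes the dominant
*called* group per layer (raw support counts as tie-breaking evidence) and
flags change-points; a change across a no-data layer is bracketed between the
flanking data layers and marked uncertain.

## Synthetic data (`palaeosed.simulate`)

The generator emulates the statistical structure of the real inputs:

* **Panels** — independent random circular genomes per family (inter-family
  divergence ~75%, far above the ≥ 10% the assignment tests assume), optional
  close intra-family variants, diagnostic-position tables (≥ 3 positions per
  group) and six hominin lineage haplotypes sharing their group's derived
  states plus private substitutions (default `max(8, L/150)` sites each,
  ~1–2% pairwise divergence at the default 2 kb genome length).
* **Fragments** — log-normal lengths (arithmetic mean 55 bp, sd 15 bp,
  truncated at 35 bp to mirror the length filter), uniform circular start,
  random strand; C→T damage applied on the fragment's own strand at
  `p_terminal_ct` (default 0.30) in the outermost base of each end and
  `p_interior_ct` (default 0.02) elsewhere. Contaminant fragments come from
  the modern-human haplotype with zero damage. Truth labels (family, source
  lineage/group, contaminant and damage flags) ride on every fragment.
* **Grain samples** — log-normal dose mixtures with overdispersion added in
  quadrature to the per-grain relative error; truth component labels kept.
* **Sites** — ordered layer intervals in ka; each sample's true age uniform
  in its layer, dose × rate giving the main D_e component; reworking adds an
  older component drawn from a stratigraphically older layer.

What the generator does *not* emulate — and therefore what passing tests do
not demonstrate about real data: sequencing error beyond C→T, indels,
quality-score structure, capture bias, fragment-length distributions of real
libraries (the log-normal is a modelling choice, not an inference),
position-decay damage profiles along the read, and reference databases with
realistic inter-family divergence (~10–30% rather than ~75%). Real-data
performance of the family-assignment step in particular will be worse than
the synthetic accuracy figures.

## Problem sizes

Validation studies run at desk scale, chosen to give stable pass/fail
behaviour from binomial/Monte-Carlo error while keeping the suite quick:
grain-model recovery at 300–600 grains; CAM coverage at 200 replicates;
Bayesian coverage at 20 sites × 8,000 MCMC iterations; authentication
sensitivity/specificity at 100 seeds × 300 fragments per family; lineage and
turnover recovery at 20 seeds. `scripts/acceptance.py` recomputes all of
these from scratch plus the printed detection-rate arithmetic.

## Known limitations

* The FMM reports conditional (responsibility-weighted) standard errors, not
  full-information errors accounting for uncertainty in k.
* The MCMC boundary sampler updates one boundary at a time; strongly
  overlapping phases mix slowly (monitor the reported ESS).
* The mapping-quality analogue is a score-gap heuristic; absolute values are
  not comparable to any specific aligner, only the thresholding behaviour is.
* k-mer lineage scoring ignores damage-induced mismatches inside k-mers; with
  heavy interior damage, sensitivity drops (fragments become unassigned, not
  misassigned).
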
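# Methods

This note documents the statistical machinery implemented in `pedvar`, its
assumptions, the defaults that matter, and what the synthetic-data
generators do and do not emulate.

## Pedigree model

A pedigree is a set of records (id, sire, dam, sex, birth year, status)
forming a DAG; unknown parents are modelled as missing links. Validation
enforces uniqueness, acyclicity, parent existence (or, on request,
auto-created phantom records), sex consistency of named parents, and birth
years increasing from parent to offspring. All downstream computation runs
over a topological order, so results are invariant to the input record
order.

*Founder* follows the any-unknown-parent convention (an animal with at
least one unknown parent is a conduit of outside variation); the stricter
both-parents-unknown subset is always computed alongside, because much of
the literature uses it. Every statistic that needs a founder set says which
one it uses.

For kinship arithmetic each unknown parent slot behaves as a distinct,
unrelated, non-inbred phantom: the recursion simply contributes zero for
that slot. This is the standard treatment and is required for animals with
half-known parentage.

## Kinship, inbreeding and derived summaries

The coancestry matrix is built by the tabular method: with
a(i,j) = 2 f(i,j) the additive relationship,

    a(i,i) = 1 + F_i,   F_i = a(sire_i, dam_i) / 2
    a(i,j) = (a(sire_i, j) + a(dam_i, j)) / 2      for j preceding i.

All values are dyadic rationals, so IEEE doubles represent them exactly;
the test suite checks exact agreement (1e-12) with an independent Wright
path-counting oracle that enumerates disjoint ancestor paths. The matrix is
dense; at the intended scale (hundreds to a few thousand animals) this is
a few megabytes.

Derived quantities:

- **Average relatedness** AR_i: the mean of 2 f(i, j) over every animal j
  in the pedigree, including j = i.
- **Mean kinship** MK over a cohort is the mean of f over all ordered pairs
  *including* the diagonal self-kinship terms — the "mean kinship matrix"
  convention of pedigree-management software. An option excludes the
  diagonal, since published reports rarely say which convention they used.
  Gene diversity GD = 1 − MK and founder genome equivalents fge = 1/(2 MK)
  are algebraic identities of MK and are asserted as such on every run.
- **Rate of inbreeding** uses the individual-increase formulation:
  ΔF_i = 1 − (1 − F_i)^(1/(t_i − 1)) for animals with equivalent complete
  generations t_i > 1, where t_i = Σ (1/2)^g over known ancestor positions.
  The exponent discounts the animal's own generation: in an idealised
  population with constant ΔF, E[F] after g discrete generations is
  1 − (1 − ΔF)^(g−1), which makes the estimator unbiased there (and the
  generator test below exploits exactly this). Realized Ne = 1/(2 mean ΔF);
  the demographic estimator 4 N_m N_f/(N_m + N_f) from counts of sires and
  dams actually used is reported alongside, because the two answer
  different questions and published "Ne" values rarely state their
  estimator. The census N for Ne/N ratios is a user input.
- Kinship is always computed on the full pedigree and then *subset* to a
  cohort; truncating the pedigree first would change F.

## Gene drop

Each replicate assigns two globally unique alleles to every root genome
source — founders with both parents unknown carry their own pair; every
unknown parent slot of a partially known founder contributes a phantom root
— and transmits one allele per parent uniformly at random down the
topological order. Retention r_f is the expected fraction of a root's two
alleles present in the scored cohort, and founder genome surviving is
FGS = Σ_f r_f. The named statistic is reported with its Monte-Carlo
standard error (between-replicate), and scoring can be restricted to named
(non-phantom) roots. Defaults: 10,000 replicates, cohort = all named
animals. Note that with the whole pedigree as cohort the founders score
themselves and FGS is deterministic; meaningful FGS values come from a
living or recent cohort, as in the README example. FGS ignores
allele-frequency evenness, so it upper-bounds the kinship-based fge; on
deep random-mating pedigrees the two converge, which the suite checks.

## Marker statistics

For each locus, frequencies are counted over typed genotypes (missing calls
excluded). He = 1 − Σ p² (the *plain* estimator) is the default because it
reproduces the published reference table to its printed precision; the
small-sample-corrected 2n/(2n−1) variant is available by flag.
PIC = He − Σ_{i<j} 2 p_i² p_j² (computed as 1 − Σp² − ((Σp²)² − Σp⁴)).
FIS = 1 − Ho/He, undefined (NaN with a warning) at monomorphic loci.
Frequency vectors that do not sum to 1 (e.g. printed, rounded tables) are
renormalised with a warning, never silently. Cross-locus means are
unweighted by sample size, matching how panel tables are usually printed.

A calibration subtlety the acceptance suite documents: under exact HWE
sampling, E[1 − Ho/He_plain] ≈ −1/(2n) (about −0.003 at n = 174), because
the plain He estimator is biased low by the factor (2n−1)/2n. With the
corrected He the null mean FIS is statistically indistinguishable from
zero. Both facts are asserted; the plain-estimator offset is an order of
magnitude below the published panel mean FIS of −0.018.

## Exact Hardy–Weinberg test

Conditional on allele counts m_1..m_k of n diploids, a genotype array
{n_ab} has probability

    P = n! 2^h Π_a m_a! / ((2n)! Π_{a≤b} n_ab!),   h = # heterozygotes.

The exact p-value is the total probability of arrays no more probable than
the observed one; ties count in the tail (standard convention; ties are
compared with a 1e-9 log tolerance).

Two engines:

- **Exhaustive**: recursive enumeration of the fiber, feasible up to a
  configurable 5·10⁶ arrays; it also verifies the enumeration identity
  Σ P = 1 on every call. This is the oracle.
- **MCMC**: a Metropolis–Hastings chain over individual genotype
  assignments with stationary weight 2^h, whose induced marginal over
  count arrays is exactly the conditional distribution above (the
  multiplicity of assignments per array is n!/Π n_ab!, supplying the
  remaining factors). The proposal redistributes the four alleles of two
  random individuals (the classic two-genotype switch); because the number
  of proposal channels producing a move and its reverse can differ (e.g.
  het+het → hom+hom), the acceptance includes the exact channel-count
  Hastings ratio. Stationarity is verified against the exhaustive engine on
  random small fibers. Defaults mirror common practice for this chain: 100
  batches, 10,000 dememorization steps, 5,000 iterations per batch, with
  the p-value's standard error from the between-batch variance and bitwise
  determinism for a given seed. The inner loop is numba-compiled.
  Significance stars use 0.05 / 0.01 thresholds on the MCMC p.

Calibration runs in the acceptance suite (200-fiber oracle agreement;
type-I error at nominal 0.05 over 1,000 HWE-simulated loci at n = 174 with
the published frequency sets) use 500 iterations per batch — 50,000
retained samples per locus — as their problem size.

## Synthetic data

The pedigree generator emulates a small closed studbook with overlapping
generations. Defaults are fixed to the studied population's structure: 912
records; 83 founders of which 27 have both parents unknown and 56 have one
recorded parent; founders entering over the first nine years; litters of
2–16 pups with target mean 6, drawn beta-binomially (real litter records
are overdispersed and both range extremes occur); an integer breeding-age
window of 2–10 years (the 1.5-year minimum breeding age rounded up to whole
birth years, which the files carry); parent ages drawn from a symmetric
bell around a 5-year target, giving a generation interval of about 5;
random sex with a 0.5 ratio (founder sexes alternate so tiny configurations
always contain both sexes); and a mate-choice policy that by default
rejects parent–offspring, full-sib and half-sib pairs.

Close matings are *planted*: litters in the requested years are reserved
when created (their pups never breed), and after simulation their parents
are reassigned to an eligible related pair — full sibs, half sibs sharing
exactly one parent, or a parent–offspring pair — that is not already a
mating pair. Reserving litters up front keeps litter counts intact and
guarantees a planted mating cannot ripple into accidental close matings
elsewhere, so planted counts are recovered exactly by the classifier
(default plants: 2 full-sib, 21 half-sib, 2 parent–offspring).

A second generator builds an idealised discrete-generation population with
fixed breeder numbers per sex (default 10 + 10 over 20 generations of 50
offspring), for which ΔF = 1/(8N_m) + 1/(8N_f) = 0.025 and Ne = 20 are
known; the ΔF/Ne estimator is validated by recovering these within 10%
(averaged over six replicate pedigrees — a single 1,000-animal pedigree
realizes Ne with ~6% drift noise).

The genotype generator drops Mendelian alleles from founder draws at
configured frequencies (defaults: the embedded 21-locus panel) with an
optional missing-call rate. What it does *not* emulate: mutation,
genotyping error beyond missingness, selection on phenotype, null alleles,
linkage, or the real population's year-by-year census trajectory. Passing
tests therefore demonstrate correctness of the estimators under the stated
sampling models, not robustness to those artefacts.

All generators derive independent named sub-streams from one integer seed,
so pedigree and genotypes can be regenerated independently and every
output is byte-stable for a given seed.

## Numerical and interface choices

- Kinship values are exact in doubles (dyadic rationals); comparisons
  against the path-counting oracle use 1e-12.
- Comparisons against printed three-decimal tables use ±0.005: rounded
  frequency vectors (some printed sets sum to 0.999–1.008) propagate about
  that much into He and PIC.
- Mating percentages divide the count of distinct close-mating parent
  pairs by the total record count — the convention under which 2 full-sib
  matings among 912 records print as 0.22% — with per-offspring counts
  reported alongside.
- Full-sib group statistics are reported both as number of groups and as
  number of member individuals (published phrasing is often ambiguous
  between the two), with singleton groups counted separately.
- CLI exit codes: 0 success, 2 validation failure, 3 runtime error.
  Reports render percentages to 2 decimals and statistics to 3 in TSV;
  JSON keeps full precision. Figures are emitted as tables
  (inbreeding-by-year, F-distribution bins); no plotting dependency.

## Known limitations

- The dense kinship matrix is O(n²) memory; beyond ~20k animals a sparse
  or blockwise approach would be needed.
- The exhaustive HWE engine is exponential in allele count; it exists as
  an oracle and for small fibers, not for production panels.
- Generation intervals use whole birth years, so sub-year age structure is
  invisible.
- FGS depends on the scored cohort; no attempt is made to standardise a
  "living population" definition beyond user-supplied cohorts.
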
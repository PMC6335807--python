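# Methods

## Karyotype model

A race karyotype is a set of Robertsonian fusions over the 19 autosomal
arms of the house mouse; the diploid number is 2n = 40 − 2k for k
fusions.  Fusions are stored canonically `(min, max)` but parsed in
either arm order, since the literature prints both.  Sex chromosomes
never fuse (all fusions in the modelled races are autosomal); attempting
to fuse `X`/`Y` is a parse error.  Race definitions default to female
(XX); individuals carry an explicit sex pair.  Arm sublabels,
heteromorphisms, fissions and non-centric translocations are out of
scope, and races are treated as karyotypically fixed.

## Meiotic configurations

An F1 complement holds one haploid set from each parent plus a sex pair.
Because every autosomal arm occurs on exactly two chromosomes, the
arm-homology pairing structure is a multigraph with exactly 19 edges
whose components are the meiosis-I configurations.  Classification is
purely combinatorial: 2-node components are bivalents (including the
double-edged pair of identical metacentrics — counted as a bivalent, not
a "ring of two"), open paths are chains, simple cycles are rings.  Under
the one-fusion-per-arm invariant every component is a path or a simple
cycle, and every ring has even length; anything else raises an error as
corrupted input.  The sex pair is reported as a separate sex bivalent
and excluded from the autosomal graph.

Chain strings print each metacentric entering-arm first along the
traversal (`18-18.1-1.3-...`).  Since only one direction of a chain is
ever printed in the field, the canonical orientation is defined as the
lexicographically smaller of the two traversal strings; rings start at
the member carrying the smallest arm.  Comparisons should therefore use
`chain_strings_equal`, which treats orientations (and, for rings,
rotations) as equal.

## Segregation and the breeding model

Balanced gametes come from alternate segregation only: alternating
members of each chain/ring, one homolog per bivalent, Cartesian product
across configurations, collapsed to karyotypically distinct classes.
For a single chain this gives exactly two classes; for an odd chain they
differ by one chromosome.  Backcross predictions weight the balanced
classes equally (the null transmission expectation).

The male sterility rule is empirical: males carrying a chain of ≥ 4
(configurable) are classified sperm-free.  Sterility is demonstrated
only for the chain of fifteen; applying the rule to shorter chains emits
an extrapolation warning.  Females are never sterile by rule — their
output emerges from simulation.

The breeding simulator draws, per female cycle: Poisson(ovulation_count)
eggs, Binomial fertilisation, malsegregation of each fertilised egg with
probability `nondisjunction_rate` (only if the carrier has a
multivalent), a 1:1 monosomic:trisomic split of unbalanced zygotes, and
`baseline_loss` for balanced zygotes.  Fates: monosomics die before
implantation (no scar); trisomics implant and die (scar, no birth);
balanced zygotes implant (scar) and are born unless lost.  Hence the
closed form used throughout:

    E[scars − litter] per fertilised egg = rate/2 + (1 − rate)·loss
    E[litter] per cycle = ovulation · fert · (1 − rate) · (1 − loss)

`NondisjunctionModel` inverts the first expression (method of moments on
pooled sums, baseline loss supplied as a known prior) with a
female-level bootstrap percentile interval.  Adjacent-1/adjacent-2
segregation modes are not modelled separately; they are aggregated into
the single nondisjunction rate, since per-mode rates are not available
for this cross.

Default model parameters (`nondisjunction_rate=0.82, ovulation_count=7,
fertilization_prob=0.95, baseline_loss=0.05`) are a one-time calibration
chosen so that carrier litters average ≈ 1.1 against ≈ 6.3 for
within-race females; the rate is a free parameter of the system, not a
measured quantity, and all simulation-based tests set it explicitly.

## Fertility inference

The inferential targets are which category contrasts are nonzero among
{CHBU, CHHN, F1, BC.23, BC.24}, with siblings clustered by parent pair.
Rather than REML mixed models, the package uses design-based inference
chosen to keep the null exact under family exchangeability:

* contrast effects are category-coefficient differences from an OLS fit
  of the response on category dummies plus the body-mass covariate
  (classical covariate-adjusted means, evaluated at a common covariate
  value);
* the null distribution permutes category labels across whole family
  clusters (clusters must be nested within categories — the colony
  design guarantees this), giving an exact level under the null;
* the multiple-contrast family (the four contrasts against CHHN plus
  BC.23−F1) is adjusted by max-T over permutation-studentised statistics.

Sperm counts are analysed as log10 within sperm-positive categories
only; presence/absence across the chain-carrier boundary uses Fisher's
exact test.  Weeks-to-first-litter uses the exact
Wilcoxon–Mann–Whitney test.  The record schema retains `parent_pair_id`
so an external mixed-model fit remains possible on the same CSVs.

## Preference analysis

P is the fraction of near-mesh time spent at the CHHN male; analysis is
on logit P with boundary values clamped at half a time-resolution unit
(ε = 1/(2·duration), configurable) — a convention, since boundary
handling has no canonical definition.  The covariate model regresses
logit P on a CHBU-female indicator, the three centred/scaled between-male
differences (body mass, age, time at mesh; CHHN − CHBU) and a side
indicator.  Male pairs are reused across trials, so uncertainty comes
from a cluster bootstrap over pairs (the stand-in for pair and side
random effects); the per-race null test uses the same clustering.
Bootstrap CIs default to 99% for parameter-recovery work.

## Synthetic data

The generator reproduces the statistical structure the analyses assume:
per-category organ masses and sperm counts (log-normal,
moment-matched) with a positive body-mass slope and sibling clusters;
per-category litter-size distributions as discretised truncated normals
(only mean ± SD summaries exist, so a parametric family had to be
chosen), with 48% of F1 females reproducing and carrier litters bounded
to the observed 1–3 range; implantation scars either parametrically
(Poisson excess) or mechanistically through the segregation simulator;
preference trials with total mesh time ≈ 34.5% of 1800 s, male-pair
reuse (22 of 36 pairs used once per female race) and a pre-scoring
neutral-zone epoch column that analyses must ignore.  Sample sizes
default to study scale (31 F1 females, 58 preference trials, 12–24
control males per race), so power behaviour is comparable.

What the generator does **not** emulate: litter-order effects and
reproductive senescence (follicle depletion in carriers), husbandry
covariates beyond cross duration, genetic background variation,
recombination/introgression on chain chromosomes, oestrus staging, and
real measurement error in organ dissection.  Passing tests therefore
validate the algebra and the inferential machinery at realistic scale
and effect sizes; they do not validate distributional assumptions
against real colonies.

Non-reproducing carrier females are split between behavioural failure
(no implantation, no scars) and implantation-plus-loss (scars without
offspring) via `nonreproducer_scar_prob` (default 0.3), since the two
mechanisms cannot be distinguished from the available summaries; both
knobs are exposed.  Scar undercounting (scars one lower than offspring)
is available as a probability parameter, off by default.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; identical
seeds give byte-identical tables.  Permutation p-values use the
add-one estimator (1 + #extreme)/(1 + B), which is exact-level at
B = 199 for α = 0.05; the degenerate `n_permutations=0` case returns
p = 1.  Calibration tests use 500 null datasets of 60 records;
recovery tests use 200 simulated females × 5 cycles and 50 preference
replicates of 58 trials — sizes chosen to keep Monte-Carlo error well
below the tested tolerances while the full suite runs in seconds.
Ill-conditioned preference designs (condition number > 1e8) warn rather
than fail, since the point fit remains defined.

## Known limitations

* The sterility rule is binary and karyotype-driven; it cannot represent
  intermediate spermatogenic impairment.
* The nondisjunction estimator assumes the baseline loss is known; with
  both free, scar excess alone cannot identify them separately.
* Ring-string orientation/rotation conventions are package-defined, as
  no published convention exists for rings in this notation.
* X-autosome fusions and within-race karyotype polymorphism are
  unsupported.
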
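# Methods

`loadfit` has two halves: an analysis stack that turns an impact-annotated
multi-sample VCF plus individual life-history metadata into mutational-load
statistics and fitness models, and a forward-in-time population simulator
whose outputs have exactly the structure the analysis expects. This note
documents the models, the defaults, the numerical choices, and what the
synthetic data can and cannot show.

## Load metrics

**Impact classes.** SnpEff-style `ANN` annotations are collapsed to four
classes by their impact field: HIGH → LoF (putative loss of function,
treated as strongly deleterious), MODERATE → missense (mildly deleterious),
LOW → synonymous (near-neutral), everything else (MODIFIER, unparseable,
absent) → OTHER. Multiallelic records are split into one biallelic record
per ALT allele, each keeping the ANN entry whose allele field matches; sites
without a matching parseable entry are kept as OTHER with a warning, never
silently dropped.

**Derived-allele convention.** The ALT allele is treated as derived. This is
an assumption, not an outgroup polarisation; with reference-biased or
mispolarised sites the "derived" SFS would fold part of the high-frequency
tail back to low frequencies.

**Site filters.** Only sites called in every individual are retained, and
sites fixed for either allele across all individuals are removed (an
all-heterozygote site is segregating and stays). The complete-call filter
makes the genotype-load denominator identical for every individual.

**Per-individual statistics.** For the three coding classes c:

* allele load p_c = (derived alleles of class c carried) / (derived alleles
  carried over all three classes); undefined (NaN, with a warning) for an
  individual carrying no derived allele;
* expressed load e_c = (homozygous-derived genotypes at class-c sites) /
  n_scored and masked load m_c = (heterozygous genotypes) / n_scored, where
  n_scored is the count of all retained LoF+missense+synonymous sites.
  A `carrier_sites` switch replaces the denominator with the individual's
  carrier-site count, for the alternative reading of "scored genotypes";
* genome-wide heterozygosity = heterozygous genotypes across **all** retained
  sites (including OTHER) × 1000 / callable length in bp. The callable
  length is supplied by the caller (the simulator's genome length, or a
  number taken from upstream coverage masks for real data); the package does
  not re-estimate it from read data, and coverage/quality filtering is
  upstream of its entry point.

**SFS.** Unfolded spectra per class: counts of sites with derived-allele
count 1 … 2N−1; both counts and proportions are written.

**Gene pools.** A LoF site belongs to a group's gene pool if at least one
member carries at least one derived allele; the contrast reports per-group
totals, counts private to each group, and the percent excess of group B over
group A to one decimal.

## Fitness models

* **Transforms are frozen**: square root for LRS (zero LRS is legal), log
  for longevity (adults only, positive years), identity for litter size.
  `boxcox_advise` maximises the Box-Cox profile log-likelihood on a grid
  λ ∈ [−2, 2] (step 0.01) and maps |λ| ≤ 0.25 → log, (0.25, 0.75] → sqrt,
  else identity — but it is advisory output only.
* **Trait LMs** are ordinary least squares with sex and rodent-cycle phase
  as default covariates, two-sided t tests, 95% CIs and R²; rank-deficient
  designs raise an error naming the collinear terms.
* **Juvenile survival** uses a binomial GLM with logit link and Wald z
  tests. Separation is detected on the scale of the fitted linear predictor
  (|η| > 30), not the coefficients, because load predictors live on a ~10⁻³
  scale where coefficients in the thousands are legitimate; a detected
  separation raises an error advising a penalised fit.
* **Ancestry LMMs** are random-intercept models (natal den) fitted by REML,
  with rodent phase (and sex, where applicable) as fixed effects and
  treatment coding against a configurable reference (native, or
  native×native for litters). F2–F4 individuals are pooled into one later-
  generation class for the individual-level contrasts. Wald t tests use a
  residual (n − rank) degrees-of-freedom approximation — an approximation,
  documented as such. When the random-effect variance is estimated at the
  boundary the fit is retained, the variance is reported as ~0 with a
  warning, and fixed-effect inference falls back to the exactly equivalent
  OLS fit (whose standard errors are defined).
* **Mann–Whitney U** is exact for combined n ≤ 20 without ties, otherwise
  the normal approximation with tie correction. The location-shift estimate
  is the Hodges–Lehmann median of pairwise differences (B − A), with a ~95%
  CI from the normal approximation to the U distribution on the ordered
  differences.
* **Correlations** are Pearson r with Fisher-z 95% intervals.
* No multiple-testing adjustment is applied across the model battery; the
  pipeline report carries that caveat explicitly.

## Candidate screens

The screens implement the strict reading of the zygosity rules, with
thresholds that reproduce the relaxed variants:

* ancestry screen: LoF absent from every native genome and at derived-allele
  frequency ≥ 20% (inclusive) over hybrid chromosomes (2 × n individuals);
* litter-size screen: every low-fecundity individual carries the allele
  (het or hom, never absent) and no high-fecundity individual is homozygous;
  the homozygous fraction of the low group is reported;
* longevity screen: no long-lived individual is homozygous and the fraction
  of homozygous short-lived individuals is ≥ `min_hom_fraction` (1.0 =
  strict single-hit rule; 0.4 = relaxed rule).

Screens are monotone in their thresholds and invariant to individual and
site ordering (property-tested). Enrichment uses the one-sided Fisher exact
p (hypergeometric upper tail) per term with Bonferroni correction over the
terms actually tested (switchable to all terms); terms with zero candidate
hits are skipped from testing by default.

## The simulator

**Genetics.** Diploid individuals on a single pseudo-autosomal chromosome of
`genome_length` bp (default 2 Mb — a desk-scale stand-in for a callable
genome). Mutations occupy an infinite-sites lattice; each meiosis performs
exactly one crossover at a uniform position. New coding mutations are
assigned LoF : missense : synonymous with probabilities proportional to
1300 : 44,433 : 86,508 (the segregating-count ratio of the study system);
a fourth, neutral non-coding class (annotated MODIFIER) contributes most
heterozygosity. Founders carry standing variation with frequencies drawn
from a neutral 1/i spectrum — they are modelled as a bottleneck sample of a
formerly larger population, so deleterious standing alleles can start at
drift-inflated frequencies and the LoF/synonymous SFS contrast *develops*
over the simulated generations rather than being imposed.

**Selection.** Viability w = Π (1 − s·h)^het (1 − s)^hom per coding class;
defaults s = 0.35, h = 0 for LoF (strong, recessive), s = 0.02, h = 0.2 for
missense, s = 0 for synonymous. The literature gives no class-specific
(s, h) for this system; these are conventional magnitudes. Selection is
**soft**: w is scaled by the cohort mean (capped at 1) before being
multiplied into survival. Absolute (hard) viability with realistic standing
load simply drove the population extinct; with soft selection, density
regulation is handled by the carrying capacity, which is the standard
forward-simulation arrangement.

**Life cycle.** Discrete generations. Adults pair monogamously at random
(established immigrant males always pair, mirroring their documented
breeding success); each pair occupies a den drawn from a finite den pool
with lognormal quality effects. Pair litter size is Poisson with log-mean =
log(base litter) + phase effect + den effect + β_LRS·(pair expressed LoF −
centring) + heterosis·(expected offspring heterozygosity − centring). The
heterosis term uses the *expected offspring* heterozygosity computed from
parental dosages, which is what makes native × immigrant (F1-producing)
litters the largest — the mechanism, masking of recessive load in divergent
crosses, rather than a labelled bonus.

**Traits.** Drawn per birth cohort from predictors computed over the sites
segregating within that cohort — exactly the quantities the load module
recomputes from a VCF of the same cohort, so generative truth and analysis
predictors coincide:

* juvenile survival ~ Bernoulli(w_rel · logit⁻¹(a₀ + β_het·het/kb +
  β_mis·e_mis));
* longevity = (1 + Geometric) · exp(β_LoF,long·(e_LoF − centring)) in
  continuous years (it can dip slightly below one year for heavily loaded
  individuals — kept continuous so the log-linear generative model is the
  model the analysis fits, without rounding bias);
* LRS sums Poisson litters over the individual's breeding years, with
  phase-dependent breeding probability; mean litter size is the mean of
  those draws.

**Immigration.** At a configured generation, immigrant males arrive from an
idealised outbred source: Hardy–Weinberg genotypes at existing sites with
allele frequencies blending the recipients' with an independent draw of the
founding spectrum (`immigrant_divergence`, default 0.6 — the documented
source was a mix of several distinct subpopulations), plus novel
source-private sites per class (default 15 LoF / 60 missense / 120
synonymous / 240 non-coding at diversity 1, a ~1:10 scale-down of the 132
novel LoFs reported for the real rescue). Each novel site is guaranteed to
enter on at least one immigrant haplotype.

**Rodent cycle.** Phase alternates deterministically: the first half of each
`rodent_cycle_period` (default 4) is "increase", the second "decrease".
Litters are larger in decrease years and breeding is more likely in increase
years, matching the directions reported for this system.

**Panel.** The written VCF covers a stratified subsample (default 37) of the
final birth cohort — natives and immigrant descendants, survivors and dead
juveniles — mirroring a deliberately balanced resequencing panel. The full
final cohort, with survival outcomes, is available in memory for
experiments.

**Randomness.** One `numpy` Generator seeded by `SimConfig.seed` feeds every
draw in a fixed order (standing variation, den effects, founder traits, then
per generation: immigration, pairing, litters, meiosis, mutation, sexes,
survival, traits, capacity subsampling, panel choice). A fixed seed gives
byte-identical output files.

**Default scenario.** 36 founders, carrying capacity 120, 18 generations,
immigration of 3 males at generation 15. Trait-effect defaults
(β_LoF,long = β_LoF,LRS = −60 on the e_LoF scale, β_het = 8 per het/kb,
β_mis = −30 on the e_mis scale) were chosen once so that the effects are
strong on the scales the simulator actually produces (e_LoF ≈ 0.002–0.015,
het ≈ 0.2–0.4/kb), comparable to the large R² the genuine study reports,
and so that the default demography is comfortably viable (no extinction in
a 30-seed sweep). The `recovery` scenario (selection off, capacity 500,
survival intercept recentred so outcomes are near 50/50, β_het = 16) is
sized by a standard power analysis (|z| ≈ 2.5 at n = 500) so that
coefficient-recovery experiments test estimator correctness rather than
statistical power.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the study data: impact-annotated
genotypes with purifying selection strongest on LoF, an admixture pulse
introducing novel HIGH-impact alleles, den/phase-structured litters, and
fitness traits causally driven by expressed load and heterozygosity. Tests
passing on it demonstrate that the pipeline's bookkeeping is exact (oracle
equality), its estimators are calibrated (type-I error, CI coverage), and it
recovers causal signs under the assumed model. They do **not** validate the
biological assumptions themselves: no linkage map realism, no genotype
error or missingness, ALT-as-derived holds by construction, environmental
covariates are binary and exogenous, and generations are discrete. Effect
sizes recovered from synthetic data say nothing about effect sizes in any
real population.

## Numerical and degenerate-input choices

* Genotypes are int8 codes (0 hom-ref, 1 het, 2 hom-alt, −1 missing);
  haplotypes uint8. Exact integer tallies; no floating-point accumulation
  in load counts.
* Zero derived alleles → allele-load NaN with a warning (never silent 0);
  empty VCF body → empty table, not an error; a category with no sites →
  all-zero SFS.
* Fisher p values come from `scipy.stats.hypergeom.sf`, verified against
  exact `math.comb` enumeration for every table with universe ≤ 30.
* The Box-Cox grid is deterministic; constant input returns identity with a
  degenerate-data warning.
* MixedLM retries with Powell on linear-algebra failures; boundary variance
  triggers the documented OLS fallback.
* Ties in screens and sorts are broken by stable sort on input order;
  screen output is order-invariant in content.

## Problem sizes used in validation

Validation experiments run at desk scale: coefficient recovery uses 100
replicates of the recovery scenario with fits at n = 500; calibration uses
1000 null replicates per test; direction properties pool three default-
scenario replicates (panels of 37). These sizes give Monte-Carlo error
comfortably below the margins being asserted (e.g. binomial SE ≈ 2% for a
95% coverage estimate at 100 replicates).
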
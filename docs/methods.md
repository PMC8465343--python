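# Methods

## The model

A new allele arises once, on one chromosome. Every modern copy of that
allele sits on a descendant of that founder chromosome, and each descent
path accumulates recombination events that replace flanking material
with unrelated sequence. After τ generations, the probability that a
flank of genetic length *l* Morgans survives unbroken is e^(−τl), so
each flank length is approximately exponential with rate τ and the
two-sided carrier-haplotype length *l* = *l*_left + *l*_right is
approximately gamma(shape 2, rate τ). The shorter the shared haplotypes,
the older the allele.

Given observed lengths *l*₁…*l*ₙ (Morgans), the maximum-likelihood
estimator of the rate of a gamma(2, τ) sample is 2n/Σ*l*ᵢ; because
Σ*l*ᵢ ~ gamma(2n, τ), E[2n/Σ*l*ᵢ] = 2nτ/(2n−1), and the bias-corrected
estimator used here,

    τ̂ = (2n − 1) / Σᵢ lᵢ,

is exactly unbiased under the model. Ages convert to years by a fixed
generation time (default 25 years). Uncertainty is quantified by a
nonparametric bootstrap: n lengths are resampled with replacement,
τ̂ → age is recomputed per replicate, and the distribution is summarized
by its median, raw minimum/maximum, mean, and 2.5/97.5 percentiles. The
raw extrema are reported because they are a conventional summary for
this estimator's bootstrap distribution; the percentile bounds are the
better-behaved interval and are labeled as such.

Assumptions worth stating plainly: one founder (no recurrent mutation),
independent descent paths (no correction for the shared genealogy of the
carriers, which makes lengths positively correlated and the effective n
optimistic), no selection on the haplotype background, a correct
recombination map, and fully observed lengths (no truncation by the
boundaries of the genotyped window).

## Measuring carrier-haplotype lengths from unphased genotypes

Lengths are observed via the homozygotes-first procedure:

1. **Core region.** Among all individuals homozygous for the focal minor
   allele, extend from the focal variant in each direction while every
   carrier is homozygous and all carriers share the same homozygous
   genotype. Homozygotes expose their haplotype directly, so this run is
   the segment shared by all carriers, snapped to the variant grid.
2. **Per-individual extension.** Beyond the core, carriers begin to
   disagree. Stepping one variant at a time over the still-"extending"
   carriers, the majority allele among their homozygous calls is
   determined; a carrier continues iff it is homozygous for that
   majority allele, otherwise its boundary is fixed at the last agreeing
   variant. A direction terminates when no majority can be determined —
   a homozygous-call tie, which subsumes the case of the last two
   extending carriers disagreeing — or at the window end.
3. **Template.** The longest haplotype joins the deepest-reaching left
   and right arms across the core and serves as the phasing template.
   Equal-depth ties resolve to the first individual in input order
   (deterministic; logged if covering alleles ever disagree, which the
   extension rule itself cannot produce).
4. **Heterozygote phasing.** A heterozygote at the focal variant is
   walked outward; it remains consistent while its genotype contains the
   template allele, and stops at the first homozygous-non-template call.
   Phased heterozygote segments never extend beyond the template span.

Numerical/edge conventions, chosen where the procedure itself is silent:

- **Missing calls** stop extension for the affected individual, in core
  finding, homozygote extension and phasing alike. This is conservative:
  it can shorten haplotypes but never fabricates sharing.
- **Boundary convention.** A boundary is the last agreeing variant;
  physical length = right_pos − left_pos (no +1), and genetic length is
  taken between the same two positions. Coordinates are 1-based.
- **Ties.** An exact 50/50 homozygous-call split with more than two
  extending members also terminates the direction (no majority is
  determinable), generalizing the two-member disagreement rule.
- **Zero-length segments** (carrier stopped at the focal variant on both
  sides) carry no recombination signal and are excluded from the length
  sample, with a logged count.

By default only homozygote lengths (one per homozygous individual) feed
the age estimator; `--include-het-haplotypes` adds the template-phased
heterozygote segments. Heterozygote lengths are truncated by the
template span and are phased against an inferred object, so they are
measured but not used for dating unless requested.

The association scan around the focal allele uses a two-sided Fisher
exact test on the 2×2 major/minor allele-count table (point-probability
sum definition, computed from log-binomial coefficients with a 1e-7
relative tie tolerance), pooled-minor-allele orientation with ties
toward the alt allele, missing genotypes excluded from all counts, and
the Levene–Haldane exact Hardy–Weinberg test per group (log-space ratio
recurrence, so cohort-scale counts are no problem). No multiple-testing
correction is applied; results are sorted by p with a flag column at the
informal 5×10⁻⁷ threshold.

## Genetic maps

Maps are the HapMap four-column text format. Cumulative cM is linearly
interpolated in physical position between map points; positions outside
the mapped interval are clamped to the nearest end with a warning rather
than extrapolated (extrapolating edge rates can produce negative or
inflated lengths). The simulator inverts the same map to place
breakpoints, keeping simulation and inference on one coordinate system.

## The synthetic cohort generator

`SimConfig` defaults define the reference study conditions: 197
individuals (71 cases, 126 controls), a focal allele at target MAF 0.272
enriched in controls, 448 variants (~4.5 kb spacing) across a ~2 Mb
window on chromosome 12, founder age τ = 317.4 generations, a constant
1 cM/Mb map, and background allele frequencies uniform on (0.05, 0.95).

Generation proceeds per individual: each of the two haplotypes carries
the founder allele with probability `target_maf` (so the realized MAF is
binomial around the target); carrier haplotypes copy a fixed founder
haplotype over [focal − left arm, focal + right arm] with arms drawn
exponential(rate τ) in Morgans and mapped to bp through the genetic map
(clipped to the window); all other alleles are independent across sites
(linkage equilibrium). Phenotypes are assigned by penetrance-weighted
sampling without replacement so group sizes are exactly (n_case,
n_control); the default penetrance (0.544, 0.185, 0.0 for 0/1/2 copies)
makes the minor allele protective and homozygous-minor individuals never
cases.

Two deliberate idealizations:

- **Homozygous carriers are autozygous for the founder segment**: both
  copies share one breakpoint pair. The detection procedure measures a
  homozygote's *run of homozygosity*, which is the intersection of its
  two haplotypes; modeling the two copies with independent breakpoints
  would make that observable gamma(2, 2τ) and the one-length-per-
  homozygote convention internally inconsistent. With shared breakpoints
  the observed run is exactly one gamma(2, τ) draw, which is the regime
  the estimator assumes.
- **Background in linkage equilibrium** means any extended sharing among
  carriers is attributable to the founder alone. Real SNP-array data has
  background LD, which lengthens chance runs of agreement and would blur
  detected boundaries; passing tests on this generator therefore
  validate the machinery and the estimator's calibration under its own
  assumptions, not robustness to background LD, array genotyping error,
  or genealogical correlation between carriers.

What boundary accuracy to expect on simulated data: inside its true
founder segment a homozygous carrier can never be stopped early by its
own genotypes, so detected segments contain the truth segment snapped
inward to the variant grid (up to rare early termination of a whole
direction by majority ties among chance-extending carriers). Beyond a
true breakpoint a carrier keeps extending while it happens to be
homozygous for the majority allele, a geometric overshoot averaging
under one variant per side for mid-range background frequencies. Both
effects are a few kb against flank lengths of hundreds of kb at
τ ≈ 300, and the end-to-end benchmark bounds their joint impact.

## Problem sizes and benchmark design

The estimator-calibration benchmark uses 1000 Monte-Carlo samples of
n = 188 lengths at τ = 317.4 — n matching the scale of a combined
two-cohort homozygote sample. The end-to-end recovery benchmark
simulates 2000 individuals at MAF 0.3095 (≈190 homozygous carriers, the
scale of the larger public cohort the method targets), over a 6 Mb
window rather than 2 Mb: at τ ≈ 317 a flank exceeds 1 Mb with
probability e^(−3.17) ≈ 4%, so a 2 Mb window would truncate a visible
fraction of lengths and bias τ̂ upward, while beyond ±3 Mb truncation is
negligible (≈7×10⁻⁵ per flank). Variant spacing stays at ~4.5 kb. The
default bootstrap is 100,000 replicates (10,000 in the recovery test,
where the median is already stable to well under 0.5%); replicates are
drawn in fixed-size chunks from a single seeded NumPy generator, so
results are bit-reproducible and memory-bounded.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| `shape` | 2 | — | gamma shape of two-sided lengths (two exponential flanks); the estimator keeps its two-flank bias-corrected form regardless — a documented limitation, not a free parameter of the estimator |
| `years_per_generation` | 25 | years | calendar conversion only |
| `n_bootstrap` | 100,000 | replicates | bootstrap distribution size |
| `seed` | 0 | — | one RNG stream per run |
| `tau_true` | 317.4 | generations | simulator founder age |
| `target_maf` | 0.272 | frequency | expected focal minor allele frequency |
| `n_case` / `n_control` | 71 / 126 | individuals | exact group sizes |
| `n_variants` | 448 | count | ~4.5 kb spacing on the default window |
| `recomb_rate` | 1.0 | cM/Mb | constant-rate map when none supplied |
| `background_freq_range` | (0.05, 0.95) | frequency | background alt-allele frequencies |
| `penetrance` | (0.544, 0.185, 0.0) | P(case) | per focal genotype 0/1/2 |
| `missing_rate` | 0.0 | fraction | optional missing-call injection |

## Known limitations

- The genealogical correlation between carriers is ignored, as is allele
  frequency growth and selection; the bootstrap quantifies resampling
  noise only, not model error. The estimate dates the most recent common
  ancestor of the sampled carriers, a lower bound on the allele's age.
- The exact Hardy–Weinberg p-values are the Levene–Haldane conditional
  test; other software reports χ² or differently-defined exact variants,
  so HWE columns are comparable across tools only in test flavor.
- Input phase is deliberately discarded; if upstream data are already
  accurately phased, that information is not exploited.
- Multiallelic sites are rejected (optionally split keeping the first
  alt); there is no imputation, no liftover, and coordinates are treated
  as opaque within one dataset — mixing genome builds is the user's
  responsibility.
- Window truncation biases lengths short and ages old; choose analysis
  windows generously relative to the expected flank length 1/τ̂ Morgans.
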
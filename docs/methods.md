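# Methods

This note documents the models behind each module, the default parameters
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions that affect results.

## 1. Allele-balance spectra (`ploidy_spectrum`)

At a biallelic heterozygous site with read depths (d_ref, d_alt), the minor
allele fraction is MAF = min(d_ref, d_alt) / (d_ref + d_alt) ∈ [0, 0.5].
Under ploidy *k* with *m* alternate copies, reads are approximately
Binomial(d, m/k), so MAF mass concentrates near min(m, k−m)/k.

Sites are read from VCF with `cyvcf2`. A site is used iff it is biallelic,
genotyped heterozygous, and passes depth/quality floors (defaults: total
depth ≥ 10, GQ ≥ 20 — conventional short-read floors below which allele
balance is dominated by sampling noise). Allele depths come from FORMAT/AD
when present, else INFO/DP4; sites with neither are skipped with a warning
rather than guessed.

Diagnostic windows (closed intervals on MAF):

| ploidy     | expected MAF | window          |
|------------|--------------|-----------------|
| tetraploid | 0.25         | [0.225, 0.275]  |
| triploid   | 1/3          | [0.305, 0.355]  |
| diploid    | 0.5          | [0.45, 0.5]     |

Each window is ±0.025 around the expectation (the diploid window is
half-width because MAF is folded at 0.5). Windows may not overlap; shared
endpoints count as overlap, so every site falls in at most one window.

## 2. Ploidy classification (`ploidy_model`)

The classifier follows the Gaussian-mixture ΔlogL idea of nQuire. Base
frequencies are alternate-read fractions d_alt/(d_ref+d_alt) restricted to
(0.1, 0.9) to exclude homozygous calls and mapping artefacts.

Fixed models: equal-weight Gaussian mixtures with means fixed at
{1/2} (diploid), {1/3, 2/3} (triploid), {1/4, 1/2, 3/4} (tetraploid), and a
single shared standard deviation fitted by bounded 1-D likelihood
maximisation on [10⁻³, 0.5] (scipy `minimize_scalar`, xatol 10⁻⁶).

Free model: a 3-component Gaussian mixture fitted by EM with quartile
initialisation (deterministic — no random restarts), equal initial weights,
sd floor 10⁻³, convergence tolerance 10⁻⁶ on logL, max 1000 iterations.
The E/M steps run in linear space with a density clamp at 10⁻³⁰⁰; this is
safe because the data live in (0,1) and sds are floored, and it is ~20×
faster than log-space.

For each fixed model, Δ = logL_free − logL_fixed ≥ 0 (floored at 10⁻⁴ to
avoid division blow-ups) and the reported statistic is 1/Δ. The best model
maximises 1/Δ; exact ties (within 10⁻⁶) resolve toward the *lower* ploidy,
the conservative direction when claiming a WGD. Per-scaffold mode applies
the same classifier to the `top_n` scaffolds with ≥ `min_sites` usable
sites (defaults 100 and 500), flagging scaffolds below the floor instead of
classifying them.

## 3. Orthogroup copy-number patterns (`orthogroups`)

Orthogroup gene counts per species are reduced to pattern classes with
alphabet {0, 1, 2, multi} per species, labelled in the fixed species order
(e.g. "2:1:1" = two focal copies, one in each sister).

The duplication-excess test uses a pooled 2×2 table:

|                    | duplicated (x:1:1 with x=2) | not |
|--------------------|------------------------------|-----|
| focal species      | a                            | b   |
| both sisters pooled| c = n(1:2:1)+n(1:1:2)        | d   |

where margins count orthogroups in which the species is present (count ≥ 1)
and b, d subtract the duplicated ones. Significance is Fisher's exact test
(two-sided) and the effect size is the conditional maximum-likelihood odds
ratio with its 95% CI (`scipy.stats.contingency.odds_ratio`). Tables with a
zero cell are reported with a one-sided p and an unbounded/zero OR, flagged
`degenerate`, never raised.

Two screening filters mirror common comparative-genomics practice:
`expanded_filter` keeps orthogroups where the focal count strictly exceeds
double each sister's count; `cafe_prefilter` (for 5-species tables) keeps
families with focal − max(other) ≥ 3 and all five species ≥ 1 copy.

## 4. Divergence dating (`divergence`)

Patristic distance is the branch-length sum along the unique path between
two leaves, computed by walking to the common ancestor with cumulative
distances (equivalent to a graph shortest path on a tree; tested against
networkx). For a 2:1:1 quartet tree, the summary reports the copy-to-copy
(homoeolog) distance and, per sister, the mean of both copies' distances to
that sister.

Distributions are summarised by a Gaussian-KDE peak: density evaluated on a
10,000-point grid over [0, 1.05·max] with Silverman bandwidth by default.
Peak location — not mean or median — is used because divergence
distributions are right-skewed by rate variation.

Sequence-level distances: the p-distance counts mismatches over sites where
both sequences have unambiguous ACGT; Kimura 2-parameter distance is
−½ln((1−2P−Q)√(1−2Q)), raising a "saturated" error when the argument is
non-positive.

## 5. Microsynteny (`synteny`)

Gene orders are dense per-scaffold ordinals from coordinate-sorted
positions (stable mergesort keyed by start, orthogroup id, copy tag;
duplicate rows are fatal). For an anchor orthogroup, the reference
neighbourhood is up to `window` = 5 genes per side. In every other
assembly, each copy of the anchor passes iff on each side at least
(available − 1) of the reference neighbours are found within ±(2·window+1)
ordinals of the counterpart — one missing neighbour per side is tolerated
(local loss), a wider span tolerates small inversions. A 2:1:1 anchor is
conserved only if *both* focal copies pass. Failures are classified:
`absent` (no counterpart), `translocated` (counterpart present, no
neighbours found), `rearranged` (some neighbours found, too few).

## 6. Annotation screens (`annotation_screens`)

Inventory: a BLAST-style hit counts as a gene copy iff hit length ≥ 80% of
the query length; presence in any assembly marks the gene present. The
summary reports percent present (integer, half-up) and the multicopy
fraction among present genes (two decimals).

TE bursts: a family passes for a species pair iff copy difference ≥ 100 and
fold ≥ 5 (a zero denominator passes when the difference criterion holds).
Both thresholds must hold so that neither large-but-proportionate families
nor tiny-but-high-fold families pass. Landscape analysis bins copy
divergences into 1%-wide bins as percent of genome; the young-to-mid ratio
compares 0–2% with 3–5% bins, ratio > 2 indicating a recent burst.

## 7. Synthetic generators (`synthetic_data`)

All generators are seeded (`numpy.random.default_rng`) and byte-for-byte
deterministic.

* **Read depths:** per site, a dosage class *m* ∈ {1..k−1} is drawn
  (uniform by default), depth ~ Poisson(60) truncated at ≥ 1, and alternate
  reads ~ Binomial(depth, (m/k)(1−e) + (1−m/k)e) with error e = 0.005.
  This emulates allele sampling and base error but not mapping bias,
  paralog collapse, or depth heterogeneity.
* **Gene families:** a clock tree with WGD at t_wgd = 0.7 and speciations
  at 3.3/3.6 (rate 0.005 per unit time, so expected homoeolog and
  focal-sister divergences are 2·0.005·0.7 = 0.007 and 0.033). A fraction
  `wgd_retention` = 0.4 of families retains both WGD copies (2:1:1);
  background duplication at rate 0.01 per species per family creates the
  analogous classes. Branch lengths get multiplicative lognormal noise with
  mean 1 and CV 0.2. Gene conversion, biased fractionation and rate shifts
  are not modelled.
* **Gene orders:** a reference order is perturbed per assembly by gene loss,
  inversions (span 2–8), and translocations to a second scaffold, all with
  configurable rates; truth events are returned.
* **TE tables:** lognormal base copy numbers with per-species noise;
  planted bursts multiply the focal count by `burst_scale` and add the
  copy-difference threshold, guaranteeing detectability at default filter
  settings.

## 8. Numerical conventions

* All user-facing rounding is half-up (`decimal.ROUND_HALF_UP` on
  `Decimal(repr(x))`), not banker's rounding, so 12.5% → 13%.
* Percentages are computed in exact decimal arithmetic
  (`Decimal(count)·100/Decimal(total)`) before rounding, avoiding binary
  float artefacts at the rounding boundary.
* Fractions reported alongside integer percentages keep two decimals.

## 9. Open design decisions and limitations

* Problem sizes in the recovery tests (10,000 sites, 60× coverage, 100
  replicates; 5,000-site scaffolds; 1,000–5,000 families) are the package's
  own choice: large enough that recovery failures indicate bugs rather than
  sampling noise, small enough for a single CPU in minutes.
* The ploidy classifier assumes a single genome-wide mixture; aneuploidy
  finer than scaffold level, allele-specific expression of mapping bias,
  and contamination are out of scope.
* The microsynteny rule is ordinal-based and ignores physical distances;
  tandem arrays collapse to their copy tags.
* The enrichment test treats orthogroups as independent, as is standard;
  shared tree uncertainty is not propagated.
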
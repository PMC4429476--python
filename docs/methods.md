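# Methods

## The question and the model

Autism spectrum disorder is diagnosed about four times as often in males as
in females (published estimates range from 2.8:1 to 6.4:1, and the largest
mixed-sex GWAS cohort modelled here had 5.25:1 male:female cases).  One
candidate explanation is a female protective effect (FPE): females exposed
to the same inherited risk convert to a diagnosis less often.  The
quantitative severity score used throughout (the Social Responsiveness
Scale, SRS, roughly 0–200 points, higher = more impairment) is strikingly
bimodal among females of multiplex families but unimodal among their
brothers, which is what a *single*, common, dominant protective factor
would produce.  `fpescan` implements that single-locus hypothesis end to
end: its predicted case/control signature, the power of mixed-sex versus
female-only scans to find it, the liability-threshold score distributions
it implies, and a female-only tiered association scan exercised on
synthetic genotypes.

### Single-locus dominant protection (`fpescan.model`)

Let allele 2 of a biallelic locus be protective with population frequency
`q`, acting dominantly and only in females.  Females of multiplex families
are treated as universally exposed to high inherited risk: an exposed
female is diagnosed unless she carries working protection, and a carrier's
protection fails with probability `1 − e` (`e` = `protection_efficacy`).
With Hardy–Weinberg genotypes the female:male incidence ratio attributable
to the locus is

    r_fpe = 1 / (1 − e·q(2−q)),

and the share `s` (`fpe_share`) of an observed ratio `r` attributed to the
locus is interpreted multiplicatively on the incidence-ratio excess:
`r_fpe = 1 + s(r − 1)`.

Two frequency scales are reported.  The *risk-genotype* scale — the share
of a group carrying no working protection — is what a dominant
carrier-versus-noncarrier test compares, and is the scale of the headline
predicted contrast.  The plain allele-frequency scale from enumerating the
six genotype-by-outcome classes is carried alongside.

**The calibrated contrast (97.0% vs <24.3%, carrier OR >88).**  The
`calibrated_4to1` preset fixes `r = 4`, full attribution, and one
calibration constant λ = 0.97: the predicted share of affected females
with the fully unprotected genotype (the "modest deviation from ideal";
the other 3% are carriers whose protection failed).  Solving
`P(affected) = 1/r` together with the λ constraint gives
`(1−q)² = λ/r = 0.2425` exactly, i.e. `q = 0.5076`, `e = 0.9901`.  The
unaffected-group figure is an upper *bound*: it equals the Hardy–Weinberg
noncarrier share `(1−q)² = 24.25%` in the limit of unexposed
(population-like) controls, and any risk exposure among controls removes
unprotected females into the affected group, depleting the noncarrier
class — hence the strict `<`.  The implied carrier odds ratio is
`(0.97/0.03)/(0.2425/0.7575) = 101`.  This derivation was chosen because
the printed trio is *not* jointly attainable on the allele-frequency scale
for any `(q, e, exposure)` of this model family with a sex bias ≤ 5.25
(the allele-2 frequency among protected carriers is capped at `1/(2−q)`,
which would require `q ≥ 0.68`, incompatible with a 97% unprotected case
share); on the risk-genotype scale it drops out exactly.

**The attenuated model (`half_fpe_5.25to1`).**  When the locus explains
only half the bias, the decomposition used is: `q` keeps its ideal
full-ratio value (`(1−q)² = 1/5.25`, `q = 0.5636`) and the efficacy is
scaled down so the attributable factor is `1 + 0.5(5.25−1) = 3.125`
(`e = 0.84`).  The alternative — re-solving `q` at the attenuated ratio
with complete protection — leaves the female case/control contrast at
full strength and makes the mixed-sex scan nearly certain to detect the
locus, which contradicts the scenario this preset exists to express; the
chosen decomposition reproduces the intended ~30%/100% power contrast.

`solve_protective_freq(r, s, e)` solves the general problem (given
efficacy, find `q`), raising `InfeasibleModelError` when the required risk
reduction exceeds what the efficacy permits.

## Power analysis (`fpescan.power`)

Power is computed for a two-sided Fisher exact test comparing the
risk-genotype share between cases and controls, one observation per
subject.  Males are diluting noise: the locus has no phenotypic effect in
them, so a hemizygous male counts as "unprotected genotype" with
probability equal to the population allele-1 frequency, identically in
cases and controls.  Mixed groups therefore pool per individual:

    p_eff = (w_male · (1 − q) + p_female) / (w_male + 1),

with `w_male` the male:female ratio.  An allele-count pooling mode (males
one X allele, females two) is available but is not the default: it leaves
the diluted contrast far too strong to reproduce the intended mixed-sex
power level.

Exact power enumerates binomial outcome pairs `(k1, k2)` (supports
truncated at binomial mass `1e-13`), grouping tables by their margin
`k1 + k2` so that each margin costs a single hypergeometric pmf (computed
via log-gamma) and one sorted cumulative scan; the two-sided p-value
convention (total probability of outcomes no likelier than observed, tie
tolerance `1 + 1e-7`) matches `scipy.stats.fisher_exact` to numerical
precision.  Mid-p is deliberately not used.  Above `max_enum` enumerated
pairs (default `1e7`) a two-proportion normal approximation with
continuity correction is used and a `RuntimeWarning` is issued.

The headline scenario is 2,678 cases vs 2,678 pseudocontrols
(family-based controls treated as ordinary controls with the same 5.25:1
sex composition), Bonferroni alpha `0.05 / n_tests`.  The panel size
behind that alpha is exposed as a parameter; the default is a conventional
round genome-wide figure of 500,000 tests (per-test alpha `1e-7`).  Under
it: ideal model ~100%, attenuated model 28.6%, female-only subset
(428 + 428 subjects, 16% of the cohort) ~100%.  The tier-specific counts
of the targeted female-only study (451 / 6,955 / 317,574) are passed
explicitly where they apply; at 208 cases / 151 controls and the tier-1
alpha the calibrated locus is detected with essentially certain power
(>0.999).

## Liability simulations (`fpescan.liability`)

Scores are normal liabilities with a diagnostic threshold; ties at the
threshold count as affected.

* `expected_threshold_distribution` fits the observed mean/SD, redraws the
  same number of deviates, and places the threshold so the simulated
  affected count is *exactly* the observed one (order statistic), for any
  seed.
* `simulate_factor_scenarios`: score = base draw − (present factors ×
  effect), factors i.i.d. Bernoulli.  Defaults emulate multiplex females:
  base N(100, 20) (the affected mode), presence probability 0.75 (the
  carrier share of a dominant allele at `q = 0.5`), single-factor effect
  90 points = 4.5 SD (the observed distance between the two female SRS
  modes).  One large factor ⇒ bimodal; twenty factors of 4.5 points ⇒
  unimodal; zero factors ⇒ plain normal.
* `simulate_multiplex_ascertainment`: families with 2–4 children (uniform;
  the real family-size distribution is not public, this is the documented
  stand-in), 1:1 child sex ratio, liabilities N(offset·sex, 1), family
  retained when ≥ 2 children are affected.  The diagnostic threshold is
  tuned (`tune_threshold`, Brent root-finding on the normal tail ratio) so
  a 0.66-SD male-female offset yields a 4:1 affected sex ratio
  (`T ≈ 2.02`).  A 0.17-SD offset — the male-female SRS difference seen in
  the general population (3 points at 17.6 points/SD) — cannot reach 4:1
  at any plausible threshold (it would need ~8 SD), so the weak-offset
  scenario reuses the threshold tuned under 0.66 SD.
* SRS points per liability SD is a config constant, default 18.2.  The
  published conversions are not mutually consistent (90/4.5 = 20,
  12/0.66 ≈ 18.2, 3/0.17 ≈ 17.6); each recipe states the constant it
  uses.

Ascertainment alone makes the retained children's score distribution a
reweighted mixture of sub- and supra-threshold truncations, i.e. visibly
bimodal, and more so for the sex with the lower mean liability (rarer
affected ⇒ stronger relative enrichment).  At the 0.66-SD offset the
female-minus-male dip-statistic difference is positive in ≥95% of
replicates; at 0.17 SD the difference shrinks about five-fold but does not
vanish — across 100 replicates of 50,000 families its effect size sits at
≈1.06 replicate SD, i.e. a small systematic female excess remains
detectable at these simulation sizes even though single replicates rarely
show a clear distinction.

## The dip statistic (`fpescan.dip`)

Bimodality is assessed with Hartigan's dip — the sup-norm distance from
the empirical CDF to the nearest unimodal CDF — because the claim under
test is purely "more than one mode", not any particular mixture.  The
implementation is native.  A unimodal CDF is convex up to its mode and
concave after (an atom at the mode allowed), so feasibility of a fit
within half-width `t` decomposes per candidate mode position into a convex
and a concave flank problem.  In step counts, the convex flank is feasible
iff the lower convex hull of the band ceilings clears every band floor
(the hull is the pointwise-greatest convex function under the ceilings),
giving the closed form

    2·n·dip = min over mode positions of max(E_left, E_right)

with hull-versus-staircase flank errors, monotone in the split, hence
locatable by bisection in O(n log n).  Two refinements make this exact:
the [0, 1] range of a CDF (caps on the bands), and mode coupling — the
convex piece's forced floor, propagated by a monotone-slope line envelope,
must not exceed the concave piece's forced ceiling.  The closed form is
confirmed by one exact feasibility probe; when a cap or the coupling binds
(it typically does, slightly), the statistic is recomputed by bisection
against the probe.  The test suite validates the whole construction
against an independent linear-programming oracle on thousands of small
samples, including ties.

The dip test's p-value is a parametric bootstrap from the uniform
distribution (the asymptotically least favourable unimodal case), 1,000
seeded resamples by default, null tables cached per sample size.  The
numerical core is numba-JIT-compiled when available, with an identical
pure-Python fallback.

## Synthetic genotypes and the scan (`fpescan.genotypes`, `fpescan.assoc`)

The default cohort is the discovery shape: 208 affected / 151 unaffected
females, one per family (mirroring the unrelatedness restriction), with
optional SRS scores drawn from status-specific normals 4.5 SD apart.  The
default panel mirrors the discovery arrays: 451 X SNPs inside
X-inactivation-escape regions and outside Y-homology, 6,504 other X SNPs,
plus an autosomal backbone; MAFs uniform on [0.03, 0.5]; Hardy–Weinberg
genotypes independent of status; optional independent missingness.
Linkage disequilibrium is deliberately not simulated — the hypothesis
concerns one common locus and independent SNPs are exactly the null the
scan calibrates against — so the panels say nothing about LD-induced
clumping of association signals in real data.  The chromosome X region
sets shipped as defaults are synthetic stand-ins (the two pseudoautosomal
regions as Y-homology, plus a plausible escape arrangement totalling
~21.8 Mbp, 14% of the chromosome); the real annotation is not
redistributable here.

The embedded locus draws carrier status of the protective allele per
status group at the model-implied rates and splits carriers
heterozygote/homozygote by the Hardy–Weinberg conditional at `q`.  Allele
1 is always the risk allele, matching the reporting orientation.

QC order: samples below 95% call rate, then SNPs by missingness (>0.1),
MAF (<0.03), and the Hardy–Weinberg exact test (p < 1e-4), each SNP
attributed to the first criterion it fails.  The HWE exact test conditions
on allele counts and enumerates the heterozygote distribution by the
standard recurrence.  By default it is computed in unaffected individuals
only: a genuinely associated locus departs from HWE in the pooled sample
(the embedded calibrated locus shows a large heterozygote deficit there
and would be discarded by a pooled filter), and the conventional
case/control practice of the tooling this emulates likewise tests
controls.  Pooled testing remains available.

Tiers: 1 = X SNPs inside escape regions and outside Y-homology, 2 = all X
SNPs, 3 = everything; region files are BED (0-based half-open), SNP
positions 1-based, converted in one place.  The Bonferroni multiplier is
the number of SNPs actually tested in the tier.  The dominant test is a
two-sided Fisher exact test on carriers of allele 1 versus non-carriers
(chi-square available for speed); odds ratios use the Haldane–Anscombe 0.5
correction on empty cells.  The additive test is the Cochran–Armitage
trend test with weights (0, 1, 2).  The genomic-inflation factor is the
median implied 1-df chi-square over its null median.

## Pipeline, sizes and determinism

`run_pipeline` chains cohort → panel (± embedded locus) → PED/MAP/BED/TSV
→ QC → tiered scan → top-k report, writing a manifest with per-stage
seeds, counts and SHA-256 checksums of every output; identical configs
give byte-identical outputs.  All randomness flows from integer seeds
through `numpy.random.default_rng`.

Default problem sizes were chosen to keep full runs comfortable on a
single CPU while preserving the study's shape where it matters: pipelines
default to the real tier-1/tier-2 X panel (451 + 6,504 SNPs) with a
2,000-SNP autosomal backbone standing in for the genome-wide tier;
replicate suites use 200 null scans of 1,000 SNPs (family-wise error),
500 embedded-locus replicates at 208/151 (recovery), and 100 family
simulations of 50,000 families per offset.  The exact power computations
enumerate the full 2,678 + 2,678 scenario directly.

## Known limitations

* No linkage disequilibrium, population structure, relatedness or
  genotyping-batch structure in the synthetic panels; ancestry and
  identity-by-descent cleaning steps of real pipelines are out of scope.
* The male genotype model is "no phenotypic effect"; male genotypes enter
  only as allele-frequency noise in power calculations.
* The calibrated preset reconstructs a published summary row from the
  model's internal logic; its λ = 0.97 constant is a calibration, not a
  fitted quantity.
* The weak-offset ascertainment scenario retains a small systematic sex
  difference in bimodality (see above); conclusions about "no
  distinction" at 0.17 SD hold only approximately at large replicate
  counts.
* Liability is strictly normal within sex; no family-level random effects
  (siblings are independent given sex), which understates familial
  clustering relative to real multiplex data.
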
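# fpescan

Could a *single* common genetic locus — most plausibly on chromosome X —
mediate the female protective effect (FPE) thought to underlie the ~4:1
male:female bias of autism spectrum disorder?  `fpescan` implements the
analytical machinery for that question as a tested Python package, for
statistical geneticists and methods researchers who want to reproduce,
probe or extend the reasoning: the single-locus dominant protection model
and its predicted case/control signature, exact Fisher-test power for
mixed-sex versus female-only GWAS designs, liability-threshold simulations
of SRS-like severity scores (including multiplex-family ascertainment
bias), and a tiered female-only case/control association scan — exercised
entirely on synthetic genotypes the package generates itself.

## The model in brief

A biallelic locus with protective allele 2 at population frequency `q`
acts dominantly and only in females; a risk-exposed female is diagnosed
unless she carries working protection, which fails with probability
`1 − e`.  The locus then accounts for an incidence-ratio factor

    r_fpe = 1 / (1 − e·q(2−q)),

and attributing a share `s` of an observed male:female ratio `r` to the
locus means `r_fpe = 1 + s(r − 1)`.  Under full attribution of a 4:1 bias
with a 3% protection-failure share among affected females, the model
predicts the dominant-test contrast **97.0%** unprotected genotypes among
affected females versus **< 24.3%** among unaffected ones (carrier odds
ratio **> 88**) — a signal so strong that 208 cases vs 151 controls
detect it with essentially certain power.  Diluted by males (who carry
the allele at equal rates in cases and controls), the same locus under
half attribution is missed by a 2,678-case mixed-sex GWAS in two of three
attempts, while the female third of the same cohort detects it always.
Hartigan's dip statistic (implemented natively, with an exact
linear-programming cross-check in the tests) quantifies when score
distributions are genuinely bimodal, as the single-locus hypothesis
predicts for multiplex females.

## Worked example

```python
from fpescan import model, power

cal = model.get_preset("calibrated_4to1")
locus = model.predict_case_control_freqs(cal, n_cases=208, n_controls=151,
                                         n_tests=451)
print(f"affected risk-genotype share {locus.case_allele1_freq:.1f}%")
print(f"unaffected bound             <{locus.control_allele1_freq_bound:.2f}%")
print(f"carrier odds ratio           >{locus.odds_ratio_bound:.0f}")

mixed = power.CohortSpec(2678, 2678, 5.25, 5.25, n_tests=500_000)
half = model.get_preset("half_fpe_5.25to1")
print(f"mixed-sex power      {100 * power.gwas_power(half, mixed).power:.1f}%")
fem = power.female_subset(mixed)
print(f"female-only power    {100 * power.gwas_power(half, fem).power:.1f}%")
```

prints

```
affected risk-genotype share 97.0%
unaffected bound             <24.25%
carrier odds ratio           >101
mixed-sex power      28.6%
female-only power    100.0%
```

i.e. the calibrated locus signature (97.0 vs <24.3, OR > 88), ~30% power
for the large mixed-sex design, and complete power for its female-only
subset.  The same library drives an end-to-end synthetic scan:

```python
from fpescan.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(scenario="embedded", tier=1, seed=1,
                                  out_dir="run1"))
print(manifest["stages"]["association"]["top_hit"])        # 'rsFPE'
```

which simulates 208 affected / 151 unaffected females, a 451-SNP
X-inactivation-escape tier-1 panel with the calibrated locus embedded,
cleans it (call rate, missingness, MAF, Hardy-Weinberg exact test), runs
the dominant Fisher scan with Bonferroni correction, and recovers the
embedded locus as the top hit.  A `fpescan` console script exposes the
same stages (`power`, `simulate-genotypes`, `simulate-liability`,
`assoc`, `pipeline`, `figures`); see `fpescan --help`.

The scientific background, parameter derivations, numerical choices and
limitations are documented in [docs/methods.md](docs/methods.md).

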
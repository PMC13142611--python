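# cnvdose

Federated meta-analysis of recurrent copy-number-variant (CNV) dosage
effects on height and body-mass index.

## The problem

Recurrent deletions (DEL) and duplications (DUP) arise repeatedly at the
same genomic hotspots through non-allelic homologous recombination, which
makes them natural, modular perturbations of gene dosage: the same allele
can be observed in many unrelated carriers, and at segmented hotspots such
as 22q11.2 the breakpoints tile adjacent subregions (A-B, B-C, C-D, …)
individually and in combination. Because individual-level biobank data
cannot be pooled across institutions, analyses of these alleles are
federated: a harmonized per-cohort workflow produces summary statistics, and
only those summaries cross cohort boundaries.

`cnvdose` is that workflow as a tested, reusable Python package, for
statistical geneticists and biobank analysts. It covers:

- **locus genotyping** — assigning per-sample DEL/DUP/REF calls at
  catalogued allele spans from raw BED-like interval calls, with merged
  fragments, a ≥50%-per-segment coverage rule and flanking-segment
  exclusion for composite spans;
- **trait scaling** — within-cohort residualization on sex, age, age²,
  per-sex Box-Cox normalization and standardization, so effects are in
  comparable SD units; pediatric LMS z-scores;
- **per-cohort models** — genotype-factor regressions with ancestry PCs,
  CNV×PGS and CNV×sex interactions, variance explained, medication
  tabulation and carrier-enrichment tests, stratified group means;
- **meta-analysis** — inverse-variance fixed-effects pooling
  (β̂ = Σwᵢβᵢ/Σwᵢ, w = SE⁻², SE = (Σw)^(−1/2)), Fisher-transform pooling of
  √R² with n−3 weights, carrier filters, Bonferroni correction;
- **dose-response structure** — pairing each locus's DEL and DUP meta
  effects and fitting 1- vs 2-component mixtures of linear regressions by
  EM with known measurement error, selected by BIC, to separate "mirror"
  from buffered/asymmetric loci;
- **sex differences** — identity-line F-tests on sex-stratified effects and
  pooled female−male contrasts grouped by effect sign;
- **developmental trajectories** — natural-spline likelihood-ratio tests
  for age-dependent carrier effects, obesity-stratified comparisons and
  age-binned cross-sectional mediation (ACME = a·b, ADE, percentile
  bootstrap);
- **subregion additivity** — observed-vs-expected tests
  (E[A-D] = ΣE[components], z-deviation) with sub-/super-additive tagging;
- **synthetic data** — a fully parameterized multi-cohort generator with
  truth tables, used throughout the test suite.

## Worked example

Run the full federated pipeline on the packaged demo configuration
(3 adult cohorts of 20,000/12,000/8,000 plus one carrier-enriched pediatric
cohort of 6,000; planted effects include a 16p11.2-like mirror pair, a
segmented 22q11.2-like locus and a female-biased 15q11.2-like BMI allele):

```bash
cnvdose run-all --demo --seed 11 --out demo_run
```

which runs in under a minute, prints `{"n_significant": 3}` and writes
per-cohort summaries, pooled tables and a manifest under `demo_run/`.
Inspecting the pooled results:

```python
>>> import pandas as pd
>>> meta = pd.read_csv("demo_run/meta/meta_main.tsv", sep="\t")
>>> cols = ["span", "allele", "beta", "se", "p", "n_carriers"]
>>> meta.loc[meta.trait.eq("height_scaled")
...          & meta.span.eq("16p11.2_BP4-BP5:BP4-BP5"), cols]
                      span allele      beta        se         p  n_carriers
3  16p11.2_BP4-BP5:BP4-BP5    DEL -0.335751  0.141585  0.017722          50
5  16p11.2_BP4-BP5:BP4-BP5    DUP  0.288037  0.137526  0.036223          53
```

The pooled deletion effect, −0.34 SD of sex/age-corrected height, and the
reciprocal duplication effect, +0.29 SD, show the mirror dose-response
pattern; with ~50 carriers per allele both 95% CIs cover the generative
truths (−0.55 and +0.35). The pooled variance explained by all CNV loci,
`report.json` → `pooled_delta_r2`, comes out at 0.27% for height — the
order of magnitude these alleles explain at population scale. The
additivity table (`demo_run/meta/additivity.tsv`) compares the 22q11.2-like
A-D deletion (observed −0.36 SD) against the additive expectation from its
A-B, B-C, C-D components (−1.06 SD): the planted buffering yields z = 1.92,
p = 0.055 at demo carrier counts — detecting it reliably is what the
full-scale acceptance experiment below does. Because every stage is seeded,
rerunning the same command reproduces all outputs byte for byte.

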
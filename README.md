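# copigment

Copigmentation colorimetry for model-wine studies: from visible
absorbance spectra (400–800 nm) to CIELAB color coordinates,
copigmentation-effectiveness (Cp) slopes, hyper/bathochromic effect
classification, family aggregation, group statistics with compact letter
displays, and PCA of the color variables. A synthetic spectrum generator
with known ground truth supports validation and parameter-recovery
testing.

## What it does

- **colorimetry** — resamples spectra onto a fixed 5 nm grid (400–780 nm),
  converts absorbance to transmittance, integrates against the embedded
  CIE 1964 10° observer under illuminant D65 (trapezoidal quadrature,
  whitepoint recomputed on the same truncated grid so a blank maps to
  L\* = 100 exactly), and reports A520, XYZ, L\*, a\*, b\*, C\*ab and the
  signed hue angle hab.
- **copigmentation** — blank subtraction, copigment/pigment mass ratios,
  per-replicate OLS slopes (Cp) of each color parameter on the ratio,
  effect classification, strict best-copigment win counting under the
  direction rule (higher Cp better for A520/a\*/C\*ab, lower for
  L\*/b\*/hab), and two-level product → origin → family aggregation.
- **stats** — Shapiro–Wilk (pooled residuals) + Levene decision tree
  selecting ANOVA/Tukey HSD or Kruskal–Wallis/pairwise rank-sum with Holm
  adjustment; compact letter display by insert-and-absorb; correlation
  PCA with a deterministic sign convention.
- **synth** — Gaussian pigment band with flavylium pH response, a binding
  isotherm with ethanol-sensitive strength, hyperchromic gain and
  bathochromic shift per bound fraction, colored copigment blanks and
  seeded Gaussian noise, plus analytic ground-truth A520 slopes.
- **tables** — packaged fixtures of the printed reference Cp tables
  (per-product values and the pH / ethanol condition tables) used by the
  counting and aggregation operations.

## CLI

```sh
copigment simulate --seed 1 --out data/              # synthetic dataset
copigment cp --manifest data/manifest.csv \
             --spectra data/spectra.csv --out results/   # full pipeline
copigment color --manifest data/manifest.csv \
             --spectra data/spectra.csv --out colors.csv
copigment stats --cp-table results/slopes.csv --out stats.csv
copigment pca --colors colors.csv --out pca/
copigment report --bundle results/
```

`simulate` accepts a JSON or YAML config (see `copigment.io.synth_config_from_dict`
for the keys); every output table carries the package version and a config
hash in a header comment, and reruns are byte-identical.

Spectra are exchanged as long-format CSV (`sample_id, wavelength_nm,
absorbance`); the manifest is a CSV with one row per sample
(`sample_id, role, copigment, family, dose_g_per_L, pigment_mg_per_L, pH,
ethanol_pct, replicate`). Every `mix` row must have a `blank` with the
same copigment/dose/condition/replicate and a `control` at the same
condition.

## Known limitation

One acceptance test
(`tests/test_acceptance.py::TestCriterion6StatisticalPipeline::test_planted_separation_distinct_letter`)
is expected to fail: with 3 groups of n = 3, the specified decision tree
cannot give a separated group its own letter in ≥ 95 % of seeds. The
pretests route ~10 % of seeds to the nonparametric branch, where the
minimum exact two-sided rank-sum p-value at n = 3 vs 3 is 0.1 (never
significant), and Tukey HSD power at a 3σ shift with n = 3 is only
~0.56. The test is kept faithful to the stated threshold rather than
weakened; the observed rate is asserted in-line for transparency.
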
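# mrscreen

A two-sample Mendelian randomization (MR) screening pipeline for testing many
exposures against one outcome from GWAS summary statistics, plus a synthetic
summary-statistics generator with known ground truth so every stage is
testable without any external data.

The pipeline per exposure:

1. **Instrument selection** (`mrscreen.instruments`) — p-value threshold
   (default p < 1e-5), greedy LD clumping (drop r² ≥ 0.1 within a 500 kb
   window), instrument-strength filtering via
   R² = β²/(β² + se²·N) and F = R²/(1−R²)·(N−2) (drop F < 10), and an
   optional confounder-SNP exclusion list.
2. **Harmonization** (`mrscreen.harmonize`) — align outcome effects onto the
   exposure's effect allele, resolving allele swaps and strand flips;
   palindromic SNPs are oriented by allele frequency or dropped when the
   frequency is within ±0.08 of 0.5 (configurable, or drop all).
3. **Estimation** (`mrscreen.estimators`) — multiplicative random-effects
   inverse-variance-weighted (IVW, main analysis), weighted median with
   parametric-bootstrap SE, and MR-Egger regression (t-based inference),
   all reported as OR per SD of exposure with 95% CI.
4. **Sensitivity** (`mrscreen.sensitivity`) — Cochran's Q, MR-Egger intercept
   test, leave-one-out analysis, and funnel-plot data.
5. **Classification** (`mrscreen.screening`) — an exposure is `risk` /
   `protective` when IVW p < 0.05 with OR above/below 1; a `caution` flag
   marks significant exposures whose WM/Egger point estimates disagree in
   direction with IVW. Raw p-values drive classification (a
   Benjamini-Hochberg column is emitted as extra output only).

`mrscreen.synthetic_data` simulates summary-statistic-level studies: true
SNP→exposure effects, a true causal effect θ, per-SNP horizontal pleiotropy
(balanced or directional, with a configurable invalid-instrument fraction,
InSIDE satisfied by default), and standard errors consistent with allele
frequency and sample size.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: the worked-example
classification, estimator-vs-oracle equivalences, hand-computed fixtures, and
simulation checks of type-I error, parameter recovery, pleiotropy recovery,
weighted-median robustness, and the null distribution of Cochran's Q.

## CLI

```sh
# synthetic study with known truth
mrscreen simulate --config sim.yaml --seed 1 --out-prefix sim/

# instrument selection
mrscreen clump --sumstats exposure.tsv --ld ld.tsv --p-threshold 1e-5 \
    --r2 0.1 --window-kb 500 --f-min 10 --exclude confounders.txt --out iv.tsv

# harmonization
mrscreen harmonize --exposure iv.tsv --outcome outcome.tsv \
    --tolerance 0.08 --out harmonized.tsv --report report.tsv

# full screen over a directory of exposure tables
mrscreen screen --exposure-dir taxa/ --outcome outcome.tsv \
    --config config.yaml --out results/
```

`screen` writes `results.tsv`, `sensitivity.tsv`, `loo.tsv`, `funnel.tsv`,
and `classification.tsv`. Input column names are mapped with a small YAML
column map (`snp`, `ea`, `oa`, `beta`, `se` mandatory; `chr`, `pos`, `eaf`,
`p`, `n` optional); gzipped input is accepted.

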
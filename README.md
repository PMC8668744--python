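# decade-enm

Cumulative-window ecological niche modeling with trend tests for
accumulating occurrence records.

## The problem

Occurrence records of poorly sampled species accumulate slowly and
unevenly: collections cluster near research centers, and each decade adds
records that can reshape the species' estimated potential distribution.
This package implements, as a tested pipeline, the analysis of that
"decade effect": it cleans and windows dated occurrence records
cumulatively (1900–1950, 1900–1960, …), fits a three-algorithm
suitability ensemble per window, and asks two questions of the resulting
series:

1. **Decade effect** — does the predicted potential area grow as records
   accumulate? Tested with beta regression (logit link, precision φ) of
   the predicted-area proportion *p* on the cumulative record count *N*:
   `logit(E[p]) = β₀ + β₁·N`, `p ~ Beta(μφ, (1−μ)φ)`, run for a
   *conservative* area (cells where all three algorithms agree) and a
   *non-conservative* area (cells predicted by any algorithm).
2. **Wallacean distance** — do newly added records lie progressively
   farther from research centers? Per record, the Euclidean distance to
   the nearest center; per year, the maximum distance; then weighted
   least squares of yearly maxima on year, weighted by each year's
   record count. The adjusted R² is reported (it can be negative).

Per window the modeling follows standard presence-only practice: layers
are reduced by PCA to the axes explaining ≥ 95% of variance; 50
pseudo-absences are drawn outside the presences' environmental envelope;
10,000 background points are drawn over the study area; a
maximum-entropy-style regularized binomial model (MXT), a random forest
(RDF) and an RBF support vector machine (SVM) are fitted; skill is the
true skill statistic (TSS = sensitivity + specificity − 1) on a
checkerboard geographic two-fold split; maps are binarized at the
threshold maximizing sensitivity + specificity and summed into a 0–3
agreement ensemble.

A virtual-species simulator (smooth multi-layer landscapes, logistic
suitability truth, center-biased decade-stamped sampling) makes the whole
pipeline testable against known truth, with no downloads.

## Worked example

`examples/full_decade_analysis.py` simulates the default study
conditions (100×100 landscape, eight periods adding
30, 1, 9, 8, 3, 23, 70, 9 records — 153 in total — with collection bias
toward 5 research centers) and runs everything:

```
   period  added_points  total_points  tss_mxt  tss_rdf  tss_svm
1900–1950            30            30    0.474    0.654    0.741
...
1900–2010            70           144    0.627    0.887    0.831
1900–2020             9           153    0.625    0.871    0.774

decade effect, conservative:     slope=0.00192  p=0.000
decade effect, non-conservative: slope=0.00012  p=0.805
Wallacean distance: slope=0.00160  adj R2=0.193  F=16.330  p=0.000
```

Reading the output: each row is one cumulative window with its record
count and per-algorithm cross-validated TSS. The conservative
decade-effect slope (per added record, on the logit scale of area
proportion) is positive and significant here — the strictly agreed area
grows as records accumulate — while the non-conservative area shows no
trend. The other examples (`simulate_virtual_species.py`,
`evaluate_one_window.py`) demonstrate the generator and the single-window
modeling stages.

A thin CLI wraps the same functions for shell use:

```bash
decade-enm simulate --rows 100 --cols 100 --out synthetic/
decade-enm run --config synthetic/config.yaml
decade-enm report synthetic/out
```

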
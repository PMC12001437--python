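# uromark

Urinary-DNA methylation markers and a three-marker qMSP diagnostic model
for urothelial cancer (UC).

Cystoscopy, the diagnostic gold standard for UC, is invasive; urine
cytology is non-invasive but insensitive. A promising alternative reads
tumor-derived DNA directly from urine: promoter CpG islands of silenced
tumor-suppressor genes are hypermethylated in UC, and quantitative
methylation-specific PCR (qMSP) on bisulfite-converted urinary DNA can
detect that signal cheaply. `uromark` implements the complete
marker-development pipeline at desk scale, for methods developers and
biostatisticians who want every filtering rule and performance statistic
of such a test to be reproducible and testable:

* **Discovery** — differential methylation on 450K-style beta-value
  matrices (Welch test, Benjamini–Hochberg FDR < 0.01, tumor−normal
  Δβ > 0.2), with a blood-leukocyte background screen (mean β < 0.1;
  urinary cell-free DNA is heavily leukocyte-contaminated), WGBS
  interval scanning (|Δ| > 0.05 per 100 kb window), strand-aware
  promoter/CGI panel construction (TSS −2.5 kb / +500 bp), and
  cross-platform candidate intersection.
* **Screening** — qMSP Ct calling (positive iff Ct < 45, strict),
  cell-line sensitivity (> 60%) and urine specificity (> 80%) filters,
  and accuracy ranking to pick the final marker trio
  (*VIM*, *TMEM220*, *PPM1N*).
* **The diagnostic model** — the parallel OR rule: one positive marker ⇒
  UC-positive; all three negative ⇒ UC-negative. Its continuous
  companion is the risk score `45 − Ct` (0 when nothing amplifies)
  combined by max across markers, whose thresholding family is exactly
  the family of OR rules; a logistic-regression comparator is included.
* **Performance** — confusion matrices over a four-group cohort (UC,
  non-neoplastic, benign, other cancers), sensitivity / per-group and
  pooled specificity / PPV / NPV / accuracy as exact integer ratios,
  exact Clopper–Pearson 95% CIs, stage-stratified sensitivity,
  call-pattern and marker-overlap tables, and utilities that reconstruct
  integer counts from published summary rates and CI triples.
* **Synthetic cohorts** — Beta-distributed array matrices with planted
  hypermethylated probes, binomial WGBS sites with hot differential
  intervals, and a calibrated four-group qMSP cohort (108/191/76/57
  samples) with copula-dependent marker positivity, so the whole
  pipeline is testable without any external download.

## Worked example

The published validation-cohort statistics are fully determined by the
printed group sizes, per-group specificities and the true-positive
count; `reproduce-paper` rebuilds the integer confusion matrix and
recomputes everything:

```sh
$ uromark reproduce-paper
metric                  recomputed   printed
sensitivity                 94.44   94.44
specificity_overall         93.52   93.52
ppv                         82.93   82.93
npv                         98.06   98.06
accuracy                    93.75

stage strata (recovered counts and exact 95% CI):
  0a/0is   8/10  80.00%  CI 44.39-97.48%
  I        31/35  88.57%  CI 73.26-96.80%
  II       21/21  100.00%  CI 83.89-100.00%
```

Reading: with 102/108 UC samples called positive and 184/191, 69/76 and
50/57 true negatives in the three non-UC groups, sensitivity is 102/108
= 94.44%, pooled specificity 303/324 = 93.52%, PPV 102/123 = 82.93% and
NPV 303/309 = 98.06%. Each stage stratum's success/trial counts are
recovered uniquely from its printed percentage-plus-CI triple, and the
exact binomial bounds recomputed from those counts re-render the printed
intervals digit for digit. (The command also warns that the published
benign-group specificity of 90.76% is reproduced by no integer count out
of 76; the count consistent with the pooled specificity is 69/76 =
90.79%.)

A full synthetic run of the model end to end:

```sh
uromark simulate --kind qmsp --seed 1 --out-prefix scratch/cohort
uromark diagnose --ct scratch/cohort.ct.csv \
    --calls-out scratch/calls.csv --report-out scratch/report.json
uromark evaluate --calls scratch/calls.csv --out scratch/perf.json
```

With the default calibrated cohort this yields OR-rule sensitivity and
pooled specificity within Monte-Carlo noise of the published operating
point (≈ 94.4% / 93.5%) and a combined-score AUC above every
single-marker AUC.

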
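# Methods

## The discovery cascade

Marker discovery combines two platforms. On 450K-style array data
(beta values β ∈ [0,1], probes × samples), probes with more than 70%
missing values are removed (strictly "exceeding"; probes at exactly 70%
stay). Each remaining probe gets a Welch unequal-variance t-test on the
beta values between tumor and adjacent-normal samples; p-values are
Benjamini–Hochberg corrected across **all** tested probes, and a probe is
flagged significant when adjusted p < 0.01 **and** the tumor-minus-normal
mean difference exceeds 0.2. Selection is one-directional — only
hypermethylation in tumor is of interest, because the downstream assay
(qMSP) amplifies methylated template. A separate leukocyte matrix then
annotates each probe with its mean blood-leukocyte methylation; the
probe passes only if that mean is strictly below 0.1. The rationale is
biological: urinary cell-free DNA carries abundant leukocyte DNA, so a
locus methylated in leukocytes would fire in benign inflammatory
conditions. Survivors are ranked by descending delta, ties by ascending
adjusted p then probe id, and the top 100 kept.

The array-based test uses beta values rather than M-values; at the
effect sizes the cascade targets (Δβ > 0.2) the two are equivalent in
power, and betas keep the thresholds on the same scale as every other
filter. The test function is isolated so an M-value test can be swapped
in.

WGBS-style data are scanned in fixed 100 kb windows anchored at
position 0 of each chromosome (0-based half-open throughout): a CpG is
differential when |tumor − normal| strictly exceeds 0.05, and per-window
differential counts partition the qualifying sites exactly (an invariant
the tests check against a brute-force double loop). Site-level
filtering uses the one-directional tumor − normal > 0.1 rule. The two
candidate streams are intersected at gene level (array ranking wins,
top 25), refined on targeted-panel urine data with the same > 0.1 rule
restricted to the candidate set.

Panel regions are promoters — 2.5 kb upstream and 500 bp downstream of
the TSS, mirrored on the minus strand and clipped at 0 — merged with
CpG-island, shore (≤ 2 kb) and shelf (2–4 kb) intervals into a sorted
non-overlapping union.

**Strictness and float ties.** Every printed threshold is applied as a
strict inequality exactly as written (">", "<"). Because decimal
thresholds are not exactly representable in binary floating point
(0.55 − 0.50 > 0.05 in IEEE arithmetic), methylation differences are
rounded at 1e-9 before comparison, which makes the strict decimal
semantics hold; 1e-9 is far below any meaningful methylation
difference.

## qMSP calling and marker screening

A qMSP well is positive iff its Ct is strictly below 45 cycles; a well
that never amplifies carries the NA sentinel and is negative. Numeric
Ct ≥ 45 is rejected at input — the sentinel is the only representation
of non-amplification, so there is no ambiguity between "late
amplification" and "none". One well per (sample, marker) is assumed;
duplicates are an input error.

Candidates are screened with strict filters — sensitivity > 60% across
tumor cell lines and specificity > 80% in non-cancerous urine — then
ranked by accuracy (TP + TN)/N on a three-group cohort in which both
non-neoplastic and other-cancer samples count as negatives. Ties break
by higher sensitivity, then marker name, making the ranking invariant
to input row order. The top three markers form the panel. The
selection is by accuracy ranking; a maximum-likelihood logistic
regression on the risk scores is provided strictly as a comparator
model, never as the selector.

## The parallel OR rule and its ROC curve

The classifier is deliberately simple: positive if any marker is
positive, negative only if all are. For ROC analysis the rule needs a
continuous score; the package uses the per-marker risk score
`45 − Ct` (0 for non-amplifying wells, which anchors them at the
origin-most end of the curve) combined by **max** across markers. This
is the unique choice whose threshold family reproduces the OR rule: the
combined score exceeds t exactly when some marker has Ct < 45 − t, i.e.
the OR rule at a shared shifted cutoff. In particular, thresholding
just above 0 reproduces the rule at Ct < 45 exactly (a consistency
contract the tests enforce). AUC is trapezoidal, with tied scores
moving together (the Mann–Whitney tie convention; tests verify equality
with the pairwise U statistic on all small fixtures).

The logistic comparator fits by Newton/IRLS (tolerance 1e-8, at most
100 iterations). Perfect separation is flagged, not fatal — the fit
falls back to BFGS and reports coefficients as-is; zero-variance
features are dropped, and with none left the model is intercept-only
(AUC 0.5).

## Performance evaluation

All point estimates are exact integer ratios; percent rendering rounds
half away from zero at two decimals (102/108 → "94.44"). Overall
specificity pools true negatives across the negative groups
(Σtn / Σn), never the unweighted mean of per-group rates. Confidence
intervals are exact two-sided Clopper–Pearson bounds from beta
quantiles, with lo = 0 at x = 0 and hi = 1 at x = n; an analytic check
in the tests confirms coverage ≥ 95% by exact binomial summation on a
(p, n) grid. Stage-stratified sensitivity excludes UC samples with
unknown stage, with a warning carrying the excluded count.

Two reconstruction utilities make published summary tables computable:

* `reconstruct_counts` turns per-group rates and sizes into integer
  counts (round half away from zero) and re-renders each rate,
  warning when no integer count reproduces the printed value. The
  published benign-group specificity of 90.76% is such a case: 69/76 =
  90.79% and 68/76 = 89.47%. The package carries 69 — the count
  consistent with the published pooled specificity 303/324 = 93.52% —
  and surfaces the discrepancy rather than hiding it.
* `recover_counts` recovers (successes, trials) from a printed
  percentage-plus-CI triple by exhaustive search over all counts whose
  point estimate and Clopper–Pearson bounds re-render, at each printed
  string's own decimal precision, to the printed digits. For the three
  published stage strata the recovery is unique: 8/10, 31/35, 21/21.
  The printed bounds match the exact binomial method and no other
  common interval (Wilson and Wald give different digits), which is
  what fixes the CI method choice.

## Synthetic cohorts: what they emulate and what they do not

**Array matrices.** Null probes draw a per-probe baseline mean from a
Beta(0.8, 0.8) distribution (bimodal, like real 450K data) shared by
all groups; per-sample values are Beta-distributed around that mean
with precision `noise_dispersion` (default 50, i.e. a per-value SD of
about 0.06 at β = 0.3 — the scale of inter-individual variation on
arrays). Planted probes get a low normal-tissue mean (uniform on
[0.02, 0.25]), tumor mean shifted up by `planted_delta` (default 0.3),
and leukocyte mean fixed at 0.05, so they represent exactly the marker
class the cascade is built to find. Default group sizes are 50/50/50 —
enough for the t-test to be well-powered at the planted effect while
keeping the suite fast.

**WGBS sites.** CpGs are scattered proportionally to chromosome length
over a two-chromosome 3.5 Mb toy genome (5,000 CpGs by default);
differential sites (delta 0.2) are confined to a random ~10% subset of
the 100 kb windows, emulating the clustered structure of differentially
methylated regions. Methylation estimates are binomial at 30× depth, so
sampling noise is realistic for the stated coverage: at 30× many null
sites fluctuate past the |Δ| > 0.05 site criterion, which is faithful
to why the window-level view (counts per 100 kb) rather than single
sites drives that stage.

**qMSP cohort.** Group sizes default to the published validation cohort
(UC 108 with stages 10/35/21/12 + 30 unstaged, non-neoplastic 191,
benign 76, other cancers 57). Marker calls within a patient share a
latent Gaussian factor (correlation ρ = 0.4): marker m is positive iff
√ρ·Z + √(1−ρ)·E_m < Φ⁻¹(p_m). Independence is not an option — the
published pattern tables (38/39 triple positives being UC) require
strong within-patient dependence. ρ itself is a free parameter with no
published estimate; 0.4 gives a realistic spread of mixed patterns and
is documented as a choice, not a fact. Given ρ, the per-group marker
positivity probabilities are solved by Gauss–Hermite quadrature
(`union_positive_prob`) so the expected OR-rule operating point equals
the published one: VIM fixed at 83/108, the other two markers solved
jointly for a union of 102/108, and each negative group's common
marker rate solved for its published specificity. The solved values
live in the versioned `data/qmsp_defaults.yaml`, not in code. Positive
wells draw Ct from a truncated normal strictly below 45 (UC mean 33,
SD 3.5; non-UC mean 38, SD 3 — less template in incidental positives).

What the generators do **not** emulate: batch and array normalization
effects (betas are taken as already normalized), probe cross-reactivity,
stage-dependent tumor DNA shedding (synthetic stage strata share one
positivity rate, so the published stage gradient is not reproduced —
stage arithmetic is exercised on the published counts instead),
inhibitor-driven qMSP failures, and within-gene correlation of CpG
sites. Passing tests therefore demonstrate that the pipeline's logic,
thresholds and statistics behave exactly as specified under the stated
generative assumptions — not that the markers themselves would validate
in new patients.

## Problem sizes and determinism

Every generator is deterministic given its seed, and all randomness in a
CLI run flows from the single `--seed`. The test suite uses desk-scale
problems: 1,000-probe matrices at 50v50 over 20 seeds for the discovery
recovery study, 200 seeds of the 432-sample qMSP cohort for the
operating-point recovery, 200 random instances for the brute-force
oracle comparisons. These sizes make the recovery estimates' Monte-Carlo
error small relative to the asserted tolerances while keeping the whole
suite under a minute of compute.

## Known limitations

* The accuracy ranking assumes a single well per (sample, marker);
  replicate-well reconciliation is not modeled.
* No sample-level QC gate (e.g. internal-control amplification) exists;
  a sample with all markers failed for technical reasons is
  indistinguishable from a true triple negative.
* The logistic comparator's features are the continuous risk scores;
  fitting on raw Ct or binary calls would be alternative designs.
* `recover_counts` is exhaustive in (x, n) up to `n_max`; printed
  triples with very low precision may recover non-unique counts, which
  the caller must check.
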
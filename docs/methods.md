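# Methods

This note documents the models, parameter choices and numerical conventions
behind `cnvsig`, and what the synthetic benchmarks do and do not demonstrate.

## Copy-number segmentation and calling

Profiles are log2 tumour/reference ratios per clone. Preprocessing averages
replicate spots per clone (entries missing in every replicate stay missing),
drops blacklisted (polymorphic / unmapped / absent) clones, and
median-centres each sample so a global intensity offset cannot masquerade as
a whole-genome shift.

Segmentation is circular binary segmentation. For an arc (i, j] of a
chromosome profile the change statistic is the two-sample pooled-variance t
comparing the arc's mean against the remaining clones, taken in absolute
value; wrap-around arcs are covered by complements of linear arcs, so the
scan over linear arcs covers the circle. Degenerate pooled variance (all
values in both groups constant) maps to +inf when the means differ and 0
otherwise. The maximal arc is accepted when its permutation p-value —
add-one estimator (r+1)/(n_perm+1) over within-segment shuffles — is below
`alpha` (default 0.01, 1000 shuffles; fewer than 100 is rejected as
unstable). The permutation loop stops early once enough exceedances
guarantee the no-split decision; the decision is identical to the full run.
Each recursion node draws its shuffles from a stream keyed by (seed, absolute
offset, length), so a node's p-value does not depend on how the recursion
reached it — this makes segment counts monotone in `alpha` on a fixed seed.
Adjacent segments whose means agree within 1e-9 are merged; the full
"undo-splits" pruning of reference CBS implementations is deliberately out of
scope. Minimum segment width defaults to 2 clones.

Calls: segment mean >= +0.2 log2 is a gain, <= -0.2 a loss, boundaries
inclusive; thresholds are configurable since single-copy changes in admixed
tumours sit near +0.4/-0.6 but purity varies. Missing clones are removed
before segmentation and reported as `missing` calls. Cross-platform
agreement is summarised as percent identical calls over mutually non-missing
positions, one decimal.

## Endpoints and clone-outcome association

Two binary endpoints: 2yDFS (poor = never disease free, or recurrence or
disease death within 24 months; good = disease-free at 24 months) and 5yDSS
(poor = dead of disease by 60 months; good = alive at 60; censored alive
earlier = ineligible, excluded from testing). Contradictory flag
combinations raise rather than silently relabel.

Per clone and alteration type, eligible patients with non-missing calls form
the 2x2 table (altered/not x poor/good); gains and losses of the same clone
are tested as separate hypotheses. The test is the two-sided Fisher exact
test (hypergeometric tail sum); a zero margin yields p = 1 with a warning.
The odds ratio is the sample OR ad/(bc), infinite when b = 0 or c = 0 (CI
reported absent); otherwise a Woolf log-normal 95% interval with
Haldane–Anscombe 0.5 correction when some cell is zero, with an
exact-conditional interval available. No clone-level multiplicity correction
is applied — a deliberate, documented limitation of the procedure being
reproduced; the region rule and downstream expression filters act as the
practical guards.

Regions: clones with p < 0.05 of one type on one chromosome chain while
consecutive significant clones are <= 11.5 Mb apart. Region boundaries are
the first/last clone positions (Mb, closed intervals); region-level
p/OR/CI/n_altered come from the representative clone (minimum p, ties to the
smaller position; a most-altered-patients alternative is available).
Single-clone regions are kept but flagged. Gap statistics (median/mean gap
between consecutive in-region clones) summarise how densely regions are
supported.

## SAM screen and target-gene filters

For probes mapped into a region (single position, closed interval), the
moderated statistic is d_i = (x̄_altered − x̄_neutral)/(s_i + s0) with s_i the
pooled two-sample standard error and s0 the percentile of {s_i} minimising
the coefficient of variation of within-window MAD(d) across windows of s
(median of s when too few probes for windows). The null re-computes d under
label reassignments — exhaustive when the number of distinct assignments is
within the permutation budget (default 1000), sampled otherwise. At each
observed |d| threshold the FDR estimate is (summary of null exceedance
counts across assignments) / (observed count); the selected set is the first
(loosest) threshold where the estimate drops below the target (10%). An
empty selection is a valid outcome and common for true-null regions.

The null summary defaults to the **mean** (the expected-false-calls
convention of the original SAM formulation); `median` and quantile summaries
are available. The mean was chosen after a calibration analysis: with the
median summary, the top observed |d| exceeds the median permutation maximum
about half the time under a global null (the estimate hits 0 and one probe
is spuriously selected in ~50% of null cohorts), while the mean summary
yields spurious selections at roughly the FDR level (~10%), which is the
intended behaviour of the screen. Note a structural property of any
first-crossing FDR rule: under a complete null the probability of a
non-empty selection is approximately 1 − e^(−q) (~9.5% at q = 0.10) plus a
small threshold-scanning bias, irrespective of probe count — measured at
~11.8% over 500 null cohorts here. Consumers should treat occasional
single-probe selections on null data as expected false positives, and rely
on the fold filters to remove them.

Fold changes are ratios of anti-logged group means, oriented so that > 1
means change in the alteration's direction (carrier/comparator for gains,
comparator/carrier for losses). A screened probe becomes a target gene when
its oriented fold is strictly > 2 versus copy-neutral tumours OR strictly
> 3 versus normal testes; both flags are reported so conjunctive analyses
remain possible. Gene sets from the two endpoints are combined by union with
per-probe provenance.

## Classifier and batch normalization

Nearest shrunken centroids: per-probe class offsets d_ik = (x̄_ik − x̄_i) /
(m_k (s_i + s0)) with m_k = sqrt(1/n_k − 1/n), pooled within-class s_i, and
s0 = median(s_i); offsets are soft-thresholded by Δ and centroids
reconstructed around the overall centroid. Prediction minimises the
standardized squared distance to each shrunken centroid minus 2·log(prior);
priors default to training frequencies (uniform available); discriminant
ties break deterministically to the first class in sorted order. Δ is chosen
by stratified cross-validation (default 10 folds, reduced with a warning to
the smallest class size when necessary; seed-controlled fold assignment),
ties broken toward more shrinkage. At Δ = 0 the model provably equals plain
nearest centroids under the same standardization; at Δ beyond the largest
offset, predictions collapse to the prior argmax — both limits are pinned by
tests.

Validation batches are reconciled by per-gene median matching: each gene of
the second batch is scaled (linear scale; equivalently shifted on log2) so
its median equals the reference batch's median. The correction is exact up
to floating tolerance, idempotent, and rank-preserving within samples when
factors are constant across genes.

The multivariate analysis fits the binary five-year outcome on the gene-model
prediction plus IGCCCG risk twice: an ordinary least-squares
linear-probability model (the form clinical reports often use for binary
endpoints, kept verbatim for comparability) and a logistic companion. IGCCCG coding is either continuous (good = 0,
intermediate = 1, poor = 2 — the numeric assignment is this package's
choice) or binary (intermediate+poor merged). Quasi-separation in the
logistic fit (fitted probabilities at 0/1, detected by coefficient blow-up)
is reported with p-values suppressed rather than raised. Survival curves use
the product-limit estimator and separation the two-group log-rank test with
a chi-square(1) two-sided p; no Cox model is fit.

## Synthetic study generator: what it emulates

The generator is the package's test bed and defines its reference
conditions. It produces: a clone map of 4 chromosomes x 50 clones at 1 Mb
spacing (a deliberately compact genome so multi-cohort benchmarks run at
desk scale; coordinates and rules are identical to full-genome use); a
training cohort of 53 tumours with copy-number and expression; a validation
cohort of 54 tumours (expression only) split into two 27-sample batches, the
second carrying per-gene lognormal multiplicative batch factors (sigma 0.3
log2); and 6 normal testis references.

Three regions are planted — chr1 10–20 Mb loss (prevalence 0.25), chr2
25–33 Mb gain (0.18), chr3 5–12 Mb gain (0.15) — with conditional
poor-outcome log-odds of 4.5, 4.5 and +inf on a baseline poor rate of 0.05.
These were calibrated analytically (closed-form mixture arithmetic over
independent carriers) so that the *marginal* carrier-versus-rest odds ratios
land around 13–15 for the finite regions plus one infinite-OR region where
every carrier dies of disease — the strongly penetrant regime the approach
exists to detect. Two consequences are worth stating plainly: the overall
poor-outcome fraction is ~45%, higher than typical cisplatin-treated NSGCT
cohorts, because three regions at prevalence >= 0.15 with this penetrance
arithmetically force it; and endpoint labels are fully concordant between
2yDFS and 5yDSS by default (poor patients recur within two years and die
within five; good patients stay disease-free), with censoring applied only
to the validation cohort (~9% of good patients censored between 2 and 5
years, leaving ~49 of 54 eligible for the five-year endpoint).

Copy number: carriers' region clones shift by +0.4 (gain) or −0.6 (loss)
log2; Gaussian noise sd 0.15; clone-by-sample missingness 2%. Expression:
per-probe baselines uniform on [6, 10] log2, noise sd 0.5; each region
carries 4 dosage probes shifted by log2(2.5) in carriers, signed by
alteration type; ~30 background probes per chromosome are exchangeable
between groups; a couple of unannotated probes exercise bookkeeping. Normals
share the tumour baseline (so the 3x-vs-normals filter mostly matters for
real data where tumour and normal baselines differ). IGCCCG risk is drawn
with outcome-dependent frequencies so the multivariate adjustment is
non-trivial.

What passing benchmarks on these cohorts shows: the pipeline recovers
planted regions (interval Jaccard >= 0.5, ~95% sensitivity), nominates
planted dosage genes (~90% recall), transfers across a batch effect, and
predicts validation outcome near the Bayes rate of the generative model
(~80% median prediction rate against a Bayes ceiling of ~85–90%). What it
does not show: robustness to probe-level annotation error, copy-number
aneuploidy backgrounds, purity variation, non-multiplicative batch
artefacts, or discordant endpoints — none of which the generator simulates.

## Numerical conventions and edge cases

Seeds propagate through `numpy.random.SeedSequence` spawn keys, so every
artifact is reproducible byte-for-byte from (config, seed); CBS node streams
are position-keyed as described. Percentages (concordance, prediction rate)
are reported to one decimal. Probes or clones with undefined coordinates are
excluded from mapping with counts logged. Fisher tables with a zero margin
return p = 1 with a warning; SAM screens need >= 2 samples per group; the
classifier refuses silently-missing probes at prediction time. Benchmark
problem sizes (100 cohorts in the acceptance test, 25 in the acceptance
script; 200/1000 permutations for CBS/SAM defaults) were chosen as the
smallest sizes at which the Monte-Carlo error of the reported rates is well
below the margins being checked.
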
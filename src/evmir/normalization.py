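"""Reference-miRNA validation and dCq normalization.

Two complementary checks precede normalization:

* a model-based stability analysis (variance-components decomposition in
  the spirit of NormFinder): candidate expression on the log2 scale
  (-Cq) is decomposed, per candidate, into intragroup variance and
  intergroup bias; the stability value combines both, lower = more
  stable;
* the pairwise-variation series of Vandesompele et al. (geNorm): V[n] is
  the standard deviation, over samples, of the difference between
  normalization factors built from the best n and n+1 candidates; when
  V drops below 0.15 no further reference gene is needed.

Normalization itself is the Livak convention: dCq(sample, target) =
Cq(target) - mean over reference targets of Cq, i.e. division by the
geometric mean of the reference expressions on the linear scale.
Assumes 100% amplification efficiency throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .panel import REFERENCE_TARGETS
from .plate_io import CqMatrix


@dataclass
class StabilityTable:
    """Per-candidate stability (ascending = best first) with components."""

    table: pd.DataFrame  # index candidate; stability, intra_var, inter_sd
    groups_used: list[str]
    fallback_single_group: bool = False

    @property
    def ranked(self) -> list[str]:
        return list(self.table.sort_values("stability").index)


@dataclass
class PairwiseVariationSeries:
    ranked: list[str]
    v: dict[int, float]  # v[n] compares best n vs n+1 candidates
    threshold: float = 0.15
    pass_3_4: bool | None = None
    truncated: bool = False
    n_samples_used: int = 0


@dataclass
class DcqTable:
    """Reference-normalized Cq per sample per target (cycles).

    Lower dcq = higher relative expression.  A cell is absent whenever
    the target Cq or any reference Cq is missing; samples with every
    reference missing are excluded entirely.
    """

    values: pd.DataFrame
    refs: list[str]
    excluded_samples: list[str] = field(default_factory=list)


def normfinder_stability(
    matrix: CqMatrix,
    groups: Mapping[str, str],
    candidates: Sequence[str] | None = None,
) -> StabilityTable:
    """Model-based reference stability on the -Cq (log2 expression) scale.

    For each group the per-sample level is removed by subtracting the
    sample mean across candidates; residual mean squares per candidate
    are bias-corrected for the shared sample-mean subtraction
    (``sigma2 = (s2 - mean(s2)/(k-1)) * k/(k-2)`` for k >= 3 candidates,
    clipped at zero).  Intergroup bias per candidate is the spread of its
    group means after empirical-Bayes shrinkage toward zero; stability is
    the group average of |shrunk bias| + sampling SD.  With a single
    group the method degrades to ranking by SD, with a warning.
    """
    candidates = list(candidates) if candidates is not None else list(matrix.targets)
    missing = [c for c in candidates if c not in matrix.values.columns]
    if missing:
        raise ValidationError(f"candidates absent from matrix: {missing}")
    k = len(candidates)
    if k < 2:
        raise InsufficientDataError("need >= 2 candidate references")

    expr = -matrix.values[candidates]  # log2 expression scale
    grp = pd.Series({s: groups[s] for s in matrix.sample_ids if s in groups})
    expr = expr.loc[grp.index]
    usable_groups = [g for g, idx in grp.groupby(grp).groups.items() if len(idx) >= 2]

    if len(usable_groups) < 2:
        warnings.warn(
            "fewer than 2 groups with >= 2 samples; falling back to lowest-SD ranking",
            stacklevel=2,
        )
        sd = expr.std(ddof=1)
        table = pd.DataFrame({"stability": sd, "intra_var": sd**2, "inter_sd": 0.0})
        table.index.name = "candidate"
        return StabilityTable(table=table, groups_used=usable_groups, fallback_single_group=True)

    G = len(usable_groups)
    sigma2 = pd.DataFrame(index=candidates, columns=usable_groups, dtype=float)
    gmeans = pd.DataFrame(index=candidates, columns=usable_groups, dtype=float)
    n_per_group: dict[str, int] = {}

    for g in usable_groups:
        sub = expr.loc[grp == g].dropna(axis=0, how="any")
        n_g = len(sub)
        n_per_group[g] = n_g
        x = sub.to_numpy(dtype=float).T  # k x n_g
        sample_mean = x.mean(axis=0)
        z = x - sample_mean  # remove per-sample level
        gene_mean = z.mean(axis=1)
        gmeans[g] = gene_mean
        if n_g >= 2:
            resid = z - gene_mean[:, None]
            s2 = (resid**2).sum(axis=1) / (n_g - 1)
            if k >= 3:
                s2 = (s2 - s2.mean() / (k - 1)) * k / (k - 2)
            sigma2[g] = np.clip(s2, 0.0, None)
        else:
            sigma2[g] = 0.0

    # Intergroup differences and their sampling variances.
    d = gmeans.sub(gmeans.mean(axis=1), axis=0)
    c = sigma2.div(pd.Series(n_per_group), axis=1)
    df = (k - 1) * (G - 1)
    gamma2 = max(0.0, float((d**2).to_numpy().sum()) / df - float(c.to_numpy().mean()))
    shrink = gamma2 / (gamma2 + c) if gamma2 > 0 else c * 0.0
    d_shrunk = d * shrink

    stability = (d_shrunk.abs() + np.sqrt(c)).mean(axis=1)
    table = pd.DataFrame(
        {
            "stability": stability,
            "intra_var": sigma2.mean(axis=1),
            "inter_sd": d.abs().mean(axis=1),
        }
    )
    table.index.name = "candidate"
    return StabilityTable(table=table.sort_values("stability"), groups_used=usable_groups)


def pairwise_variation(
    matrix: CqMatrix,
    ranked: Sequence[str],
    threshold: float = 0.15,
) -> PairwiseVariationSeries:
    """Pairwise variation V[n] between normalization factors.

    The normalization factor over the best n candidates is, per sample,
    the arithmetic mean of their Cqs — the geometric mean on the linear
    scale — so V[n] is an SD of log2 ratios, in cycle units.  Computed on
    pairwise-complete samples.  ``pass_3_4`` evaluates V[3] (3 vs 4
    candidates) against the threshold; with fewer than 4 candidates the
    series is truncated and the decision falls to the last available
    slot, noted via ``truncated``.
    """
    ranked = list(ranked)
    if len(ranked) < 2:
        raise InsufficientDataError("need >= 2 ranked candidates")
    sub = matrix.values[ranked].dropna(axis=0, how="any")
    n_used = len(sub)
    if n_used < 2:
        raise InsufficientDataError("need >= 2 complete samples for pairwise variation")

    v: dict[int, float] = {}
    for n in range(1, len(ranked)):
        nf_n = sub[ranked[:n]].mean(axis=1)
        nf_n1 = sub[ranked[: n + 1]].mean(axis=1)
        v[n] = float((nf_n - nf_n1).std(ddof=1))

    truncated = len(ranked) < 4
    slot = 3 if not truncated else max(v)
    pass_3_4 = v[slot] < threshold
    return PairwiseVariationSeries(
        ranked=ranked,
        v=v,
        threshold=threshold,
        pass_3_4=pass_3_4,
        truncated=truncated,
        n_samples_used=n_used,
    )


def normalize_dcq(
    matrix: CqMatrix,
    refs: Sequence[str] = REFERENCE_TARGETS,
    targets: Sequence[str] | None = None,
) -> DcqTable:
    """dCq(sample, target) = Cq(target) - mean over refs of Cq.

    Equivalent to dividing by the geometric mean of the reference
    expressions on the linear scale; invariant to any per-sample additive
    Cq shift (plate effects cancel).  Cells with any missing input are
    absent; samples missing every reference are excluded with a report
    entry.
    """
    refs = list(refs)
    missing = [r for r in refs if r not in matrix.values.columns]
    if missing:
        raise ValidationError(f"reference targets absent from matrix: {missing}")
    targets = list(targets) if targets is not None else list(matrix.targets)

    ref_block = matrix.values[refs]
    ref_mean = ref_block.mean(axis=1)
    ref_mean[ref_block.isna().any(axis=1)] = np.nan  # all refs required per sample

    excluded = list(matrix.values.index[ref_block.isna().all(axis=1)])
    dcq = matrix.values[targets].sub(ref_mean, axis=0)
    dcq = dcq.drop(index=excluded)
    return DcqTable(values=dcq, refs=refs, excluded_samples=excluded)
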
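"""Independent loop-coded oracles shared across test modules."""

import numpy as np


def stability_oracle(cq: np.ndarray, group_sizes: list[int]) -> np.ndarray:
    """Direct loop-coded variance-components stability computation.

    Independent re-derivation of the estimator: per group, remove the
    per-sample mean across candidates, estimate each candidate's residual
    variance with the shared-mean bias correction, measure intergroup
    bias of the group means with empirical-Bayes shrinkage, and combine.
    """
    x = -cq  # log2 expression
    k = x.shape[1]
    starts = np.cumsum([0] + group_sizes)
    G = len(group_sizes)
    s2 = np.zeros((k, G))
    m = np.zeros((k, G))
    for g in range(G):
        block = x[starts[g] : starts[g + 1]]
        n_g = block.shape[0]
        for j in range(k):
            resid_sq = 0.0
            mean_j = 0.0
            for i in range(n_g):
                z = block[i, j] - block[i].mean()
                mean_j += z / n_g
            m[j, g] = mean_j
            for i in range(n_g):
                z = block[i, j] - block[i].mean()
                resid_sq += (z - mean_j) ** 2
            s2[j, g] = resid_sq / (n_g - 1)
        if k >= 3:
            bar = s2[:, g].mean()
            for j in range(k):
                s2[j, g] = max(0.0, (s2[j, g] - bar / (k - 1)) * k / (k - 2))
    c = s2 / np.array(group_sizes)[None, :]
    d = m - m.mean(axis=1, keepdims=True)
    gamma2 = max(0.0, (d**2).sum() / ((k - 1) * (G - 1)) - c.mean())
    shrink = gamma2 / (gamma2 + c) if gamma2 > 0 else np.zeros_like(c)
    return (np.abs(d * shrink) + np.sqrt(c)).mean(axis=1)
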
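"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy.stats import norm


def brute_force_dispersion_entropy(
    x: np.ndarray, m: int, c: int, d: int, premapped: bool = False
) -> float:
    """Materialize every embedding vector as a tuple, count with a hash map.

    Deliberately naive: python loops, Counter, math.log.
    """
    x = np.asarray(x, dtype=float)
    if premapped:
        z = [int(v) for v in x]
    else:
        mu = x.mean()
        sigma = x.std()
        if sigma == 0:
            z = [1] * len(x)
        else:
            z = []
            for v in x:
                y = norm.cdf((v - mu) / sigma)
                k = math.floor(c * y + 1.0)  # round-half-up of c*y + 0.5
                z.append(min(max(k, 1), c))
    n_vec = len(z) - (m - 1) * d
    counts = Counter(
        tuple(z[i + j * d] for j in range(m)) for i in range(n_vec)
    )
    total = sum(counts.values())
    ent = 0.0
    for cnt in counts.values():
        p = cnt / total
        ent -= p * math.log(p)
    return ent


def anova_by_sums_of_squares(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA by explicit between/within sum-of-squares decomposition."""
    from scipy.stats import f as fdist

    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    F = ms_between / ms_within
    p = fdist.sf(F, df_between, df_within)
    return float(F), float(p)


def one_vs_rest_metrics(cm: np.ndarray) -> dict[str, float]:
    """Macro metrics by explicit per-class tallying over the count matrix."""
    k = cm.shape[0]
    total = cm.sum()
    recalls, specs, precs, f1s = [], [], [], []
    for i in range(k):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        rec = tp / (tp + fn) if tp + fn else 0.0
        sp = tn / (tn + fp) if tn + fp else 0.0
        pr = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * pr * rec / (pr + rec) if pr + rec else 0.0
        recalls.append(rec)
        specs.append(sp)
        precs.append(pr)
        f1s.append(f1)
    return {
        "accuracy": 100 * np.trace(cm) / total,
        "sensitivity": 100 * np.mean(recalls),
        "specificity": 100 * np.mean(specs),
        "precision": 100 * np.mean(precs),
        "f1": 100 * np.mean(f1s),
        "recalls": [100 * r for r in recalls],
    }
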
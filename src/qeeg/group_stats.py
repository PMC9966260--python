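"""Per-feature group screening: one-way ANOVA with Tukey HSD post hoc tests.

Each feature is tested across the three diagnostic groups with a classic
one-way ANOVA; features with omnibus p < alpha are followed up with
Tukey-Kramer pairwise comparisons (valid for unequal group sizes).  P-values
are reported raw, per channel/pair — no correction across features is
applied by default, which inflates the family-wise error rate over the
feature set; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .montage import GROUP_ORDER, Group

#: Reserved column holding group labels in a feature matrix.
GROUP_COL = "group"


def split_by_group(fm: pd.DataFrame, feature: str) -> list[np.ndarray]:
    """Feature values per group, in canonical group order."""
    if GROUP_COL not in fm.columns:
        raise ValueError(f"feature matrix must contain a {GROUP_COL!r} column")
    groups = [g for g in GROUP_ORDER if (fm[GROUP_COL] == g.value).any()]
    return [fm.loc[fm[GROUP_COL] == g.value, feature].to_numpy(dtype=float) for g in groups]


def _check_groups(samples: list[np.ndarray]) -> None:
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for i, s in enumerate(samples):
        if len(s) < 2:
            raise ValueError(f"group {i} has fewer than 2 members")


def anova_oneway(*samples: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across groups."""
    _check_groups(list(samples))
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def tukey_hsd(*samples: np.ndarray) -> dict[tuple[int, int], float]:
    """Tukey-Kramer pairwise p-values, keyed by group index pair (i < j)."""
    _check_groups(list(samples))
    res = stats.tukey_hsd(*samples)
    return {
        (i, j): float(res.pvalue[i, j])
        for i, j in combinations(range(len(samples)), 2)
    }


def screen_features(
    fm: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """ANOVA + Tukey screening of every feature column.

    Returns one row per feature with the omnibus F and p, the three pairwise
    Tukey p-values, and significance flags at ``alpha``.  With ``fdr=True``
    the omnibus flags use Benjamini-Hochberg-adjusted p-values instead of
    the raw ones (off by default; the conventional report is raw per-feature
    p-values).
    """
    features = [c for c in fm.columns if c != GROUP_COL]
    present = [g for g in GROUP_ORDER if (fm[GROUP_COL] == g.value).any()]
    pair_names = [
        f"p_{a.value}_vs_{b.value}" for a, b in combinations(present, 2)
    ]
    if not features:
        cols = ["F", "anova_p", *pair_names, "significant"]
        return pd.DataFrame(columns=cols)
    rows = []
    for feat in features:
        samples = split_by_group(fm, feat)
        f, p = anova_oneway(*samples)
        pw = tukey_hsd(*samples)
        row: dict[str, float | str | bool] = {"feature": feat, "F": f, "anova_p": p}
        for (i, j), name in zip(combinations(range(len(present)), 2), pair_names):
            row[name] = pw[(i, j)]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature")
    if fdr:
        from statsmodels.stats.multitest import multipletests

        table["anova_p_fdr"] = multipletests(table["anova_p"], method="fdr_bh")[1]
        table["significant"] = table["anova_p_fdr"] < alpha
    else:
        table["significant"] = table["anova_p"] < alpha
    for name in pair_names:
        table[f"sig_{name[2:]}"] = table[name] < alpha
    return table
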
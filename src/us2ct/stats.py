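"""Statistical test harness for metric comparisons.

The analysis mirrors common practice for non-normal, heteroscedastic image
metrics: Anderson-Darling normality and Levene variance checks are run as
preliminaries and reported, the Kruskal-Wallis omnibus compares stage
groups, Dunn's rank-based post-hoc locates significant pairs, and a
dependent (paired) t-test handles paired Jaccard comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on pooled ranks with tie correction.

    Returns a symmetric DataFrame of two-sided p-values (diagonal 1).  The
    z statistic for groups i, j is the mean-rank difference scaled by
    sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with T = Σ(t³−t)/(12(N−1)) over
    tied values.  P-values are reported unadjusted.
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for d in data:
        mean_ranks.append(ranks[start : start + d.size].mean())
        sizes.append(d.size)
        start += d.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    p = np.ones((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p[i, j] = p[j, i] = 2.0 * sps.norm.sf(abs(z))
    return pd.DataFrame(p, index=names, columns=names)


@dataclass
class StatsReport:
    anderson: dict[str, tuple[float, float]]    # name → (statistic, 5% critical)
    levene_p: float
    kruskal_p: float
    dunn_p: pd.DataFrame
    significant: pd.DataFrame                   # boolean grid at alpha
    alpha: float = ALPHA
    paired_t_p: float | None = None

    @property
    def any_normal(self) -> dict[str, bool]:
        """Per group: statistic below the 5% critical value ⇒ consistent
        with normality."""
        return {k: s < c for k, (s, c) in self.anderson.items()}


def stats_suite(
    metric_groups: dict[str, np.ndarray],
    paired: tuple[np.ndarray, np.ndarray] | None = None,
    alpha: float = ALPHA,
) -> StatsReport:
    """Run the full test battery on named metric groups.

    ``metric_groups`` maps group label → metric values (≥ 2 groups, each of
    size ≥ 3).  ``paired`` optionally supplies two matched vectors (e.g.
    Jaccard with/without overlay) for the dependent t-test.
    """
    if len(metric_groups) < 2:
        raise ValueError("need at least 2 groups for the omnibus test")
    arrays = {k: np.asarray(v, dtype=float) for k, v in metric_groups.items()}
    for k, v in arrays.items():
        if v.size < 3:
            raise ValueError(f"group {k!r} too small (n={v.size} < 3)")

    anderson = {}
    for k, v in arrays.items():
        with warnings.catch_warnings():
            # scipy is migrating anderson() to a p-value API; the
            # statistic/critical-value form is what we report
            warnings.simplefilter("ignore", FutureWarning)
            res = sps.anderson(v, dist="norm")
        crit_5 = float(res.critical_values[list(res.significance_level).index(5.0)])
        anderson[k] = (float(res.statistic), crit_5)

    levene_p = float(sps.levene(*arrays.values()).pvalue)
    kruskal_p = float(sps.kruskal(*arrays.values()).pvalue)
    dunn_p = dunn_test(arrays)
    significant = dunn_p < alpha
    np.fill_diagonal(significant.values, False)

    paired_p = None
    if paired is not None:
        a, b = (np.asarray(x, dtype=float) for x in paired)
        if a.shape != b.shape:
            raise ValueError("paired vectors must share a shape")
        paired_p = float(sps.ttest_rel(a, b).pvalue)

    return StatsReport(
        anderson=anderson,
        levene_p=levene_p,
        kruskal_p=kruskal_p,
        dunn_p=dunn_p,
        significant=significant,
        alpha=alpha,
        paired_t_p=paired_p,
    )
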
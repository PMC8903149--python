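"""Group rankings, CI-overlap clusters, rank concordance, convergent validity.

Rankings from aligned factor means and from conventional weighted prevalence
are compared on the same footing: normal-approximation confidence intervals
(99.9% by default, guarding against the many pairwise comparisons), ranks
descending by estimate, and contiguous clusters of rank-adjacent groups whose
intervals mutually overlap — within a cluster, rankings are not
interpretable.  Rank concordance uses the matched-pairs signed-rank test with
an exact small-sample null distribution; convergent validity is the
product-moment correlation of aligned factor means with prevalence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


@dataclass
class RankingTable:
    """Per-group estimate, CI, rank and CI-overlap cluster id."""

    table: pd.DataFrame  # index: group; estimate, se, lo, hi, rank, tied, cluster
    ci_level: float

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]

    @property
    def n_clusters(self) -> int:
        if "cluster" not in self.table.columns:
            raise ValueError("run cluster_by_ci_overlap first")
        return int(self.table["cluster"].nunique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def rank_groups(estimates: pd.DataFrame, ci_level: float = 0.999) -> RankingTable:
    """Rank groups by estimate with normal-approximation CIs.

    ``estimates`` needs columns ``estimate`` and ``se`` indexed by group.
    Groups with missing SE are excluded with a warning.  Rank 1 is the
    highest estimate; exact ties keep label order and are flagged.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    df = estimates[["estimate", "se"]].copy()
    bad = df.index[df["se"].isna() | (df["se"] <= 0) | df["estimate"].isna()]
    if len(bad):
        warnings.warn(f"excluding groups with missing estimate/SE: {list(bad)}")
        df = df.drop(index=bad)
    z = norm.ppf(0.5 + ci_level / 2.0)
    df["lo"] = df["estimate"] - z * df["se"]
    df["hi"] = df["estimate"] + z * df["se"]
    df = df.sort_index().sort_values("estimate", ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df["estimate"].duplicated(keep=False)
    return RankingTable(table=df, ci_level=ci_level)


def cluster_by_ci_overlap(ranking: RankingTable) -> RankingTable:
    """Assign contiguous-in-rank clusters of mutually overlapping CIs.

    Scanning groups in rank order, a new cluster starts when a group's CI
    fails to overlap the CI of every group already in the current cluster.
    """
    df = ranking.table.copy()
    clusters = []
    cluster_id = 0
    max_lo = -np.inf
    min_hi = np.inf
    for lo, hi in zip(df["lo"], df["hi"]):
        if clusters and not (lo <= min_hi and hi >= max_lo):
            cluster_id += 1
            max_lo, min_hi = lo, hi
        else:
            max_lo = max(max_lo, lo)
            min_hi = min(min_hi, hi)
        clusters.append(cluster_id)
    df["cluster"] = clusters
    return RankingTable(table=df, ci_level=ranking.ci_level)


def _exact_signed_rank_sf(ranks: np.ndarray) -> dict:
    """Distribution of W+ (sum of ranks with positive sign) over sign flips.

    Works on midranks scaled by 2 so the support is integer; returns the pmf
    keyed by doubled statistic values.
    """
    scaled = np.round(2.0 * ranks).astype(int)
    pmf = {0: 1.0}
    for r in scaled:
        nxt: dict = {}
        for w, p in pmf.items():
            nxt[w] = nxt.get(w, 0.0) + 0.5 * p
            nxt[w + r] = nxt.get(w + r, 0.0) + 0.5 * p
        pmf = nxt
    return pmf


def wilcoxon_signed_rank(
    ranks_a, ranks_b, alternative: str = "two-sided", exact_limit: int = 15
) -> tuple[float, float]:
    """Matched-pairs signed-rank test on paired values.

    Zero differences are excluded; ties get midranks.  The null distribution
    is exact (full enumeration over sign assignments, tie-aware) for up to
    ``exact_limit`` informative pairs, otherwise normal with tie and
    continuity corrections.  Returns (W+, p).  With no informative pairs the
    test is degenerate and p = 1.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have identical length")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided, greater or less")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    r = rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    if n <= exact_limit:
        pmf = _exact_signed_rank_sf(r)
        w2 = int(round(2.0 * w_plus))
        p_ge = sum(p for w, p in pmf.items() if w >= w2)
        p_le = sum(p for w, p in pmf.items() if w <= w2)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return w_plus, float(p)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(r, return_counts=True)
    tie_corr = np.sum(counts**3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if var <= 0:
        return w_plus, 1.0
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / np.sqrt(var)
        p = float(norm.sf(z))
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / np.sqrt(var)
        p = float(norm.cdf(z))
    else:
        z = (np.abs(w_plus - mean) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(z)))
    return w_plus, p


def convergent_correlations(
    factor_means: pd.Series, prevalence: pd.DataFrame, method: str = "pearson"
) -> pd.Series:
    """Correlations of aligned factor means with prevalence columns.

    Groups are matched by index; a zero-variance vector yields NaN (undefined)
    for that column.  ``method`` is ``pearson`` (default) or ``spearman``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    common = factor_means.index.intersection(prevalence.index)
    if len(common) < 3:
        raise ValueError("need at least 3 groups with both scores and prevalence")
    fm = factor_means.loc[common]
    out = {}
    for col in prevalence.columns:
        p = prevalence.loc[common, col]
        if fm.std(ddof=0) == 0 or p.std(ddof=0) == 0 or p.isna().any():
            out[col] = np.nan
        else:
            out[col] = float(fm.corr(p, method=method))
    return pd.Series(out, name=f"corr_{method}")
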
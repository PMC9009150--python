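"""Correlation screens, differential expression, stratification, EMT score,
group comparison, and over-representation statistics.

These are the "around" statistics of the pipeline: Pearson correlations
with two-sided t-based p-values, Welch differential expression with
Benjamini–Hochberg control, quantile stratification of per-sample scores,
the in-silico EMT statistic (sum of z-scored mesenchymal genes minus sum
of z-scored epithelial genes), a Mann–Whitney group comparison for
therapy-response contrasts, and the hypergeometric over-representation
test for user-supplied annotation sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "CorrelationResult",
    "pearson_with_p",
    "vectorized_pearson",
    "de_test",
    "bh_adjust",
    "quantile_stratify",
    "emt_score",
    "group_compare",
    "ora_test",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-based p-value.

    p comes from t = r*sqrt(n-2)/sqrt(1-r^2) against Student t with n-2
    degrees of freedom; |r| = 1 returns p = 0.  Constant input is an
    error (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, p=0.0, n=n)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r=r, p=float(min(p, 1.0)), n=n)


def vectorized_pearson(matrix: np.ndarray, y: np.ndarray):
    """Pearson r and two-sided p of every matrix row against ``y``.

    Rows with zero variance get r = nan, p = 1.  Returns ``(r, p)``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    yc = y - y.mean()
    ynorm = np.sqrt(np.dot(yc, yc))
    xc = matrix - matrix.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((xc * xc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (xnorm * ynorm)
    bad = (xnorm == 0) | (ynorm == 0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, np.minimum(p, 1.0))
    r[bad] = np.nan
    p[bad] = 1.0
    return r, p


def bh_adjust(p) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    expr: ExpressionMatrix, group_a, group_b
) -> pd.DataFrame:
    """Per-gene Welch differential expression between two sample groups.

    Returns a frame indexed by gene with columns ``logfc`` (mean_a -
    mean_b in the log2 domain), ``t``, ``p`` and ``p_adj`` (BH across all
    tested genes).  Genes constant in both groups get t = 0, p = 1.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = expr.subset_samples(group_a).values
    b = expr.subset_samples(group_b).values
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"logfc": logfc, "t": t, "p": p, "p_adj": bh_adjust(p)}, index=expr.gene_ids
    )


def quantile_stratify(scores, k: int = 4) -> pd.Series:
    """Assign each sample a quantile-group label 1..k (group 1 = lowest).

    Breaks are the j/k empirical quantiles (linear / type-7
    interpolation); ties fall in the lower group.
    """
    if k < 2:
        raise ValueError("need at least 2 quantile groups")
    s = pd.Series(scores, dtype=float)
    if len(s) < k:
        raise ValueError(f"need at least {k} samples for {k} quantile groups")
    breaks = np.quantile(s.to_numpy(), np.arange(1, k) / k)
    labels = np.searchsorted(breaks, s.to_numpy(), side="left") + 1
    if np.ptp(s.to_numpy()) == 0:
        warnings.warn("all scores identical; every sample assigned to group 1")
    return pd.Series(labels, index=s.index, name="quantile_group")


def emt_score(
    expr: ExpressionMatrix,
    epithelial,
    mesenchymal,
) -> pd.Series:
    """In-silico EMT score: sum of z-scored mesenchymal genes minus sum of
    z-scored epithelial genes, per sample.  Higher = more mesenchymal.
    """
    gene_pos = set(expr.gene_ids)
    epi = [g for g in epithelial if g in gene_pos]
    mes = [g for g in mesenchymal if g in gene_pos]
    if len(epi) < 2 or len(mes) < 2:
        raise ValueError("each EMT program must match at least 2 genes")
    data = expr.data
    for name, members in (("epithelial", epi), ("mesenchymal", mes)):
        sd = data.loc[members].std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant gene(s) in {name} set: "
                             f"{list(sd.index[sd == 0])[:5]}")

    def zsum(members):
        block = data.loc[members]
        z = block.sub(block.mean(axis=1), axis=0).div(block.std(axis=1, ddof=1), axis=0)
        return z.sum(axis=0)

    score = zsum(mes) - zsum(epi)
    score.name = "emt_score"
    return score


def group_compare(scores, labels) -> dict:
    """Compare a per-sample score between two groups (Mann–Whitney U).

    Uses :func:`scipy.stats.mannwhitneyu` with ``method='auto'``: exact
    enumeration for small tie-free groups, tie-corrected normal
    approximation otherwise.  Returns the U statistic (for the first
    group), two-sided p, group medians, and the direction of the shift.
    """
    s = pd.Series(scores, dtype=float)
    lab = pd.Series(labels)
    groups = list(pd.unique(lab.dropna()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 group labels, got {groups}")
    x = s[lab == groups[0]].to_numpy()
    y = s[lab == groups[1]].to_numpy()
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    med_x, med_y = float(np.median(x)), float(np.median(y))
    direction = (
        f"{groups[0]} > {groups[1]}" if med_x > med_y
        else f"{groups[0]} < {groups[1]}" if med_x < med_y
        else "no median shift"
    )
    return {
        "u": float(u),
        "p": float(p),
        "median": {groups[0]: med_x, groups[1]: med_y},
        "direction": direction,
        "n": {groups[0]: len(x), groups[1]: len(y)},
    }


def ora_test(
    query,
    sets: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list in each set.

    Sets are intersected with the universe first; sets disjoint from the
    universe are skipped with a warning.  p is the upper tail
    P(X >= k); ``p_adj`` is BH across the tested sets.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = [g for g in dict.fromkeys(query)]
    if not query:
        raise ValueError("query gene list is empty")
    missing = [g for g in query if g not in uni]
    if missing:
        raise ValueError(f"query gene(s) not in universe: {missing[:5]}")
    n_query = len(query)
    n_universe = len(universe)
    qset = set(query)
    rows = []
    for name in sets:
        members = [g for g in sets[name] if g in uni]
        if not members:
            warnings.warn(f"gene set {name!r} disjoint from universe; skipped")
            continue
        big_k = len(members)
        k = len(qset & set(members))
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append(
            {"set_name": name, "k": k, "K": big_k, "n": n_query,
             "N": n_universe, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.set_index("set_name")
    return out
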
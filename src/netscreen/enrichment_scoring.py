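"""Single-sample gene-set enrichment engines.

Three per-sample scoring statistics and one list-level statistic:

* :func:`gsva_scores` — the kernel-CDF random-walk statistic used for the
  NET score.  Each gene's expression is converted to a smoothed empirical
  CDF (Gaussian kernel, bandwidth s_i/4), genes are ranked per sample by
  that CDF, and a weighted Kolmogorov–Smirnov-like walk over the ranked
  list yields the signed max-deviation ("max-diff") enrichment score.
* :func:`ssgsea_scores` — the rank-weighted running-sum single-sample
  score (weight exponent alpha, optional range normalization).
* :func:`marker_mean_score` — marker-gene arithmetic-mean abundance
  estimates for immune/stromal cell populations.
* :func:`preranked_gsea` — classic pre-ranked GSEA enrichment score with
  a seeded gene-set permutation null giving NES and a permutation p.

All rankings break ties by input gene position (stable sort) so results
are deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core_io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "gsva_scores",
    "ssgsea_scores",
    "marker_mean_score",
    "preranked_gsea",
    "GseaResult",
    "RankedList",
]


@dataclass(frozen=True)
class RankedList:
    """Genes sorted by a ranking metric, descending (ties broken by input order)."""

    genes: list[str]
    metric: np.ndarray

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        order = np.argsort(-s.to_numpy(), kind="stable")
        return cls(list(s.index[order]), s.to_numpy()[order])

    def __post_init__(self):
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate genes")
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric length mismatch")
        if np.any(np.diff(np.asarray(self.metric, dtype=float)) > 0):
            raise ValueError("metric must be sorted descending")


@dataclass(frozen=True)
class GseaResult:
    """Pre-ranked GSEA outcome for one gene set."""

    set_name: str
    es: float
    nes: float
    p: float
    n_perm: int


def _matched_sets(
    sets: GeneSetCollection, genes: list[str], min_genes: int
) -> dict[str, np.ndarray]:
    """Index each set into the gene list, warning on sets that match too few genes."""
    pos = {g: i for i, g in enumerate(genes)}
    out: dict[str, np.ndarray] = {}
    for name in sets:
        idx = np.array([pos[g] for g in sets[name] if g in pos], dtype=int)
        if len(idx) < min_genes:
            warnings.warn(
                f"gene set {name!r} matches only {len(idx)} gene(s) in the matrix "
                f"(need >= {min_genes}); skipped"
            )
            continue
        out[name] = idx
    if not out:
        raise ValueError("no gene set matches enough genes in the matrix")
    return out


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True)
    def _kernel_cdf_jit(x, bandwidth):  # pragma: no cover - compiled
        g, n = x.shape
        out = np.empty((g, n))
        inv_sqrt2 = 1.0 / math.sqrt(2.0)
        for i in range(g):
            h = bandwidth[i]
            acc = np.zeros(n)
            for j in range(n):
                xj = x[i, j]
                for k in range(j):
                    v = 0.5 * (1.0 + math.erf((xj - x[i, k]) / h * inv_sqrt2))
                    acc[j] += v
                    acc[k] += 1.0 - v
                acc[j] += 0.5  # the j = k term: Phi(0)
            out[i] = acc / n
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _kernel_cdf(x: np.ndarray, bandwidth: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF estimate F_i(x_ij) = mean_k Phi((x_ij - x_ik) / h_i).

    ``x`` is genes x samples.  A jit-compiled kernel exploits the
    antisymmetry of the pairwise differences; the numpy fallback chunks
    genes to bound memory.  Both evaluate the same statistic (libm erf
    vs scipy ndtr agree to ~1e-15).
    """
    if _HAVE_NUMBA:
        return _kernel_cdf_jit(
            np.ascontiguousarray(x, dtype=np.float64),
            np.ascontiguousarray(bandwidth, dtype=np.float64),
        )
    n_genes, n_samples = x.shape
    out = np.empty_like(x)
    chunk = max(1, int(2e7 // (n_samples * n_samples)))
    for start in range(0, n_genes, chunk):
        stop = min(start + chunk, n_genes)
        block = x[start:stop]
        diff = (block[:, :, None] - block[:, None, :]) / bandwidth[
            start:stop, None, None
        ]
        out[start:stop] = ndtr(diff).mean(axis=2)
    return out


def gsva_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
) -> pd.DataFrame:
    """Kernel-CDF random-walk enrichment scores (set x sample).

    Per gene i the smoothed empirical CDF F_i(x_ij) is estimated with a
    Gaussian kernel of bandwidth h_i = s_i / 4 (s_i the gene's sample
    standard deviation).  Per sample the genes are ranked by F descending
    (rank r_ij in 1..p) and converted to the symmetric statistic
    z_ij = |p/2 - r_ij|.  The walk down the ranked list adds
    z^tau / sum_set(z^tau) at in-set genes and subtracts 1/(p - m)
    elsewhere; the score is the largest positive plus the largest
    negative deviation of the running sum (signed, in [-1, 1]).

    Constant genes (s_i = 0) are dropped with a warning before scoring.
    """
    if expr.shape[1] < 3:
        raise ValueError("gsva_scores needs at least 3 samples")
    x = expr.values
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes are constant; GSVA undefined")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant gene(s) before GSVA")
        x = x[keep]
        sd = sd[keep]
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    matched = _matched_sets(sets, genes, min_genes=2)

    cdf = _kernel_cdf(x, sd / 4.0)
    p, n = cdf.shape
    # per sample: descending CDF order, stable in input gene position
    order = np.argsort(-cdf, axis=0, kind="stable")  # positions -> gene index
    ranks = np.empty_like(order)
    cols = np.arange(n)[None, :]
    ranks[order, cols] = np.arange(1, p + 1)[:, None]
    z = np.abs(p / 2.0 - ranks) ** tau  # genes x samples

    scores = np.empty((len(matched), n))
    for si, (name, idx) in enumerate(matched.items()):
        m = len(idx)
        in_set = np.zeros(p, dtype=bool)
        in_set[idx] = True
        dec = 1.0 / (p - m)
        for j in range(n):
            walk_in = in_set[order[:, j]]
            zj = z[order[:, j], j]
            steps = np.where(walk_in, 0.0, -dec)
            wsum = zj[walk_in].sum()
            steps[walk_in] = zj[walk_in] / wsum
            running = np.cumsum(steps)
            scores[si, j] = max(running.max(), 0.0) + min(running.min(), 0.0)
    return pd.DataFrame(scores, index=list(matched), columns=expr.sample_ids)


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Rank-weighted running-sum single-sample enrichment scores.

    Per sample, genes are ranked by expression descending; walking the
    list, the score accumulates (weighted in-set cumulative fraction -
    out-of-set cumulative fraction) over all positions, with in-set
    weights rank_value**alpha (the top gene has rank value p).  With
    ``normalize`` the whole matrix is divided by its score range.
    """
    if expr.shape[1] < 3:
        raise ValueError("ssgsea_scores needs at least 3 samples")
    x = expr.values
    genes = expr.gene_ids
    matched = _matched_sets(sets, genes, min_genes=2)
    p, n = x.shape
    order = np.argsort(-x, axis=0, kind="stable")
    rank_value = np.arange(p, 0, -1, dtype=float)  # position 0 -> p, last -> 1
    w = rank_value**alpha

    scores = np.empty((len(matched), n))
    for si, (name, idx) in enumerate(matched.items()):
        m = len(idx)
        in_set = np.zeros(p, dtype=bool)
        in_set[idx] = True
        for j in range(n):
            walk_in = in_set[order[:, j]]
            win = np.where(walk_in, w, 0.0)
            p_in = np.cumsum(win) / win.sum()
            p_out = np.cumsum(~walk_in) / float(p - m)
            scores[si, j] = np.sum(p_in - p_out)
    out = pd.DataFrame(scores, index=list(matched), columns=expr.sample_ids)
    if normalize:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng > 0:
            out = out / rng
    return out


def marker_mean_score(
    expr: ExpressionMatrix, marker_sets: GeneSetCollection
) -> pd.DataFrame:
    """Marker-gene mean abundance per cell population (set x sample).

    score(cell, sample) = arithmetic mean of the population's marker-gene
    expression values in that sample.  Sets matching no gene are skipped
    with a warning.
    """
    matched = _matched_sets(marker_sets, expr.gene_ids, min_genes=1)
    x = expr.values
    rows = {name: x[idx].mean(axis=0) for name, idx in matched.items()}
    return pd.DataFrame(rows, index=expr.sample_ids).T


def _walk_es(in_set: np.ndarray, weight: np.ndarray) -> float:
    """Enrichment score of a weighted KS walk: value at the maximum deviation."""
    n = len(in_set)
    m = int(in_set.sum())
    steps = np.where(in_set, 0.0, -1.0 / (n - m))
    wsum = weight[in_set].sum()
    if wsum <= 0:
        steps[in_set] = 1.0 / m
    else:
        steps[in_set] = weight[in_set] / wsum
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranked: RankedList,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "set",
) -> GseaResult:
    """Pre-ranked GSEA with a seeded gene-set permutation null.

    The enrichment score is the running-sum value at its maximum absolute
    deviation, with in-set increments |metric| normalized to the in-set
    total and out-of-set decrements 1/(N - m).  The null is built from
    ``n_perm`` random same-size gene sets; NES divides ES by the mean
    |null ES| of matching sign and p is the one-sided permutation tail
    (add-one corrected) among same-sign nulls.
    """
    genes = ranked.genes
    metric = np.abs(np.asarray(ranked.metric, dtype=float))
    members = set(gene_set) & set(genes)
    n, m = len(genes), len(members)
    if m == 0 or m == n:
        raise ValueError("gene set must be a nonempty proper subset of the ranked genes")
    in_set = np.array([g in members for g in genes])
    es = _walk_es(in_set, metric)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        null[b] = _walk_es(mask, metric)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same) == 0:
        nes = float("nan")
        p = 1.0 / (1.0 + n_perm)
    else:
        nes = es / np.abs(same).mean()
        p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
    return GseaResult(set_name=set_name, es=es, nes=float(nes), p=float(p), n_perm=n_perm)
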
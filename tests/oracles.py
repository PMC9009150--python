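"""Independent brute-force reference implementations used only by tests.

These are deliberately written as literal, loop-based transcriptions of
the scoring definitions (pure Python, no vectorization) so they share no
code with the package under test.
"""

import math
import statistics


def oracle_kernel_cdf(matrix):
    """Gaussian-kernel CDF per cell: mean_k Phi((x_ij - x_ik) / (s_i / 4))."""
    out = []
    for row in matrix:
        s = statistics.stdev(row)
        h = s / 4.0
        n = len(row)
        out.append(
            [
                sum(
                    0.5 * (1.0 + math.erf((xj - xk) / h / math.sqrt(2.0)))
                    for xk in row
                )
                / n
                for xj in row
            ]
        )
    return out


def oracle_gsva(matrix, gene_set_idx, tau=1.0):
    """Literal walk enumeration of the kernel-CDF enrichment score.

    ``matrix``: list of per-gene rows (no constant rows); ``gene_set_idx``:
    indices of the in-set genes.  Returns one score per sample.
    """
    cdf = oracle_kernel_cdf(matrix)
    p = len(matrix)
    n = len(matrix[0])
    m = len(gene_set_idx)
    in_set = set(gene_set_idx)
    scores = []
    for j in range(n):
        # rank genes by CDF descending, ties by input position (stable)
        order = sorted(range(p), key=lambda i: (-cdf[i][j], i))
        rank = {g: pos + 1 for pos, g in enumerate(order)}
        z = {g: abs(p / 2.0 - rank[g]) ** tau for g in range(p)}
        wsum = sum(z[g] for g in in_set)
        running = 0.0
        peaks = []
        for g in order:
            if g in in_set:
                running += z[g] / wsum
            else:
                running -= 1.0 / (p - m)
            peaks.append(running)
        scores.append(max(max(peaks), 0.0) + min(min(peaks), 0.0))
    return scores


def oracle_ssgsea(matrix, gene_set_idx, alpha=0.25):
    """Literal rank-weighted running-sum score, one per sample."""
    p = len(matrix)
    n = len(matrix[0])
    m = len(gene_set_idx)
    in_set = set(gene_set_idx)
    scores = []
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-matrix[i][j], i))
        weights = [(p - pos) ** alpha for pos in range(p)]  # top gene -> p**alpha
        w_in_total = sum(w for pos, w in enumerate(weights) if order[pos] in in_set)
        cum_in = cum_out = 0.0
        total = 0.0
        for pos, g in enumerate(order):
            if g in in_set:
                cum_in += weights[pos] / w_in_total
            else:
                cum_out += 1.0 / (p - m)
            total += cum_in - cum_out
        scores.append(total)
    return scores


def oracle_walk_es(in_flags, weights):
    """Pre-ranked GSEA enrichment score: running-sum value at max |deviation|."""
    n = len(in_flags)
    m = sum(in_flags)
    wsum = sum(w for w, f in zip(weights, in_flags) if f)
    running = 0.0
    best = 0.0
    for f, w in zip(in_flags, weights):
        running += (w / wsum) if f else (-1.0 / (n - m))
        if abs(running) > abs(best):
            best = running
    return best


def oracle_km(times, events):
    """Product-limit estimator as (event_time, survival) pairs."""
    out = []
    surv = 1.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        surv *= 1.0 - d / at_risk
        out.append((t, surv))
    return out


def oracle_cox_score(beta, times, events, xs):
    """Efron partial-likelihood score U(beta) for a single covariate."""
    total = 0.0
    event_times = sorted({t for t, e in zip(times, events) if e == 1})
    for t in event_times:
        tied = [i for i in range(len(times)) if times[i] == t and events[i] == 1]
        risk = [i for i in range(len(times)) if times[i] >= t]
        d = len(tied)
        s0_risk = sum(math.exp(beta * xs[i]) for i in risk)
        s1_risk = sum(xs[i] * math.exp(beta * xs[i]) for i in risk)
        s0_tied = sum(math.exp(beta * xs[i]) for i in tied)
        s1_tied = sum(xs[i] * math.exp(beta * xs[i]) for i in tied)
        total += sum(xs[i] for i in tied)
        for l in range(d):
            total -= (s1_risk - (l / d) * s1_tied) / (s0_risk - (l / d) * s0_tied)
    return total


def oracle_logrank_permutation_p(times, events, group, n_stat_fn):
    """Exact permutation p for the log-rank statistic over all label
    assignments of the observed group sizes (small n only)."""
    from itertools import combinations

    n = len(times)
    k = sum(group)
    observed = n_stat_fn(group)
    count = total = 0
    for idx in combinations(range(n), k):
        g = [i in set(idx) for i in range(n)]
        total += 1
        if n_stat_fn(g) >= observed - 1e-12:
            count += 1
    return count / total
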
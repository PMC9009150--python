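"""Kaplan–Meier estimation, log-rank testing, univariate Cox fitting,
maximally selected cutpoints, and per-cancer survival-direction
classification.

The product-limit estimator and the two-group log-rank statistic are
implemented directly on numpy arrays (the cutpoint search evaluates the
log-rank statistic at every admissible threshold, so it needs a cheap
inner loop); Cox models are fit with lifelines (Newton–Raphson on the
Efron-corrected partial likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats

from .core_io import AnalysisConfig

__all__ = [
    "KMCurve",
    "CoxFit",
    "LogrankResult",
    "CutpointResult",
    "km_estimate",
    "km_median",
    "logrank_test",
    "cox_univariate",
    "optimal_cutpoint",
    "classify_net_survival",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t: float) -> float:
        """Ŝ(t): right-continuous step function, Ŝ(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox proportional-hazards fit (log hazard ratio beta)."""

    beta: float
    hr: float
    se: float
    z: float
    p: float
    converged: bool
    n: int
    n_events: int


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    o_minus_e: float  # observed-minus-expected events in group 1


@dataclass(frozen=True)
class CutpointResult:
    """Maximally selected log-rank cutpoint.

    ``p`` is the unadjusted log-rank p at the selected threshold; it is
    selection-biased (``selection_biased`` is always True) because the
    threshold maximizes the statistic.
    """

    threshold: float
    statistic: float  # standardized |z| = sqrt(chi2) at the threshold
    chi2: float
    p: float
    n_high: int
    n_low: int
    selection_biased: bool = True


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(time <= 0) or not np.isfinite(time).all():
        raise ValueError("survival times must be positive and finite")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return time, event.astype(int)


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censored subjects leave the risk set after their time; at tied
    times, events are handled before censorings (both count as at risk
    at that time).
    """
    time, event = _check_surv(time, event)
    if len(time) < 1:
        raise ValueError("empty survival data")
    event_times = np.unique(time[event == 1])
    order = np.sort(time)
    n = len(time)
    if len(event_times) == 0:
        return KMCurve(
            times=np.array([]), survival=np.array([]),
            at_risk=np.array([], dtype=int), events=np.array([], dtype=int),
        )
    at_risk = n - np.searchsorted(order, event_times, side="left")
    ev_sorted = np.sort(time[event == 1])
    d = (
        np.searchsorted(ev_sorted, event_times, side="right")
        - np.searchsorted(ev_sorted, event_times, side="left")
    )
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=event_times, survival=surv,
                   at_risk=at_risk.astype(int), events=d.astype(int))


def km_median(curve: KMCurve) -> float:
    """Median survival: first event time with Ŝ(t) <= 0.5 (inf if never reached)."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[below[0]]) if len(below) else float("inf")


def logrank_test(time, event, group1_mask) -> LogrankResult:
    """Two-group log-rank test (1 df chi-square).

    Sums observed-minus-expected events for group 1 over the distinct
    event times, with the usual hypergeometric variance.
    """
    time, event = _check_surv(time, event)
    g = np.asarray(group1_mask, dtype=bool)
    if g.all() or not g.any():
        raise ValueError("both groups must be non-empty")
    if event.sum() == 0:
        raise ValueError("need at least one event")
    chi2, p, ome, _ = _logrank_core(time, event, g)
    return LogrankResult(chi2=chi2, p=p, o_minus_e=ome)


def _logrank_core(time, event, g):
    """(chi2, p, O-E for group g, variance) over distinct event times."""
    event_times = np.unique(time[event == 1])
    order = np.sort(time)
    order1 = np.sort(time[g])
    ev_sorted = np.sort(time[event == 1])
    ev1_sorted = np.sort(time[g & (event == 1)])
    n = len(time)
    n1 = int(g.sum())
    nj = n - np.searchsorted(order, event_times, side="left")
    n1j = n1 - np.searchsorted(order1, event_times, side="left")
    dj = (
        np.searchsorted(ev_sorted, event_times, side="right")
        - np.searchsorted(ev_sorted, event_times, side="left")
    )
    d1j = (
        np.searchsorted(ev1_sorted, event_times, side="right")
        - np.searchsorted(ev1_sorted, event_times, side="left")
    )
    frac = n1j / nj
    ome = float(np.sum(d1j - dj * frac))
    ok = nj > 1
    var = float(
        np.sum(dj[ok] * frac[ok] * (1 - frac[ok]) * (nj[ok] - dj[ok]) / (nj[ok] - 1))
    )
    if var <= 0:
        return 0.0, 1.0, ome, 0.0
    chi2 = ome * ome / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1)), ome, var


def cox_univariate(time, event, covariate) -> CoxFit:
    """Univariate Cox proportional-hazards fit via the partial likelihood
    (Efron tie correction, Newton–Raphson).

    A monotone likelihood (perfect separation) yields ``converged=False``
    with NaN estimates; a constant covariate is an error.
    """
    time, event = _check_surv(time, event)
    x = np.asarray(covariate, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; Cox fit undefined")
    if event.sum() == 0:
        raise ValueError("need at least one event")
    df = pd.DataFrame({"T": time, "E": event, "x": x})
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            warnings.simplefilter("ignore", category=RuntimeWarning)
            cph.fit(df, duration_col="T", event_col="E")
    except (ConvergenceError, ConvergenceWarning):
        # retry tolerantly to distinguish hard failure from noisy warnings
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="T", event_col="E")
            converged = bool(np.isfinite(cph.params_["x"]) and
                             np.isfinite(cph.standard_errors_["x"]) and
                             abs(cph.params_["x"]) < 20)
        except ConvergenceError:
            return CoxFit(
                beta=float("nan"), hr=float("nan"), se=float("nan"),
                z=float("nan"), p=float("nan"), converged=False,
                n=len(time), n_events=int(event.sum()),
            )
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    # monotone-likelihood diagnostic, scale-free: a log hazard ratio (or
    # its standard error) above 10 per covariate SD means the estimate ran
    # toward infinity (perfect separation)
    sd_x = float(np.std(x, ddof=1))
    if abs(beta) * sd_x > 10 or se * sd_x > 10 or not np.isfinite(beta):
        converged = False
    z = beta / se if se > 0 else float("nan")
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return CoxFit(
        beta=beta, hr=float(np.exp(beta)), se=se, z=z, p=min(p, 1.0) if
        np.isfinite(p) else p, converged=converged,
        n=len(time), n_events=int(event.sum()),
    )


def optimal_cutpoint(
    scores, time, event, quantile_range: tuple[float, float] = (0.10, 0.90)
) -> CutpointResult:
    """Maximally selected log-rank cutpoint on a continuous score.

    Evaluates the log-rank statistic at every distinct score value inside
    the admissible quantile window (default 10%–90%) and returns the
    maximizing threshold (high group = score > threshold).  The reported
    p is the unadjusted chi-square tail and is selection-biased.
    """
    s = np.asarray(scores, dtype=float)
    time, event = _check_surv(time, event)
    if len(s) != len(time):
        raise ValueError("scores and survival data must have equal length")
    if len(s) < 20:
        raise ValueError("need at least 20 subjects for cutpoint selection")
    if np.ptp(s) == 0:
        raise ValueError("scores are constant; no admissible split")
    if event.sum() == 0:
        raise ValueError("need at least one event")
    lo, hi = np.quantile(s, quantile_range)
    candidates = np.unique(s)
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    candidates = candidates[candidates < s.max()]  # high group must be non-empty
    if len(candidates) == 0:
        raise ValueError("no admissible split inside the quantile window")
    best = None
    for v in candidates:
        g = s > v
        chi2, p, ome, var = _logrank_core(time, event, g)
        if best is None or chi2 > best[0]:
            best = (chi2, p, v, int(g.sum()))
    chi2, p, threshold, n_high = best
    return CutpointResult(
        threshold=float(threshold), statistic=float(np.sqrt(chi2)), chi2=chi2,
        p=p, n_high=n_high, n_low=len(s) - n_high,
    )


def classify_net_survival(
    scores: pd.Series,
    clinical: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Classify each cancer type as favorable / poor / neutral NET-related
    survival.

    Per cancer type, samples are dichotomized at the maximally selected
    cutpoint of the NET score; the class is ``favorable`` when the
    log-rank p < p_sig and the high-score group has the larger KM median
    survival, ``poor`` when it has the smaller, else ``neutral``.  The
    reported HR is high-vs-low from a univariate Cox fit on the group
    indicator.  Types with too few subjects (or no admissible cutpoint)
    are classified neutral with a warning.
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    clin = clinical.dropna(subset=["time", "event"])
    for ctype, sub in clin.groupby("cancer_type", sort=True):
        samples = [s for s in sub["sample"] if s in scores.index]
        sub = sub.set_index("sample").loc[samples]
        record = {
            "cancer_type": ctype, "n": len(samples), "class": "neutral",
            "cutoff": np.nan, "logrank_p": np.nan, "hr": np.nan,
            "n_high": 0, "n_low": 0,
        }
        try:
            time = sub["time"].to_numpy(dtype=float)
            event = sub["event"].to_numpy(dtype=float)
            sc = scores.loc[samples].to_numpy(dtype=float)
            cut = optimal_cutpoint(sc, time, event, cfg.cutpoint_quantile_range)
            high = sc > cut.threshold
            record.update(cutoff=cut.threshold, logrank_p=cut.p,
                          n_high=int(high.sum()), n_low=int((~high).sum()))
            fit = cox_univariate(time, event, high.astype(float))
            if fit.converged:
                record["hr"] = fit.hr
            if cut.p < cfg.p_sig:
                med_hi = km_median(km_estimate(time[high], event[high]))
                med_lo = km_median(km_estimate(time[~high], event[~high]))
                if med_hi > med_lo:
                    record["class"] = "favorable"
                elif med_hi < med_lo:
                    record["class"] = "poor"
                else:
                    # medians tied or both unreached: direction from the
                    # high group's observed-minus-expected event count
                    lr = logrank_test(time, event, high)
                    record["class"] = "poor" if lr.o_minus_e > 0 else "favorable"
        except ValueError as exc:
            warnings.warn(f"cancer type {ctype}: {exc}; classified neutral")
        rows.append(record)
    out = pd.DataFrame(rows).set_index("cancer_type")
    if (out["class"] == "neutral").all():
        warnings.warn("all cancer types classified neutral; downstream "
                      "screen needs both survival classes")
    return out
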
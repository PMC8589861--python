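"""Kaplan-Meier estimation, log-rank testing and univariate Cox regression.

The stratified analyses pair a grouping from :mod:`scnadriver.landscape`
(quartile or median split on one gene) with overall-survival curves and a
Cox-Mantel log-rank test; per-gene hazard tables fit a univariate Cox model
on standardized expression, so hazard ratios are per standard deviation.

KM curves and the log-rank statistic are delegated to lifelines. The Cox
model is fit here directly: Breslow tie handling, damped Newton iteration on
the partial likelihood, Wald confidence intervals from the observed
information. Breslow ties are adequate for the continuous times the
simulator produces; on heavily tied data hazard ratios are attenuated
relative to exact methods. Monotone likelihoods (perfect separation) are
detected by coefficient divergence and flagged with an unbounded CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .landscape import StratificationResult

MAX_ABS_COEF = 15.0  # |log HR| beyond this is treated as separation


@dataclass
class KMCurve:
    """Product-limit estimate: step function S(t) on the event-time grid."""
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below.argmax()]) if below.any() else np.inf


@dataclass
class LogRankResult:
    statistic: float
    p: float


@dataclass
class CoxResult:
    name: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    se: float
    p: float
    n: int
    n_events: int
    separation: bool = False


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times events precede censorings (the standard convention), so a
    subject censored at an event time is still in the risk set for that
    event.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or None)
    tab = kmf.event_table
    grid = tab.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    at_risk = tab["at_risk"].to_numpy(float)
    return KMCurve(grid, surv, at_risk, np.sort(times[events == 0]), label)


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group Cox-Mantel log-rank test (chi-square, 1 df)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("log-rank test needs subjects in both groups")
    res = _ll_logrank(ta, tb, event_observed_A=np.asarray(events_a, int),
                      event_observed_B=np.asarray(events_b, int))
    return LogRankResult(float(res.test_statistic), float(res.p_value))


def _breslow_loglik_score_info(beta: float, t_ord: np.ndarray, e_ord: np.ndarray,
                               x_ord: np.ndarray) -> tuple[float, float, float]:
    """Log partial likelihood, score and information at ``beta``.

    Input arrays must be sorted by descending time so that reverse risk-set
    sums become cumulative sums; tied event times share one risk set
    (Breslow).
    """
    eta = beta * x_ord
    w = np.exp(eta - eta.max())  # rescale for overflow safety
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x_ord)
    s2 = np.cumsum(w * x_ord ** 2)
    # risk set of time t = all subjects with time >= t: with descending sort,
    # the cumsum through the LAST index sharing that time
    n = len(t_ord)
    last_of_tie = np.r_[t_ord[1:] != t_ord[:-1], True]
    # for each i, the last index of its tie run = nearest last-of-tie index >= i
    idx = np.minimum.accumulate(np.where(last_of_tie, np.arange(n), n)[::-1])[::-1]
    ev = e_ord == 1
    r0, r1, r2 = s0[idx][ev], s1[idx][ev], s2[idx][ev]
    loglik = float(np.sum(eta[ev] - np.log(r0)) )
    score = float(np.sum(x_ord[ev] - r1 / r0))
    info = float(np.sum(r2 / r0 - (r1 / r0) ** 2))
    return loglik, score, info


def cox_univariate(times, events, covariate, name: str = "x",
                   tol: float = 1e-8, max_iter: int = 50) -> CoxResult:
    """Univariate Cox proportional-hazards fit.

    Maximizes the Breslow partial likelihood by damped Newton iteration
    (step halving when the likelihood does not improve); converged when the
    absolute score drops below ``tol``. Returns the hazard ratio with a 95%
    Wald interval. A constant covariate or a dataset with no events is an
    error; a monotone likelihood is flagged and the CI reported unbounded.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    x = np.asarray(covariate, float)
    if e.sum() < 1:
        raise ValueError("no events: Cox model is not identified")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")

    order = np.argsort(-t, kind="stable")
    t_ord, e_ord, x_ord = t[order], e[order], x[order]

    beta = 0.0
    loglik, score, info = _breslow_loglik_score_info(beta, t_ord, e_ord, x_ord)
    separation = False
    for _ in range(max_iter):
        if abs(score) < tol:
            break
        step = score / info if info > 0 else np.sign(score)
        new_beta = beta + step
        new_ll, new_sc, new_info = _breslow_loglik_score_info(new_beta, t_ord, e_ord, x_ord)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_sc, new_info = _breslow_loglik_score_info(new_beta, t_ord, e_ord, x_ord)
            halvings += 1
        beta, loglik, score, info = new_beta, new_ll, new_sc, new_info
        if abs(beta) > MAX_ABS_COEF:
            separation = True
            break

    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    z = 1.959963984540054
    if separation:
        ci_low, ci_high = (0.0, np.inf)
        p = np.nan
    else:
        ci_low = float(np.exp(beta - z * se))
        ci_high = float(np.exp(beta + z * se))
        p = float(2 * stats.norm.sf(abs(beta) / se)) if np.isfinite(se) else np.nan
    return CoxResult(name, float(beta), float(np.exp(beta)), ci_low, ci_high,
                     float(se), p, len(t), int(e.sum()), separation)


def filter_by_dcn_status(values: pd.Series, threshold: float = -0.2,
                         keep: str = "wild_type") -> list[str]:
    """Split samples on a gene's log2 copy ratio at ``threshold``.

    ``keep="wild_type"`` retains samples at or above the threshold (no loss);
    ``keep="deleted"`` retains samples strictly below it.
    """
    values = values.dropna()
    if keep == "wild_type":
        return sorted(values.index[values >= threshold])
    if keep == "deleted":
        return sorted(values.index[values < threshold])
    raise ValueError("keep must be 'wild_type' or 'deleted'")


def stratified_survival(
    clinical: pd.DataFrame, stratification: StratificationResult
) -> tuple[KMCurve, KMCurve, LogRankResult]:
    """KM curves and log-rank test for a high/low stratification.

    Samples without clinical records are dropped (count logged via the
    returned curve sizes). Returns (low curve, high curve, log-rank result).
    """
    hi = [s for s in stratification.group_high if s in clinical.index]
    lo = [s for s in stratification.group_low if s in clinical.index]
    if not hi or not lo:
        raise ValueError("a stratification group has no clinical records")
    c_hi = clinical.loc[hi]
    c_lo = clinical.loc[lo]
    km_lo = km_estimate(c_lo["os_time"], c_lo["os_event"], label=f"{stratification.gene_id}_low")
    km_hi = km_estimate(c_hi["os_time"], c_hi["os_event"], label=f"{stratification.gene_id}_high")
    lr = logrank_test(c_lo["os_time"], c_lo["os_event"], c_hi["os_time"], c_hi["os_event"])
    return km_lo, km_hi, lr


def hazard_table(clinical: pd.DataFrame, de: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Univariate Cox fit per gene on standardized expression, sorted by HR.

    Duplicated genes in the request collapse to a single row; a gene absent
    from the matrix raises ``KeyError`` naming it.
    """
    samples = [s for s in clinical.index if s in de.columns]
    rows = []
    for gene in dict.fromkeys(genes):
        if gene not in de.index:
            raise KeyError(f"gene {gene!r} absent from the DE matrix")
        x = de.loc[gene, samples].to_numpy(float)
        z = (x - x.mean()) / x.std(ddof=1)
        res = cox_univariate(clinical.loc[samples, "os_time"],
                             clinical.loc[samples, "os_event"], z, name=gene)
        rows.append((gene, res.hr, res.ci_low, res.ci_high, res.coef, res.se,
                     res.p, res.n_events, res.separation))
    out = pd.DataFrame(rows, columns=["gene_id", "hr", "ci_low", "ci_high", "coef",
                                      "se", "p", "n_events", "separation"])
    return out.set_index("gene_id").sort_values("hr")
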
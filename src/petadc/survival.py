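"""Exploratory survival analysis: median dichotomization, Kaplan-Meier,
log-rank, and univariate Cox proportional hazards.

Imaging metrics are treated as categorical, split at the cohort median
(values <= median -> "low", otherwise "high"; the midpoint of the two
central order statistics defines the median for even n, and ties straddling
it all land in "low").  Kaplan-Meier curves and the two-group log-rank test
come from lifelines.  The univariate Cox model is fitted here directly by
Newton iteration on the partial likelihood — the single-covariate case is
tiny, tie handling is Breslow by default (Efron optionally), and divergence
toward a monotone likelihood (all events in one group) is detected during
iteration (|beta| > 10) and reported as a diagnostic instead of a spurious
finite hazard ratio.

Conventions: times in months, >= 0; event flag True means the event was
observed, False means censored at that time; censored-at-t subjects remain
at risk for events at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "KaplanMeierCurve",
    "LogrankResult",
    "CoxResult",
    "dichotomize_by_median",
    "kaplan_meier",
    "logrank_test",
    "cox_univariate",
    "cox_score_test",
    "survival_table",
]


def _clean(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1D and of equal length")
    if t.size == 0:
        raise ValueError("need at least one subject")
    if not np.isfinite(t).all() or (t < 0).any():
        raise ValueError("times must be finite and >= 0")
    return t, e


def dichotomize_by_median(cohort, metric: str | None = None) -> np.ndarray:
    """Split patients at the median of a metric: <= median -> "low", else "high".

    Accepts a cohort DataFrame plus a column name, or a bare vector.  The
    median is the midpoint of the two central order statistics for even n.
    A metric with all values identical cannot be split and raises.
    """
    if isinstance(cohort, pd.DataFrame):
        if metric is None:
            raise TypeError("metric column name required with a DataFrame")
        values = pd.to_numeric(cohort[metric], errors="raise").to_numpy(dtype=np.float64)
    else:
        values = np.asarray(cohort, dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("metric has missing/non-finite values")
    if float(np.ptp(values)) == 0.0:
        raise ValueError("all metric values identical; median split is degenerate")
    med = float(np.median(values))
    return np.where(values <= med, "low", "high")


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray  # includes t = 0
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): the step value at the largest grid time <= t."""
        if t < 0:
            raise ValueError("t must be >= 0")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.survival[max(idx, 0)])


def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator for one group."""
    t, e = _clean(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return KaplanMeierCurve(
        times=sf.index.to_numpy(dtype=np.float64),
        survival=sf.iloc[:, 0].to_numpy(dtype=np.float64),
    )


@dataclass
class LogrankResult:
    chi2: float
    p: float


def logrank_test(times, events, groups) -> LogrankResult:
    """Standard two-group log-rank test (chi-square with 1 df).

    ``groups`` holds exactly two distinct labels; the statistic is invariant
    to which label is which.
    """
    t, e = _clean(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must match times in length")
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(labels)}")
    in_a = g == labels[0]
    if not in_a.any() or in_a.all():
        raise ValueError("each group needs at least one subject")
    res = _ll_logrank(t[in_a], t[~in_a], event_observed_A=e[in_a], event_observed_B=e[~in_a])
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value))


@dataclass
class CoxResult:
    """Univariate Cox fit. ``diverged`` flags a monotone partial likelihood
    (e.g. all events in one group); hr/ci/p are None in that case."""

    beta: float | None
    se: float | None
    hr: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    n_events: int
    diverged: bool = False


def _cox_derivatives(t, e, x, beta: float, ties: str):
    """Log partial likelihood, score and information for one covariate.

    Subjects are at risk at every event time <= their own time (censored
    subjects included at their censoring time).  Breslow treats the d tied
    events at a time as sharing one risk set; Efron downweights the event
    group progressively.
    """
    order = np.argsort(-t, kind="stable")  # descending time
    ts, es, xs = t[order], e[order], x[order]
    w = np.exp(beta * xs)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xs)
    s2 = np.cumsum(w * xs * xs)

    loglik = 0.0
    score = 0.0
    info = 0.0
    i = 0
    n = ts.size
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # block [i, j) shares time ts[i]; risk set = indices [0, j)
        ev = es[i:j]
        if ev.any():
            d = int(ev.sum())
            xe = xs[i:j][ev]
            we = w[i:j][ev]
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            loglik += beta * xe.sum()
            if ties == "breslow" or d == 1:
                loglik -= d * np.log(S0)
                score += xe.sum() - d * S1 / S0
                info += d * (S2 / S0 - (S1 / S0) ** 2)
            else:  # efron
                e0, e1, e2 = we.sum(), (we * xe).sum(), (we * xe * xe).sum()
                for k in range(d):
                    f = k / d
                    D0 = S0 - f * e0
                    D1 = S1 - f * e1
                    D2 = S2 - f * e2
                    loglik -= np.log(D0)
                    score += xe.sum() / d - D1 / D0
                    info += D2 / D0 - (D1 / D0) ** 2
        i = j
    return loglik, score, info


def cox_univariate(
    times, events, covariate, *, ties: str = "breslow", max_iter: int = 50, tol: float = 1e-12
) -> CoxResult:
    """Cox proportional hazards with a single (typically binary) covariate.

    HR = exp(beta) with a 95% Wald interval exp(beta ± z_{0.975} * se) and a
    two-sided Wald p-value.  If Newton iteration escapes |beta| > 10 the
    likelihood is effectively monotone and a divergence diagnostic is
    returned instead of a finite HR.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    t, e = _clean(times, events)
    if isinstance(covariate, (pd.Series, pd.Categorical)):
        covariate = np.asarray(covariate)
    x = np.asarray(covariate)
    if x.dtype.kind in "OUSb":  # labels -> 0/1 indicator for the second level
        levels = pd.unique(x)
        if len(levels) != 2:
            raise ValueError(f"categorical covariate must have 2 levels, got {len(levels)}")
        x = (x == levels[1]).astype(np.float64)
    x = np.asarray(x, dtype=np.float64)
    if x.shape != t.shape:
        raise ValueError("covariate must match times in length")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events observed; Cox model is undefined")
    if float(np.ptp(x)) == 0.0:
        raise ValueError("covariate is constant; hazard ratio is undefined")

    beta = 0.0
    for _ in range(max_iter):
        _, score, info = _cox_derivatives(t, e, x, beta, ties)
        if info <= 0:
            return CoxResult(None, None, None, None, None, None, n_events, diverged=True)
        step = score / info
        beta += step
        if abs(beta) > 10.0:
            return CoxResult(None, None, None, None, None, None, n_events, diverged=True)
        if abs(step) < tol:
            break
    _, _, info = _cox_derivatives(t, e, x, beta, ties)
    se = float(1.0 / np.sqrt(info))
    z = float(stats.norm.ppf(0.975))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p=p,
        n_events=n_events,
    )


def cox_score_test(times, events, covariate) -> LogrankResult:
    """Cox score test at beta = 0 (chi-square, 1 df).

    On tie-free two-group data this equals the log-rank statistic — the
    classical equivalence, used as an internal consistency check.
    """
    t, e = _clean(times, events)
    x = np.asarray(covariate)
    if x.dtype.kind in "OUSb":
        levels = pd.unique(x)
        if len(levels) != 2:
            raise ValueError("categorical covariate must have 2 levels")
        x = (x == levels[1]).astype(np.float64)
    x = np.asarray(x, dtype=np.float64)
    _, score, info = _cox_derivatives(t, e, x, 0.0, "breslow")
    if info <= 0:
        raise ValueError("score test undefined: zero information at beta = 0")
    chi2 = float(score * score / info)
    return LogrankResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)))


def survival_table(
    cohort: pd.DataFrame,
    metrics: list[str],
    time_col: str = "dfs_time",
    event_col: str = "dfs_event",
    *,
    ties: str = "breslow",
) -> pd.DataFrame:
    """Per-metric median-dichotomized analysis for one endpoint.

    For each metric: split at the median, fit the univariate Cox model for
    high vs low (low is the reference), and run the log-rank test.  Returns
    one row per metric with HR, 95% CI, Wald p, log-rank chi2/p, and a
    divergence flag.  No multiple-testing correction is applied.
    """
    t = pd.to_numeric(cohort[time_col]).to_numpy(dtype=np.float64)
    e = cohort[event_col].astype(bool).to_numpy()
    rows = []
    for metric in metrics:
        groups = dichotomize_by_median(cohort, metric)
        ind = (groups == "high").astype(np.float64)
        cox = cox_univariate(t, e, ind, ties=ties)
        lr = logrank_test(t, e, groups)
        rows.append(
            {
                "metric": metric,
                "hr": cox.hr,
                "ci_low": cox.ci_low,
                "ci_high": cox.ci_high,
                "cox_p": cox.p,
                "cox_diverged": cox.diverged,
                "logrank_chi2": lr.chi2,
                "logrank_p": lr.p,
                "n_low": int((groups == "low").sum()),
                "n_high": int((groups == "high").sum()),
                "n_events": cox.n_events,
            }
        )
    return pd.DataFrame(rows)
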
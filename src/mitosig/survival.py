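"""Survival analysis: Kaplan-Meier, log-rank, cutpoints, univariable Cox.

Overall survival is time in months from sample collection to death
(event = 1) or loss of follow-up (event = 0).  Multi-protein signature
scores are dichotomized at the cutpoint maximizing the log-rank statistic
over all candidate thresholds within a quantile window (maximally selected
rank statistic); single-protein measurements use a median split.  Because
maximizing over cutpoints inflates the type I error, :func:`maxstat_cutpoint`
reports the naive log-rank p at the selected cutpoint and, optionally, a
permutation-adjusted p.

The log-rank statistic is the standard observed-minus-expected chi-square
with hypergeometric variance at each distinct event time; the univariable
Cox model is a Newton-Raphson fit of the partial likelihood with Breslow
tie handling (Efron available through lifelines).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DAYS_PER_MONTH",
    "days_to_months",
    "KMCurve",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "median_split",
    "MaxstatResult",
    "maxstat_cutpoint",
    "CoxResult",
    "cox_univariable",
    "drop_missing_survival",
]

DAYS_PER_MONTH = 30.4375  # Julian-year convention


def days_to_months(days):
    return np.asarray(days, dtype=float) / DAYS_PER_MONTH


def _clean(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float).astype(bool)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if len(time) == 0:
        raise ValueError("need at least one sample")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be positive and finite")
    return time, event


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclasses.dataclass
class KMCurve:
    """Product-limit estimate: S(t) at each distinct event time."""

    event_times: np.ndarray    # ascending distinct times with >= 1 death
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk just before each event time
    n_events: np.ndarray       # deaths at each event time
    n: int

    def survival_at(self, t):
        """S(t) via right-continuous step interpolation (S(0) = 1)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float),
                              side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def to_frame(self):
        return pd.DataFrame({
            "time": self.event_times, "survival": self.survival,
            "at_risk": self.at_risk, "n_events": self.n_events,
        })

    def plot(self, ax=None, label=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.event_times])
        s = np.concatenate([[1.0], self.survival])
        ax.step(t, s, where="post", label=label)
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("months")
        ax.set_ylabel("overall survival")
        if label:
            ax.legend()
        return ax


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator (ties decrement simultaneously)."""
    from lifelines import KaplanMeierFitter

    time, event = _clean(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    death_rows = table[table["observed"] > 0]
    times = death_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy()
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=death_rows["at_risk"].to_numpy(dtype=int),
        n_events=death_rows["observed"].to_numpy(dtype=int),
        n=len(time),
    )


# ---------------------------------------------------------------------------
# log-rank


@dataclasses.dataclass
class LogrankResult:
    chi_sq: float
    p: float
    observed: np.ndarray   # deaths per group
    expected: np.ndarray


def logrank_test(time, event, group) -> LogrankResult:
    """Two-group log-rank test (1 df).

    ``group`` is boolean or two-level; at each distinct event time the
    group-1 death count is compared with its hypergeometric expectation and
    variance given the margins.
    """
    time, event = _clean(time, event)
    g = np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, found {len(levels)}")
    g1 = g == levels[1]
    if event.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    chi, o1, e1 = _logrank_chi(time, event, g1)
    d = float(event.sum())
    return LogrankResult(
        chi_sq=chi, p=float(stats.chi2.sf(chi, 1)),
        observed=np.array([d - o1, o1]), expected=np.array([d - e1, e1]),
    )


def _logrank_chi(time, event, g1):
    """(chi_sq, observed group-1 deaths, expected group-1 deaths)."""
    order = np.argsort(time, kind="stable")
    t, e, m = time[order], event[order], g1[order]
    ut, start = np.unique(t, return_index=True)
    n_total = len(t)
    # at-risk counts just before each distinct time
    n_at = n_total - start
    cum_m = np.concatenate([[0], np.cumsum(m)])
    n1_at = cum_m[-1] - cum_m[start]
    # deaths at each distinct time
    d_tot = np.add.reduceat(e.astype(float), start)
    d1 = np.add.reduceat((e & m).astype(float), start)
    keep = d_tot > 0
    n_at, n1_at, d_tot, d1 = n_at[keep], n1_at[keep], d_tot[keep], d1[keep]
    frac = n1_at / n_at
    expected = d_tot * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d_tot * frac * (1 - frac) * (n_at - d_tot) / (n_at - 1)
    var = np.where(n_at > 1, var, 0.0)
    o_minus_e = float((d1 - expected).sum())
    v = float(var.sum())
    chi = (o_minus_e ** 2) / v if v > 0 else 0.0
    return chi, float(d1.sum()), float(expected.sum())


# ---------------------------------------------------------------------------
# splits


def median_split(values) -> np.ndarray:
    """Dichotomize at the median: value <= median -> "low", else "high"."""
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 2:
        raise ValueError("median split needs >= 2 distinct values")
    med = float(np.median(v))
    return np.where(v <= med, "low", "high")


@dataclasses.dataclass
class MaxstatResult:
    cutpoint: float
    max_chi_sq: float
    p_naive: float               # log-rank p at the selected cutpoint
    p_permutation: float | None  # selection-adjusted p (if permutations run)
    n_candidates: int
    candidates: pd.DataFrame     # cutpoint, chi_sq

    def groups(self, scores):
        """Label each sample "low" (score <= cutpoint) or "high"."""
        return np.where(np.asarray(scores, float) <= self.cutpoint, "low", "high")


def maxstat_cutpoint(scores, time, event, quantile_window=(0.1, 0.9),
                     n_permutations=0, seed=0) -> MaxstatResult:
    """Maximally selected log-rank cutpoint within a quantile window.

    Every distinct score inside the window is evaluated as a dichotomizing
    threshold (low: score <= cut); the maximizing cutpoint is returned, ties
    broken toward the lower cutpoint.  With ``n_permutations`` > 0 a
    permutation-adjusted p (scores permuted against the survival data, the
    whole maximization repeated) is reported alongside the naive p.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = _clean(time, event)
    if len(scores) != len(time):
        raise ValueError("scores and survival data must have equal length")
    if len(scores) < 10:
        raise ValueError("maxstat needs >= 10 samples")
    lo, hi = np.quantile(scores, quantile_window)
    in_window = np.unique(scores[(scores >= lo) & (scores <= hi)])
    if len(in_window) < 2:
        raise ValueError("need >= 2 distinct scores inside the quantile window")
    cand = np.unique(scores)
    cand = cand[(cand >= lo) & (cand <= hi) & (cand < scores.max())]
    if len(cand) == 0:
        raise ValueError("no valid cutpoint: every candidate leaves a side empty")

    def scan(sc):
        chis = np.empty(len(cand))
        for i, c in enumerate(cand):
            chis[i], _, _ = _logrank_chi(time, event, sc > c)
        return chis

    chis = scan(scores)
    best = int(np.argmax(chis))  # first occurrence = lower cutpoint on ties
    cut = float(cand[best])
    max_chi = float(chis[best])
    p_naive = float(stats.chi2.sf(max_chi, 1))

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(scores)
            if scan(perm).max() >= max_chi:
                exceed += 1
        p_perm = (1 + exceed) / (1 + n_permutations)

    return MaxstatResult(
        cutpoint=cut, max_chi_sq=max_chi, p_naive=p_naive, p_permutation=p_perm,
        n_candidates=len(cand),
        candidates=pd.DataFrame({"cutpoint": cand, "chi_sq": chis}),
    )


# ---------------------------------------------------------------------------
# Cox


@dataclasses.dataclass
class CoxResult:
    hr: float
    ci95: tuple
    p: float
    n: int
    n_events: int
    log_hr: float
    se: float
    converged: bool


def cox_univariable(time, event, covariate, ties="breslow") -> CoxResult:
    """Univariable Cox proportional-hazards model.

    Newton-Raphson on the Breslow partial likelihood (default); ``ties=
    "efron"`` delegates to lifelines.  Monotone likelihood (perfect risk
    separation) is flagged as non-convergence rather than raised.
    """
    time, event = _clean(time, event)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(time):
        raise ValueError("covariate and survival data must have equal length")
    if event.sum() < 2:
        raise ValueError("Cox fit needs >= 2 events")
    if np.ptp(x) == 0:
        raise ValueError("covariate does not vary")
    if ties == "efron":
        return _cox_efron_lifelines(time, event, x)
    if ties != "breslow":
        raise ValueError(f"unknown tie handling {ties!r}")

    order = np.argsort(time, kind="stable")
    t, e, xv = time[order], event[order], x[order]
    ut, start = np.unique(t, return_index=True)
    d_tot = np.add.reduceat(e.astype(float), start)
    sx = np.add.reduceat(np.where(e, xv, 0.0), start)
    keep = d_tot > 0
    xsd = float(np.std(xv))

    def derivs(beta):
        w = np.exp(beta * xv)
        # risk set at distinct time k = samples with index >= start[k]
        ca = np.cumsum(w[::-1])[::-1]
        cb = np.cumsum((w * xv)[::-1])[::-1]
        cc = np.cumsum((w * xv * xv)[::-1])[::-1]
        A, B, C = ca[start][keep], cb[start][keep], cc[start][keep]
        d, s = d_tot[keep], sx[keep]
        ll = float((s * beta - d * np.log(A)).sum())
        grad = float((s - d * B / A).sum())
        hess = float((-d * (C / A - (B / A) ** 2)).sum())
        return ll, grad, hess

    beta = 0.0
    converged = False
    ll, grad, hess = derivs(beta)
    for _ in range(60):
        if hess >= 0:
            break
        step = -grad / hess
        # step halving to keep the likelihood non-decreasing
        for _ in range(30):
            new_ll, new_grad, new_hess = derivs(beta + step)
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
        beta += step
        ll, grad, hess = new_ll, new_grad, new_hess
        if abs(step) < 1e-10 or abs(grad) < 1e-10:
            converged = True
            break
    if abs(beta) * max(xsd, 1e-12) > 10:
        converged = False  # monotone likelihood: estimate diverging
    se = float(1.0 / np.sqrt(-hess)) if hess < 0 else np.inf
    zq = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        ci = (float(np.exp(beta - zq * se)), float(np.exp(beta + zq * se)))
    return CoxResult(
        hr=float(np.exp(beta)),
        ci95=ci,
        p=float(2 * stats.norm.sf(abs(beta) / se)) if np.isfinite(se) else 1.0,
        n=len(time), n_events=int(event.sum()),
        log_hr=float(beta), se=se, converged=converged,
    )


def _cox_efron_lifelines(time, event, x) -> CoxResult:
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"time": time, "event": event.astype(int), "x": x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    zq = stats.norm.ppf(0.975)
    return CoxResult(
        hr=float(np.exp(beta)),
        ci95=(float(np.exp(beta - zq * se)), float(np.exp(beta + zq * se))),
        p=float(cph.summary.loc["x", "p"]),
        n=len(time), n_events=int(event.sum()),
        log_hr=beta, se=se, converged=True,
    )


def drop_missing_survival(samples: pd.DataFrame):
    """Drop samples lacking survival information; return (subset, n_dropped)."""
    ok = samples["os_time"].notna() & samples["os_event"].notna()
    return samples[ok], int((~ok).sum())
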
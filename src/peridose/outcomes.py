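"""Dose-correlation and survival statistics.

Correlations between biomarkers and dose use Spearman rank correlation
(exact permutation p-value for tiny n, t-approximation otherwise) or
Pearson product-moment correlation. Survival endpoints — overall survival
and time to first post-RT cardiovascular diagnosis — are analyzed with
the Kaplan-Meier product-limit estimator, the two-sample log-rank test,
and a univariable proportional-hazards (Cox) fit on a binary group
indicator with Breslow tie handling and a Wald 95% CI on the log scale.
Cohorts are split into groups at the cohort mean of a covariate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from peridose.cohort import ValidationError


@dataclass
class SurvivalSample:
    """Per-patient time-to-event datum: time (days), event flag, binary group."""

    time: float
    event: bool
    group: int = 0

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValidationError(f"survival time must be > 0, got {self.time}")
        if self.group not in (0, 1):
            raise ValidationError("group must be 0 or 1")


@dataclass
class TestResult:
    """Statistic, p-value and effect size with its 95% CI."""

    statistic: float
    p_value: float
    effect: float
    effect_name: str = ""
    ci_low: float = math.nan
    ci_high: float = math.nan
    n: int = 0
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _check_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant variable")
    return x, y


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks on ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y, exact_below: int = 10) -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks. For n below ``exact_below`` the p-value is an
    exact two-sided permutation test (all n! orderings of y); otherwise
    the usual t-approximation with n - 2 degrees of freedom.
    """
    x, y = _check_xy(x, y, 3)
    n = x.size
    rho = _rank_corr(x, y)
    if n < exact_below:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_corr(x, y[list(perm)])
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    else:
        res = stats.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
    return TestResult(statistic=rho, p_value=min(p, 1.0), effect=rho,
                      effect_name="rho", n=n)


def pearson(x, y) -> TestResult:
    """Pearson product-moment correlation, two-sided t-test p (n-2 df)."""
    x, y = _check_xy(x, y, 3)
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95) if x.size > 3 else (math.nan, math.nan)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      effect=float(res.statistic), effect_name="r",
                      ci_low=float(ci[0]), ci_high=float(ci[1]), n=x.size)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _to_arrays(samples: Sequence[SurvivalSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(samples) == 0:
        raise ValidationError("empty survival sample")
    t = np.array([s.time for s in samples], dtype=float)
    e = np.array([s.event for s in samples], dtype=bool)
    g = np.array([s.group for s in samples], dtype=int)
    return t, e, g


def km_estimate(samples: Sequence[SurvivalSample]) -> Callable[[float], float]:
    """Kaplan-Meier product-limit survival function.

    Returns a right-continuous step function S(t) with S(0) = 1; right
    censoring is respected. The function exposes ``.times`` (distinct
    event times) and ``.survival`` (S just after each event time).
    """
    t, e, _ = _to_arrays(samples)
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)

    def S(query: float) -> float:
        i = np.searchsorted(times, query, side="right") - 1
        return float(surv[i]) if i >= 0 else 1.0

    event_times = np.sort(np.unique(t[e]))
    S.times = event_times  # type: ignore[attr-defined]
    S.survival = np.array([S(tt) for tt in event_times])  # type: ignore[attr-defined]
    return S


def logrank(samples: Sequence[SurvivalSample]) -> TestResult:
    """Two-sample log-rank test (1-df chi-square) between groups 0 and 1."""
    t, e, g = _to_arrays(samples)
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise ValidationError("log-rank needs both groups non-empty")
    if not e.any():
        raise ValidationError("log-rank undefined with no events")
    from lifelines.statistics import logrank_test

    res = logrank_test(t[g == 0], t[g == 1], event_observed_A=e[g == 0],
                       event_observed_B=e[g == 1])
    return TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value),
                      effect=float(res.test_statistic), effect_name="chi2", n=t.size)


def _breslow_loglik(beta: float, t, e, g) -> tuple[float, float, float]:
    """Breslow partial log-likelihood, score and information for binary x."""
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n = t.size
    ll = score = info = 0.0
    eb = math.exp(beta)
    i = 0
    # walk distinct times ascending; risk set = all with time >= current
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            s = int(g[i:j][e[i:j]].sum())  # events in group 1 at this time
            n1 = int(g[i:].sum())
            n0 = (n - i) - n1
            denom = n0 + n1 * eb
            mu = n1 * eb / denom
            ll += beta * s - d * math.log(denom)
            score += s - d * mu
            info += d * mu * (1.0 - mu)
        i = j
    return ll, score, info


def hazard_ratio(samples: Sequence[SurvivalSample]) -> TestResult:
    """Univariable proportional-hazards fit on the binary group indicator.

    Cox partial likelihood with Breslow tie handling, Newton-Raphson to
    |change in log-likelihood| < 1e-8, Wald 95% CI on the log scale. The
    reported effect is HR = exp(beta) for group 1 vs group 0. When either
    group has zero events the HR is non-estimable: the result carries
    ``estimable=False`` and NaN effect rather than an infinite estimate.
    """
    t, e, g = _to_arrays(samples)
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise ValidationError("hazard ratio needs both groups non-empty")
    if not e.any():
        raise ValidationError("hazard ratio undefined with no events")
    if e[g == 1].sum() == 0 or e[g == 0].sum() == 0:
        return TestResult(statistic=math.nan, p_value=math.nan, effect=math.nan,
                          effect_name="HR", n=t.size, estimable=False)
    beta = 0.0
    ll_prev, score, info = _breslow_loglik(beta, t, e, g)
    for _ in range(100):
        if info <= 0:
            break
        beta = float(np.clip(beta + score / info, -30.0, 30.0))
        ll, score, info = _breslow_loglik(beta, t, e, g)
        if abs(ll - ll_prev) < 1e-8:
            break
        ll_prev = ll
    if abs(beta) >= 30.0 or info <= 0:
        # monotone partial likelihood (quasi-separated groups): no finite MLE
        return TestResult(statistic=math.nan, p_value=math.nan, effect=math.nan,
                          effect_name="HR", n=t.size, estimable=False)
    se = 1.0 / math.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    ci = np.exp(np.clip([beta - 1.959963984540054 * se,
                         beta + 1.959963984540054 * se], -700, 700))
    return TestResult(statistic=z, p_value=float(p), effect=math.exp(beta),
                      effect_name="HR", ci_low=float(ci[0]), ci_high=float(ci[1]),
                      n=t.size)


def dichotomize_at_mean(values: Sequence[float]) -> np.ndarray:
    """Binary groups at the cohort mean: 1 = above mean, 0 = at or below.

    Values exactly equal to the mean go to group 0 (deterministic
    boundary rule). A constant covariate is an error.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values to split")
    if np.ptp(v) == 0:
        raise ValidationError("cannot split a constant covariate at its mean")
    return (v > v.mean()).astype(int)


def survival_table(
    times: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame,
    endpoint: str,
) -> pd.DataFrame:
    """Mean-split log-rank + HR for every covariate column against one endpoint.

    Returns tidy rows (covariate, endpoint, logrank_p, hr, ci_low,
    ci_high, n_events, estimable); covariates that cannot be split or
    yield no events in a group produce flagged rows, never infinities.
    """
    rows = []
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    for col in covariates.columns:
        row = {"covariate": col, "endpoint": endpoint, "n_events": int(events.sum())}
        try:
            groups = dichotomize_at_mean(covariates[col].to_numpy())
            samples = [SurvivalSample(t, bool(ev), int(gr))
                       for t, ev, gr in zip(times, events, groups)]
            lr = logrank(samples)
            hr = hazard_ratio(samples)
            row.update(logrank_p=lr.p_value, hr=hr.effect, ci_low=hr.ci_low,
                       ci_high=hr.ci_high, estimable=hr.estimable)
        except ValidationError as exc:
            row.update(logrank_p=math.nan, hr=math.nan, ci_low=math.nan,
                       ci_high=math.nan, estimable=False, note=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
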
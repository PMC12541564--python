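"""Survival analysis: KM, log-rank, Cox, and maximally selected rank statistics.

Kaplan–Meier estimation, the two-sample log-rank test and univariate Cox
regression are delegated to lifelines; cut-point discovery by maximally
selected rank statistics — the step for which no maintained Python
implementation exists — is implemented here with the Lausen–Schumacher
adjusted p-value.

Cut-point direction convention: the "high" group is ``marker >= cutpoint``
everywhere downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import norm

logger = logging.getLogger(__name__)

DEFAULT_ENDPOINTS = (("pfs", "pfs_time", "pfs_event"),
                     ("os", "os_time", "os_event"))


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("no survival records")
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    return t, e.astype(int)


def km_estimate(times, events, alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit survival curve with Greenwood confidence band.

    Returns a tidy frame: time, survival, ci_lower, ci_upper, at_risk.
    """
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, e)
    timeline = kmf.survival_function_.index.to_numpy()
    ci = kmf.confidence_interval_survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy()
    return pd.DataFrame({
        "time": timeline,
        "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        "ci_lower": ci.iloc[:, 0].to_numpy(),
        "ci_upper": ci.iloc[:, 1].to_numpy(),
        "at_risk": at_risk,
    })


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p)."""
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"exactly two groups required, got {labels.size}")
    m = g == labels[0]
    res = _ll_logrank(t[m], t[~m], e[m], e[~m])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# maximally selected rank statistics

@dataclass(frozen=True)
class CutpointResult:
    """Cut point maximizing the standardized log-rank statistic."""

    cutpoint: float
    statistic: float          # max |standardized statistic|
    p_adjusted: float         # Lausen-Schumacher approximation
    quantile_range: tuple[float, float]
    n_candidates: int

    def high_group(self, marker) -> np.ndarray:
        """Boolean mask for the 'high' group (marker >= cutpoint)."""
        return np.asarray(marker, dtype=float) >= self.cutpoint


def logrank_scores(times, events) -> np.ndarray:
    """Log-rank (Savage-type) scores a_i = delta_i - H(t_i).

    ``H`` is the Nelson-Aalen cumulative hazard; scores sum to zero.
    """
    t, e = _as_arrays(times, events)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uniq, first = np.unique(ts, return_index=True)
    n = ts.size
    at_risk = n - first
    d = np.add.reduceat(es, first)
    increments = np.where(d > 0, d / at_risk, 0.0)
    cumhaz_at_uniq = np.cumsum(increments)
    idx = np.searchsorted(uniq, t, side="right") - 1
    return np.asarray(events, dtype=float) - cumhaz_at_uniq[idx]


def _ls_adjusted_p(b: float, q1: float, q2: float) -> float:
    """Lausen-Schumacher approximation for P(max |Z| over [q1, q2] > b)."""
    if b <= 0:
        return 1.0
    phi = norm.pdf(b)
    p = phi * (b - 1.0 / b) * np.log((q2 * (1 - q1)) / (q1 * (1 - q2))) \
        + 4.0 * phi / b
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def maxstat_cutpoint(times, events, marker,
                     quantile_range: tuple[float, float] = (0.10, 0.90),
                     ) -> CutpointResult:
    """Cut-point discovery by maximally selected rank statistics.

    Every observed marker value whose induced low-group proportion lies
    inside ``quantile_range`` is a candidate threshold; for each, the sum of
    log-rank scores in the low group is standardized by its permutation
    variance and the threshold with maximal |statistic| is returned (ties
    toward the smaller cutpoint), with the Lausen-Schumacher adjusted p.
    """
    t, e = _as_arrays(times, events)
    x = np.asarray(marker, dtype=float)
    if x.size != t.size:
        raise ValueError("marker and survival records must align")
    if x.size < 10:
        raise ValueError("need at least 10 records for cut-point discovery")
    if np.unique(x).size < 2:
        raise ValueError("all marker values equal: no candidate splits")
    q1, q2 = quantile_range
    if not 0 < q1 < q2 < 1:
        raise ValueError("quantile_range must satisfy 0 < lo < hi < 1")

    a = logrank_scores(t, e)
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = a[order]
    x_sorted = x[order]
    csum = np.cumsum(xs)
    # thresholds c = observed values; low group = {marker < c}; m = its size.
    # for sorted x, candidate c = x_sorted[j] with m = index of first
    # occurrence of that value
    uniq_vals, first_idx = np.unique(x_sorted, return_index=True)
    m = first_idx[1:]                      # low-group sizes for c = uniq[1:]
    cands = uniq_vals[1:]
    frac = m / n
    keep = (frac >= q1) & (frac <= q2)
    if not keep.any():
        raise ValueError("no candidate splits inside the quantile range")
    m = m[keep]
    cands = cands[keep]
    s = csum[m - 1]
    var = m * (n - m) / (n * (n - 1.0)) * np.sum(a ** 2)
    z = np.abs(s) / np.sqrt(var)
    best = int(np.argmax(z))              # argmax returns first (smallest c)
    eps1, eps2 = frac[keep].min(), frac[keep].max()
    return CutpointResult(
        cutpoint=float(cands[best]),
        statistic=float(z[best]),
        p_adjusted=_ls_adjusted_p(float(z[best]), float(eps1), float(eps2)),
        quantile_range=(q1, q2),
        n_candidates=int(cands.size))


# ---------------------------------------------------------------------------
# univariate Cox regression

@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox fit (Efron ties, Wald inference)."""

    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    n_events: int
    converged: bool
    log_hr: float
    se_log_hr: float

    def summary(self) -> str:
        return (f"HR = {self.hr:.2f}, 95% CI [{self.ci_lower:.2f}, "
                f"{self.ci_upper:.2f}], p = {self.p_value:.3f} "
                f"(n = {self.n}, events = {self.n_events})")


def cox_univariate(times, events, covariate) -> CoxFit:
    """Cox partial-likelihood fit of a single (typically binary) covariate."""
    t, e = _as_arrays(times, events)
    x = np.asarray(covariate, dtype=float)
    if e.sum() == 0:
        raise ValueError("no events: Cox model is not estimable")
    for level in np.unique(x):
        if x.size and e[x == level].sum() == 0 and np.unique(x).size == 2:
            warnings.warn(f"covariate level {level} has no events",
                          stacklevel=2)
    df = pd.DataFrame({"t": t, "e": e, "x": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="t", event_col="e")
        converged = True
    except ConvergenceError:
        logger.warning("Cox fit failed to converge (monotone likelihood?)")
        return CoxFit(hr=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                      p_value=np.nan, n=int(t.size), n_events=int(e.sum()),
                      converged=False, log_hr=np.nan, se_log_hr=np.nan)
    log_hr = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = log_hr / se
    return CoxFit(
        hr=float(np.exp(log_hr)),
        ci_lower=float(np.exp(log_hr - 1.96 * se)),
        ci_upper=float(np.exp(log_hr + 1.96 * se)),
        p_value=float(2 * norm.sf(abs(z))),
        n=int(t.size), n_events=int(e.sum()),
        converged=converged, log_hr=log_hr, se_log_hr=se)


def subgroup_compare(records: pd.DataFrame, stratum_filter: dict,
                     group_col: str,
                     endpoints=DEFAULT_ENDPOINTS) -> pd.DataFrame:
    """Per-stratum log-rank comparison (e.g. chemotherapy addition).

    ``stratum_filter`` maps column -> required value; rows failing the
    filter are excluded.  Returns one row per endpoint with the log-rank p;
    an empty or single-group stratum yields an empty frame with a warning.
    """
    sub = records
    for col, val in stratum_filter.items():
        sub = sub[sub[col] == val]
    if sub.empty:
        warnings.warn(f"stratum filter {stratum_filter} matched no records",
                      stacklevel=2)
        return pd.DataFrame(columns=["endpoint", "statistic", "p", "n"])
    groups = sub[group_col]
    if groups.nunique() < 2 or groups.value_counts().min() < 2:
        warnings.warn("stratum needs >= 2 records in each of two groups; "
                      "skipped", stacklevel=2)
        return pd.DataFrame(columns=["endpoint", "statistic", "p", "n"])
    rows = []
    for name, tcol, ecol in endpoints:
        stat, p = logrank_test(sub[tcol], sub[ecol], groups)
        rows.append({"endpoint": name, "statistic": stat, "p": p,
                     "n": int(len(sub))})
    return pd.DataFrame(rows)
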
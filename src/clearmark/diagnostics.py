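"""Response classification and diagnostic performance of the biomarkers.

Non-response is progression within 6 months of the first dose; a positive
biomarker call (high baseline clearance, or diminished clearance decline)
flags predicted non-response.  Sensitivity, specificity, PPV and NPV carry
Wald 95% intervals (Wilson available), clipped to [0, 1]; a metric with a
zero denominator is reported as NaN and flagged undefined rather than 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_HORIZON_MONTHS = 6.0


def classify_response(pfs_time: float, pfs_event: int,
                      horizon_months: float = RESPONSE_HORIZON_MONTHS) -> str:
    """'non_responder' iff progression occurred on or before the horizon.

    Records censored before the horizon are classified by last known status,
    i.e. as responders; callers may count these via
    :func:`censored_before_horizon`.
    """
    if pfs_time is None or pfs_event is None:
        raise ValueError("pfs_time and pfs_event are required")
    if not math.isfinite(pfs_time) or pfs_time < 0:
        raise ValueError(f"invalid pfs_time: {pfs_time}")
    if pfs_event not in (0, 1):
        raise ValueError(f"pfs_event must be 0/1, got {pfs_event}")
    if pfs_event == 1 and pfs_time <= horizon_months:
        return "non_responder"
    return "responder"


def classify_cohort(records: pd.DataFrame,
                    horizon_months: float = RESPONSE_HORIZON_MONTHS
                    ) -> pd.Series:
    """Vectorized response labels; logs the censored-before-horizon count."""
    labels = np.where((records["pfs_event"] == 1)
                      & (records["pfs_time"] <= horizon_months),
                      "non_responder", "responder")
    n_cens = int(((records["pfs_event"] == 0)
                  & (records["pfs_time"] < horizon_months)).sum())
    if n_cens:
        logger.info("%d records censored before the %.0f-month horizon were "
                    "classified responder by last known status",
                    n_cens, horizon_months)
    return pd.Series(labels, index=records.index, name="response")


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    se = math.sqrt(p * (1 - p) / n)
    return max(p - 1.96 * se, 0.0), min(p + 1.96 * se, 1.0)


def _wilson_ci(p: float, n: int) -> tuple[float, float]:
    z = 1.96
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


@dataclass(frozen=True)
class DiagnosticTable:
    """2x2 confusion counts and the four derived metrics with 95% CIs.

    Positive = biomarker flags non-response; truth positive = actual
    non-responder (progression within the horizon).
    """

    tp: int
    fn: int
    fp: int
    tn: int
    ci_method: str = "wald"

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ci_method not in ("wald", "wilson"):
            raise ValueError("ci_method must be 'wald' or 'wilson'")

    def _metric(self, num: int, den: int):
        if den == 0:
            return float("nan"), (float("nan"), float("nan"))
        p = num / den
        ci = (_wald_ci if self.ci_method == "wald" else _wilson_ci)(p, den)
        return p, ci

    @property
    def sensitivity(self) -> float:
        return self._metric(self.tp, self.tp + self.fn)[0]

    @property
    def specificity(self) -> float:
        return self._metric(self.tn, self.tn + self.fp)[0]

    @property
    def ppv(self) -> float:
        return self._metric(self.tp, self.tp + self.fp)[0]

    @property
    def npv(self) -> float:
        return self._metric(self.tn, self.tn + self.fn)[0]

    def to_dict(self) -> dict:
        out = {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}
        for name, num, den in (
                ("sensitivity", self.tp, self.tp + self.fn),
                ("specificity", self.tn, self.tn + self.fp),
                ("ppv", self.tp, self.tp + self.fp),
                ("npv", self.tn, self.tn + self.fn)):
            p, ci = self._metric(num, den)
            out[name] = p
            out[f"{name}_ci"] = list(ci)
            out[f"{name}_defined"] = den > 0
        return out


def diagnostic_metrics(truth_positive, biomarker_positive,
                       ci_method: str = "wald") -> DiagnosticTable:
    """Cross-tabulate truth vs biomarker call into a DiagnosticTable."""
    y = np.asarray(truth_positive).astype(bool)
    yhat = np.asarray(biomarker_positive).astype(bool)
    if y.size == 0:
        raise ValueError("empty input vectors")
    if y.size != yhat.size:
        raise ValueError("input vectors must have equal length")
    return DiagnosticTable(
        tp=int((y & yhat).sum()), fn=int((y & ~yhat).sum()),
        fp=int((~y & yhat).sum()), tn=int((~y & ~yhat).sum()),
        ci_method=ci_method)


def table_from_rates(n_positive: int, n_negative: int,
                     sensitivity: float, specificity: float,
                     ci_method: str = "wald") -> DiagnosticTable:
    """Reconstruct integer 2x2 counts from prevalence and printed rates.

    Useful for checking published sensitivity/specificity against the
    predictive values they imply: tp = round(sens * n_positive) etc.
    """
    tp = round(sensitivity * n_positive)
    tn = round(specificity * n_negative)
    return DiagnosticTable(tp=tp, fn=n_positive - tp,
                           fp=n_negative - tn, tn=tn, ci_method=ci_method)
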
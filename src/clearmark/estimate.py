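"""Empirical-Bayes (MAP) estimation of individual clearance.

With population parameters fixed, each patient's random effects ``eta`` are
estimated by minimizing the standard FOCE-style empirical-Bayes objective

    sum_j [ (DV_j - F_j(eta))^2 / g_j^2 + ln g_j^2 ]  +  eta' Omega^{-1} eta,
    g_j^2 = (sigma_prop * F_j)^2 + sigma_add^2,

i.e. the negative log posterior up to a constant under log-normal
between-subject variability and combined residual error.  The quantities of
interest are the LBW-normalized clearance at the first dose and at 6 weeks,
and their percent change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import EARLY_CHANGE_DAY, VirtualPatient
from .params import PopPKParams, RANDOM_EFFECT_NAMES
from .pk import (DoseEvent, IndividualPKParams, clearance_at_time,
                 lean_body_weight, normalize_clearance, percent_change,
                 predict_concentration)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndividualClearanceEstimate:
    """MAP clearance estimates for one patient."""

    id: int | str
    cl_first_dose: float
    cl_first_dose_norm: float
    cl_6w: float
    delta_pct: float
    eta_hat: dict[str, float]
    n_samples_used: int
    converged: bool
    objective: float


class IndividualPKResults:
    """Fit results; thin wrapper with a human-readable summary."""

    def __init__(self, model: "IndividualPKModel", eta_hat: np.ndarray,
                 objective: float, converged: bool, grad_norm: float):
        self.model = model
        self.eta_hat = dict(zip(model.random_effects, eta_hat))
        self.objective = float(objective)
        self.converged = bool(converged)
        self.grad_norm = float(grad_norm)
        self.params_hat = IndividualPKParams.from_population(
            model.pop, model.lbw, self.eta_hat)
        self.cl_first_dose = self.params_hat.cl0
        self.cl_first_dose_norm = normalize_clearance(
            self.cl_first_dose, model.lbw, model.pop.theta_size)
        self.cl_6w = clearance_at_time(self.params_hat, EARLY_CHANGE_DAY)
        self.delta_pct = percent_change(self.cl_first_dose, self.cl_6w)

    def to_estimate(self, patient_id: int | str = 0) -> IndividualClearanceEstimate:
        return IndividualClearanceEstimate(
            id=patient_id, cl_first_dose=self.cl_first_dose,
            cl_first_dose_norm=self.cl_first_dose_norm, cl_6w=self.cl_6w,
            delta_pct=self.delta_pct, eta_hat=self.eta_hat,
            n_samples_used=self.model.nobs, converged=self.converged,
            objective=self.objective)

    def summary(self) -> str:
        lines = [
            "Individual clearance MAP fit",
            "----------------------------",
            f"observations used : {self.model.nobs}",
            f"converged         : {self.converged} "
            f"(|grad| = {self.grad_norm:.2e})",
            f"objective         : {self.objective:.6g}",
            f"CL first dose     : {self.cl_first_dose:.4f} L/day "
            f"({self.cl_first_dose_norm:.4f} normalized to 52.5 kg LBW)",
            f"CL at 6 weeks     : {self.cl_6w:.4f} L/day",
            f"6-week decline    : {self.delta_pct:.1f} %",
            "eta_hat           : " + ", ".join(
                f"{k}={v:+.4f}" for k, v in self.eta_hat.items()),
        ]
        return "\n".join(lines)


class IndividualPKModel:
    """MAP model for one patient's concentration data.

    Parameters
    ----------
    times, conc : array-like
        Quantified observation times (days) and concentrations (mg/L).
    doses : list of DoseEvent
    lbw : float
        Individual lean body weight (kg).
    pop : PopPKParams
        Fixed population parameters (priors and residual-error model).
    random_effects : sequence of str, optional
        Which etas to estimate; defaults to those with positive omega_sq.
    """

    def __init__(self, times, conc, doses: list[DoseEvent], lbw: float,
                 pop: PopPKParams,
                 random_effects: tuple[str, ...] | None = None):
        self.times = np.asarray(times, dtype=float)
        self.conc = np.asarray(conc, dtype=float)
        if self.times.size == 0:
            raise ValueError(
                "patient has zero usable (above-LLOQ) samples; "
                "ineligible for empirical-Bayes estimation")
        if self.times.size != self.conc.size:
            raise ValueError("times and conc must have equal length")
        self.doses = list(doses)
        self.lbw = float(lbw)
        self.pop = pop
        if random_effects is None:
            random_effects = tuple(n for n in RANDOM_EFFECT_NAMES
                                   if pop.omega_sq.get(n, 0.0) > 0)
        if not random_effects:
            raise ValueError("no random effects with positive omega_sq")
        self.random_effects = tuple(random_effects)
        self._omega = np.array([pop.omega_sq[n] for n in self.random_effects])
        if np.any(self._omega <= 0):
            raise ValueError("omega_sq must be > 0 for estimated effects")

    @property
    def nobs(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_patient(cls, patient: VirtualPatient, pop: PopPKParams,
                     **kw) -> "IndividualPKModel":
        """Build from a simulated patient, using non-BLQ observations only."""
        keep = ~patient.blq
        return cls(patient.sample_times[keep], patient.conc_obs[keep],
                   patient.doses, patient.lbw, pop, **kw)

    @classmethod
    def from_dataframe(cls, pk: pd.DataFrame, patient_id,
                       pop: PopPKParams, **kw) -> "IndividualPKModel":
        """Build from a long-format dosing/observation table (one patient).

        Expects columns ID, TIME, AMT, RATE, DV, BLQ, EVID, WT, HT, SEX.
        """
        sub = pk[pk["ID"] == patient_id]
        if sub.empty:
            raise ValueError(f"no rows for patient {patient_id!r}")
        drows = sub[sub["EVID"] == 1]
        doses = [DoseEvent(r.TIME, r.AMT, r.AMT / r.RATE)
                 for r in drows.itertuples()]
        obs = sub[(sub["EVID"] == 0) & (sub["BLQ"] == 0)]
        sex = "male" if int(sub["SEX"].iloc[0]) == 1 else "female"
        lbw = lean_body_weight(float(sub["WT"].iloc[0]),
                               float(sub["HT"].iloc[0]), sex)
        return cls(obs["TIME"].to_numpy(), obs["DV"].to_numpy(),
                   doses, lbw, pop, **kw)

    def _params_at(self, eta_vec: np.ndarray) -> IndividualPKParams:
        return IndividualPKParams.from_population(
            self.pop, self.lbw, dict(zip(self.random_effects, eta_vec)))

    def map_objective(self, eta_vec) -> float:
        """Penalized least squares: data term plus eta' Omega^{-1} eta."""
        eta_vec = np.asarray(eta_vec, dtype=float)
        f = np.atleast_1d(predict_concentration(
            self._params_at(eta_vec), self.doses, self.times))
        g2 = (self.pop.sigma_prop * f) ** 2 + self.pop.sigma_add ** 2
        data_term = np.sum((self.conc - f) ** 2 / g2 + np.log(g2))
        return float(data_term + np.sum(eta_vec ** 2 / self._omega))

    def fit(self, n_starts: int = 3, tol: float = 1e-8,
            restart_seed: int = 0) -> IndividualPKResults:
        """Minimize the MAP objective (L-BFGS-B, multi-start on failure)."""
        k = len(self.random_effects)
        bounds = [(-6.0 * np.sqrt(w), 6.0 * np.sqrt(w)) for w in self._omega]
        rng = np.random.default_rng(restart_seed)
        starts = [np.zeros(k)]
        best = None
        for attempt in range(n_starts):
            x0 = starts[0] if attempt == 0 else rng.normal(
                0.0, np.sqrt(self._omega))
            res = minimize(self.map_objective, x0, method="L-BFGS-B",
                           bounds=bounds,
                           options={"ftol": tol, "gtol": 1e-7,
                                    "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            if res.success:
                if attempt == 0:
                    break
        grad_norm = float(np.linalg.norm(np.atleast_1d(best.jac)))
        # L-BFGS-B reports success=False when the finite-difference gradient
        # noise floor (~1e-4) exceeds gtol; a tiny gradient is still converged
        converged = bool(best.success) or grad_norm < 1e-3 * (1.0 + abs(best.fun))
        if not converged:
            logger.warning("MAP fit did not converge after %d starts "
                           "(|grad|=%.2e)", n_starts, grad_norm)
        return IndividualPKResults(self, np.asarray(best.x), best.fun,
                                   converged, grad_norm)


def estimate_cohort(cohort: list[VirtualPatient], pop: PopPKParams,
                    random_effects: tuple[str, ...] | None = None,
                    ) -> pd.DataFrame:
    """MAP-estimate every eligible patient; one row per patient.

    Patients whose samples are all BLQ, or whose optimizer fails to
    converge, are flagged (``converged=False`` / skipped with a logged
    reason) rather than aborting the cohort.
    """
    rows = []
    n_skipped = 0
    n_nonconv = 0
    for p in cohort:
        try:
            model = IndividualPKModel.from_patient(
                p, pop, random_effects=random_effects)
        except ValueError as exc:
            n_skipped += 1
            logger.info("patient %s skipped: %s", p.id, exc)
            continue
        res = model.fit()
        if not res.converged:
            n_nonconv += 1
        est = res.to_estimate(p.id)
        rows.append({
            "id": est.id,
            "cl_first_dose": est.cl_first_dose,
            "cl_first_dose_norm": est.cl_first_dose_norm,
            "cl_6w": est.cl_6w,
            "delta_pct": est.delta_pct,
            "n_samples_used": est.n_samples_used,
            "converged": est.converged,
            "objective": est.objective,
            **{f"eta_{k}": v for k, v in est.eta_hat.items()},
        })
    df = pd.DataFrame(rows)
    if len(df):
        logger.info(
            "cohort estimation: n=%d, median CL0_norm=%.4f L/day, "
            "median 6-week decline=%.1f%%, skipped=%d, non-converged=%d",
            len(df), df["cl_first_dose_norm"].median(),
            df["delta_pct"].median(), n_skipped, n_nonconv)
    return df
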
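"""End-to-end orchestration: simulate -> estimate -> cut-point -> survival
-> diagnostics -> design evaluation, with provenance-stamped outputs.

Every artifact records the seed and a hash of the full configuration; the
bundle is byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .cohort import (CohortConfig, HazardConfig, apply_lloq_filter,
                     simulate_cohort, simulate_outcomes, survival_to_frame,
                     write_cohort, cohort_to_pk_frame)
from .diagnostics import classify_cohort, diagnostic_metrics
from .estimate import estimate_cohort
from .params import PopPKParams, default_pop_params
from .sampling import limited_design, rich_design, run_design_eval
from .survival import (cox_univariate, km_estimate, maxstat_cutpoint,
                       subgroup_compare)

logger = logging.getLogger(__name__)

PK_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "BLQ", "EVID",
              "WT", "HT", "SEX"]
SURV_COLUMNS = ["id", "pfs_time", "pfs_event", "os_time", "os_event",
                "regimen", "pd_l1_stratum"]


class AnalysisOptions(BaseModel):
    quantile_range: tuple[float, float] = (0.10, 0.90)
    horizon_months: float = Field(default=6.0, gt=0)
    ci_method: str = "wald"
    theta_size: float = 0.75
    eval_n: int = Field(default=1000, ge=0)  # 0 disables design evaluation


class PipelineConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    seed: int = Field(ge=0, lt=2 ** 31)
    outdir: str
    cohort: CohortConfig = CohortConfig()
    hazards: HazardConfig = HazardConfig()
    analysis: AnalysisOptions = AnalysisOptions()
    pop_params_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        if cfg.pop_params_path and not Path(cfg.pop_params_path).exists():
            raise FileNotFoundError(cfg.pop_params_path)
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        canon = json.dumps(self.model_dump(exclude={"outdir"}),
                           sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def pop_params(self) -> PopPKParams:
        if self.pop_params_path:
            return PopPKParams.from_json(self.pop_params_path)
        return default_pop_params()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_inputs(pk: pd.DataFrame,
                    survival: pd.DataFrame) -> list[str]:
    """Schema / ordering / cross-file consistency checks.

    All violations are reported; nothing is silently fixed.
    """
    violations: list[str] = []
    for col in PK_COLUMNS:
        if col not in pk.columns:
            violations.append(f"pk: missing column {col}")
    for col in SURV_COLUMNS:
        if col not in survival.columns:
            violations.append(f"survival: missing column {col}")
    if violations:
        return violations
    for pid, sub in pk.groupby("ID"):
        if not sub["TIME"].is_monotonic_increasing:
            violations.append(f"pk: patient {pid}: times not sorted")
        doses = sub[sub["EVID"] == 1]
        obs = sub[sub["EVID"] == 0]
        if doses.empty:
            violations.append(f"pk: patient {pid}: no dose events")
        elif not obs.empty and obs["TIME"].min() < doses["TIME"].min():
            violations.append(
                f"pk: patient {pid}: sample precedes first dose")
        for col in ("WT", "HT", "SEX"):
            if sub[col].nunique() > 1:
                violations.append(
                    f"pk: patient {pid}: conflicting {col} values")
    if pk["TIME"].lt(0).any():
        violations.append("pk: negative TIME values")
    for col in ("pfs_time", "os_time"):
        if survival[col].le(0).any():
            violations.append(f"survival: non-positive {col}")
    for col in ("pfs_event", "os_event"):
        if not survival[col].isin((0, 1)).all():
            violations.append(f"survival: non-binary {col}")
    if survival["id"].duplicated().any():
        violations.append("survival: duplicated patient ids")
    missing = set(survival["id"]) - set(pk["ID"])
    if missing:
        violations.append(
            f"survival ids absent from pk dataset: {sorted(missing)[:5]}")
    return violations


def _stamp(obj: dict, cfg: PipelineConfig) -> dict:
    return {"seed": cfg.seed, "config_hash": cfg.config_hash(), **obj}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle; returns the report."""
    if config.cohort.n < 1:
        raise ValueError("cohort n must be >= 1 for a pipeline run")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop = config.pop_params()
    report: dict[str, Any] = _stamp({}, config)
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        cohort = simulate_cohort(config.cohort, config.seed, pop)
        cohort = apply_lloq_filter(cohort, config.cohort.lloq)
        if not cohort:
            raise RuntimeError("no eligible patients after LLOQ filter")
        records = simulate_outcomes(cohort, config.hazards, config.seed + 1)
        write_cohort(cohort, records, outdir, config.cohort,
                     config.hazards, config.seed)
        surv = survival_to_frame(records)
        violations = validate_inputs(cohort_to_pk_frame(cohort), surv)
        if violations:
            raise RuntimeError(f"generated data failed validation: "
                               f"{violations[:3]}")
        timings[stage] = time.perf_counter() - t0

        stage = "estimate"
        t0 = time.perf_counter()
        est = estimate_cohort(cohort, pop)
        est_path = outdir / "estimates.csv"
        est.to_csv(est_path, index=False)
        df = est.merge(surv, on="id")
        report["cohort"] = {
            "n": len(df),
            "median_cl_first_norm": float(df["cl_first_dose_norm"].median()),
            "median_delta_pct": float(df["delta_pct"].median()),
            "pfs_event_fraction": float(df["pfs_event"].mean()),
            "os_event_fraction": float(df["os_event"].mean()),
            "n_nonconverged": int((~df["converged"]).sum()),
        }
        timings[stage] = time.perf_counter() - t0

        stage = "cutpoint"
        t0 = time.perf_counter()
        markers = {"cl_first_norm": df["cl_first_dose_norm"].to_numpy(),
                   "delta_pct": df["delta_pct"].to_numpy()}
        cuts: dict[str, Any] = {}
        for mname, mvals in markers.items():
            cuts[mname] = {}
            for ep, tcol, ecol in (("pfs", "pfs_time", "pfs_event"),
                                   ("os", "os_time", "os_event")):
                res = maxstat_cutpoint(df[tcol], df[ecol], mvals,
                                       config.analysis.quantile_range)
                cuts[mname][ep] = {
                    "cutpoint": res.cutpoint, "statistic": res.statistic,
                    "p_adjusted": res.p_adjusted,
                    "n_candidates": res.n_candidates}
        (outdir / "cutpoints.json").write_text(
            json.dumps(_stamp(cuts, config), indent=2) + "\n")
        report["cutpoints"] = cuts
        timings[stage] = time.perf_counter() - t0

        stage = "survival"
        t0 = time.perf_counter()
        cox: dict[str, Any] = {}
        for mname, mvals in markers.items():
            cut = cuts[mname]["pfs"]["cutpoint"]
            # "high" = marker >= cutpoint; for the decline marker the
            # at-risk group is the LOW-decline one, i.e. below the cut
            high = (mvals >= cut) if mname == "cl_first_norm" else (mvals < cut)
            cox[mname] = {}
            for ep, tcol, ecol in (("pfs", "pfs_time", "pfs_event"),
                                   ("os", "os_time", "os_event")):
                fit = cox_univariate(df[tcol], df[ecol], high.astype(int))
                cox[mname][ep] = {
                    "hr": fit.hr, "ci": [fit.ci_lower, fit.ci_upper],
                    "p": fit.p_value, "n": fit.n, "events": fit.n_events}
                for gname, gmask in (("risk", high), ("ref", ~high)):
                    km = km_estimate(df.loc[gmask, tcol], df.loc[gmask, ecol])
                    km.to_csv(outdir / f"km_{mname}_{ep}_{gname}.csv",
                              index=False)
        (outdir / "cox.json").write_text(
            json.dumps(_stamp(cox, config), indent=2) + "\n")
        report["cox"] = cox
        df["chemo_added"] = (df["regimen"] != "monotherapy").astype(int)
        sub = subgroup_compare(df, {"pd_l1_stratum": ">=50%"}, "chemo_added")
        report["subgroup_pdl1_high_chemo"] = sub.to_dict(orient="records")
        timings[stage] = time.perf_counter() - t0

        stage = "diagnostics"
        t0 = time.perf_counter()
        truth_nonresp = (classify_cohort(df, config.analysis.horizon_months)
                         == "non_responder").to_numpy()
        diag: dict[str, Any] = {}
        for mname, mvals in markers.items():
            cut = cuts[mname]["pfs"]["cutpoint"]
            positive = (mvals >= cut) if mname == "cl_first_norm" \
                else (mvals < cut)
            diag[mname] = diagnostic_metrics(
                truth_nonresp, positive,
                ci_method=config.analysis.ci_method).to_dict()
        (outdir / "diagnostics.json").write_text(
            json.dumps(_stamp(diag, config), indent=2) + "\n")
        report["diagnostics"] = diag
        timings[stage] = time.perf_counter() - t0

        stage = "eval-design"
        t0 = time.perf_counter()
        if config.analysis.eval_n > 0:
            evals = {}
            for design in (limited_design(), rich_design()):
                rep = run_design_eval(design, config.analysis.eval_n,
                                      config.seed + 2, pop)
                evals[design.label] = {"n": rep.n, "mpe_pct": rep.mpe_pct,
                                       "nrmse_pct": rep.nrmse_pct}
            (outdir / "sampling_eval.json").write_text(
                json.dumps(_stamp(evals, config), indent=2) + "\n")
            report["sampling_eval"] = evals
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    # timings are diagnostics, not part of the reproducible bundle
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2) + "\n")
    (outdir / "summary.txt").write_text(_summary_text(report))
    logger.info("stage timings (s): %s",
                {k: round(v, 3) for k, v in timings.items()})
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    return report


def _summary_text(report: dict[str, Any]) -> str:
    c = report["cohort"]
    lines = [
        f"clearmark pipeline report  (seed={report['seed']}, "
        f"config={report['config_hash']})",
        "",
        f"cohort: n={c['n']}, median CL0_norm={c['median_cl_first_norm']:.3f} "
        f"L/day, median 6-week decline={c['median_delta_pct']:.1f}%",
        f"events: PFS {100 * c['pfs_event_fraction']:.0f}%, "
        f"OS {100 * c['os_event_fraction']:.0f}%  "
        f"(non-converged fits: {c['n_nonconverged']})",
        "",
    ]
    for mname, label in (("cl_first_norm", "baseline CL (high)"),
                         ("delta_pct", "6-week decline (low)")):
        cut = report["cutpoints"][mname]
        cox = report["cox"][mname]
        lines.append(
            f"{label}: cut PFS={cut['pfs']['cutpoint']:.3f} "
            f"(adj p={cut['pfs']['p_adjusted']:.3g}), "
            f"OS={cut['os']['cutpoint']:.3f}")
        for ep in ("pfs", "os"):
            f = cox[ep]
            lines.append(f"  {ep.upper()}: HR={f['hr']:.2f} "
                         f"[{f['ci'][0]:.2f}, {f['ci'][1]:.2f}], "
                         f"p={f['p']:.3g}")
    if "sampling_eval" in report:
        lines.append("")
        for label, ev in report["sampling_eval"].items():
            lines.append(f"design {label}: MPE={ev['mpe_pct']:+.1f}%, "
                         f"NRMSE={ev['nrmse_pct']:.1f}% (n={ev['n']})")
    return "\n".join(lines) + "\n"
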
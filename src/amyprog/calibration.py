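"""Calibration of whole-body clearance to printed physiological anchors.

The healthy adult brain turns over its Abeta pool fast: production
around 7.6% and clearance around 8.3% of the pool per hour, with
about 85% of all clearance routed across the blood-brain barrier.
``ClearanceCalibration`` adjusts three transport rates so the model's
homeostatic steady state reproduces those anchors:

* RAGE influx ``F_in``   — sets the clearance-minus-production gap,
* LRP1/P-gp efflux ``F_out`` — sets the BBB share,
* glymphatic flow ``Q_ipv``/``Q_pvL`` — sets the non-BBB remainder.

The late-onset-AD (LOAD) parameterisation is derived from the healthy
one by scaling every brain elimination route (BBB efflux, glymphatic
drainage, CSF absorption, enzymatic capacity) by a common factor, so
the steady-state fractional clearance drops by exactly that factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .lifespan import LifespanModel, SubjectProfile
from .params import ParameterSet
from .transport import BrainClearanceAudit

__all__ = [
    "ClearanceCalibration",
    "CalibrationResults",
    "calibrate_to_constraints",
    "apply_load",
    "healthy_audit",
]

_FREE = (
    "transport.transporters.F_in.ab40",      # scale shared with ab42
    "transport.transporters.F_out.ab40",     # ab42 follows at fixed ratio
    "transport.flows.Q_ipv",                 # Q_pvL follows (continuity)
)


def healthy_audit(params: ParameterSet,
                  profile: SubjectProfile | None = None,
                  y_guess=None) -> BrainClearanceAudit:
    """Homeostatic brain-clearance audit for a healthy reference subject."""
    profile = profile or SubjectProfile(disease_status="healthy")
    model = LifespanModel(profile, params)
    y0 = model.initialize_homeostasis(y_guess=y_guess)
    return model.audit(y0)


def apply_load(params: ParameterSet) -> ParameterSet:
    """LOAD parameter set: impaired brain clearance machinery.

    Every CNS fluid-clearance pathway — BBB efflux, barrier fluid
    permeation, ISF/CSF exchange, CSF absorption, glymphatic drainage,
    PVS macrophage uptake — and the protease capacity are scaled by the
    configured ``clearance.load_factor`` (0.7 by default), modelling
    the globally reduced Abeta turnover of the late-onset-AD brain;
    RAGE influx and production are untouched.
    """
    f = float(params.get("clearance.load_factor"))
    out = params.copy()
    for path in ("transport.transporters.F_out.ab40",
                 "transport.transporters.F_out.ab42",
                 "transport.transporters.F_out_D.ab40",
                 "transport.transporters.F_out_D.ab42",
                 "transport.flows.Q_Bi",
                 "transport.flows.Q_Bc",
                 "transport.flows.Q_ic",
                 "transport.flows.Q_ipv",
                 "transport.flows.Q_pvL",
                 "transport.flows.Q_cabs",
                 "clearance.Vmax0",
                 "clearance.k_mac_pv"):
        out.set(path, f * float(params.get(path)))
    return out


class ClearanceCalibration:
    """Bounded least squares of the free transport rates against the
    physiological constraint targets.

    Targets default to the ``calibration.targets`` block of the
    parameter set. The optimisation is deterministic (no stochastic
    search), so repeated fits are bit-identical.
    """

    def __init__(self, params: ParameterSet | None = None,
                 targets: dict[str, float] | None = None,
                 profile: SubjectProfile | None = None):
        self.params = params.copy() if params is not None else ParameterSet.defaults()
        self.targets = targets or {
            k: float(v) for k, v in self.params.section("calibration.targets").items()
        }
        self.profile = profile or SubjectProfile(disease_status="healthy")
        self.rel_tol = float(self.params.get("calibration.rel_tol"))
        self._warm = None  # warm-start state reused across residual evaluations

    def _with_free(self, x: np.ndarray) -> ParameterSet:
        p = self.params.copy()
        f_in, f_out, q_pv = np.exp(x)
        ratio_in = (self.params.get("transport.transporters.F_in.ab42")
                    / self.params.get("transport.transporters.F_in.ab40"))
        ratio_out = (self.params.get("transport.transporters.F_out.ab42")
                     / self.params.get("transport.transporters.F_out.ab40"))
        p.set("transport.transporters.F_in.ab40", f_in)
        p.set("transport.transporters.F_in.ab42", f_in * ratio_in)
        p.set("transport.transporters.F_out.ab40", f_out)
        p.set("transport.transporters.F_out.ab42", f_out * ratio_out)
        p.set("transport.flows.Q_ipv", q_pv)
        p.set("transport.flows.Q_pvL", q_pv)
        return p

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        model = LifespanModel(self.profile, self._with_free(x))
        y0 = model.initialize_homeostasis(y_guess=self._warm)
        self._warm = y0
        audit = model.audit(y0)
        t = self.targets
        return np.array([
            (audit.production_pct_per_h - t["production_pct_per_h"])
            / t["production_pct_per_h"],
            (audit.clearance_pct_per_h - t["clearance_pct_per_h"])
            / t["clearance_pct_per_h"],
            (audit.bbb_share_pct - t["bbb_share_pct"]) / t["bbb_share_pct"],
        ])

    def fit(self, xtol: float = 1e-10) -> "CalibrationResults":
        x0 = np.log([float(self.params.get(p)) for p in _FREE])
        r0 = self._residuals(x0)
        if np.max(np.abs(r0)) <= self.rel_tol:
            # already satisfying: fixed point, return unchanged
            return CalibrationResults(
                params=self.params.copy(), residuals=r0, x=x0, n_evals=1,
                audit=healthy_audit(self.params, self.profile),
                targets=self.targets, converged=True)
        res = least_squares(self._residuals, x0, method="trf",
                            bounds=(x0 - np.log(50.0), x0 + np.log(50.0)),
                            xtol=xtol, ftol=1e-12, gtol=1e-12)
        params = self._with_free(res.x)
        resid = self._residuals(res.x)
        converged = bool(np.max(np.abs(resid)) <= self.rel_tol)
        if not converged:
            worst = dict(zip(self.targets, resid))
            raise RuntimeError(
                f"calibration infeasible within bounds; residuals {worst}")
        return CalibrationResults(
            params=params, residuals=resid, x=res.x, n_evals=res.nfev,
            audit=healthy_audit(params, self.profile),
            targets=self.targets, converged=converged)


@dataclass
class CalibrationResults:
    params: ParameterSet
    residuals: np.ndarray
    x: np.ndarray
    n_evals: int
    audit: BrainClearanceAudit
    targets: dict[str, float]
    converged: bool

    def free_values(self) -> dict[str, float]:
        return dict(zip(_FREE, map(float, np.exp(self.x))))

    def summary(self) -> str:
        a = self.audit
        lines = [
            "Clearance calibration",
            f"  converged: {self.converged}  (evaluations: {self.n_evals})",
            f"  production: {a.production_pct_per_h:.3f} %/h "
            f"(target {self.targets['production_pct_per_h']})",
            f"  clearance:  {a.clearance_pct_per_h:.3f} %/h "
            f"(target {self.targets['clearance_pct_per_h']})",
            f"  BBB share:  {a.bbb_share_pct:.2f} % "
            f"(target {self.targets['bbb_share_pct']})",
        ]
        for k, v in self.free_values().items():
            lines.append(f"  {k} = {v:.6g}")
        return "\n".join(lines)


def calibrate_to_constraints(params: ParameterSet | None = None,
                             constraints: dict[str, float] | None = None
                             ) -> ParameterSet:
    """Spec-shaped convenience wrapper returning the calibrated set."""
    return ClearanceCalibration(params, constraints).fit().params
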
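"""Coupled whole-body simulation over a simulated lifespan.

``LifespanModel`` assembles APP processing (in the brain ISF), the
two-isoform aggregation cascade (ISF), whole-body transport and the
age/state-dependent clearance machinery into one ODE system with a
single clock in hours (1 year of age = 8766 h). A run starts from the
homeostatic steady state at the starting age, with aggregates beyond
the dimer seeded at a trace level so that the secondary processes can
ignite, and integrates to the final age with

* enzymatic capacity Vmax declining with age,
* the microglial phenotype fraction fr responding to plaque burden
  (AD-prone subjects), and
* APOE and sex modifiers scaling microglial clearance.

State layout: 15 secretase-pathway species in the ISF, then per
isoform the monomer and dimer in all 11 compartments, the o/O/F
assemblies on the glymphatic route (ISF, PVS, lymph) and plaque in
ISF + PVS — 81 states in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from . import aggregation as agg
from .app import APP_SPECIES, build_app_network, generation_fluxes
from .clearance import (
    ClearanceParams,
    MicrogliaState,
    microglial_clearance_rate,
    microglia_density,
    enzymatic_degradation_rate,
    risk_profile_from_genotype,
    sex_clearance_factor,
)
from .imaging import SUVRConstants, abeta_load, suvr_from_load
from .params import HOURS_PER_YEAR, ParameterSet
from .transport import (
    COMPARTMENTS,
    GLYMPH_COMPARTMENTS,
    ISOFORMS,
    PLAQUE_COMPARTMENTS,
    BrainClearanceAudit,
    TransportParams,
    brain_clearance_audit,
    transport_matrix,
)

__all__ = [
    "SubjectProfile",
    "LifespanModel",
    "LifespanResult",
    "initialize_homeostasis",
    "run_lifespan",
    "plaque_onset_shift",
]

_SPECIES_COMPS = {
    "M": COMPARTMENTS,
    "D": COMPARTMENTS,
    "o": GLYMPH_COMPARTMENTS,
    "O": GLYMPH_COMPARTMENTS,
    "F": GLYMPH_COMPARTMENTS,
    "P": PLAQUE_COMPARTMENTS,
}
_APP_OTHER = [s for s in APP_SPECIES if s not in ("Ab40", "Ab42")]
_N_APP = len(_APP_OTHER)            # 15
_ISO_BLOCK = sum(len(c) for c in _SPECIES_COMPS.values())  # 33
N_STATES = _N_APP + 2 * _ISO_BLOCK  # 81


@dataclass(frozen=True)
class SubjectProfile:
    """Who is being simulated: sex, APOE genotype, age span, status."""

    sex: str = "male"
    apoe_genotype: str = "e3/e3"
    age_start: float = 20.0
    age_end: float = 100.0
    disease_status: str = "ad_prone"   # "healthy" | "ad_prone"
    alpha_override: float | None = None

    def __post_init__(self):
        if self.age_start >= self.age_end:
            raise ValueError("age_start must be below age_end")
        if self.disease_status not in ("healthy", "ad_prone"):
            raise ValueError("disease_status must be 'healthy' or 'ad_prone'")


def _state_index() -> dict[tuple[str, str], tuple[slice, tuple[str, ...]]]:
    layout = {}
    offset = _N_APP
    for iso in ISOFORMS:
        for sp, comps in _SPECIES_COMPS.items():
            layout[(iso, sp)] = (slice(offset, offset + len(comps)), comps)
            offset += len(comps)
    return layout


class LifespanModel:
    """Full coupled model for one subject profile.

    Parameters
    ----------
    profile : SubjectProfile
    params : ParameterSet, optional
        Defaults to the shipped calibrated set.
    qss_app : bool
        If True, hold the secretase network at its homeostatic state and
        inject the corresponding constant generation fluxes (a speed
        toggle; the full network is the default).
    """

    def __init__(self, profile: SubjectProfile, params: ParameterSet | None = None,
                 qss_app: bool = False):
        self.profile = profile
        self.params = params.copy() if params is not None else ParameterSet.defaults()
        self.qss_app = qss_app
        self.tp = TransportParams.from_parameter_set(self.params)
        self.cp = ClearanceParams.from_parameter_set(self.params)
        self.suvr_k = SUVRConstants.from_parameter_set(self.params)
        self.risk = risk_profile_from_genotype(
            profile.apoe_genotype, profile.sex, self.params)
        alpha = (profile.alpha_override if profile.alpha_override is not None
                 else self.risk.alpha)
        self._clear_factor = max(0.0, (1.0 - alpha)
                                 * sex_clearance_factor(profile.sex, self.params))
        self.alpha = alpha
        self.layout = _state_index()
        self._build()

    # -- assembly -----------------------------------------------------
    def _build(self) -> None:
        self._net, self._app_rhs = build_app_network(
            self.params, include_abeta_sinks=False)
        full_pos: dict[str, int] = {name: k for k, name in enumerate(_APP_OTHER)}
        full_pos["Ab40"] = self._pos("ab40", "M", "i")
        full_pos["Ab42"] = self._pos("ab42", "M", "i")
        self._app_map = np.array(
            [full_pos[name] for name in self._net.species_names], dtype=int)
        self._mats = {}
        for iso in ISOFORMS:
            for sp in _SPECIES_COMPS:
                comps, A = transport_matrix(self.tp, iso, sp, cp=self.cp,
                                            include_elimination=True)
                self._mats[(iso, sp)] = A
        self._agg_p = {iso: agg.AggregationParams.from_parameter_set(self.params, iso)
                       for iso in ISOFORMS}
        if (self._agg_p["ab42"].kfM < self._agg_p["ab40"].kfM
                or self._agg_p["ab42"].kfF < self._agg_p["ab40"].kfF):
            raise ValueError(
                "Abeta42 forward chain constants must not be below Abeta40's")
        sol = self.params.section("lifespan.solver")
        self.rtol = float(sol["rtol"])
        self.atol = float(sol["atol"])
        self.ss_tol = float(sol["ss_tol"])
        self.method = str(sol["method"])
        self.q0 = float(self.params.get("lifespan.quiescent_level"))
        self._qss_flux = None  # set lazily when qss_app is used

    def _pos(self, iso: str, sp: str, comp: str) -> int:
        sl, comps = _state_index()[(iso, sp)]
        return sl.start + comps.index(comp)

    # -- clearance machinery ------------------------------------------
    def kg_isf(self, plaque_burden: float) -> dict[str, float]:
        """Effective microglial clearance constants in the ISF (1/h).

        Healthy subjects keep a fully functional phenotype (fr = 1, so
        the mixture sits at Vi_high) with density 1 throughout; AD-prone
        subjects retain the homeostatic phenotype fraction fr0 (failed
        activation, the mixture sits near Vi_low) while the density
        mu declines with plaque burden (exhaustion). The APOE factor
        (1 - alpha) and the sex modifier scale the result.
        """
        if self.profile.disease_status == "healthy":
            mg = MicrogliaState(mu=self.cp.mu0, fr=1.0)
        else:
            mg = MicrogliaState(mu=microglia_density(plaque_burden, self.cp),
                                fr=self.cp.fr0)
        return {sp: self._clear_factor * microglial_clearance_rate(sp, mg, self.cp)
                for sp in ("o", "O", "F", "P")}

    # -- right-hand side ----------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        y = np.clip(np.asarray(y, dtype=float), 0.0, None)
        age = self.profile.age_start + t / HOURS_PER_YEAR
        dy = np.zeros(N_STATES)

        # secretase processing (ISF); Abeta entries alias the ISF monomers
        if self.qss_app and self._qss_flux is not None:
            dy[self._pos("ab40", "M", "i")] += self._qss_flux["ab40"]
            dy[self._pos("ab42", "M", "i")] += self._qss_flux["ab42"]
        else:
            app_vec = y[self._app_map]
            np.add.at(dy, self._app_map, self._app_rhs(t, app_vec))

        p_i40 = y[self._pos("ab40", "P", "i")]
        p_i42 = y[self._pos("ab42", "P", "i")]
        kg = self.kg_isf(p_i40 + p_i42)

        for iso in ISOFORMS:
            # linear whole-body transport + peripheral/macrophage losses
            for sp in _SPECIES_COMPS:
                sl, _ = self.layout[(iso, sp)]
                dy[sl] += self._mats[(iso, sp)] @ y[sl]
            # ISF reaction terms
            isf = np.array([y[self._pos(iso, sp, "i")]
                            for sp in ("M", "D", "o", "O", "F", "P")])
            p = self._agg_p[iso]
            d_isf = (agg.nucleation_polymerization_rate(isf, p)
                     + agg.secondary_nucleation_rate(isf, p)
                     + agg.plaque_growth_rate(isf, p)
                     + agg.fragmentation_rate(isf, p))
            d_isf[0] -= enzymatic_degradation_rate(isf[0], age, self.cp)
            for j, sp in enumerate(("o", "O", "F", "P"), start=2):
                d_isf[j] -= kg[sp] * isf[j]
            for j, sp in enumerate(("M", "D", "o", "O", "F", "P")):
                dy[self._pos(iso, sp, "i")] += d_isf[j]
        return dy

    # -- homeostatic initialisation -----------------------------------
    def initialize_homeostasis(self, y_guess: np.ndarray | None = None) -> np.ndarray:
        """Steady state at the starting age with quiescent aggregates.

        The species beyond the dimer are pinned at a trace level
        (``lifespan.quiescent_level``) and the remaining system is
        relaxed by long-horizon integration followed by a bounded
        root polish. Raises if the residual exceeds ``ss_tol``.
        A previous solution can be passed as ``y_guess`` to warm-start
        (used heavily by the calibration loop).
        """
        frozen = np.zeros(N_STATES, dtype=bool)
        for iso in ISOFORMS:
            for sp in ("o", "O", "F", "P"):
                sl, _ = self.layout[(iso, sp)]
                frozen[sl] = True
        y = np.full(N_STATES, 1.0) if y_guess is None else np.asarray(
            y_guess, dtype=float).copy()
        y[frozen] = self.q0

        def rhs_red(t, yr):
            full = y.copy()
            full[~frozen] = yr
            d = self.rhs(0.0, full)      # age pinned at age_start
            return d[~frozen]

        yr = np.clip(y[~frozen], 0.0, None)
        if float(np.max(np.abs(rhs_red(0.0, yr)))) > 1e-2:
            sol = solve_ivp(rhs_red, (0.0, 5e4), yr, method="LSODA",
                            rtol=1e-8, atol=1e-11)
            if sol.success:
                yr = np.clip(sol.y[:, -1], 0.0, None)
        res = least_squares(lambda x: rhs_red(0.0, x), yr, bounds=(0.0, np.inf),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        yr = res.x
        resid = float(np.max(np.abs(rhs_red(0.0, yr))))
        if resid > self.ss_tol:
            raise RuntimeError(
                f"homeostatic initialisation did not converge: residual "
                f"{resid:.3g} nM/h exceeds ss_tol {self.ss_tol:g}")
        y[~frozen] = yr
        if self.qss_app:
            state = self.app_state(y)
            flux = generation_fluxes(state, self.params)
            self._qss_flux = {"ab40": flux.J_Ab40, "ab42": flux.J_Ab42}
        return y

    # -- simulation ----------------------------------------------------
    def run(self, y0: np.ndarray | None = None) -> "LifespanResult":
        if y0 is None:
            y0 = self.initialize_homeostasis()
        prof = self.profile
        t_end = (prof.age_end - prof.age_start) * HOURS_PER_YEAR
        step_y = float(self.params.get("lifespan.output_every_years"))
        ages = np.arange(prof.age_start, prof.age_end + 1e-9, step_y)
        t_eval = (ages - prof.age_start) * HOURS_PER_YEAR
        sol = solve_ivp(self.rhs, (0.0, t_end), y0, method=self.method,
                        t_eval=t_eval, rtol=self.rtol, atol=self.atol)
        if not sol.success:
            raise RuntimeError(f"lifespan integration failed: {sol.message}")
        states = np.clip(sol.y.T, 0.0, None)
        return LifespanResult(model=self, ages=ages, states=states,
                              y0=np.asarray(y0, dtype=float))

    # -- helpers -------------------------------------------------------
    def app_state(self, y: np.ndarray) -> dict[str, float]:
        return {name: float(y[self._app_map[k]])
                for k, name in enumerate(self._net.species_names)}

    def conc_map(self, y: np.ndarray) -> dict[tuple[str, str], dict[str, float]]:
        out: dict[tuple[str, str], dict[str, float]] = {}
        for (iso, sp), (sl, comps) in self.layout.items():
            out[(iso, sp)] = dict(zip(comps, map(float, y[sl])))
        return out

    def audit(self, y: np.ndarray, age: float | None = None) -> BrainClearanceAudit:
        """Brain clearance audit at an arbitrary state vector."""
        age = self.profile.age_start if age is None else age
        flux = generation_fluxes(self.app_state(y), self.params)
        p_tot = (y[self._pos("ab40", "P", "i")] + y[self._pos("ab42", "P", "i")])
        return brain_clearance_audit(
            self.conc_map(y), self.tp, self.cp, age,
            {"ab40": flux.J_Ab40, "ab42": flux.J_Ab42},
            kg_isf=self.kg_isf(p_tot),
        )


@dataclass
class LifespanResult:
    """Trajectory of the coupled system indexed by age, with derived
    series and audit snapshots."""

    model: LifespanModel
    ages: np.ndarray
    states: np.ndarray
    y0: np.ndarray

    def series(self, iso: str, sp: str, comp: str = "i") -> np.ndarray:
        return self.states[:, self.model._pos(iso, sp, comp)]

    def soluble_isf(self, iso: str = "ab42") -> np.ndarray:
        """Soluble ISF pool: monomer + dimer (nM)."""
        return self.series(iso, "M") + self.series(iso, "D")

    def insoluble_isf(self, iso: str = "ab42") -> np.ndarray:
        """Insoluble ISF pool: o + O + F + P (nM, lumped units)."""
        return sum(self.series(iso, sp) for sp in ("o", "O", "F", "P"))

    def abeta_load_series(self, k: SUVRConstants | None = None,
                          isoform: str = "both") -> np.ndarray:
        k = k or self.model.suvr_k
        isos = ISOFORMS if isoform == "both" else (isoform,)
        agg_sum = {sp: sum(self.series(iso, sp) for iso in isos)
                   for sp in ("o", "O", "F", "P")}
        return (agg_sum["o"] + agg_sum["O"] + agg_sum["F"]
                + k.c4 * agg_sum["P"])

    def suvr_series(self, k: SUVRConstants | None = None,
                    isoform: str = "both") -> np.ndarray:
        k = k or self.model.suvr_k
        return suvr_from_load(self.abeta_load_series(k, isoform), k)

    def suvr_at(self, age: float, isoform: str = "both") -> float:
        return float(np.interp(age, self.ages, self.suvr_series(isoform=isoform)))

    def value_at(self, age: float, iso: str, sp: str, comp: str = "i") -> float:
        return float(np.interp(age, self.ages, self.series(iso, sp, comp)))

    def audit_at(self, age: float) -> BrainClearanceAudit:
        k = int(np.argmin(np.abs(self.ages - age)))
        return self.model.audit(self.states[k], age=float(self.ages[k]))

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for (iso, sp), (sl, comps) in self.model.layout.items():
            for j, comp in enumerate(comps):
                cols[f"{iso}_{sp}_{comp}"] = self.states[:, sl.start + j]
        for k, name in enumerate(_APP_OTHER):
            cols[f"app_{name}"] = self.states[:, k]
        df = pd.DataFrame(cols)
        df.insert(0, "age", self.ages)
        return df

    def summary(self) -> str:
        prof = self.model.profile
        suvr = self.suvr_series()
        lines = [
            "Lifespan simulation summary",
            f"  profile: {prof.sex}, APOE {prof.apoe_genotype} "
            f"(alpha={self.model.alpha:.3g}), {prof.disease_status}, "
            f"ages {prof.age_start:g}-{prof.age_end:g}",
            f"  parameter hash: {self.model.params.hash()[:12]}",
            f"  ISF Abeta42 soluble @ start/end: "
            f"{self.soluble_isf()[0]:.3g} / {self.soluble_isf()[-1]:.3g} nM",
            f"  ISF Abeta42 insoluble @ start/end: "
            f"{self.insoluble_isf()[0]:.3g} / {self.insoluble_isf()[-1]:.3g} nM",
            f"  SUVR @ 70 / end: {self.suvr_at(70.0):.3f} / {suvr[-1]:.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# module-level operations

def initialize_homeostasis(profile: SubjectProfile,
                           params: ParameterSet | None = None) -> np.ndarray:
    return LifespanModel(profile, params).initialize_homeostasis()


def run_lifespan(profile: SubjectProfile,
                 params: ParameterSet | None = None, **kw) -> LifespanResult:
    return LifespanModel(profile, params, **kw).run()


def plaque_onset_shift(result_a: LifespanResult, result_b: LifespanResult,
                       threshold: float, iso: str = "ab42") -> float:
    """Years by which run A reaches the plaque threshold before run B.

    Positive means A crossed earlier. Crossing ages are found by
    monotone linear interpolation of the ISF plaque trajectories;
    a run that never crosses raises, naming the offending profile.
    """

    def crossing_age(res: LifespanResult, label: str) -> float:
        p = res.series(iso, "P")
        above = np.nonzero(p >= threshold)[0]
        if above.size == 0 or above[0] == 0:
            if above.size == 0:
                raise ValueError(
                    f"profile {label} never reaches plaque threshold {threshold:g} nM")
            return float(res.ages[0])
        k = above[0]
        return float(np.interp(threshold, p[k - 1:k + 1], res.ages[k - 1:k + 1]))

    age_a = crossing_age(result_a, "A")
    age_b = crossing_age(result_b, "B")
    return age_b - age_a
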
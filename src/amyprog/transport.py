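"""Whole-body compartmental transport of soluble Abeta species.

Eleven compartments: six CNS (brain vascular ``bv``, BBB endothelium
``bb``, BCSFB epithelium ``cb``, interstitial fluid ``i``, CSF ``c``,
perivascular space ``pv``) and five systemic (plasma ``pl``, lymph
``L``, tissue vascular ``tv``, tissue barrier ``tvb``, tissue
interstitium ``ti``). Monomer and dimer circulate everywhere; the
larger soluble assemblies (o, O, F) move only along the glymphatic
route ISF -> PVS -> lymph, throttled by per-species reflection
coefficients; plaque is immobile apart from macrophage clearance in
the PVS.

Fluid permeation across a barrier carries ``Q * (1 - sigma) * C``
(amount/h); sigma = 1 means impermeable. Transporters are lumped
convective rates: RAGE influx from brain vascular to ISF (scaled by
the unbound plasma fraction fu_p) and LRP1/P-gp efflux from ISF to
brain vascular. All fluxes are linear, so each species' transport is
a constant matrix acting on its concentration vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clearance import ClearanceParams
from .params import ParameterSet

__all__ = [
    "COMPARTMENTS",
    "CNS_COMPARTMENTS",
    "BRAIN_POOL",
    "PERIPHERAL",
    "TransportParams",
    "convective_flux",
    "transporter_flux",
    "transport_matrix",
    "build_transport_rhs",
    "brain_clearance_audit",
    "BrainClearanceAudit",
]

COMPARTMENTS = ("pl", "bv", "bb", "cb", "i", "c", "pv", "L", "tv", "tvb", "ti")
CNS_COMPARTMENTS = ("bv", "bb", "cb", "i", "c", "pv")
#: compartments whose content counts as "brain Abeta" in the audit
BRAIN_POOL = ("i", "c", "pv")
#: compartments where the constant peripheral degradation applies
PERIPHERAL = ("pl", "L", "tv", "tvb", "ti")
#: compartments whose content is plasma (unbound fraction applies at source)
PLASMA_SIDE = ("pl", "bv", "tv")

ISOFORMS = ("ab40", "ab42")
SOLUBLE_FULL = ("M", "D")            # transported through all 11 compartments
GLYMPHATIC_ONLY = ("o", "O", "F")    # i -> pv -> L route only
GLYMPH_COMPARTMENTS = ("i", "pv", "L")
PLAQUE_COMPARTMENTS = ("i", "pv")


class TransportConfigError(ValueError):
    pass


def convective_flux(C_src: float, Q: float, sigma: float) -> float:
    """Amount flux Q*(1-sigma)*C (pmol/h for nM and mL/h inputs)."""
    if not 0.0 <= sigma <= 1.0:
        raise TransportConfigError(f"reflection coefficient must lie in [0,1], got {sigma}")
    if Q < 0:
        raise TransportConfigError("flow must be >= 0")
    return Q * (1.0 - sigma) * C_src

def transporter_flux(C: float, F: float, fu: float = 1.0) -> float:
    """Lumped carrier flux F*fu*C; fu < 1 only where the source is plasma."""
    if F < 0:
        raise TransportConfigError("transporter rate must be >= 0")
    if not 0.0 < fu <= 1.0:
        raise TransportConfigError(f"unbound fraction must lie in (0,1], got {fu}")
    return F * fu * C


@dataclass(frozen=True)
class TransportParams:
    volumes: dict[str, float]
    flows: dict[str, float]
    sigma_bv_i: float
    sigma_bv_c: float
    sigma_tv: float
    sigma_c_pl: float
    sigma_i_pv: dict[str, float]
    sigma_pv_L: dict[str, float]
    F_in: dict[str, float]        # per isoform, RAGE
    F_out: dict[str, float]       # per isoform, LRP1 + P-gp
    F_out_D: dict[str, float]
    fu_p: float

    def __post_init__(self):
        missing = set(COMPARTMENTS) - set(self.volumes)
        if missing:
            raise TransportConfigError(f"volumes missing for compartments {sorted(missing)}")
        if any(v <= 0 for v in self.volumes.values()):
            raise TransportConfigError("compartment volumes must be positive")
        for name, table in (("i_pv", self.sigma_i_pv), ("pv_L", self.sigma_pv_L)):
            for sp, s in table.items():
                if not 0.0 <= s <= 1.0:
                    raise TransportConfigError(
                        f"sigma_{name}[{sp}] = {s} outside [0, 1]")
        if not 0.0 < self.fu_p <= 1.0:
            raise TransportConfigError("fu_p must lie in (0, 1]")

    @classmethod
    def from_parameter_set(cls, params: ParameterSet) -> "TransportParams":
        t = params.section("transport")
        sig = t["sigma"]
        return cls(
            volumes={k: float(v) for k, v in t["volumes"].items()},
            flows={k: float(v) for k, v in t["flows"].items()},
            sigma_bv_i=float(sig["bv_i"]), sigma_bv_c=float(sig["bv_c"]),
            sigma_tv=float(sig["tv"]), sigma_c_pl=float(sig["c_pl"]),
            sigma_i_pv={k: float(v) for k, v in sig["i_pv"].items()},
            sigma_pv_L={k: float(v) for k, v in sig["pv_L"].items()},
            F_in={k: float(v) for k, v in t["transporters"]["F_in"].items()},
            F_out={k: float(v) for k, v in t["transporters"]["F_out"].items()},
            F_out_D={k: float(v) for k, v in t["transporters"]["F_out_D"].items()},
            fu_p=float(t["fu_p"]),
        )


def _soluble_edges(tp: TransportParams, isoform: str, species: str):
    """(src, dst, rate mL/h) edges for a fully circulating species."""
    Q = tp.flows
    fu = tp.fu_p
    if species == "M":
        F_in, F_out = tp.F_in[isoform], tp.F_out[isoform]
    elif species == "D":
        F_in, F_out = 0.0, tp.F_out_D[isoform]
    else:  # pragma: no cover - guarded by callers
        raise TransportConfigError(f"{species!r} does not circulate systemically")
    edges = [
        ("pl", "bv", Q["Q_pl_bv"]),
        ("bv", "pl", Q["Q_pl_bv"]),
        # BBB fluid path bv -> bb -> i (fu on the plasma-side step)
        ("bv", "bb", Q["Q_Bi"] * (1.0 - tp.sigma_bv_i) * fu),
        ("bb", "i", Q["Q_Bi"] * (1.0 - tp.sigma_bv_i)),
        # BCSFB fluid path bv -> cb -> c
        ("bv", "cb", Q["Q_Bc"] * (1.0 - tp.sigma_bv_c) * fu),
        ("cb", "c", Q["Q_Bc"] * (1.0 - tp.sigma_bv_c)),
        # transporters across the BBB
        ("bv", "i", F_in * fu),
        ("i", "bv", F_out),
        # free ISF/CSF exchange
        ("i", "c", Q["Q_ic"]),
        ("c", "i", Q["Q_ic"]),
        # glymphatic route, per-species reflection
        ("i", "pv", Q["Q_ipv"] * (1.0 - tp.sigma_i_pv[species])),
        ("pv", "L", Q["Q_pvL"] * (1.0 - tp.sigma_pv_L[species])),
        # CSF absorption
        ("c", "pl", Q["Q_cabs"] * (1.0 - tp.sigma_c_pl)),
        # systemic path
        ("pl", "tv", Q["Q_pl_tv"]),
        ("tv", "pl", Q["Q_pl_tv"]),
        ("tv", "tvb", Q["Q_tv_tvb"] * (1.0 - tp.sigma_tv) * fu),
        ("tvb", "ti", Q["Q_tvb_ti"] * (1.0 - tp.sigma_tv)),
        ("ti", "L", Q["Q_ti_L"]),
        ("L", "pl", Q["Q_L_pl"]),
    ]
    return edges


def _check_connected(edges, comps) -> None:
    adj: dict[str, set[str]] = {c: set() for c in comps}
    for s, d, q in edges:
        if q > 0:
            adj[s].add(d)
            adj[d].add(s)
    seen = {comps[0]}
    stack = [comps[0]]
    while stack:
        for nxt in adj[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    if seen != set(comps):
        raise TransportConfigError(
            f"compartment graph disconnected: unreachable {sorted(set(comps) - seen)}")


def transport_matrix(
    tp: TransportParams,
    isoform: str,
    species: str,
    cp: ClearanceParams | None = None,
    include_elimination: bool = True,
    check_connectivity: bool = True,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Constant matrix A with dC/dt = A @ C for one species' transport.

    Off-diagonals carry inter-compartment flows divided by the receiving
    volume; the diagonal carries the matching losses plus, when
    ``include_elimination`` and clearance parameters are given, the
    peripheral degradation (pl, L, tv, tvb, ti) and the PVS macrophage
    clearance of insoluble species.
    """
    if species in SOLUBLE_FULL:
        comps = COMPARTMENTS
        edges = _soluble_edges(tp, isoform, species)
    elif species in GLYMPHATIC_ONLY:
        comps = GLYMPH_COMPARTMENTS
        edges = [
            ("i", "pv", tp.flows["Q_ipv"] * (1.0 - tp.sigma_i_pv[species])),
            ("pv", "L", tp.flows["Q_pvL"] * (1.0 - tp.sigma_pv_L[species])),
        ]
    elif species == "P":
        comps = PLAQUE_COMPARTMENTS
        edges = []
    else:
        raise TransportConfigError(f"unknown species kind {species!r}")
    if check_connectivity and species in SOLUBLE_FULL:
        _check_connected(edges, comps)
    idx = {c: k for k, c in enumerate(comps)}
    n = len(comps)
    A = np.zeros((n, n))
    for src, dst, q in edges:
        A[idx[dst], idx[src]] += q / tp.volumes[dst]
        A[idx[src], idx[src]] -= q / tp.volumes[src]
    if include_elimination and cp is not None:
        for c in PERIPHERAL:
            if c in idx:
                fu = tp.fu_p if c in PLASMA_SIDE else 1.0
                A[idx[c], idx[c]] -= cp.kperiph * fu
        if species in (*GLYMPHATIC_ONLY, "P") and "pv" in idx:
            A[idx["pv"], idx["pv"]] -= cp.k_mac_pv
    return tuple(comps), A


def build_transport_rhs(
    tp: TransportParams, cp: ClearanceParams | None = None,
    include_elimination: bool = True,
):
    """Derivative contributions for a whole-body state.

    Returns ``(layout, rhs)`` where layout maps ``(isoform, species)``
    to its compartment tuple and ``rhs(state)`` maps a dict of
    concentration vectors (one per (isoform, species)) to derivative
    vectors. Reaction terms (aggregation, APP processing, enzymatic and
    microglial clearance in the ISF) are not included here.
    """
    mats: dict[tuple[str, str], tuple[tuple[str, ...], np.ndarray]] = {}
    for iso in ISOFORMS:
        for sp in (*SOLUBLE_FULL, *GLYMPHATIC_ONLY, "P"):
            mats[(iso, sp)] = transport_matrix(
                tp, iso, sp, cp=cp, include_elimination=include_elimination)
    layout = {key: comps for key, (comps, _) in mats.items()}

    def rhs(state: dict[tuple[str, str], np.ndarray]) -> dict[tuple[str, str], np.ndarray]:
        return {key: mats[key][1] @ np.asarray(state[key], dtype=float)
                for key in mats}

    rhs.matrices = {k: A for k, (_, A) in mats.items()}  # type: ignore[attr-defined]
    return layout, rhs


# ---------------------------------------------------------------------------
# steady-state audit

@dataclass
class BrainClearanceAudit:
    """Partition of brain Abeta turnover at a (near-)steady state.

    Fluxes are amounts per hour (pmol/h with nM and mL inputs); the
    fractional rates are percent of the brain pool per hour.
    """

    pool: float
    production: float
    influx: float
    bbb_efflux: float
    glymphatic: float
    csf_absorption: float
    enzymatic: float
    microglial: float
    extras: dict = field(default_factory=dict)

    @property
    def total_clearance(self) -> float:
        return (self.bbb_efflux + self.glymphatic + self.csf_absorption
                + self.enzymatic + self.microglial)

    @property
    def production_pct_per_h(self) -> float:
        return 100.0 * self.production / self.pool

    @property
    def clearance_pct_per_h(self) -> float:
        return 100.0 * self.total_clearance / self.pool

    @property
    def bbb_share_pct(self) -> float:
        return 100.0 * self.bbb_efflux / self.total_clearance

    def partition(self) -> dict[str, float]:
        t = self.total_clearance
        return {
            "bbb": self.bbb_efflux / t,
            "glymphatic": self.glymphatic / t,
            "csf_absorption": self.csf_absorption / t,
            "enzymatic": self.enzymatic / t,
            "microglial": self.microglial / t,
        }

    def to_dict(self) -> dict:
        return {
            "pool_pmol": self.pool,
            "production_pmol_per_h": self.production,
            "influx_pmol_per_h": self.influx,
            "clearance_pmol_per_h": self.total_clearance,
            "production_pct_per_h": self.production_pct_per_h,
            "clearance_pct_per_h": self.clearance_pct_per_h,
            "bbb_share_pct": self.bbb_share_pct,
            "partition": self.partition(),
            **self.extras,
        }


def brain_clearance_audit(
    conc: dict[tuple[str, str], dict[str, float]],
    tp: TransportParams,
    cp: ClearanceParams,
    age: float,
    production_nM_per_h: dict[str, float],
    kg_isf: dict[str, float] | None = None,
) -> BrainClearanceAudit:
    """Audit brain Abeta turnover at the supplied concentrations.

    ``conc[(isoform, species)][compartment]`` are concentrations in nM;
    ``production_nM_per_h`` maps isoform to its monomer generation rate
    in the ISF; ``kg_isf`` gives the effective microglial clearance
    constants for o, O, F, P in the ISF (defaults to zero, the
    homeostatic trace-aggregate case).
    """
    from .clearance import enzymatic_degradation_rate  # local: avoid cycle at import

    V = tp.volumes
    kg_isf = kg_isf or {}
    pool = 0.0
    for (iso, sp), by_comp in conc.items():
        for comp, c in by_comp.items():
            if comp in BRAIN_POOL:
                pool += c * V[comp]
    if pool <= 0:
        raise ValueError("brain Abeta pool is zero; audit undefined")

    production = sum(production_nM_per_h.values()) * V["i"]
    bbb = glym = csf = enz = micro = influx = 0.0
    for iso in ISOFORMS:
        cM = conc[(iso, "M")]
        bbb += transporter_flux(cM["i"], tp.F_out[iso])
        if (iso, "D") in conc:
            bbb += transporter_flux(conc[(iso, "D")]["i"], tp.F_out_D[iso])
        enz += enzymatic_degradation_rate(cM["i"], age, cp) * V["i"]
        influx += transporter_flux(cM["bv"], tp.F_in[iso], tp.fu_p)
        for sp in ("M", "D", "o", "O", "F"):
            if (iso, sp) in conc and "pv" in conc[(iso, sp)]:
                glym += convective_flux(
                    conc[(iso, sp)]["pv"], tp.flows["Q_pvL"], tp.sigma_pv_L[sp])
        for sp in ("M", "D"):
            if (iso, sp) in conc:
                csf += convective_flux(
                    conc[(iso, sp)]["c"], tp.flows["Q_cabs"], tp.sigma_c_pl)
                influx += convective_flux(
                    conc[(iso, sp)]["bb"], tp.flows["Q_Bi"], tp.sigma_bv_i)
                influx += convective_flux(
                    conc[(iso, sp)]["cb"], tp.flows["Q_Bc"], tp.sigma_bv_c)
        for sp in ("o", "O", "F", "P"):
            if (iso, sp) in conc:
                micro += kg_isf.get(sp, 0.0) * conc[(iso, sp)]["i"] * V["i"]
                if "pv" in conc[(iso, sp)]:
                    micro += cp.k_mac_pv * conc[(iso, sp)]["pv"] * V["pv"]
    return BrainClearanceAudit(
        pool=pool, production=production, influx=influx, bbb_efflux=bbb,
        glymphatic=glym, csf_absorption=csf, enzymatic=enz, microglial=micro,
    )
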
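"""APP secretase processing and homeostatic Abeta generation.

The amyloid precursor protein (APP) is processed by two competing
pathways. In the non-amyloidogenic branch alpha-secretase (aS) sheds
sAPPalpha leaving the C83 stub, which gamma-secretase (gS) cleaves to
the inert p3 peptide. In the amyloidogenic branch beta-secretase (bS)
sheds sAPPbeta leaving C99, whose gamma cleavage releases the Abeta40
or Abeta42 monomer. Enzymes act catalytically: each secretase consumed
by complex formation is returned by the cleavage step. The 22-reaction
table below is instantiated through the generic reaction engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet
from .reactions import (
    ConfigurationError,
    ReactionNetwork,
    build_rhs,
    parse_reactions,
    steady_state,
)

__all__ = [
    "APP_SPECIES",
    "GenerationFlux",
    "app_reaction_table",
    "build_app_network",
    "app_homeostasis",
]

#: every species of the processing network, in declaration order
APP_SPECIES = [
    "APP", "bS", "gS", "aS", "saS", "sbS",
    "APP:aS", "APP:bS", "C83", "C99", "C83:gS", "C99:gS",
    "sAPPa", "sAPPb", "p3", "Ab40", "Ab42",
]

_TABLE = """
# generation
0 <-> APP    ; kf=app_processing.ksyn_APP kb=app_processing.kdeg_APP
0 <-> bS     ; kf=app_processing.ksyn_bS  kb=app_processing.kdeg_bS
0 <-> gS     ; kf=app_processing.ksyn_gS  kb=app_processing.kdeg_gS
0 <-> aS     ; kf=app_processing.ksyn_aS  kb=app_processing.kdeg_aS
# non-amyloidogenic pathway
aS -> saS                 ; kf=app_processing.kshed_aS
APP + aS <-> APP:aS       ; kf=app_processing.kon_aS kb=app_processing.koff_aS
APP:aS -> C83 + aS + sAPPa ; kf=app_processing.kcat_aS
C83 + gS <-> C83:gS       ; kf=app_processing.kon_g83 kb=app_processing.koff_g83
C83:gS -> p3 + gS         ; kf=app_processing.kcat_g83
saS -> 0                  ; kf=app_processing.kdeg_saS
C83 -> 0                  ; kf=app_processing.kdeg_C83
sAPPa -> 0                ; kf=app_processing.kdeg_sAPPa
p3 -> 0                   ; kf=app_processing.kdeg_p3
# amyloidogenic pathway
bS -> sbS                 ; kf=app_processing.kshed_bS
APP + bS <-> APP:bS       ; kf=app_processing.kon_bS kb=app_processing.koff_bS
APP:bS -> C99 + bS + sAPPb ; kf=app_processing.kcat_bS
C99 + gS <-> C99:gS       ; kf=app_processing.kon_g99 kb=app_processing.koff_g99
C99:gS -> Ab42 + gS       ; kf=__kcat_g99_42
C99:gS -> Ab40 + gS       ; kf=__kcat_g99_40
sbS -> 0                  ; kf=app_processing.kdeg_sbS
C99 -> 0                  ; kf=app_processing.kdeg_C99
sAPPb -> 0                ; kf=app_processing.kdeg_sAPPb
"""

_ABETA_SINKS = """
Ab42 -> 0                 ; kf=app_processing.kdeg_Ab42
Ab40 -> 0                 ; kf=app_processing.kdeg_Ab40
"""


@dataclass(frozen=True)
class GenerationFlux:
    """Cleavage fluxes (nM/h) at a given network state."""

    J_Ab40: float
    J_Ab42: float
    J_p3: float
    J_sAPPa: float
    J_sAPPb: float

    @property
    def J_total(self) -> float:
        return self.J_Ab40 + self.J_Ab42


def app_reaction_table(include_abeta_sinks: bool = True) -> str:
    """The processing table as parser input (Abeta sinks optional).

    In the coupled whole-body model the monomer sinks are replaced by
    the aggregation, clearance and transport modules, so the table is
    built without them there.
    """
    return _TABLE + (_ABETA_SINKS if include_abeta_sinks else "")


def _flat_rates(params: ParameterSet) -> dict[str, float]:
    """Resolve the gamma-cleavage branching into the two printed reactions."""
    kcat = float(params.get("app_processing.kcat_g99"))
    r42 = float(params.get("app_processing.r42"))
    if not 0.0 <= r42 <= 1.0:
        raise ConfigurationError(f"r42 must lie in [0, 1], got {r42}")
    return {"__kcat_g99_42": kcat * r42, "__kcat_g99_40": kcat * (1.0 - r42)}


class _RateView:
    """Parameter lookup that also serves the derived branching constants."""

    def __init__(self, params: ParameterSet, extra: dict[str, float]):
        self._params, self._extra = params, extra

    def __getitem__(self, key: str) -> float:
        if key in self._extra:
            return self._extra[key]
        return self._params.get(key)


def build_app_network(
    params: ParameterSet, include_abeta_sinks: bool = True
) -> tuple[ReactionNetwork, object]:
    """Instantiate the processing table; returns ``(network, rhs)``."""
    net = parse_reactions(app_reaction_table(include_abeta_sinks))
    rhs = build_rhs(net, _RateView(params, _flat_rates(params)))
    return net, rhs


def generation_fluxes(state: dict[str, float], params: ParameterSet) -> GenerationFlux:
    """Instantaneous cleavage fluxes at a given concentration map."""
    branch = _flat_rates(params)
    return GenerationFlux(
        J_Ab40=branch["__kcat_g99_40"] * state["C99:gS"],
        J_Ab42=branch["__kcat_g99_42"] * state["C99:gS"],
        J_p3=params.get("app_processing.kcat_g83") * state["C83:gS"],
        J_sAPPa=params.get("app_processing.kcat_aS") * state["APP:aS"],
        J_sAPPb=params.get("app_processing.kcat_bS") * state["APP:bS"],
    )


def app_homeostasis(
    params: ParameterSet, ss_tol: float = 1e-9
) -> tuple[dict[str, float], GenerationFlux]:
    """Steady state of the standalone processing network and its fluxes.

    The flux ratio J_Ab42 / (J_Ab40 + J_Ab42) equals the configured
    gamma-cleavage branching ratio exactly, since both reactions share
    the C99:gS pool.
    """
    net, rhs = build_app_network(params, include_abeta_sinks=True)
    guess = np.full(len(net.species), 1.0)
    y = steady_state(rhs, guess, ss_tol=ss_tol)
    state = dict(zip(net.species_names, y))
    return state, generation_fluxes(state, params)
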
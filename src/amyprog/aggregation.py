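"""Six-species reduced-order Abeta aggregation cascade.

Each isoform (Abeta40, Abeta42) aggregates independently through a
lumped ladder: monomer (M), dimer (D), small oligomer (o), large
oligomer (O), protofibril (F) and plaque (P). The reversible chain

    2M <-> D,  M + D <-> o,  M + o <-> O,  M + O <-> F,  M + F <-> P

is augmented with plaque-catalysed secondary nucleation (two monomers
nucleating on plaque surface into a dimer), saturating monomer-driven
plaque growth, and fragmentation of protofibrils and plaques. The
higher-order species are assemblies with composite rate constants, so
strict monomer-equivalent conservation is asserted only for the
isolated M<->D subsystem; nominal multiplicities serve mass reporting
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "SPECIES",
    "AggregationParams",
    "nucleation_polymerization_rate",
    "secondary_nucleation_rate",
    "plaque_growth_rate",
    "fragmentation_rate",
    "aggregation_rhs",
    "mass_concentrations",
]

#: state ordering used by every rate function
SPECIES = ("M", "D", "o", "O", "F", "P")
_M, _D, _o, _O, _F, _P = range(6)


class AggregationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AggregationParams:
    """Rate constants for one isoform (units: 1/(nM h) forward chain,
    1/h backward, 1/(nM^2 h) secondary nucleation, nM capacity)."""

    kfM: float
    kbM: float
    kfD: float
    kbD: float
    kfo: float
    kbo: float
    kfO: float
    kbO: float
    kfF: float
    kbF: float
    k2n: float
    kPg: float
    Pmax: float
    kfragF: float
    kfragP: float
    frag_split_o: float = 0.5
    frag_split_O: float = 0.5
    # nominal monomer multiplicities, reporting only
    n_D: float = 2.0
    n_o: float = 8.0
    n_O: float = 24.0
    n_F: float = 100.0
    n_P: float = 1e4

    def __post_init__(self):
        for name in ("kfM", "kbM", "kfD", "kbD", "kfo", "kbo", "kfO", "kbO",
                     "kfF", "kbF", "k2n", "kPg", "kfragF", "kfragP"):
            if getattr(self, name) < 0:
                raise AggregationConfigError(f"{name} must be >= 0")
        if self.Pmax <= 0:
            raise AggregationConfigError("Pmax must be positive")
        s = self.frag_split_o + self.frag_split_O
        if not (0 <= self.frag_split_o <= 1 and 0 <= self.frag_split_O <= 1
                and abs(s - 1.0) < 1e-12):
            raise AggregationConfigError(
                f"fragmentation split fractions must lie in [0,1] and sum to 1, got {s}"
            )

    @classmethod
    def from_parameter_set(cls, params: ParameterSet, isoform: str) -> "AggregationParams":
        iso = params.section(f"aggregation.{isoform}")
        shared = params.section("aggregation.shared")
        return cls(
            **{k: float(iso[k]) for k in (
                "kfM", "kbM", "kfD", "kbD", "kfo", "kbo", "kfO", "kbO",
                "kfF", "kbF", "k2n", "kPg", "kfragF", "kfragP")},
            Pmax=float(shared["Pmax"]),
            frag_split_o=float(shared["frag_split_o"]),
            frag_split_O=float(shared["frag_split_O"]),
            n_D=float(shared["n_D"]), n_o=float(shared["n_o"]),
            n_O=float(shared["n_O"]), n_F=float(shared["n_F"]),
            n_P=float(shared["n_P"]),
        )


def _check_state(state) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise ValueError("aggregation state must have 6 entries (M, D, o, O, F, P)")
    if np.any(y < 0):
        raise ValueError(f"negative concentration in aggregation state: {y.min():g}")
    return y


def nucleation_polymerization_rate(state, p: AggregationParams) -> np.ndarray:
    """Reversible-chain contributions, one entry per species.

    The monomer entry is
    ``-2 kfM M^2 + 2 kbM D - kfD M D + kbD o - kfo M o + kbo O
    - kfO M O + kbO F - kfF M F + kbF P``;
    every chain step appears once with + and once with - in the two
    species it couples.
    """
    M, D, o, O, F, P = _check_state(state)
    f1 = p.kfM * M * M - p.kbM * D       # 2M <-> D (per-event)
    f2 = p.kfD * M * D - p.kbD * o       # M + D <-> o
    f3 = p.kfo * M * o - p.kbo * O       # M + o <-> O
    f4 = p.kfO * M * O - p.kbO * F       # M + O <-> F
    f5 = p.kfF * M * F - p.kbF * P       # M + F <-> P
    out = np.zeros(6)
    out[_M] = -2.0 * f1 - f2 - f3 - f4 - f5
    out[_D] = f1 - f2
    out[_o] = f2 - f3
    out[_O] = f3 - f4
    out[_F] = f4 - f5
    out[_P] = f5
    return out


def secondary_nucleation_rate(state, p: AggregationParams) -> np.ndarray:
    """Plaque-surface-catalysed nucleation: 2M --P--> D at k2n*M^2*P."""
    M, D, o, O, F, P = _check_state(state)
    r = p.k2n * M * M * P
    out = np.zeros(6)
    out[_M] = -2.0 * r
    out[_D] = r
    return out


def plaque_growth_rate(state, p: AggregationParams) -> np.ndarray:
    """Monomer addition to oligomers and conversion toward plaque.

    Rate kPg*M*(o+O)*sat(P) with sat(P) = max(0, 1 - P/Pmax); the
    consumed oligomer mass (and the added monomer) moves to P.
    """
    M, D, o, O, F, P = _check_state(state)
    sat = max(0.0, 1.0 - P / p.Pmax)
    r_o = p.kPg * M * o * sat
    r_O = p.kPg * M * O * sat
    out = np.zeros(6)
    out[_M] = -(r_o + r_O)
    out[_o] = -r_o
    out[_O] = -r_O
    out[_P] = r_o + r_O
    return out


def fragmentation_rate(state, p: AggregationParams) -> np.ndarray:
    """Protofibril breakup into o/O (configurable split) and plaque
    shedding back to protofibrils."""
    M, D, o, O, F, P = _check_state(state)
    rF = p.kfragF * F
    rP = p.kfragP * P
    out = np.zeros(6)
    out[_o] = p.frag_split_o * rF
    out[_O] = p.frag_split_O * rF
    out[_F] = -rF + rP
    out[_P] = -rP
    return out


def aggregation_rhs(state, p: AggregationParams, clearance_hook=None, efflux_hook=None):
    """Full cascade derivative for one isoform.

    ``clearance_hook(state) -> (Rcl_IDE, kg)`` supplies the enzymatic
    monomer degradation rate (nM/h) and the per-species first-order
    microglial clearance constants (1/h, entries for o, O, F, P used);
    ``efflux_hook(state) -> J`` supplies per-species net transport
    fluxes (nM/h, positive into the compartment). Hooks default to
    zero, reducing the system to the closed cascade.
    """
    y = _check_state(state)
    dy = (nucleation_polymerization_rate(y, p)
          + secondary_nucleation_rate(y, p)
          + plaque_growth_rate(y, p)
          + fragmentation_rate(y, p))
    if clearance_hook is not None:
        rcl, kg = clearance_hook(y)
        kg = np.asarray(kg, dtype=float)
        if not (np.isfinite(rcl) and np.all(np.isfinite(kg))):
            raise RuntimeError("clearance hook returned a non-finite value")
        dy[_M] -= rcl
        dy[2:] -= kg[2:] * y[2:]
    if efflux_hook is not None:
        J = np.asarray(efflux_hook(y), dtype=float)
        if not np.all(np.isfinite(J)):
            raise RuntimeError("efflux hook returned a non-finite value")
        dy += J
    return dy


def mass_concentrations(state, p: AggregationParams) -> dict[str, float]:
    """Monomer-equivalent (reporting) concentrations via the nominal
    multiplicities."""
    M, D, o, O, F, P = _check_state(state)
    return {
        "M": M, "D": p.n_D * D, "o": p.n_o * o,
        "O": p.n_O * O, "F": p.n_F * F, "P": p.n_P * P,
    }
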
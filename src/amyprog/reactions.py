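"""Declarative reaction tables compiled to mass-action ODE systems.

The engine turns a plain-text reaction table (one reaction per line,
``A + B <-> A:B ; kf=kon kb=koff``) into a vectorised right-hand side
for :func:`scipy.integrate.solve_ivp`. Both the unicode arrows
``↔``/``→`` and ASCII ``<->``/``->`` are accepted; ``0`` denotes an
empty side, so ``0 <-> X`` is zero-order synthesis paired with
first-order elimination and ``X -> 0`` is first-order elimination.

Rate constants may be given inline as numbers or as names resolved
against a parameter mapping at compile time.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .params import ParameterSet

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "ReactionParseError",
    "ConfigurationError",
    "parse_reactions",
    "build_rhs",
    "simulate",
    "steady_state",
]


class ReactionParseError(ValueError):
    """A reaction line did not match the grammar."""


class ConfigurationError(ValueError):
    """A rate constant is missing or invalid."""


class IntegrationError(RuntimeError):
    """Stiff integration failed; carries the last successful time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class Species:
    """A chemical species. Complexes like ``APP:bS`` are ordinary species."""

    name: str
    compartment: str | None = None
    role: str = ""


@dataclass
class Reaction:
    """One reaction with integer stoichiometry and mass-action kinetics.

    ``kf``/``kb`` may be floats or parameter names; ``kb`` is meaningful
    only for reversible reactions. ``modifier`` optionally replaces the
    mass-action forward flux with a custom callable ``flux(conc_map)``.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    reversible: bool
    kf: float | str
    kb: float | str | None = None
    modifier: Callable[[Mapping[str, float]], float] | None = None
    label: str = ""

    def __post_init__(self):
        for side in (self.reactants, self.products):
            for name, coeff in side:
                if coeff < 1:
                    raise ConfigurationError(
                        f"stoichiometric coefficient of {name!r} must be >= 1"
                    )
        if self.reversible and self.kb is None:
            raise ConfigurationError(f"reversible reaction {self.label!r} lacks kb")


@dataclass
class ReactionNetwork:
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        names = [s.name for s in self.species]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            # identical duplicate declarations collapse; conflicting ones error
            seen: dict[str, Species] = {}
            for s in self.species:
                if s.name in seen and seen[s.name] != s:
                    raise ConfigurationError(
                        f"species {s.name!r} declared twice with conflicting annotation"
                    )
                seen[s.name] = s
            self.species = list(seen.values())
        declared = {s.name for s in self.species}
        for rxn in self.reactions:
            for name, _ in (*rxn.reactants, *rxn.products):
                if name not in declared:
                    raise ConfigurationError(
                        f"reaction {rxn.label!r} references undeclared species {name!r}"
                    )

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def stoichiometry_matrix(self) -> np.ndarray:
        """(n_species x n_reactions) net stoichiometry matrix."""
        S = np.zeros((len(self.species), len(self.reactions)))
        idx = {n: i for i, n in enumerate(self.species_names)}
        for j, rxn in enumerate(self.reactions):
            for name, coeff in rxn.reactants:
                S[idx[name], j] -= coeff
            for name, coeff in rxn.products:
                S[idx[name], j] += coeff
        return S


@dataclass
class Trajectory:
    """Concentrations (nM) sampled on a strictly increasing time grid (h)."""

    times: np.ndarray
    states: np.ndarray
    species_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.size:
            raise ValueError("states must have one row per time point")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species_names.index(name)]

    def final(self) -> dict[str, float]:
        return dict(zip(self.species_names, self.states[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species_names)
        df.insert(0, "time_h", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# parsing

_ARROWS = [("↔", True), ("<->", True), ("→", False), ("->", False)]
_TERM_RE = re.compile(r"^\s*(?:(\d+)\s*\*?\s*)?(\S+)\s*$")


def _parse_side(side: str, lineno: int) -> tuple[tuple[str, int], ...]:
    side = side.strip()
    if side == "0" or side == "":
        return ()
    terms = []
    for raw in side.split("+"):
        m = _TERM_RE.match(raw)
        if not m or m.group(2) == "0":
            raise ReactionParseError(f"line {lineno}: cannot parse term {raw!r}")
        coeff = int(m.group(1)) if m.group(1) else 1
        terms.append((m.group(2), coeff))
    return tuple(terms)


def _parse_rates(tail: str, lineno: int) -> dict[str, float | str]:
    out: dict[str, float | str] = {}
    for token in tail.replace(",", " ").split():
        if "=" not in token:
            raise ReactionParseError(f"line {lineno}: bad rate token {token!r}")
        key, val = token.split("=", 1)
        if key not in ("kf", "kb"):
            raise ReactionParseError(f"line {lineno}: unknown rate key {key!r}")
        try:
            out[key] = float(val)
        except ValueError:
            out[key] = val  # parameter name, resolved at compile time
    return out


def parse_reactions(text: str) -> ReactionNetwork:
    """Parse a reaction table into a :class:`ReactionNetwork`.

    Each non-blank, non-comment line is ``[terms] ARROW [terms] [; rates]``
    with terms joined by ``+`` and ``0`` for an empty side. Duplicate
    reactions are kept (their fluxes sum) with a warning.
    """
    species: dict[str, Species] = {}
    reactions: list[Reaction] = []
    seen_keys: set[tuple] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        body, _, tail = line.partition(";")
        arrow = next(((a, rev) for a, rev in _ARROWS if a in body), None)
        if arrow is None:
            raise ReactionParseError(f"line {lineno}: no reaction arrow in {raw!r}")
        lhs, rhs = body.split(arrow[0], 1)
        reactants = _parse_side(lhs, lineno)
        products = _parse_side(rhs, lineno)
        if not reactants and not products:
            raise ReactionParseError(f"line {lineno}: empty reaction")
        rates = _parse_rates(tail, lineno) if tail.strip() else {}
        label = f"R{len(reactions) + 1}"
        for name, _ in (*reactants, *products):
            species.setdefault(name, Species(name))
        key = (reactants, products, arrow[1])
        if key in seen_keys:
            warnings.warn(
                f"duplicate reaction at line {lineno}; fluxes will be summed",
                stacklevel=2,
            )
        seen_keys.add(key)
        reactions.append(
            Reaction(
                reactants=reactants,
                products=products,
                reversible=arrow[1],
                kf=rates.get("kf", f"kf_{label}"),
                kb=rates.get("kb", f"kb_{label}") if arrow[1] else rates.get("kb"),
                label=label,
            )
        )
    return ReactionNetwork(species=list(species.values()), reactions=reactions)


# ---------------------------------------------------------------------------
# compilation

def _resolve(k: float | str | None, params, label: str) -> float:
    if k is None:
        return 0.0
    if isinstance(k, str):
        if params is None:
            raise ConfigurationError(f"missing rate constant {k!r} ({label})")
        try:
            if isinstance(params, ParameterSet):
                k = params.get(k)
            else:
                k = params[k]
        except KeyError as exc:
            raise ConfigurationError(f"missing rate constant {exc.args[0]!r}") from exc
    k = float(k)
    if k < 0:
        raise ConfigurationError(f"negative rate constant in {label}: {k}")
    return k


def build_rhs(net: ReactionNetwork, params: Mapping | ParameterSet | None = None):
    """Compile a network to a derivative function ``f(t, y) -> dy/dt``.

    Forward flux of a mass-action reaction is ``kf * prod(reactant^coeff)``
    and, if reversible, backward flux ``kb * prod(product^coeff)``; the
    species derivative is the stoichiometry-weighted sum of fluxes, so
    molar balance holds per reaction by construction. A zero-order
    synthesis (empty reactant side) has forward flux ``kf``.
    """
    names = net.species_names
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    compiled = []
    for rxn in net.reactions:
        order = sum(c for _, c in rxn.reactants)
        if order > 3:
            raise ConfigurationError(
                f"reaction {rxn.label!r} has mass-action order {order} > 3"
            )
        kf = _resolve(rxn.kf, params, rxn.label)
        kb = _resolve(rxn.kb, params, rxn.label) if rxn.reversible else 0.0
        r_idx = np.array([idx[m] for m, _ in rxn.reactants], dtype=int)
        r_c = np.array([c for _, c in rxn.reactants], dtype=float)
        p_idx = np.array([idx[m] for m, _ in rxn.products], dtype=int)
        p_c = np.array([c for _, c in rxn.products], dtype=float)
        compiled.append((kf, kb, r_idx, r_c, p_idx, p_c, rxn.modifier, rxn.reversible))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        dy = np.zeros(n)
        for kf, kb, r_idx, r_c, p_idx, p_c, modifier, reversible in compiled:
            if modifier is not None:
                flux = modifier({names[i]: y[i] for i in range(n)})
            else:
                flux = kf * np.prod(y[r_idx] ** r_c) if r_idx.size else kf
                if reversible:
                    back = kb * np.prod(y[p_idx] ** p_c) if p_idx.size else kb
                    flux -= back
            if r_idx.size:
                np.subtract.at(dy, r_idx, r_c * flux)
            if p_idx.size:
                np.add.at(dy, p_idx, p_c * flux)
        return dy

    rhs.species_names = names  # type: ignore[attr-defined]
    return rhs


# ---------------------------------------------------------------------------
# integration

def simulate(
    rhs,
    y0,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    tol_neg: float = 1e-9,
) -> Trajectory:
    """Stiff-capable integration sampled exactly at ``t_grid``.

    Concentrations within ``tol_neg`` below zero are clipped to zero in
    the output (count recorded in metadata); anything more negative
    raises, as it indicates a genuinely failed step.
    """
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be nonempty")
    names = getattr(rhs, "species_names", [f"y{i}" for i in range(y0.size)])
    meta = {"method": method, "rtol": rtol, "atol": atol, "tol_neg": tol_neg}
    if t_grid.size == 1:
        return Trajectory(t_grid, y0[None, :], list(names), meta)
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, method=method, t_eval=t_grid,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else None
        raise IntegrationError(f"integration failed: {sol.message}", last_time=last)
    states = sol.y.T.copy()
    neg = states < 0
    if np.any(states < -tol_neg):
        worst = states.min()
        raise IntegrationError(f"negative concentration {worst:g} beyond tol_neg")
    meta["n_clipped"] = int(neg.sum())
    states[neg] = 0.0
    return Trajectory(t_grid, states, list(names), meta)


def steady_state(
    rhs,
    y0_guess,
    ss_tol: float = 1e-9,
    t_long: float = 2e5,
    max_rounds: int = 6,
) -> np.ndarray:
    """Non-negative steady state: long-horizon integration + root polish.

    Integrates for ``t_long`` hours (doubling the horizon each round the
    residual has not converged), then polishes with bounded least squares
    on the RHS. Raises with the residual if the budget is exhausted.
    """
    y = np.asarray(y0_guess, dtype=float)
    if not np.all(np.isfinite(rhs(0.0, y))):
        raise ValueError("rhs not finite at the initial guess")
    if float(np.max(np.abs(rhs(0.0, y)))) <= ss_tol:
        return y  # already stationary (e.g. all-zero rates)
    horizon = t_long
    for _ in range(max_rounds):
        sol = solve_ivp(rhs, (0.0, horizon), y, method="LSODA",
                        rtol=1e-10, atol=1e-13)
        if sol.success:
            y = np.clip(sol.y[:, -1], 0.0, None)
        res = least_squares(
            lambda x: rhs(0.0, x), y, bounds=(0.0, np.inf),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        y = res.x
        resid = float(np.max(np.abs(rhs(0.0, y))))
        if resid <= ss_tol:
            return np.clip(y, 0.0, None)
        horizon *= 2.0
    raise RuntimeError(
        f"steady state not reached: residual {resid:g} > ss_tol {ss_tol:g}"
    )
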
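"""Reaction-table parsing, mass-action compilation and integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amyprog.reactions import (
    ConfigurationError,
    ReactionParseError,
    build_rhs,
    parse_reactions,
    simulate,
    steady_state,
)


class TestParsing:
    def test_reversible_unicode_arrow(self):
        net = parse_reactions("APP + βS ↔ APP:βS ; kf=1 kb=2")
        assert len(net.reactions) == 1
        rxn = net.reactions[0]
        assert rxn.reversible
        assert {n for n, _ in rxn.reactants} == {"APP", "βS"}
        assert rxn.products == (("APP:βS", 1),)

    def test_generation_pair(self):
        net = parse_reactions("0 <-> APP ; kf=5 kb=0.1")
        (rxn,) = net.reactions
        assert rxn.reactants == () and rxn.products == (("APP", 1),)
        assert rxn.reversible

    def test_empty_input_is_empty_network(self):
        net = parse_reactions("")
        assert net.species == [] and net.reactions == []

    def test_stoichiometric_coefficient(self):
        net = parse_reactions("2 A <-> B ; kf=1 kb=1")
        assert net.reactions[0].reactants == (("A", 2),)

    @pytest.mark.parametrize("bad", ["A B", "A -> B ; k=1"])
    def test_unparseable_line_names_the_line(self, bad):
        with pytest.raises(ReactionParseError, match="line 1"):
            parse_reactions(bad)

    def test_duplicate_reactions_warn(self):
        with pytest.warns(UserWarning, match="duplicate"):
            parse_reactions("A -> B ; kf=1\nA -> B ; kf=2")

    def test_ascii_and_unicode_arrows_equivalent(self):
        a = parse_reactions("A -> B ; kf=1")
        b = parse_reactions("A → B ; kf=1")
        assert a.reactions[0].reversible is False
        assert b.reactions[0].reversible is False


class TestBuildRhs:
    def test_single_reversible_step(self):
        net = parse_reactions("A <-> B ; kf=2 kb=1")
        rhs = build_rhs(net)
        dA, dB = rhs(0.0, [3.0, 0.0])
        assert dA == -6.0 and dB == 6.0

    def test_dimerization_equilibrium(self):
        # at equilibrium of 2A <-> B, B = (kf/kb) A^2
        net = parse_reactions("2 A <-> B ; kf=0.3 kb=0.7")
        rhs = build_rhs(net)
        y = steady_state(rhs, [1.0, 1.0], ss_tol=1e-12)
        assert y[1] == pytest.approx(0.3 / 0.7 * y[0] ** 2, rel=1e-8)

    def test_closed_network_conservation(self):
        net = parse_reactions("A <-> B ; kf=1 kb=0.5\nB -> C ; kf=0.2")
        rhs = build_rhs(net)
        traj = simulate(rhs, [2.0, 1.0, 0.0], np.linspace(0, 50, 20))
        total = traj.states.sum(axis=1)
        assert np.allclose(total, total[0], rtol=1e-7)

    def test_missing_rate_constant_named(self):
        net = parse_reactions("A -> B ; kf=missing_key")
        with pytest.raises(ConfigurationError, match="missing_key"):
            build_rhs(net, {})

    def test_negative_rate_rejected(self):
        net = parse_reactions("A -> B ; kf=k")
        with pytest.raises(ConfigurationError, match="negative"):
            build_rhs(net, {"k": -1.0})

    def test_mass_action_order_capped(self):
        net = parse_reactions("2 A + 2 B -> C ; kf=1")
        with pytest.raises(ConfigurationError, match="order"):
            build_rhs(net)


def _oracle_rhs(net, rates, y):
    """Independent brute-force derivative: loop over reactions, literal
    mass action, sharing no code with build_rhs internals."""
    names = [s.name for s in net.species]
    dy = dict.fromkeys(names, 0.0)
    conc = dict(zip(names, y))
    for rxn in net.reactions:
        fwd = rates[rxn.kf] if isinstance(rxn.kf, str) else float(rxn.kf)
        for n, c in rxn.reactants:
            fwd *= conc[n] ** c
        flux = fwd
        if rxn.reversible:
            back = rates[rxn.kb] if isinstance(rxn.kb, str) else float(rxn.kb)
            for n, c in rxn.products:
                back *= conc[n] ** c
            flux -= back
        for n, c in rxn.reactants:
            dy[n] -= c * flux
        for n, c in rxn.products:
            dy[n] += c * flux
    return np.array([dy[n] for n in names])


@pytest.mark.filterwarnings("ignore:duplicate reaction")
@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_rhs_matches_bruteforce_oracle(seed):
    """Compiled RHS equals an independently coded mass-action evaluation
    on random <=4-species networks and random states (1e-12 relative)."""
    rng = np.random.default_rng(seed)
    species = list("ABCD")[: rng.integers(2, 5)]
    lines = []
    for j in range(rng.integers(1, 6)):
        lhs = " + ".join(rng.choice(species, size=rng.integers(1, 3), replace=True))
        rhs_side = " + ".join(rng.choice(species, size=rng.integers(1, 3), replace=True))
        if rng.random() < 0.5:
            lines.append(f"{lhs} <-> {rhs_side} ; kf={rng.uniform(0, 2):.6f} "
                         f"kb={rng.uniform(0, 2):.6f}")
        else:
            lines.append(f"{lhs} -> {rhs_side} ; kf={rng.uniform(0, 2):.6f}")
    net = parse_reactions("\n".join(lines))
    f = build_rhs(net)
    for _ in range(10):
        y = rng.uniform(0, 5, size=len(net.species))
        expected = _oracle_rhs(net, {}, y)
        got = f(0.0, y)
        assert np.allclose(got, expected, rtol=1e-12, atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_per_reaction_molar_balance(seed):
    """For closed random networks where every reaction conserves species
    count, the stoichiometry-weighted total derivative is zero."""
    rng = np.random.default_rng(seed)
    # chain conversions only: A<->B<->C (count-conserving by construction)
    lines = [f"A <-> B ; kf={rng.uniform(0, 2):.4f} kb={rng.uniform(0, 2):.4f}",
             f"B <-> C ; kf={rng.uniform(0, 2):.4f} kb={rng.uniform(0, 2):.4f}"]
    net = parse_reactions("\n".join(lines))
    f = build_rhs(net)
    y = rng.uniform(0, 3, size=3)
    assert abs(f(0.0, y).sum()) < 1e-12


class TestSimulate:
    def test_first_order_decay_closed_form(self):
        net = parse_reactions("X -> 0 ; kf=0.3")
        rhs = build_rhs(net)
        t = np.linspace(0, 20, 11)
        traj = simulate(rhs, [5.0], t, rtol=1e-10, atol=1e-13)
        assert np.allclose(traj["X"], 5.0 * np.exp(-0.3 * t), rtol=1e-7)

    def test_synthesis_decay_steady_state(self):
        net = parse_reactions("0 <-> X ; kf=4 kb=0.5")
        rhs = build_rhs(net)
        traj = simulate(rhs, [0.0], np.linspace(0, 200, 5))
        assert traj["X"][-1] == pytest.approx(4 / 0.5, rel=1e-6)

    def test_length_one_grid_returns_initial_state(self):
        net = parse_reactions("X -> 0 ; kf=1")
        traj = simulate(build_rhs(net), [2.0], np.array([0.0]))
        assert traj.states.shape == (1, 1) and traj.states[0, 0] == 2.0

    def test_negative_initial_state_rejected(self):
        net = parse_reactions("X -> 0 ; kf=1")
        with pytest.raises(ValueError, match="non-negative"):
            simulate(build_rhs(net), [-1.0], np.linspace(0, 1, 3))

    def test_trajectory_roundtrip_frame(self, tmp_path):
        net = parse_reactions("X -> 0 ; kf=1")
        traj = simulate(build_rhs(net), [1.0], np.linspace(0, 1, 4))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["time_h", "X"]
        assert len(df) == 4


class TestSteadyState:
    def test_synthesis_decay(self):
        net = parse_reactions("0 <-> X ; kf=3 kb=0.2")
        y = steady_state(build_rhs(net), [1.0])
        assert y[0] == pytest.approx(15.0, rel=1e-9)

    def test_all_zero_rates_returns_guess(self):
        net = parse_reactions("A -> B ; kf=0")
        guess = np.array([1.5, 2.5])
        y = steady_state(build_rhs(net), guess)
        assert np.array_equal(y, guess)

    def test_nonnegative_result(self):
        net = parse_reactions("0 <-> X ; kf=1 kb=1\nX -> Y ; kf=0.5\nY -> 0 ; kf=0.5")
        y = steady_state(build_rhs(net), [0.1, 0.1])
        assert np.all(y >= 0)
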
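"""Six-species aggregation cascade: rate laws, conservation, equilibria."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from amyprog.aggregation import (
    AggregationConfigError,
    AggregationParams,
    aggregation_rhs,
    fragmentation_rate,
    mass_concentrations,
    nucleation_polymerization_rate,
    plaque_growth_rate,
    secondary_nucleation_rate,
)

# a fully reversible chain with secondary processes off: equilibrium exists
CHAIN = dict(kfM=2e-3, kbM=0.05, kfD=4e-3, kbD=0.02, kfo=3e-3, kbo=0.03,
             kfO=2e-3, kbO=0.02, kfF=1e-3, kbF=0.01, k2n=0.0, kPg=0.0,
             Pmax=1e6, kfragF=0.0, kfragP=0.0)


def chain_params(**over):
    return AggregationParams(**{**CHAIN, **over})


class TestNucleationPolymerization:
    def test_all_zero_state(self):
        assert np.all(nucleation_polymerization_rate(np.zeros(6), chain_params()) == 0)

    def test_monomer_only_forward(self):
        # only M > 0 and all kb = 0: monomer term is -2 kfM M^2
        p = chain_params(kbM=0, kbD=0, kbo=0, kbO=0, kbF=0)
        out = nucleation_polymerization_rate([10, 0, 0, 0, 0, 0], p)
        assert out[0] == pytest.approx(-2 * p.kfM * 100)
        assert out[1] == pytest.approx(p.kfM * 100)

    def test_dimer_subsystem_equilibrium_and_conservation(self):
        """Isolated 2M<->D: D/M^2 -> kfM/kbM and M + 2D is conserved."""
        p = chain_params(kfD=0, kbD=0, kfo=0, kbo=0, kfO=0, kbO=0,
                         kfF=0, kbF=0)

        def rhs(t, y):
            return nucleation_polymerization_rate(np.clip(y, 0, None), p)

        y0 = np.array([8.0, 0, 0, 0, 0, 0])
        sol = solve_ivp(rhs, (0, 5e4), y0, method="LSODA",
                        rtol=1e-11, atol=1e-13)
        M, D = sol.y[0], sol.y[1]
        assert np.allclose(M + 2 * D, 8.0, rtol=1e-8)
        assert D[-1] / M[-1] ** 2 == pytest.approx(p.kfM / p.kbM, rel=1e-6)

    def test_chain_conserves_monomer_equivalents(self):
        """The literal ladder adds one monomer per step, so the weighted
        total M + 2D + 3o + 4O + 5F + 6P is invariant."""
        p = chain_params()
        w = np.array([1, 2, 3, 4, 5, 6])
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = rng.uniform(0, 10, 6)
            assert abs(w @ nucleation_polymerization_rate(y, p)) < 1e-12

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            nucleation_polymerization_rate([-1, 0, 0, 0, 0, 0], chain_params())


class TestSecondaryNucleation:
    @pytest.mark.parametrize("state", [
        [10, 0, 0, 0, 0, 0],    # no plaque catalyst
        [0, 0, 0, 0, 0, 100],   # no monomer
    ])
    def test_vanishes_without_both_reactants(self, state):
        p = chain_params(k2n=1e-6)
        assert np.all(secondary_nucleation_rate(state, p) == 0)

    def test_direct_evaluation(self):
        p = chain_params(k2n=1e-6)
        out = secondary_nucleation_rate([10, 0, 0, 0, 0, 100], p)
        assert out[0] == pytest.approx(-0.02)   # 2 * 1e-6 * 100 * 100
        assert out[1] == pytest.approx(0.01)
        assert np.all(out[2:] == 0)


class TestPlaqueGrowth:
    def test_saturated_at_pmax(self):
        p = chain_params(kPg=1e-3, Pmax=100.0)
        out = plaque_growth_rate([5, 0, 1, 1, 0, 100.0], p)
        assert np.all(out == 0)

    def test_no_oligomers_no_growth(self):
        p = chain_params(kPg=1e-3)
        assert np.all(plaque_growth_rate([5, 1, 0, 0, 1, 10], p) == 0)

    def test_halving_pmax_closes_headroom(self):
        pA = chain_params(kPg=1e-3, Pmax=200.0)
        pB = chain_params(kPg=1e-3, Pmax=100.0)
        state = [5, 0, 2, 0, 0, 100.0]
        outA = plaque_growth_rate(state, pA)   # sat = 0.5
        outB = plaque_growth_rate(state, pB)   # sat = 0
        assert outA[0] == pytest.approx(-1e-3 * 5 * 2 * 0.5)
        assert np.all(outB == 0)

    def test_invalid_pmax(self):
        with pytest.raises(AggregationConfigError, match="Pmax"):
            chain_params(Pmax=0.0)


class TestFragmentation:
    def test_zero_when_no_aggregates(self):
        p = chain_params(kfragF=1e-3, kfragP=1e-3)
        assert np.all(fragmentation_rate([5, 1, 0, 0, 0, 0], p) == 0)

    def test_plaque_shedding_direct(self):
        p = chain_params(kfragP=0.01)
        out = fragmentation_rate([0, 0, 0, 0, 0, 200.0], p)
        assert out[5] == pytest.approx(-2.0)
        assert out[4] == pytest.approx(2.0)

    def test_boundary_split_all_to_small_oligomer(self):
        p = chain_params(kfragF=0.1, frag_split_o=1.0, frag_split_O=0.0)
        out = fragmentation_rate([0, 0, 0, 0, 10.0, 0], p)
        assert out[2] == pytest.approx(1.0) and out[3] == 0.0

    def test_invalid_split_rejected(self):
        with pytest.raises(AggregationConfigError, match="split"):
            chain_params(frag_split_o=0.8, frag_split_O=0.8)


class TestFullRhs:
    def test_zero_state_stays_zero(self):
        p = chain_params(k2n=1e-4, kPg=1e-4, kfragF=1e-3, kfragP=1e-4)
        assert np.all(aggregation_rhs(np.zeros(6), p) == 0)

    def test_hooks_applied(self):
        p = chain_params()
        state = np.array([1.0, 0, 1.0, 1.0, 1.0, 1.0])
        base = aggregation_rhs(state, p)
        kg = np.array([0, 0, 0.1, 0.1, 0.1, 0.05])
        with_cl = aggregation_rhs(state, p,
                                  clearance_hook=lambda y: (0.2, kg))
        assert with_cl[0] == pytest.approx(base[0] - 0.2)
        assert np.allclose(with_cl[2:], base[2:] - kg[2:] * state[2:])

    def test_nonfinite_hook_raises(self):
        p = chain_params()
        with pytest.raises(RuntimeError, match="hook"):
            aggregation_rhs(np.ones(6), p,
                            clearance_hook=lambda y: (np.nan, np.zeros(6)))

    def test_faster_isoform_dominates(self):
        """Uniformly larger forward constants: plaque stays ahead at
        every time point from identical initial monomer."""
        slow = chain_params(k2n=1e-5, kPg=1e-5)
        fast = AggregationParams(**{**CHAIN, "k2n": 5e-5, "kPg": 5e-5,
                                    "kfM": 1e-2, "kfD": 2e-2, "kfo": 1.5e-2,
                                    "kfO": 1e-2, "kfF": 5e-3})
        y0 = np.array([10.0, 0, 0, 0, 0, 1e-6])
        t = np.linspace(0, 2e4, 30)
        out = {}
        for name, p in (("slow", slow), ("fast", fast)):
            sol = solve_ivp(lambda t, y: aggregation_rhs(np.clip(y, 0, None), p),
                            (0, t[-1]), y0, t_eval=t, method="LSODA",
                            rtol=1e-9, atol=1e-12)
            out[name] = sol.y[5]
        assert np.all(out["fast"] >= out["slow"] - 1e-12)


def _chain_equilibrium_oracle(p, total):
    """Detailed-balance fixed point of the closed reversible ladder by
    one-dimensional root finding in the monomer concentration."""
    K = [p.kfM / p.kbM, p.kfD / p.kbD, p.kfo / p.kbo,
         p.kfO / p.kbO, p.kfF / p.kbF]

    def levels(M):
        D = K[0] * M ** 2
        o = K[1] * M * D
        O = K[2] * M * o
        F = K[3] * M * O
        P = K[4] * M * F
        return np.array([M, D, o, O, F, P])

    w = np.array([1, 2, 3, 4, 5, 6])

    def excess(M):
        return w @ levels(M) - total

    M = brentq(excess, 0.0, total, xtol=1e-15, rtol=1e-15)
    return levels(M)


def test_detailed_balance_equilibrium_vs_oracle():
    """Long-time state of the closed reversible chain matches the
    root-finding equilibrium to 1e-6 relative."""
    p = chain_params()
    y0 = np.array([5.0, 0, 0, 0, 0, 0])
    total = 5.0
    sol = solve_ivp(lambda t, y: nucleation_polymerization_rate(np.clip(y, 0, None), p),
                    (0, 2e6), y0, method="LSODA", rtol=1e-12, atol=1e-14)
    expected = _chain_equilibrium_oracle(p, total)
    assert np.allclose(sol.y[:, -1], expected, rtol=1e-6)


def test_forward_scaling_does_not_decrease_plaque():
    """Scaling every forward constant up (backward fixed) weakly
    increases equilibrium plaque."""
    p1 = chain_params()
    p2 = chain_params(**{k: 2 * CHAIN[k] for k in ("kfM", "kfD", "kfo", "kfO", "kfF")})
    P1 = _chain_equilibrium_oracle(p1, 5.0)[5]
    P2 = _chain_equilibrium_oracle(p2, 5.0)[5]
    assert P2 >= P1


def test_mass_concentration_reporting():
    p = chain_params()
    m = mass_concentrations([1, 1, 1, 1, 1, 1], p)
    assert m == {"M": 1, "D": p.n_D, "o": p.n_o, "O": p.n_O,
                 "F": p.n_F, "P": p.n_P}
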
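"""Unit and property tests for the mass-action CRN core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from reflexdna import (
    ConfigurationError,
    DoseEvent,
    DoseSchedule,
    Reaction,
    ReactionNetwork,
    SolverConfig,
    SpeciesSpec,
    conservation_groups,
    mass_action_rhs,
    simulate,
    window_metrics,
)


def species(*names, init=()):
    init = dict(init)
    return [SpeciesSpec(n, initial_concentration=init.get(n, 0.0))
            for n in names]


def exchange(a, b, c, d, kf, kb, label=""):
    return Reaction((a, b), (c, d), kf, kb, label=label)


# ---------------------------------------------------------------------------
# construction and validation
# ---------------------------------------------------------------------------

class TestValidation:
    def test_duplicate_species_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            ReactionNetwork(species("A", "A"), [])

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(ConfigurationError):
            SpeciesSpec("A", initial_concentration=-1.0)

    def test_unknown_reaction_species_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown species"):
            ReactionNetwork(species("A"), [Reaction(("A",), ("B",), 1.0)])

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            Reaction(("A",), (), -1.0)

    def test_reversible_degradation_rejected(self):
        with pytest.raises(ConfigurationError, match="irreversible"):
            Reaction(("A",), (), 1.0, k_backward=0.5)

    def test_bad_state_length(self):
        net = ReactionNetwork(species("A"), [])
        with pytest.raises(ConfigurationError):
            mass_action_rhs(net, np.zeros(3))


# ---------------------------------------------------------------------------
# mass_action_rhs
# ---------------------------------------------------------------------------

class TestRhs:
    def test_no_reactions_gives_zero_flux(self):
        net = ReactionNetwork(species("A", "B"), [])
        assert np.array_equal(mass_action_rhs(net, np.array([3.0, 7.0])),
                              np.zeros(2))

    def test_linear_decay(self):
        # A -> waste at 0.01/s from 100 nM: d[A]/dt = -1 nM/s
        net = ReactionNetwork(species("A"), [Reaction(("A",), (), 0.01)])
        d = mass_action_rhs(net, np.array([100.0]))
        assert d[0] == pytest.approx(-1.0)

    def test_bimolecular_exchange_flux(self):
        # A+B <=> C+D, kf=kb=5.32e-4, [A]=[B]=100, [C]=[D]=0
        net = ReactionNetwork(
            species("A", "B", "C", "D"),
            [exchange("A", "B", "C", "D", 5.32e-4, 5.32e-4)],
        )
        d = mass_action_rhs(net, np.array([100.0, 100.0, 0.0, 0.0]))
        assert d[0] == pytest.approx(-5.32)
        assert d.tolist() == pytest.approx([-5.32, -5.32, 5.32, 5.32])

    def test_backward_flux_counted(self):
        net = ReactionNetwork(
            species("A", "B", "C", "D"),
            [exchange("A", "B", "C", "D", 0.0, 2e-3)],
        )
        d = mass_action_rhs(net, np.array([0.0, 0.0, 10.0, 5.0]))
        assert d[0] == pytest.approx(2e-3 * 50)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_empty_schedule_zero_initials_flat(self):
        net = ReactionNetwork(
            species("A", "B"), [exchange("A", "B", "B", "A", 1e-3, 1e-3)]
        )
        traj = simulate(net, DoseSchedule([], horizon=100.0))
        assert np.allclose(traj.concentrations, 0.0)

    def test_exponential_decay_closed_form(self):
        net = ReactionNetwork(species("A"), [Reaction(("A",), (), 0.01)])
        traj = simulate(
            net,
            DoseSchedule([DoseEvent(0.0, "A", 100.0)], horizon=700.0),
            solver=SolverConfig(max_grid_dt=0.1),
        )
        expected = 100.0 * np.exp(-0.01 * traj.times)
        assert np.allclose(traj.species("A"), expected, rtol=1e-6, atol=1e-8)
        # half-life: [A](69.3 s) ~ 50 nM
        i = np.argmin(np.abs(traj.times - 69.3))
        assert traj.species("A")[i] == pytest.approx(50.0, rel=1e-3)

    def test_symmetric_exchange_equilibrates_at_half(self):
        net = ReactionNetwork(
            species("A", "B", "C", "D", init={"A": 100.0, "B": 100.0}),
            [exchange("A", "B", "C", "D", 5.32e-4, 5.32e-4)],
        )
        traj = simulate(net, DoseSchedule([], horizon=50000.0))
        assert traj.concentrations[-1] == pytest.approx([50.0] * 4, rel=1e-5)

    def test_unknown_dosed_species_rejected(self):
        net = ReactionNetwork(species("A"), [])
        with pytest.raises(ConfigurationError, match="unknown species"):
            simulate(net, DoseSchedule([DoseEvent(0.0, "Z", 1.0)],
                                       horizon=10.0))

    def test_dose_applied_at_event_time(self):
        net = ReactionNetwork(species("A"), [])
        traj = simulate(
            net, DoseSchedule([DoseEvent(50.0, "A", 30.0)], horizon=100.0)
        )
        before = traj.species("A")[traj.times < 50.0]
        after = traj.species("A")[traj.times >= 50.0]
        assert np.allclose(before, 0.0) and np.allclose(after, 30.0)

    def test_nonnegative_after_clipping(self):
        net = ReactionNetwork(
            species("A", init={"A": 100.0}), [Reaction(("A",), (), 0.05)]
        )
        traj = simulate(net, DoseSchedule([], horizon=5000.0))
        assert traj.species("A").min() >= 0.0
        assert traj.concentrations.min() >= -1e-6

    @given(
        a=st.floats(1.0, 80.0),
        b=st.floats(1.0, 80.0),
    )
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_dose_additivity(self, a, b):
        """One dose of a+b nM equals doses of a and b at the same instant."""
        def run(events):
            net = ReactionNetwork(
                species("A", "B", "C", "D", init={"B": 60.0}),
                [exchange("A", "B", "C", "D", 5e-4, 5e-4)],
            )
            return simulate(net, DoseSchedule(events, horizon=2000.0))

        t1 = run([DoseEvent(100.0, "A", a + b)])
        t2 = run([DoseEvent(100.0, "A", a), DoseEvent(100.0, "A", b)])
        assert np.allclose(t1.concentrations, t2.concentrations,
                           rtol=1e-7, atol=1e-8)

    def test_grid_independence_of_peak(self):
        """Halving tolerances moves peak metrics by < 0.1%."""
        def peak(cfg):
            net = ReactionNetwork(
                species("A", "B", "C", "D", init={"B": 100.0}),
                [exchange("A", "B", "C", "D", 5.32e-4, 5.32e-4)],
            )
            traj = simulate(
                net, DoseSchedule([DoseEvent(0.0, "A", 100.0)],
                                  horizon=20000.0), solver=cfg
            )
            return window_metrics(traj, "C", (0.0, 20000.0)).peak

        p1 = peak(SolverConfig())
        p2 = peak(SolverConfig(rtol=0.5e-8, atol=0.5e-10, max_grid_dt=5.0))
        assert abs(p1 - p2) / p1 < 1e-3


# ---------------------------------------------------------------------------
# equilibrium oracle (brute-force root of the detailed-balance quadratic)
# ---------------------------------------------------------------------------

def equilibrium_extent(kf, kb, a0, b0, c0, d0):
    """Root of kf (a0-x)(b0-x) = kb (c0+x)(d0+x) on the feasible interval."""
    def g(x):
        return kf * (a0 - x) * (b0 - x) - kb * (c0 + x) * (d0 + x)

    lo = -min(c0, d0)
    hi = min(a0, b0)
    return brentq(g, lo + 1e-12, hi - 1e-12, xtol=1e-14)


@given(
    kf=st.floats(1e-4, 1e-2),
    kb=st.floats(1e-4, 1e-2),
    a0=st.floats(10.0, 100.0),
    b0=st.floats(10.0, 100.0),
    c0=st.floats(0.5, 50.0),
)
@settings(max_examples=15, deadline=None, derandomize=True)
def test_long_time_state_satisfies_detailed_balance(kf, kb, a0, b0, c0):
    """Simulated equilibrium of one reversible bimolecular reaction matches
    the closed-form quadratic root: kf [A][B] = kb [C][D] to 1e-6."""
    d0 = 2.0
    net = ReactionNetwork(
        species("A", "B", "C", "D",
                init={"A": a0, "B": b0, "C": c0, "D": d0}),
        [exchange("A", "B", "C", "D", kf, kb)],
    )
    traj = simulate(net, DoseSchedule([], horizon=2e6),
                    solver=SolverConfig(max_grid_dt=1e4))
    x = equilibrium_extent(kf, kb, a0, b0, c0, d0)
    expected = np.array([a0 - x, b0 - x, c0 + x, d0 + x])
    final = traj.concentrations[-1]
    assert np.allclose(final, expected, rtol=1e-5)
    lhs = kf * final[0] * final[1]
    rhs = kb * final[2] * final[3]
    assert abs(lhs - rhs) / max(lhs, rhs) < 1e-6


# ---------------------------------------------------------------------------
# window metrics
# ---------------------------------------------------------------------------

class TestWindowMetrics:
    def test_flat_zero(self):
        net = ReactionNetwork(species("A"), [])
        traj = simulate(net, DoseSchedule([], horizon=100.0))
        m = window_metrics(traj, "A", (0.0, 100.0))
        assert (m.peak, m.peak_time, m.end_value) == (0.0, 0.0, 0.0)

    def test_monotone_decay_peaks_at_window_start(self):
        net = ReactionNetwork(species("A"), [Reaction(("A",), (), 0.01)])
        traj = simulate(
            net, DoseSchedule([DoseEvent(0.0, "A", 100.0)], horizon=1000.0)
        )
        m = window_metrics(traj, "A", (0.0, 1000.0))
        assert m.peak == pytest.approx(100.0, rel=1e-9)
        assert m.peak_time == 0.0

    def test_empty_window_rejected(self):
        net = ReactionNetwork(species("A"), [])
        traj = simulate(net, DoseSchedule([], horizon=100.0))
        with pytest.raises(ConfigurationError):
            window_metrics(traj, "A", (50.0, 50.0))


# ---------------------------------------------------------------------------
# conservation groups
# ---------------------------------------------------------------------------

class TestConservation:
    def test_isomerization_conserves_total(self):
        net = ReactionNetwork(
            species("A", "B", init={"A": 10.0}),
            [Reaction(("A",), ("B",), 1e-3, 1e-3)],
        )
        groups = conservation_groups(net)
        assert len(groups) == 1
        assert groups[0].weights == {"A": 1, "B": 1}
        assert groups[0].total == pytest.approx(10.0)
        assert not groups[0].broken_by_degradation

    def test_pure_degradation_breaks_conservation(self):
        net = ReactionNetwork(
            species("A", init={"A": 10.0}), [Reaction(("A",), (), 0.01)]
        )
        groups = conservation_groups(net)
        assert all(g.broken_by_degradation
                   for g in groups if "A" in g.weights)

    def test_two_input_circuit_groups(self, two_input_network):
        """The reflex circuit carries 7 degradation-proof conservation laws
        plus 2 broken by input degradation; the known combinations lie in
        the reversible-reaction null space."""
        groups = conservation_groups(two_input_network)
        assert len(groups) == 9
        assert sum(g.broken_by_degradation for g in groups) == 2
        # every group flagged intact must exclude the degraded free inputs
        for g in groups:
            if not g.broken_by_degradation:
                assert "I1" not in g.weights and "I2" not in g.weights
        # the field-knowledge combinations annihilate the reversible matrix
        S = two_input_network.stoichiometric_matrix(include_degradation=False)
        names = two_input_network.species_names
        known = [
            {"M1": 1, "W1": 1},
            {"O": 1, "S": 1},
            {"Y1": 1, "M1": 1, "R1": 1},
            {"Y2": 1, "R2": 1, "M2": 1},
            {"Y2p": 1, "M2p": 1},
            {"M2": 1, "M2p": 1, "W2": 1},
            {"S": 1, "R1": 1, "R2": 1},
        ]
        for combo in known:
            w = np.array([combo.get(n, 0) for n in names], dtype=float)
            assert np.allclose(w @ S, 0.0)

    def test_groups_constant_along_trajectory(self, two_input_network,
                                              bfbb_run):
        """Intact group totals drift < 1e-4 relative along a learning run."""
        traj, _ = bfbb_run
        for g in conservation_groups(two_input_network):
            if g.broken_by_degradation or g.total == 0:
                continue
            series = g.value(traj)
            assert np.max(np.abs(series - g.total)) / abs(g.total) < 1e-4
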
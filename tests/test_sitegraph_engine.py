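"""Unit and property tests for the site-graph rewriting engine."""

import numpy as np
import pytest

from ctdsim import sitegraph_engine as se
from ctdsim.sitegraph_engine import (
    A,
    AgentSignature,
    ApplicationError,
    DefinitionError,
    Mixture,
    Model,
    Pattern,
    Rule,
    apply_rule,
    count_embeddings,
    enumerate_ctmc,
    run_ensemble,
    simulate,
)


@pytest.fixture
def xsig():
    return AgentSignature("X", {"s": ("u", "p")})


def _mixture_of_x(xsig, states):
    m = Mixture([xsig])
    for st in states:
        m.add_agent("X", {"s": st})
    return m


class TestMatching:
    def test_empty_pattern_matches_vacuously(self, xsig):
        m = _mixture_of_x(xsig, ["u"] * 3)
        n, emb = count_embeddings(Pattern([]), m)
        assert n == 1 and emb == [()]

    def test_state_test_counts_matching_agents(self, xsig):
        m = _mixture_of_x(xsig, ["p", "p", "u", "p", "u"])
        n, _ = count_embeddings(Pattern([A("X", "s~p?")]), m)
        assert n == 3

    def test_bound_to_anything_distinguishes_contexts(self):
        """Only the DNA-bound polymerase satisfies the bound-test a!_,
        mirroring the elongation-context condition of the CTD rules."""
        rnap = AgentSignature("RNAPII", {"a": (), "e": (),
                                         "ser5a": ("u", "p")})
        rtr1 = AgentSignature("Rtr1", {"a": ()})
        dna = AgentSignature("DNA", {"e5": ()})
        m = Mixture([rnap, rtr1, dna])
        m.add_agent("Rtr1")
        bound = m.add_agent("RNAPII", {"ser5a": "p"})
        m.add_agent("RNAPII", {"ser5a": "p"})          # free copy
        d = m.add_agent("DNA")
        m.bind(bound.id, "a", d.id, "e5")
        pat = Pattern([A("Rtr1", "a"), A("RNAPII", "a!_", "e", "ser5a~p")])
        n, emb = count_embeddings(pat, m)
        assert n == 1
        assert emb[0][1] == bound.id

    def test_no_automorphism_division(self, xsig):
        """Two identical pattern agents count both orderings."""
        m = _mixture_of_x(xsig, ["p", "p"])
        n, _ = count_embeddings(
            Pattern([A("X", "s~p?"), A("X", "s~p?")]), m)
        assert n == 2  # 2 ordered injections of 2 agents

    def test_shared_bond_label_requires_actual_bond(self):
        a = AgentSignature("Ag", {"x": ()})
        b = AgentSignature("Bg", {"y": ()})
        m = Mixture([a, b])
        a1, b1 = m.add_agent("Ag"), m.add_agent("Bg")
        a2, b2 = m.add_agent("Ag"), m.add_agent("Bg")
        m.bind(a1.id, "x", b1.id, "y")
        pat = Pattern([A("Ag", "x!1"), A("Bg", "y!1")])
        n, emb = count_embeddings(pat, m)
        assert n == 1 and emb == [(a1.id, b1.id)]

    def test_unknown_site_is_definition_error(self, xsig):
        m = _mixture_of_x(xsig, ["u"])
        with pytest.raises(DefinitionError):
            count_embeddings(Pattern([A("X", "nope~u")]), m)

    def test_unknown_signature_is_definition_error(self, xsig):
        m = _mixture_of_x(xsig, ["u"])
        with pytest.raises(DefinitionError):
            count_embeddings(Pattern([A("Y")]), m)

    def test_counter_tests(self):
        sig = AgentSignature("T", {}, counters=("n",))
        m = Mixture([sig])
        m.add_agent("T", counters={"n": 5})
        m.add_agent("T", counters={"n": 0})
        n_ge, _ = count_embeddings(Pattern([A("T", "n>=1")]), m)
        n_eq, _ = count_embeddings(Pattern([A("T", "n=0")]), m)
        assert (n_ge, n_eq) == (1, 1)


class TestApply:
    def test_state_change_leaves_everything_else(self, xsig):
        m = _mixture_of_x(xsig, ["u", "u"])
        r = Rule("flip", [A("X", "s~u?")], [A("X", "s~p?")], 1.0)
        _, emb = count_embeddings(r.lhs, m)
        before = m.canonical()
        apply_rule(r, m, emb[0])
        assert m.agents[emb[0][0]].states["s"] == "p"
        others = [a for a in m.agents.values() if a.id != emb[0][0]]
        assert all(a.states["s"] == "u" for a in others)
        assert m.canonical() != before
        assert m.event_count == 1

    def test_identity_rewrite_changes_only_bookkeeping(self, xsig):
        m = _mixture_of_x(xsig, ["u"])
        r = Rule("noop", [A("X", "s~u?")], [A("X", "s~u?")], 1.0)
        before = m.canonical()
        apply_rule(r, m, (0,))
        assert m.canonical() == before
        assert m.event_count == 1

    def test_bind_unbind_round_trip(self):
        a = AgentSignature("Ag", {"x": ()})
        b = AgentSignature("Bg", {"y": ()})
        bind = Rule("bind", [A("Ag", "x"), A("Bg", "y")],
                    [A("Ag", "x!1"), A("Bg", "y!1")], 1.0)
        unbind = Rule("unbind", [A("Ag", "x!1"), A("Bg", "y!1")],
                      [A("Ag", "x"), A("Bg", "y")], 1.0)
        m = Mixture([a, b])
        m.add_agent("Ag"), m.add_agent("Bg")
        before = m.canonical()
        _, emb = count_embeddings(bind.lhs, m)
        apply_rule(bind, m, emb[0])
        m.validate()
        n_bound, emb2 = count_embeddings(unbind.lhs, m)
        assert n_bound == 1
        apply_rule(unbind, m, emb2[0])
        m.validate()
        assert m.canonical() == before  # event_count not part of canon

    def test_rtr1_release_semantics(self):
        """Dephosphorylation on release: enzyme freed, Ser5 reset to u,
        untouched sites unchanged."""
        rnap = AgentSignature("RNAPII", {"a": (), "ser5a": ("u", "p"),
                                         "ser2a": ("u", "p")})
        rtr1 = AgentSignature("Rtr1", {"a": ()})
        m = Mixture([rnap, rtr1])
        enz = m.add_agent("Rtr1")
        pol = m.add_agent("RNAPII", {"ser5a": "p", "ser2a": "p"})
        m.bind(enz.id, "a", pol.id, "ser5a")
        rel = Rule("release",
                   [A("Rtr1", "a!1"), A("RNAPII", "ser5a~p!1")],
                   [A("Rtr1", "a"), A("RNAPII", "ser5a~u")], 1.0)
        _, emb = count_embeddings(rel.lhs, m)
        apply_rule(rel, m, emb[0])
        assert pol.states["ser5a"] == "u"
        assert pol.states["ser2a"] == "p"          # untouched
        assert enz.bonds["a"] is None and pol.bonds["ser5a"] is None
        m.validate()

    def test_create_and_delete(self, xsig):
        msig = AgentSignature("M")
        make = Rule("make", [A("X", "s~u?")], [A("X", "s~p?"), A("M")], 1.0)
        kill = Rule("kill", [A("M")], [None], 1.0)
        m = Mixture([xsig, msig])
        m.add_agent("X")
        apply_rule(make, m, (0,))
        assert m.count("M") == 1
        _, emb = count_embeddings(kill.lhs, m)
        apply_rule(kill, m, emb[0])
        assert m.count("M") == 0

    def test_stale_embedding_raises(self, xsig):
        msig = AgentSignature("M")
        kill = Rule("kill", [A("M")], [None], 1.0)
        m = Mixture([xsig, msig])
        ag = m.add_agent("M")
        apply_rule(kill, m, (ag.id,))
        with pytest.raises(ApplicationError):
            apply_rule(kill, m, (ag.id,))


def _decay_model(n=600, k=1.0):
    xsig = AgentSignature("X", {"s": ("a", "b")})
    r = Rule("flip", [A("X", "s~a?")], [A("X", "s~b?")], k, "k")
    return Model([xsig], [r], {"X": n}), n, k


class TestGillespie:
    def test_no_applicable_rules_keeps_initial_state(self):
        xsig = AgentSignature("X", {"s": ("a", "b")})
        r = Rule("flip", [A("X", "s~b?")], [A("X", "s~a?")], 1.0)
        model = Model([xsig], [r], {"X": 5})   # all start in state a
        traj = simulate(model, 10.0, 1, [0.0, 5.0, 10.0],
                        observables=[("Xa", Pattern([A("X", "s~a?")]))])
        assert np.all(traj.values[:, 0] == 5)
        assert len(traj.times) == 3

    def test_exponential_decay_closed_form(self):
        """Fraction undecayed at t = 1/k is e^-1 within 3 binomial SE."""
        model, n, k = _decay_model()
        traj = simulate(model, 1.0 / k, seed=42, observable_times=[1.0 / k],
                        observables=[("Xa", Pattern([A("X", "s~a?")]))])
        frac = traj.values[-1, 0] / n
        p = np.exp(-1.0)
        se3 = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < se3

    def test_two_state_binding_occupancy(self):
        """Long-run bound fraction of A+B <-> AB equals kon/(kon+koff)
        (the stationary law of the corresponding 2-state chain)."""
        kon, koff = 2.0, 1.0
        a = AgentSignature("Ag", {"x": ()})
        b = AgentSignature("Bg", {"y": ()})
        bind = Rule("bind", [A("Ag", "x"), A("Bg", "y")],
                    [A("Ag", "x!1"), A("Bg", "y!1")], kon)
        unbind = Rule("unbind", [A("Ag", "x!1"), A("Bg", "y!1")],
                      [A("Ag", "x"), A("Bg", "y")], koff)
        model = Model([a, b], [bind, unbind], {"Ag": 1, "Bg": 1})
        ts = np.arange(5.0, 2000.0, 0.5)
        traj = simulate(model, ts[-1], seed=7, observable_times=ts,
                        observables=[("AB", Pattern([A("Ag", "x!_")]))])
        frac = traj.values[:, 0].mean()
        assert abs(frac - kon / (kon + koff)) < 0.03

    def test_propensity_is_mass_action_for_state_tests(self, ):
        """For single-agent state-test rules the propensity equals
        rate x reactant count at every step of a short simulation."""
        model, n, k = _decay_model(n=50)
        mix = model.initial_mixture()
        rule = model.rules[0]
        n_emb, _ = count_embeddings(rule.lhs, mix)
        assert n_emb == 50
        for emb_target in range(5):
            _, emb = count_embeddings(rule.lhs, mix)
            apply_rule(rule, mix, emb[0])
        n_emb, _ = count_embeddings(rule.lhs, mix)
        assert n_emb == 45

    def test_early_termination_records_remaining_times(self):
        model, n, k = _decay_model(n=3, k=50.0)
        traj = simulate(model, 10.0, seed=3,
                        observable_times=[0.0, 5.0, 9.9],
                        observables=[("Xa", Pattern([A("X", "s~a?")]))])
        assert len(traj.times) == 3
        assert traj.values[-1, 0] == 0

    def test_observables_use_state_after_last_event_before_time(self):
        xsig = AgentSignature("X", {"s": ("a", "b")})
        r = Rule("flip", [A("X", "s~a?")], [A("X", "s~b?")], 1e-9)
        model = Model([xsig], [r], {"X": 1})
        traj = simulate(model, 1.0, 5, [0.0, 0.5, 1.0],
                        observables=[("Xa", Pattern([A("X", "s~a?")]))])
        # with a vanishing rate no event fires before t_max
        assert np.all(traj.values[:, 0] == 1)

    def test_t_max_must_be_positive(self):
        model, _, _ = _decay_model(n=1)
        with pytest.raises(DefinitionError):
            simulate(model, 0.0, 1, [0.0])


class TestDeterminism:
    def test_same_seed_identical_trajectories(self):
        model, _, _ = _decay_model(n=100)
        ts = np.linspace(0, 2, 21)
        t1 = simulate(model, 2.0, 11, ts,
                      observables=[("Xa", Pattern([A("X", "s~a?")]))])
        t2 = simulate(model, 2.0, 11, ts,
                      observables=[("Xa", Pattern([A("X", "s~a?")]))])
        assert np.array_equal(t1.values, t2.values)
        assert t1.events == t2.events

    def test_ensemble_seeds_are_base_plus_index(self):
        model, _, _ = _decay_model(n=30)
        ts = [0.5, 1.0]
        ens = run_ensemble(model, 3, 1.0, 100, ts,
                           observables=[("Xa", Pattern([A("X", "s~a?")]))])
        assert [t.seed for t in ens] == [100, 101, 102]
        single = simulate(model, 1.0, 100, ts,
                          observables=[("Xa", Pattern([A("X", "s~a?")]))])
        assert np.array_equal(ens[0].values, single.values)

    def test_two_ensembles_same_base_seed_identical(self):
        model, _, _ = _decay_model(n=30)
        ts = [1.0]
        e1 = run_ensemble(model, 4, 1.0, 7, ts,
                          observables=[("Xa", Pattern([A("X", "s~a?")]))])
        e2 = run_ensemble(model, 4, 1.0, 7, ts,
                          observables=[("Xa", Pattern([A("X", "s~a?")]))])
        for a_t, b_t in zip(e1, e2):
            assert np.array_equal(a_t.values, b_t.values)

    def test_ensemble_mean_converges_to_closed_form(self):
        """Monte-Carlo error of the decay observable shrinks with the
        ensemble size."""
        model, n, k = _decay_model(n=20)
        target = np.exp(-1.0)
        errs = []
        for n_runs in (10, 200):
            ens = run_ensemble(model, n_runs, 1.0, 1234, [1.0],
                               observables=[("Xa",
                                             Pattern([A("X", "s~a?")]))])
            mean = np.mean([t.values[-1, 0] / 20 for t in ens])
            errs.append(abs(mean - target))
        assert errs[1] < errs[0]


class TestConservationAndValidation:
    def test_agent_counts_conserved_without_create_delete(self):
        """Rules that neither create nor delete agents leave every
        agent-type count constant along the trajectory."""
        a = AgentSignature("Ag", {"x": ()})
        b = AgentSignature("Bg", {"y": ()})
        bind = Rule("bind", [A("Ag", "x"), A("Bg", "y")],
                    [A("Ag", "x!1"), A("Bg", "y!1")], 2.0)
        unbind = Rule("unbind", [A("Ag", "x!1"), A("Bg", "y!1")],
                      [A("Ag", "x"), A("Bg", "y")], 3.0)
        model = Model([a, b], [bind, unbind], {"Ag": 4, "Bg": 3})
        traj = simulate(model, 20.0, 9, np.linspace(0, 20, 50),
                        validate_every=1)
        assert np.all(traj.values[:, traj.columns.index("Ag")] == 4)
        assert np.all(traj.values[:, traj.columns.index("Bg")] == 3)

    def test_validate_catches_asymmetric_bond(self, xsig):
        a = AgentSignature("Ag", {"x": ()})
        b = AgentSignature("Bg", {"y": ()})
        m = Mixture([a, b])
        g1, g2 = m.add_agent("Ag"), m.add_agent("Bg")
        g1.bonds["x"] = (g2.id, "y")   # deliberately corrupt: one-sided
        with pytest.raises(DefinitionError):
            m.validate()

    def test_render_round_trippable_syntax(self):
        rnap = AgentSignature("RNAPII", {"a": (), "ser5a": ("u", "p")})
        dna = AgentSignature("DNA", {"e1": ()})
        m = Mixture([rnap, dna])
        pol = m.add_agent("RNAPII", {"ser5a": "p"})
        d = m.add_agent("DNA")
        m.bind(pol.id, "a", d.id, "e1")
        text = m.render()
        assert "RNAPII(" in text and "ser5a~p" in text
        assert text.count("\n") == 1   # one agent per line


class TestCTMCOracle:
    def test_two_state_chain_matrix(self):
        a = AgentSignature("Ag", {"x": ()})
        b = AgentSignature("Bg", {"y": ()})
        bind = Rule("bind", [A("Ag", "x"), A("Bg", "y")],
                    [A("Ag", "x!1"), A("Bg", "y!1")], 2.0)
        unbind = Rule("unbind", [A("Ag", "x!1"), A("Bg", "y!1")],
                      [A("Ag", "x"), A("Bg", "y")], 1.0)
        model = Model([a, b], [bind, unbind], {"Ag": 1, "Bg": 1})
        states, i0, Q = enumerate_ctmc(model)
        assert len(states) == 2
        # hand-written generator of the 2-state chain
        assert np.allclose(Q, np.array([[-2.0, 2.0], [1.0, -1.0]]))

    def test_state_space_cap_enforced(self):
        model, _, _ = _decay_model(n=20)
        with pytest.raises(DefinitionError):
            enumerate_ctmc(model, max_states=10)


# ----------------------------------------------------------------------
# Property tests
# ----------------------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    n_a=st.integers(1, 4),
    n_b=st.integers(1, 4),
    seed=st.integers(0, 10_000),
    kon=st.floats(0.1, 5.0),
    koff=st.floats(0.1, 5.0),
)
def test_random_binding_dynamics_preserve_invariants(n_a, n_b, seed,
                                                     kon, koff):
    """For arbitrary copy numbers, rates and seeds, a bind/unbind/flip
    rule system keeps bond symmetry, single-site occupancy and agent
    counts intact at every event, and the bound count never exceeds
    min(#A, #B)."""
    a = AgentSignature("Ap", {"x": (), "s": ("u", "v")})
    b = AgentSignature("Bp", {"y": ()})
    rules = [
        Rule("bind", [A("Ap", "x"), A("Bp", "y")],
             [A("Ap", "x!1"), A("Bp", "y!1")], kon),
        Rule("unbind", [A("Ap", "x!1"), A("Bp", "y!1")],
             [A("Ap", "x"), A("Bp", "y")], koff),
        Rule("flip", [A("Ap", "s~u?", "x!_")], [A("Ap", "s~v?", "x?")], 1.0),
    ]
    model = Model([a, b], rules, {"Ap": n_a, "Bp": n_b})
    traj = simulate(model, 3.0, seed, [1.0, 2.0, 3.0], validate_every=1)
    bound = Pattern([A("Ap", "x!_")])
    mix = traj.final_mixture
    mix.validate()
    n_bound, _ = count_embeddings(bound, mix)
    assert n_bound <= min(n_a, n_b)
    assert mix.count("Ap") == n_a and mix.count("Bp") == n_b


@settings(max_examples=40, derandomize=True, deadline=None)
@given(k=st.integers(0, 5), n=st.integers(1, 6))
def test_embedding_count_of_independent_pattern_is_falling_factorial(k, n):
    """A pattern of k identical independent agents has n!/(n-k)!
    embeddings into n matching agents (ordered injections, no
    automorphism division)."""
    import math
    x = AgentSignature("X", {"s": ("a", "b")})
    m = Mixture([x])
    for _ in range(n):
        m.add_agent("X")
    pat = Pattern([A("X", "s~a?") for _ in range(k)])
    count, _ = count_embeddings(pat, m)
    expected = math.perm(n, k)
    assert count == expected
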
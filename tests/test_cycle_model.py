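import json
import math

import numpy as np
import pytest

from trap1cycle.cycle_model import (
    CycleRates,
    State,
    Variant,
    buckled_fraction,
    crystal_mode_timecourse,
    enumerate_states,
    simulate_master,
    simulate_ssa,
    single_turnover_fraction,
    transitions,
)

WT = Variant.wild_type()
E115A = Variant.het_hydrolysis_dead()
R402A = Variant.het_sensor_broken()


def absorbing_states(graph):
    has_out = {i for i, _, rate, _ in graph.edges if rate > 0}
    return [s for i, s in enumerate(graph.states) if i not in has_out]


class TestVariants:
    def test_double_pinning_rejected(self):
        from trap1cycle.cycle_model import ProtomerSpec

        with pytest.raises(ValueError, match="pinning"):
            Variant((ProtomerSpec(gamma_sensor_intact=False),
                     ProtomerSpec(gamma_sensor_intact=False)))

    def test_single_label_enforced(self):
        from trap1cycle.cycle_model import ProtomerSpec

        with pytest.raises(ValueError, match="label"):
            Variant((ProtomerSpec(labeled=True), ProtomerSpec(labeled=True)))


class TestStateGraph:
    def test_wild_type_enumeration(self):
        """The +/+ graph holds exactly the expected distinguishable states."""
        graph = enumerate_states(CycleRates.mg(), WT)
        expected = {State("open", ("T", "T"), None)}
        for b in (0, 1):
            expected.add(State("closed", ("T", "T"), b))
        # hemi pre-flip (ADP on the buckled arm) and post-flip, both arms
        expected |= {
            State("closed", ("D", "T"), 0), State("closed", ("D", "T"), 1),
            State("closed", ("T", "D"), 1), State("closed", ("T", "D"), 0),
        }
        expected |= {State("closed", ("D", "D"), 0), State("closed", ("D", "D"), 1)}
        assert set(graph.states) == expected
        assert not absorbing_states(graph)

    def test_dead_buckled_arm_has_no_hydrolysis_edge(self):
        """No hydrolysis can fire from states where the dead protomer is the
        buckled ATP carrier, and the hemi state is absorbing without a leak."""
        graph = enumerate_states(CycleRates.mg(), E115A)
        for i, j, rate, tag in graph.edges:
            if tag == "hyd":
                s = graph.states[i]
                assert s.buckled == 0  # only the competent protomer hydrolyzes
        absorbing = absorbing_states(graph)
        assert len(absorbing) == 1
        (hemi,) = absorbing
        assert hemi.conf == "closed" and hemi.n_adp == 1
        # post-flip: ATP sits on the (dead) buckled arm, ADP on the straight
        assert hemi.nuc[hemi.buckled] == "T" and hemi.buckled == 1

    def test_sensor_broken_always_straight(self):
        graph = enumerate_states(CycleRates.mg(), R402A)
        for s in graph.states:
            if s.conf == "closed":
                assert s.buckled == 0  # the intact protomer is always buckled

    def test_graph_json_round_trip(self):
        graph = enumerate_states(CycleRates.mg(), WT)
        doc = json.loads(graph.to_json())
        assert len(doc["states"]) == graph.n
        assert len(doc["edges"]) == len(graph.edges)

    def test_instantaneous_flip_skips_preflip_state(self):
        graph = enumerate_states(CycleRates.mg(k_flip=math.inf), WT)
        for s in graph.states:
            if s.conf == "closed" and s.n_adp == 1:
                # with the flip folded into hydrolysis, ADP is always straight
                assert s.nuc[s.buckled] == "T"


class TestMasterEquation:
    def test_initial_occupancy_is_initial_distribution(self):
        res = simulate_master(CycleRates.mg(), WT, [0.0, 1.0])
        assert np.allclose(res.occupancy[0], res.graph.initial)

    def test_two_state_closed_form(self):
        """With hydrolysis and reopening off the model is open<->closed."""
        r = CycleRates.mg(k_hyd_buckled=0.0, k_open_dd=0.0)
        t = np.linspace(0, 40, 81)
        res = simulate_master(r, WT, t)
        assert np.allclose(res.fraction_closed, 1.0 - np.exp(-r.k_close * t), atol=1e-10)

    def test_probability_conservation(self):
        for variant in (WT, E115A, R402A):
            res = simulate_master(CycleRates.mg(k_open_leak=0.01), variant,
                                  np.linspace(0, 60, 40))
            assert np.max(np.abs(res.occupancy.sum(axis=1) - 1.0)) <= 1e-9

    def test_cumulative_pi_non_decreasing(self):
        res = simulate_master(CycleRates.mg(), WT, np.linspace(0, 60, 200))
        assert np.all(np.diff(res.cum_pi) >= -1e-12)

    def test_single_turnover_pi_equals_adp_count(self):
        """Without turnover resets, cumulative Pi = number of ADP produced."""
        res = simulate_master(CycleRates.mg(), WT, np.linspace(0, 120, 400), mode="single")
        # cum_pi integrates the hydrolysis flux numerically, so allow a
        # small quadrature tolerance against the exact ADP count
        assert np.allclose(res.cum_pi, 2.0 * res.hydrolyzed_fraction, atol=1e-2)


class TestSSA:
    def test_reproducible_under_seed(self):
        a = simulate_ssa(CycleRates.mg(), WT, 200, 20.0, seed=42)
        b = simulate_ssa(CycleRates.mg(), WT, 200, 20.0, seed=42)
        assert np.array_equal(a.occupancy, b.occupancy)
        assert np.array_equal(a.cum_pi, b.cum_pi)

    def test_absorbing_state_pads_constant(self):
        res = simulate_ssa(CycleRates.mg(), Variant.dead_dead(), 50, 200.0, seed=0,
                           mode="single")
        # all dimers close and then stick in Closed(T,T): occupancy constant late
        assert res.fraction_closed[-1] == 1.0
        assert res.hydrolyzed_fraction[-1] == 0.0

    def test_agrees_with_master_equation(self):
        """SSA occupancies match the master equation within Monte-Carlo error."""
        n = 4000
        for variant in (WT, E115A):
            ssa = simulate_ssa(CycleRates.mg(), variant, n, 30.0, seed=7, n_times=31)
            mas = simulate_master(CycleRates.mg(), variant, ssa.times)
            se = np.sqrt(np.clip(mas.occupancy * (1 - mas.occupancy), 0, None) / n)
            assert np.all(np.abs(ssa.occupancy - mas.occupancy) <= 3 * se + 5e-3)

    def test_sequentiality_invariant(self):
        """The second hydrolysis never precedes the flip in any trajectory."""
        res = simulate_ssa(CycleRates.mg(), WT, 300, 60.0, seed=3, record_events=True)
        for events in res.events:
            hyd_times = [t for t, tag, _ in events if tag == "hyd"]
            flip_times = [t for t, tag, _ in events if tag == "flip"]
            # pair events per cycle: each 2nd hydrolysis must follow a flip
            n_cycles = len(hyd_times) // 2
            for c in range(n_cycles):
                second = hyd_times[2 * c + 1]
                assert any(hyd_times[2 * c] < f < second for f in flip_times)


class TestSingleTurnover:
    @pytest.mark.parametrize(
        "variant,asymptote",
        [(WT, 1.0), (E115A, 0.5), (Variant.dead_dead(), 0.0)],
    )
    def test_asymptotes(self, variant, asymptote):
        res = single_turnover_fraction(CycleRates.mg(), variant, t_max=300.0)
        assert res.hydrolyzed_fraction[-1] == pytest.approx(asymptote, abs=1e-3)

    def test_leak_adds_slow_phase(self):
        """A reopening leak lets the +/dead heterodimer slowly pass 0.5."""
        leak = single_turnover_fraction(
            CycleRates.mg(k_open_leak=0.01), E115A, t_max=400.0, n_times=400
        )
        tight = single_turnover_fraction(CycleRates.mg(), E115A, t_max=400.0, n_times=400)
        assert tight.hydrolyzed_fraction[-1] == pytest.approx(0.5, abs=1e-3)
        assert leak.hydrolyzed_fraction[-1] > 0.6
        # the late phase is slow compared to the fast first phase
        mid = leak.hydrolyzed_fraction[len(leak.times) // 8]
        assert 0.45 < mid < 0.65


class TestCrystalMode:
    def test_straight_rate_zero_means_no_dd(self):
        r = CycleRates.mg(k_hyd_buckled=1.0, k_hyd_straight=0.0, time_unit="day")
        df = crystal_mode_timecourse(r, [1.0, 3.0, 53.0])
        assert np.allclose(df["P_DD"], 0.0)

    def test_species_ordering_and_t_on_straight(self):
        """Dominant species progress TT -> TD -> DD; the intermediate keeps
        its remaining ATP on the straight arm."""
        r = CycleRates.mg(k_hyd_buckled=0.7, k_hyd_straight=0.05, time_unit="day")
        df = crystal_mode_timecourse(r, [1.0, 3.0, 53.0])
        assert df.loc[2, "dominant"] == "DD"
        assert df.loc[1, "dominant"] == "TD"
        assert df.loc[0, "P_TT"] > df.loc[1, "P_TT"] > df.loc[2, "P_TT"]
        assert (df["P_T_on_straight_given_TD"].dropna() > 0.9).all()

    def test_first_conversion_split_matches_competing_exponentials(self):
        """P(first conversion on the straight arm) = k_s/(k_s+k_b)."""
        k_b, k_s = 0.7, 0.2
        r = CycleRates.mg(k_hyd_buckled=k_b, k_hyd_straight=k_s, time_unit="day")
        df = crystal_mode_timecourse(r, [1e-5])
        p_t_straight = df.loc[0, "P_T_on_straight_given_TD"]
        # T remains on the straight arm iff the buckled arm converted first
        assert p_t_straight == pytest.approx(k_b / (k_b + k_s), abs=1e-4)


class TestBuckledFraction:
    def test_wild_type_is_half(self):
        res = simulate_master(CycleRates.mg(), WT, np.linspace(0, 30, 61))
        assert buckled_fraction(res, "closed_tt") == pytest.approx(0.5, abs=1e-9)

    def test_sensor_broken_pinning(self):
        res = simulate_master(CycleRates.mg(), Variant.het_sensor_broken(labeled=0),
                              np.linspace(0, 30, 61))
        assert buckled_fraction(res, "closed") == pytest.approx(1.0)
        res = simulate_master(CycleRates.mg(), Variant.het_sensor_broken(labeled=1),
                              np.linspace(0, 30, 61))
        assert buckled_fraction(res, "closed") == pytest.approx(0.0)

    def test_unlabeled_variant_rejected(self):
        res = simulate_master(CycleRates.mg(), Variant.wild_type(labeled=None),
                              np.linspace(0, 10, 11))
        with pytest.raises(ValueError, match="label"):
            buckled_fraction(res, "closed_tt")

    def test_empty_class_is_none(self):
        res = simulate_master(CycleRates.mg(), Variant.het_hydrolysis_dead(), [0.0, 1.0])
        assert buckled_fraction(res, "dd") is None


class TestRegimeOrderings:
    def test_heterodimer_accumulates_closed_under_turnover(self):
        """+/dead builds up the closed state while +/+ keeps cycling low."""
        t = np.linspace(0, 40, 81)
        wt = simulate_master(CycleRates.mg(), WT, t)
        het = simulate_master(CycleRates.mg(), E115A, t)
        assert het.fraction_closed[-1] > 0.99
        assert wt.fraction_closed[-1] < 0.35
        assert np.all(het.fraction_closed[1:] >= wt.fraction_closed[1:])

    def test_heterodimer_buildup_rate_is_k_close(self):
        """With nothing returning to the open state, +/dead closure is a
        clean exponential at k_close."""
        r = CycleRates.mg()
        t = np.linspace(0, 40, 81)
        het = simulate_master(r, E115A, t)
        assert np.allclose(het.fraction_closed, 1 - np.exp(-r.k_close * t), atol=1e-9)

    def test_heterodimer_reopens_slower_after_synchronized_closure(self):
        """From a synchronized closed start, +/+ reopens but +/dead stays closed."""
        t = np.linspace(0, 10, 51)
        leak = 0.01
        wt = simulate_master(CycleRates.mg(k_open_leak=leak), WT, t, initial="closed_tt")
        het = simulate_master(CycleRates.mg(k_open_leak=leak), E115A, t, initial="closed_tt")
        assert wt.fraction_closed[-1] < 0.3
        assert het.fraction_closed[-1] > 0.9
        # the residual reopening is slower by at least k_open_leak/k_open_dd
        ratio = (1 - het.fraction_closed[-1]) / (1 - wt.fraction_closed[-1])
        assert ratio < leak / CycleRates.mg().k_open_dd * 50

    def test_mg_free_defaults_use_printed_rates(self):
        r = CycleRates.mg_free()
        assert r.k_close == pytest.approx(6.95)
        assert r.k_hyd_buckled == pytest.approx(0.5808)
        assert r.time_unit == "hr"
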
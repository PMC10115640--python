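import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cftrgate.gating_model import (
    GatingState,
    Protocol,
    RateSet,
    _RATE_FIELDS,
    _stationary_pi,
    build_topology,
    class_switch_frequency,
    mean_class_dwell,
    occupancy_relaxation,
    simulate_ssa,
    stationary_distribution,
)

ATP = 3e-3


class TestTopology:
    def test_nine_states_thirteen_transitions(self, wt_graph):
        assert wt_graph.n_states == 9
        edges = [e for e in wt_graph.edges(ATP) if e[3] > 0]
        assert len(edges) == 13

    def test_conducting_states_are_dimerized(self, wt_graph):
        for s in wt_graph.states:
            if s.pore_conducting:
                assert s.nbd_class == "dimerized"
        with pytest.raises(ValueError):
            GatingState("bad", "separated", True)

    def test_e1371q_same_graph_no_hydrolysis(self, wt_rates):
        g = build_topology("E1371Q", rates=wt_rates)
        assert [s.name for s in g.states] == [
            s.name for s in build_topology("WT", rates=wt_rates).states]
        assert g.rates.k3 <= 1e-6
        path = simulate_ssa(g, Protocol(duration_s=500.0), seed=1)
        assert len(path.hydrolysis_events) == 0

    def test_unknown_variant_and_negative_override_rejected(self, wt_rates):
        with pytest.raises(ValueError):
            build_topology("G550E", rates=wt_rates)
        with pytest.raises(ValueError):
            build_topology("WT", overrides={"k2": -1.0}, rates=wt_rates)
        with pytest.raises(ValueError):
            build_topology("WT", overrides={"k99": 1.0}, rates=wt_rates)

    def test_dephosphorylated_blocks_dimerization(self, wt_rates):
        g = build_topology("WT", rates=wt_rates, phosphorylated=False)
        q = g.generator(ATP)
        i, j = g.index("SEP_atp"), g.index("DIM_closed")
        assert q[i, j] == 0.0


class TestGenerator:
    @pytest.mark.parametrize("variant", ["WT", "E1371Q", "W401A", "Y1219A",
                                         "G551D", "L927P"])
    @pytest.mark.parametrize("atp", [1e-6, 5e-5, 3e-3])
    def test_rows_sum_to_zero(self, variant, atp, wt_rates):
        q = build_topology(variant, rates=wt_rates).generator(atp)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-10)
        off = q[~np.eye(len(q), dtype=bool)]
        assert (off >= 0).all()

    @given(st.lists(st.floats(-2, 2), min_size=13, max_size=13))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_stationary_normalized_nonnegative(self, log_scale):
        base = RateSet.wt_calibrated()
        rates = RateSet.from_dict({
            n: getattr(base, n) * 10.0 ** s
            for n, s in zip(_RATE_FIELDS, log_scale)})
        g = build_topology("WT", rates=rates)
        res = stationary_distribution(g, ATP)
        assert res.pi.min() >= -1e-10
        assert abs(res.pi.sum() - 1.0) < 1e-10

    def test_two_state_symmetric_stationary(self):
        q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        assert np.allclose(_stationary_pi(q), [0.5, 0.5])

    def test_four_state_cycle_matches_ssa_fractions(self, wt_rates):
        # irreversible 4-cycle with rates (1,2,3,4): closed-form occupancy
        # is proportional to the holding times 1/k_i
        k = np.array([1.0, 2.0, 3.0, 4.0])
        q = np.zeros((4, 4))
        for i in range(4):
            q[i, (i + 1) % 4] = k[i]
            q[i, i] = -k[i]
        pi = _stationary_pi(q)
        expected = (1 / k) / (1 / k).sum()
        assert np.allclose(pi, expected, atol=1e-12)

    def test_stationary_requires_positive_atp(self, wt_graph):
        with pytest.raises(ValueError):
            stationary_distribution(wt_graph, 0.0)


class TestStationaryObservables:
    def test_calibrated_po_and_pdim(self, wt_graph):
        res = stationary_distribution(wt_graph, ATP)
        assert res.po == pytest.approx(0.22, abs=0.01)
        assert res.pdim == pytest.approx(0.85, abs=0.02)

    def test_po_monotone_in_atp(self, wt_graph):
        po = [stationary_distribution(wt_graph, c).po
              for c in np.geomspace(1e-6, 3e-3, 12)]
        assert all(b > a for a, b in zip(po, po[1:]))

    def test_cycle_flux_positive_and_zero_without_hydrolysis(self, wt_graph,
                                                            wt_rates):
        assert stationary_distribution(wt_graph, ATP).turnover_per_s > 0
        g0 = build_topology("WT", overrides={"k3": 0.0}, rates=wt_rates)
        assert stationary_distribution(g0, ATP).turnover_per_s == 0.0

    def test_switch_frequency_bell_shaped(self, wt_graph):
        f_low = class_switch_frequency(wt_graph, 5e-6)
        f_mid = max(class_switch_frequency(wt_graph, c)
                    for c in (5e-5, 1e-4))
        f_sat = class_switch_frequency(wt_graph, 3e-3)
        assert f_mid > f_low
        assert f_mid > f_sat


class TestRelaxation:
    def test_stationary_initial_is_flat(self, wt_graph):
        pi = stationary_distribution(wt_graph, ATP).pi
        relax = occupancy_relaxation(wt_graph, pi, ATP, 5.0, 0.05)
        assert np.allclose(relax.po, relax.po[0], atol=1e-9)
        assert np.allclose(relax.pdim, relax.pdim[0], atol=1e-9)

    def test_two_state_closed_form_time_constant(self, wt_rates):
        # separated pool of the dephosphorylated channel: a pure two-state
        # chain with rates k_bind*atp and k_unbind, tau = 1/(sum)
        g = build_topology("WT", rates=wt_rates, phosphorylated=False)
        atp = 1e-3
        k12 = wt_rates.k_bind * atp
        k21 = wt_rates.k_unbind
        p0 = np.zeros(9)
        p0[g.index("SEP_apo")] = 1.0
        relax = occupancy_relaxation(g, p0, atp, 0.5, 1e-4)
        bound = relax.occupancy[:, g.index("SEP_atp")]
        p_inf = k12 / (k12 + k21)
        expected = p_inf * (1 - np.exp(-(k12 + k21) * relax.times))
        assert np.allclose(bound, expected, atol=1e-6)

    def test_rejects_unnormalized_initial(self, wt_graph):
        with pytest.raises(ValueError):
            occupancy_relaxation(wt_graph, np.full(9, 0.2), ATP, 1.0, 0.01)


class TestSsa:
    def test_absorbing_state_single_segment(self, wt_rates):
        g = build_topology("WT", rates=wt_rates, phosphorylated=False)
        protocol = Protocol(duration_s=50.0, atp_schedule=((0.0, 0.0),),
                            phosphorylated=False)
        path = simulate_ssa(g, protocol, seed=3)
        assert len(path.states) == 1
        assert path.dwell_s[0] == pytest.approx(50.0)

    def test_two_state_dwell_means(self, wt_rates):
        # dephosphorylated separated pool: forward 2/s, backward 1/s
        rates = wt_rates.replace(k_bind=1000.0, k_unbind=1.0)
        g = build_topology("WT", rates=rates, phosphorylated=False)
        protocol = Protocol(duration_s=7000.0, atp_schedule=((0.0, 2e-3),),
                            phosphorylated=False)
        path = simulate_ssa(g, protocol, seed=11)
        apo = path.dwell_s[:-1][path.states[:-1] == g.index("SEP_apo")]
        bound = path.dwell_s[:-1][path.states[:-1] == g.index("SEP_atp")]
        assert len(apo) > 3000
        for sample, mean in ((apo, 0.5), (bound, 1.0)):
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            assert abs(sample.mean() - mean) < 3 * se

    def test_determinism(self, wt_graph):
        p1 = simulate_ssa(wt_graph, Protocol(duration_s=100.0), seed=42)
        p2 = simulate_ssa(wt_graph, Protocol(duration_s=100.0), seed=42)
        assert np.array_equal(p1.states, p2.states)
        assert np.array_equal(p1.dwell_s, p2.dwell_s)
        assert np.array_equal(p1.hydrolysis_events, p2.hydrolysis_events)

    def test_segments_tile_duration(self, wt_path_2000s):
        p = wt_path_2000s
        assert p.entry_s[0] == 0.0
        assert np.allclose(p.entry_s[1:], p.entry_s[:-1] + p.dwell_s[:-1])
        assert p.duration_s == pytest.approx(2000.0)
        assert (np.diff(p.states) != 0).all()

    def test_time_fractions_match_stationary(self, wt_graph, wt_path_2000s):
        pi = stationary_distribution(wt_graph, ATP).pi
        frac = wt_path_2000s.state_time_fractions()
        # 3-standard-error agreement on the aggregate occupancies
        for members in (wt_graph.dimer_set, wt_graph.open_set):
            got = frac[list(members)].sum()
            want = pi[list(members)].sum()
            assert abs(got - want) < 0.04

    def test_dwells_exponential_with_outflow_rate(self, wt_graph):
        path = simulate_ssa(wt_graph, Protocol(duration_s=10000.0), seed=5)
        q = wt_graph.generator(ATP)
        i_pre = wt_graph.index("OPEN_pre")
        dwells = path.dwell_s[:-1][path.states[:-1] == i_pre]
        assert len(dwells) >= 5000
        ks = stats.kstest(dwells, "expon", args=(0, 1.0 / -q[i_pre, i_pre]))
        assert ks.pvalue > 0.01

    def test_atp_withdrawal_stops_hydrolysis(self, wt_graph):
        protocol = Protocol(duration_s=400.0,
                            atp_schedule=((0.0, ATP), (200.0, 0.0)))
        path = simulate_ssa(wt_graph, protocol, seed=9)
        late = path.hydrolysis_events[path.hydrolysis_events > 210.0]
        assert len(late) == 0

    def test_e1371q_high_fret_sojourn_exceeds_wt(self, wt_graph, wt_rates,
                                                 wt_path_2000s):
        from cftrgate.kinetics import extract_dwells

        ge = build_topology("E1371Q", rates=wt_rates)
        pe = simulate_ssa(ge, Protocol(duration_s=2000.0), seed=20230322)
        amap = {ge.states[i].name: "dim" for i in ge.dimer_set}
        mean_e = extract_dwells(pe, amap).data.dwell_s.mean()
        mean_wt = extract_dwells(wt_path_2000s, amap).data.dwell_s.mean()
        assert len(pe.hydrolysis_events) == 0
        assert mean_e > mean_wt


class TestFirstPassage:
    def test_mean_dwell_matches_ssa(self, wt_graph, wt_path_2000s):
        from cftrgate.kinetics import extract_dwells

        amap = {wt_graph.states[i].name: "dim" for i in wt_graph.dimer_set}
        table = extract_dwells(wt_path_2000s, amap)
        ssa_mean = table.mean_dwell("dim")
        det_mean = mean_class_dwell(wt_graph, ATP, wt_graph.dimer_set)
        n = (~table.data.censored).sum()
        se = table.dwells("dim").std(ddof=1) / np.sqrt(n)
        assert abs(ssa_mean - det_mean) < 3 * se

    def test_bridging_extends_burst(self, wt_graph):
        plain = mean_class_dwell(wt_graph, ATP, wt_graph.open_set)
        bridged = mean_class_dwell(wt_graph, ATP, wt_graph.open_set,
                                   bridge_s=0.010)
        assert bridged > plain


class TestProtocol:
    def test_validation(self):
        with pytest.raises(ValueError):
            Protocol(duration_s=0.0)
        with pytest.raises(ValueError):
            Protocol(duration_s=1.0, atp_schedule=())
        with pytest.raises(ValueError):
            Protocol(duration_s=1.0, atp_schedule=((0.5, 1e-3),))
        with pytest.raises(ValueError):
            Protocol(duration_s=1.0, atp_schedule=((0.0, 1e-3), (0.0, 0.0)))

    def test_atp_at(self):
        p = Protocol(duration_s=10.0, atp_schedule=((0.0, 1e-3), (5.0, 0.0)))
        assert p.atp_at(0.0) == 1e-3
        assert p.atp_at(4.999) == 1e-3
        assert p.atp_at(5.0) == 0.0
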
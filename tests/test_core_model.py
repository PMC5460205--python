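"""Unit and property tests for the signaling/growth core model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapkqsp.core_model import (ConstantConcentration, Genotype, NetworkState,
                                NoDrug, SignalingParams, TargetSuppression,
                                apply_genotype, equilibrate, evaluate_cascade,
                                hill, simulate_invitro_growth,
                                simulate_perk_timecourse, simulate_system,
                                DRUG_NODES, NODE_ORDER)


# ---------------------------------------------------------------------------
# cascade algebra


class TestEvaluateCascade:
    def test_zero_feedback_zero_drug_gives_maximal_rtk1(self, base_params):
        nodes = evaluate_cascade(base_params, feedback_state=(0, 0, 0, 0))
        assert nodes["RTK1"] == pytest.approx(base_params.RTK1t)

    def test_erki_at_halfmax_halves_erk(self, base_params):
        p = base_params.replace(ki4=1.0)
        fb = (0.3, 0.25, 0.4, 0.2)
        free = evaluate_cascade(p, feedback_state=fb)
        dosed = evaluate_cascade(p, {"ERK": p.taui4}, feedback_state=fb)
        assert dosed["ERK"] == pytest.approx(0.5 * free["ERK"], rel=1e-12)

    def test_v600e_braf_signals_at_basal_without_ras(self):
        p = apply_genotype(SignalingParams(), Genotype(("BRAF_V600E",)))
        p = p.replace(RTK1t=1e-12, RTK1b=0.0, RTK2t=1e-12, RASb=1e-12)
        nodes = evaluate_cascade(p, feedback_state=(0, 0, 0, 0))
        assert nodes["RAS"] == pytest.approx(0.0, abs=1e-6)
        assert nodes["BRAF"] == pytest.approx(0.9, abs=1e-6)

    def test_negative_concentration_rejected(self, base_params):
        with pytest.raises(ValueError, match="negative concentration"):
            evaluate_cascade(base_params, {"ERK": -1.0})

    def test_unknown_drug_node_rejected(self, base_params):
        with pytest.raises(ValueError, match="unknown drug target"):
            evaluate_cascade(base_params, {"AKT": 1.0})

    def test_zero_concentration_bitwise_equals_drug_free(self, base_params):
        fb = (0.2, 0.1, 0.5, 0.3)
        free = evaluate_cascade(base_params, feedback_state=fb)
        for node in DRUG_NODES:
            dosed = evaluate_cascade(base_params, {node: 0.0},
                                     feedback_state=fb)
            assert dosed[node] == free[node]  # exact, not approximate

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 9))
    def test_activities_bounded_for_random_inputs(self, seed):
        """Every node lies in [0, Nt] for admissible parameters/inputs."""
        r = np.random.default_rng(seed)
        p = SignalingParams(
            tau1=r.uniform(0.05, 3), tau2=r.uniform(0.05, 3),
            tau3=r.uniform(0.05, 3), tau4=r.uniform(0.05, 3),
            k1=r.uniform(0.5, 5), k3=r.uniform(0.5, 5),
            RASb=r.uniform(0, 0.5), MEKb=r.uniform(0, 0.5),
            wOR=r.uniform(0, 1), wRAS=r.uniform(0, 1),
            G13=r.uniform(0, 1), Gdusp=r.uniform(0, 1),
            Gspry=r.uniform(0, 1),
        )
        fb = r.uniform(0, 2, size=4)
        conc = {n: r.uniform(0, 10) for n in DRUG_NODES}
        nodes = evaluate_cascade(p, conc, feedback_state=fb)
        d = p.to_dict()
        for name in NODE_ORDER:
            assert -1e-12 <= nodes[name] <= d[name + "t"] + 1e-12


class TestGenotype:
    def test_tissue_sets_maximal_egfr(self, base_params):
        mel = apply_genotype(base_params, Genotype(tissue="melanoma"))
        crc = apply_genotype(base_params, Genotype(tissue="CRC"))
        assert mel.RTK1t == 0.1 and crc.RTK1t == 1.0

    def test_mek_mutation_sets_basal_activity(self, base_params):
        p = apply_genotype(base_params, Genotype(("MEK_mut",)))
        assert p.MEKb == 0.9

    def test_amplifications(self, base_params):
        p = apply_genotype(base_params, Genotype(("BRAF_amp", "KRAS_amp")))
        assert p.BRAFt == 5.0 and p.RASt == 5.0

    def test_empty_genotype_is_identity(self, base_params):
        assert apply_genotype(base_params, Genotype()) == base_params

    def test_unknown_genotype_lists_known(self):
        with pytest.raises(ValueError, match="BRAF_V600E"):
            Genotype(mutations=("BRAF_X",))

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            SignalingParams(MEKb=1.5, MEKt=1.0)
        with pytest.raises(ValueError):
            SignalingParams(wOR=1.2)
        with pytest.raises(ValueError):
            SignalingParams(tau4=-0.1)


# ---------------------------------------------------------------------------
# dynamics


def _fixed_point_oracle(params, suppression=None, iters=8000, damping=0.05):
    """Independent damped iteration on the full stationarity system, using
    only the public cascade evaluation."""
    fb = np.zeros(4)
    for _ in range(iters):
        nodes = evaluate_cascade(params, feedback_state=fb,
                                 suppression=suppression)
        target = np.array([nodes["ERK"], nodes["ERK"], nodes["ERK"],
                           nodes["AKT"]])
        fb = fb + damping * (target - fb)
    nodes = evaluate_cascade(params, feedback_state=fb,
                             suppression=suppression)
    return fb, nodes


class TestSimulateSystem:
    def test_fixed_point_stays_stationary(self, crc_params):
        fb, nodes = _fixed_point_oracle(crc_params)
        st0 = NetworkState(fb=fb, td1=nodes["S6"], cells=1.0)
        traj = simulate_system(crc_params, NoDrug(), (0.0, 10.0),
                               initial_state=st0)
        assert np.allclose(traj.fb, fb[None, :], atol=1e-5)
        assert np.allclose(traj.td1, nodes["S6"], atol=1e-5)

    def test_trajectory_limit_matches_fixed_point_oracle(self, crc_params):
        traj = simulate_system(crc_params, NoDrug(), (0.0, 120.0))
        fb, nodes = _fixed_point_oracle(crc_params)
        assert np.allclose(traj.fb[-1], fb, rtol=1e-6, atol=1e-8)
        assert traj.td1[-1] == pytest.approx(nodes["S6"], rel=1e-6)

    def test_exponential_growth_limit_without_death(self, base_params):
        """With death off, TD1 saturating and CELLS << VMAX the logistic
        equation reduces to exponential growth at muMAX*Hill(TD1)."""
        p = base_params.replace(deltaMAX=1e-12, VMAX=1e9)
        td1 = 50.0 * p.taug
        st0 = NetworkState(fb=np.full(4, 10.0), td1=td1, cells=1.0)
        p2 = p.replace(r1=1e-9, r2=1e-9, r3=1e-9, r4=1e-9, r5=1e-9)
        traj = simulate_system(p2, NoDrug(), (0.0, 3.0), initial_state=st0)
        rate = p.muMAX * (td1 ** p.kg) / (p.taug ** p.kg + td1 ** p.kg)
        assert traj.cells[-1] == pytest.approx(np.exp(rate * 3.0), rel=1e-4)

    def test_carrying_capacity_is_stationary(self, crc_params):
        p = crc_params.replace(VMAX=5.0)
        st0 = equilibrate(p, cells0=5.0)
        traj = simulate_system(p, NoDrug(), (0.0, 20.0), initial_state=st0)
        assert np.allclose(traj.cells, 5.0, rtol=1e-8)

    def test_cells_bounded_by_vmax_and_positive(self, crc_params):
        p = crc_params.replace(VMAX=10.0)
        st0 = equilibrate(p, cells0=1.0)
        traj = simulate_system(p, NoDrug(), (0.0, 200.0), initial_state=st0)
        assert np.all(traj.cells > 0)
        assert np.all(traj.cells <= 10.0 * (1.0 + 1e-6))

    def test_transit_states_track_drivers_at_fast_rates(self, crc_params):
        p = crc_params.replace(r1=1e4, r2=1e4, r3=1e4, r4=1e4)
        st0 = equilibrate(p)
        traj = simulate_system(p, TargetSuppression({"MEK": 0.6}),
                               (0.0, 2.0), initial_state=st0, atol=1e-12)
        # after burn-in FB states equal their algebraic drivers
        for i in range(120, len(traj.t)):
            assert abs(traj.fb[i, 0] - traj.nodes["ERK"][i]) < 1e-3
            assert abs(traj.fb[i, 3] - traj.nodes["AKT"][i]) < 1e-3

    def test_bad_initial_cells_rejected(self, base_params):
        with pytest.raises(ValueError, match="CELLS"):
            simulate_system(base_params,
                            initial_state=NetworkState(
                                fb=np.zeros(4), td1=0.0, cells=0.0))


class TestPerkTimecourse:
    def test_no_feedback_means_no_rebound(self, crc_params):
        p = crc_params.replace(G13=1e-12, Gdusp=1e-12, Gspry=1e-12)
        t, perk = simulate_perk_timecourse(p, 0.95)
        # approaches a new plateau with no non-monotonic rebound beyond
        # integrator tolerance
        assert perk[-1] / perk.min() == pytest.approx(1.0, abs=1e-3)
        assert np.all(np.diff(perk) <= 1e-4)

    def test_rebound_in_crc_but_not_melanoma(self, crc_params,
                                             melanoma_params):
        t, perk = simulate_perk_timecourse(crc_params, 0.95)
        min24 = perk[t <= 24.0].min()
        assert perk[-1] > min24 + 0.05      # CRC rebounds by 48 h
        t, perk_m = simulate_perk_timecourse(melanoma_params, 0.95)
        # melanoma stays near its minimum (absolute rebound < 5% of baseline)
        assert perk_m[-1] - perk_m[t <= 24.0].min() < 0.05

    def test_non_equilibrated_initial_state_rejected(self, crc_params):
        bad = NetworkState(fb=np.array([0.9, 0.0, 0.2, 0.8]), td1=0.0,
                           cells=1.0)
        with pytest.raises(ValueError, match="steady state"):
            simulate_perk_timecourse(crc_params, 0.95, initial_state=bad)

    def test_invalid_suppression_rejected(self, crc_params):
        with pytest.raises(ValueError):
            simulate_perk_timecourse(crc_params, 1.0)


class TestInvitroGrowth:
    def test_drug_free_fold_matches_quadrature_oracle(self, crc_params):
        """At steady state and CELLS << VMAX, growth is exponential at
        muMAX*Hill(S6_ss) - deltaMAX (independent quadrature oracle)."""
        fold = simulate_invitro_growth(crc_params)
        _, nodes = _fixed_point_oracle(crc_params)
        s6 = nodes["S6"]
        rate = crc_params.muMAX * float(hill(s6, crc_params.taug,
                                             crc_params.kg)) \
            - crc_params.deltaMAX
        assert fold == pytest.approx(np.exp(rate * 3.0), rel=1e-3)

    def test_erki_suppresses_growth_across_genotype_panel(self, fitted_params):
        genos = [Genotype(("BRAF_V600E",), "CRC"),
                 Genotype(("BRAF_V600E", "MEK_mut"), "CRC"),
                 Genotype(("BRAF_V600E", "BRAF_amp"), "CRC"),
                 Genotype(("BRAF_V600E", "KRAS_amp"), "CRC")]
        for g in genos:
            p = apply_genotype(fitted_params, g)
            ctrl = simulate_invitro_growth(p)
            erki = simulate_invitro_growth(
                p, TargetSuppression({"ERK": 0.95}))
            assert erki < ctrl

    def test_lower_mapk_dependence_raises_viability(self, fitted_params):
        """Reducing wOR 1.0 -> 0.85 increases mean viability for each MAPKi."""
        crc = apply_genotype(fitted_params, Genotype(("BRAF_V600E",), "CRC"))
        for node in ("BRAF", "MEK", "ERK"):
            viab = {}
            for wor in (1.0, 0.85):
                p = crc.replace(wOR=wor)
                ctrl = simulate_invitro_growth(p)
                drugged = simulate_invitro_growth(
                    p, TargetSuppression({node: 0.95}))
                viab[wor] = drugged / ctrl
            assert viab[0.85] > viab[1.0]
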
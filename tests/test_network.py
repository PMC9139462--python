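"""Structure of the reaction network, condition logic, and the simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import erbbsig as e
from erbbsig.network import DIMERS, LIGAND_DIMER_COMPAT
from erbbsig.simulate import _rhs

GROUP_SIZES = {"A": 6, "B": 4, "C": 4, "D": 4, "E": 3, "F": 3, "G": 1,
               "H": 6, "I": 3, "J": 3, "K": 2, "L": 2, "M": 3}


class TestBuildNetwork:
    def test_state_and_reaction_counts(self):
        net = e.build_network()
        assert len(net.species) == 22
        assert len(net.reactions) == 44

    def test_reaction_groups(self):
        net = e.build_network()
        sizes = {}
        for r in net.reactions:
            sizes[r.group] = sizes.get(r.group, 0) + 1
        assert sizes == GROUP_SIZES

    def test_structural_closure(self):
        # every educt/product/pool member is a declared species
        e.build_network().validate()

    def test_dimer_formation_consumes_monomers(self):
        net = e.build_network()
        for r in net.reactions:
            if r.group in ("B", "C"):
                (dimer,) = r.products
                from erbbsig.network import DIMER_COMPOSITION
                assert r.educts == DIMER_COMPOSITION[dimer]


class TestDrugInhibitionFactor:
    def test_no_drug(self):
        assert e.drug_inhibition_factor([]) == 1.0

    def test_single_drug(self):
        assert e.drug_inhibition_factor([1.0]) == 0.5

    def test_combinatorial_product(self):
        assert e.drug_inhibition_factor([1.0, 3.0]) == pytest.approx(0.125)

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            e.drug_inhibition_factor([-0.1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1e3), max_size=4))
    def test_factor_in_unit_interval(self, ks):
        f = e.drug_inhibition_factor(ks)
        assert 0 < f <= 1


class TestConditionRates:
    def test_unstimulated_has_no_ligand_driven_dimerization(
            self, comp, mcf7_params):
        net = comp.network
        cond = e.ConditionSpec("MCF7", "none", ())
        k, _ = e.condition_rates(net, mcf7_params, cond, t=30.0)
        for j, r in enumerate(net.reactions):
            if r.group == "B":
                assert k[j] == 0.0
            if r.group == "C":
                assert k[j] == mcf7_params[r.rate_constant]

    def test_ligand_off_before_addition_time(self, comp, mcf7_params):
        net = comp.network
        cond = e.ConditionSpec("MCF7", "EGF", ())
        k30, _ = e.condition_rates(net, mcf7_params, cond, t=30.0)
        k90, _ = e.condition_rates(net, mcf7_params, cond, t=90.0)
        b_idx = [j for j, r in enumerate(net.reactions) if r.group == "B"]
        assert all(k30[j] == 0 for j in b_idx)
        assert any(k90[j] > 0 for j in b_idx)

    def test_nrg1_lumretuzumab(self, comp, mcf7_params):
        net = comp.network
        p = mcf7_params
        cond = e.ConditionSpec("MCF7", "NRG1", ("lumretuzumab",))
        k, _ = e.condition_rates(net, p, cond, t=120.0)
        f_lum = 1.0 / (1.0 + p["k_lumretuzumab"])
        j = {r.name: i for i, r in enumerate(net.reactions)}
        assert k[j["lig_dim_E3"]] == pytest.approx(p["dim_E3_NRG1"] * f_lum)
        assert k[j["lig_dim_23"]] == pytest.approx(p["dim_23_NRG1"] * f_lum)
        # ERBB3 degradation active, enhanced by the NRG1 input
        assert k[j["lum_deg_ERBB3"]] == pytest.approx(
            p["lumdeg_ERBB3"] * (1 + p["lumdeg_NRG1_enh"]))
        # without lumretuzumab the degradation route is off
        k0, _ = e.condition_rates(net, p, e.ConditionSpec("MCF7", "NRG1", ()),
                                  t=120.0)
        assert k0[j["lum_deg_ERBB3"]] == 0.0

    def test_egf_cetuximab_targets_egfr_dimers_only(self, comp, mcf7_params):
        net = comp.network
        p = mcf7_params
        cond = e.ConditionSpec("MCF7", "EGF", ("cetuximab",))
        k, _ = e.condition_rates(net, p, cond, t=120.0)
        f = 1.0 / (1.0 + p["k_cetuximab"])
        j = {r.name: i for i, r in enumerate(net.reactions)}
        assert k[j["lig_dim_EE"]] == pytest.approx(p["dim_EE_EGF"] * f)
        assert k[j["lig_dim_E2"]] == pytest.approx(p["dim_E2_EGF"] * f)
        assert k[j["lig_dim_E3"]] == pytest.approx(p["dim_E3_EGF"] * f)
        assert k[j["bas_dim_23"]] == pytest.approx(p["bas_dim_23"])  # unscaled
        # EGF does not drive ERBB2:ERBB3 dimers
        assert k[j["lig_dim_23"]] == 0.0

    def test_antibody_phosphorylation_requires_erbb2_antibody(
            self, comp, mcf7_params):
        net = comp.network
        j = {r.name: i for i, r in enumerate(net.reactions)}
        k_cet, _ = e.condition_rates(
            net, mcf7_params, e.ConditionSpec("MCF7", "EGF", ("cetuximab",)),
            t=10.0)
        k_tras, _ = e.condition_rates(
            net, mcf7_params, e.ConditionSpec("MCF7", "EGF", ("trastuzumab",)),
            t=10.0)
        for rec in ("EGFR", "ERBB2", "ERBB3"):
            assert k_cet[j[f"abphos_{rec}"]] == 0.0
            assert k_tras[j[f"abphos_{rec}"]] == pytest.approx(
                mcf7_params[f"abphos_{rec}_trastuzumab"])

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError):
            e.ConditionSpec("MCF7", "VEGF", ())
        with pytest.raises(ValueError):
            e.ConditionSpec("MCF7", "EGF", ("imatinib",))


def _hand_rhs(x, kk, sidx):
    """Independent dense oracle: the full equation set written out."""
    def s(name):
        return x[sidx[name]]

    vB = {d: kk[f"lig_dim_{d}"] for d in ("EE", "E2", "E3", "23")}
    vC = {d: kk[f"bas_dim_{d}"] for d in ("EE", "E2", "E3", "23")}
    f_EE = (vB["EE"] + vC["EE"]) * s("EGFR") ** 2
    f_E2 = (vB["E2"] + vC["E2"]) * s("EGFR") * s("ERBB2")
    f_E3 = (vB["E3"] + vC["E3"]) * s("EGFR") * s("ERBB3")
    f_23 = (vB["23"] + vC["23"]) * s("ERBB2") * s("ERBB3")
    pool = s("D_EE") + s("D_E2") + s("D_E3") + s("D_23")

    d = {}
    d["EGFR"] = (kk["syn_EGFR"] - kk["deg_EGFR"] * s("EGFR")
                 - 2 * f_EE - f_E2 - f_E3
                 - kk["abphos_EGFR"] * s("EGFR")
                 + kk["dephos_pEGFR_i"] * s("pEGFR_i"))
    d["ERBB2"] = (kk["syn_ERBB2"] - kk["deg_ERBB2"] * s("ERBB2")
                  - f_E2 - f_23
                  - kk["abphos_ERBB2"] * s("ERBB2")
                  + kk["dephos_pERBB2_i"] * s("pERBB2_i"))
    d["ERBB3"] = (kk["syn_ERBB3"] - kk["deg_ERBB3"] * s("ERBB3")
                  - f_E3 - f_23
                  - kk["abphos_ERBB3"] * s("ERBB3")
                  + kk["dephos_pERBB3_i"] * s("pERBB3_i")
                  - kk["lum_deg_ERBB3"] * s("ERBB3"))
    d["D_EE"] = f_EE - kk["deg_D_EE"] * s("D_EE")
    d["D_E2"] = f_E2 - kk["deg_D_E2"] * s("D_E2")
    d["D_E3"] = f_E3 - kk["deg_D_E3"] * s("D_E3")
    d["D_23"] = f_23 - kk["deg_D_23"] * s("D_23")
    for rec in ("EGFR", "ERBB2", "ERBB3"):
        d[f"p{rec}_i"] = (kk[f"abphos_{rec}"] * s(rec)
                          - kk[f"dephos_p{rec}_i"] * s(f"p{rec}_i"))
    act_pi3k = (kk["act_PI3K_D_EE"] * s("D_EE")
                + kk["act_PI3K_D_E2"] * s("D_E2")
                + kk["act_PI3K_D_E3"] * s("D_E3")
                + kk["act_PI3K_D_23"] * s("D_23")
                + kk["bas_act_PI3K"]) * s("PI3K")
    d["PI3K"] = -act_pi3k + kk["deact_PI3K"] * s("aPI3K")
    d["aPI3K"] = -d["PI3K"]
    act_craf = (kk["act_cRAF_dimers"] * pool + kk["bas_act_cRAF"]) * s("cRAF")
    d["cRAF"] = -act_craf + kk["deact_cRAF"] * s("pcRAF")
    d["pcRAF"] = -d["cRAF"]
    phos_mek = (kk["phos_MEK_pcRAF"] * s("pcRAF") + kk["bas_phos_MEK"]) * s("MEK")
    d["MEK"] = -phos_mek + kk["dephos_MEK"] * s("pMEK")
    d["pMEK"] = -d["MEK"]
    phos_erk = kk["phos_ERK_pMEK"] * s("pMEK") * s("ERK")
    d["ERK"] = -phos_erk + kk["dephos_ERK"] * s("ppERK")
    d["ppERK"] = -d["ERK"]
    phos_akt = kk["phos_AKT_aPI3K"] * s("aPI3K") * s("AKT")
    d["AKT"] = -phos_akt + kk["dephos_AKT"] * s("pAKT")
    d["pAKT"] = -d["AKT"]
    phos_s6k = (kk["phos_S6K_AKT"] * s("pAKT")
                + kk["phos_S6K_ERK"] * s("ppERK")) * s("S6K")
    d["S6K"] = -phos_s6k + kk["dephos_S6K"] * s("pS6K")
    d["pS6K"] = -d["S6K"]
    return np.array([d[sp] for sp in sorted(sidx, key=sidx.get)])


def test_rhs_matches_dense_oracle(comp):
    """Network-generated derivatives match a hand-written equation set."""
    net = comp.network
    sidx = {sp: i for i, sp in enumerate(net.species)}
    rng = np.random.default_rng(42)
    for _ in range(100):
        x = rng.uniform(0, 2, size=22)
        k = rng.uniform(0, 1, size=44)
        kk = {r.name: k[j] for j, r in enumerate(net.reactions)}
        f_net = _rhs(x, 0.0, k, comp.stoich, comp.educt1, comp.educt2,
                     comp.pool_flag, comp.pool_idx)
        f_hand = _hand_rhs(x, kk, sidx)
        np.testing.assert_allclose(f_net, f_hand, rtol=0, atol=1e-12)


class TestSteadyState:
    def test_zero_synthesis_empties_receptor_layer(self, comp, mcf7_params):
        p = dict(mcf7_params)
        for rec in ("EGFR", "ERBB2", "ERBB3"):
            p[f"syn_{rec}"] = 0.0
        x0, _ = e.steady_state_initialize(comp, p)
        sidx = {sp: i for i, sp in enumerate(comp.network.species)}
        for sp in ("EGFR", "ERBB2", "ERBB3", "D_EE", "D_E2", "D_E3", "D_23",
                   "pEGFR_i", "pERBB2_i", "pERBB3_i"):
            assert x0[sidx[sp]] == pytest.approx(0.0, abs=1e-9)

    def test_forward_integration_does_not_move(self, comp, mcf7_params):
        x0, _ = e.steady_state_initialize(comp, mcf7_params)
        cond = e.ConditionSpec("MCF7", "none", ())
        traj = e.simulate_condition(comp, mcf7_params, cond,
                                    np.linspace(0, 240, 9), x0=x0,
                                    rtol=1e-10, atol=1e-12)
        scale = np.maximum(np.abs(x0), 1e-8)
        rel = np.abs(traj.states - x0[None, :]) / scale[None, :]
        assert rel.max() < 1e-6

    def test_detailed_balance_toy(self, comp, mcf7_params):
        # isolated MEK <-> pMEK pair with equal on/off rates splits 50/50
        p = dict(mcf7_params)
        for rec in ("EGFR", "ERBB2", "ERBB3"):
            p[f"syn_{rec}"] = 0.0
        p["bas_cRAF"] = 0.0
        p["bas_MEK"] = 0.2
        p["dephos_MEK"] = 0.2
        x0, _ = e.steady_state_initialize(comp, p)
        sidx = {sp: i for i, sp in enumerate(comp.network.species)}
        total = p["total_MEK"]
        assert x0[sidx["MEK"]] == pytest.approx(total / 2, rel=1e-6)
        assert x0[sidx["pMEK"]] == pytest.approx(total / 2, rel=1e-6)

    def test_receptor_totals_match_specified_abundances(self, comp, truth):
        from erbbsig.synthetic import CELL_LINE_ABUNDANCE
        for cl in ("MCF7", "SKBR3"):
            p = truth.for_cell_line(cl)
            x0, _ = e.steady_state_initialize(comp, p)
            sidx = {sp: i for i, sp in enumerate(comp.network.species)}
            egfr = (x0[sidx["EGFR"]] + x0[sidx["pEGFR_i"]]
                    + 2 * x0[sidx["D_EE"]] + x0[sidx["D_E2"]]
                    + x0[sidx["D_E3"]])
            assert egfr == pytest.approx(
                CELL_LINE_ABUNDANCE[cl]["EGFR"], rel=1e-6)


class TestSimulateCondition:
    def test_frozen_dynamics(self, comp, mcf7_params):
        p = {k: 0.0 for k in mcf7_params}
        p.update({k: mcf7_params[k] for k in mcf7_params if
                  k.startswith(("total_", "abund_"))})
        x0 = np.linspace(0.1, 2.2, 22)
        cond = e.ConditionSpec("MCF7", "EGF", ("cetuximab",))
        traj = e.simulate_condition(comp, p, cond, (0, 60, 120, 240), x0=x0)
        np.testing.assert_allclose(
            traj.states, np.tile(x0, (len(traj.times), 1)), atol=1e-12)

    def test_ligand_pulse_consumes_monomer_into_dimer(
            self, comp, mcf7_params, mcf7_x0):
        cond = e.ConditionSpec("MCF7", "EGF", ())
        traj = e.simulate_condition(comp, mcf7_params, cond,
                                    (0, 60, 65, 75, 90), x0=mcf7_x0)
        egfr = traj.state("EGFR")
        d_ee = traj.state("D_EE")
        assert egfr[2] < egfr[1]          # monomer drops after ligand
        assert d_ee[2] > d_ee[1]          # dimer rises

    def test_linear_chain_matches_closed_form(self, comp, mcf7_params):
        # pEGFR_i --a--> EGFR --b--> 0, all other reactions frozen
        a, b = 0.05, 0.012
        p = {k: 0.0 for k in mcf7_params}
        p["dephos_pEGFR_i"] = a
        p["deg_EGFR"] = b
        x0 = np.zeros(22)
        sidx = {sp: i for i, sp in enumerate(comp.network.species)}
        x0[sidx["pEGFR_i"]] = 1.0
        x0[sidx["EGFR"]] = 0.5
        times = np.linspace(0, 240, 25)
        traj = e.simulate_condition(comp, p, e.ConditionSpec("MCF7"), times,
                                    x0=x0, rtol=1e-10, atol=1e-12)
        t = traj.times
        pi_exact = np.exp(-a * t)
        egfr_exact = (0.5 * np.exp(-b * t)
                      + a / (b - a) * (np.exp(-a * t) - np.exp(-b * t)))
        np.testing.assert_allclose(traj.state("pEGFR_i"), pi_exact, atol=1e-6)
        np.testing.assert_allclose(traj.state("EGFR"), egfr_exact, atol=1e-6)

    def test_states_nonnegative_across_random_parameters(self, comp, truth):
        rng = np.random.default_rng(1)
        base = truth.for_cell_line("MCF7")
        for trial in range(3):
            p = {k: v * 10 ** rng.uniform(-0.5, 0.5) for k, v in base.items()}
            x0, _ = e.steady_state_initialize(comp, p)
            traj = e.simulate_condition(
                comp, p, e.ConditionSpec("MCF7", "NRG1", ("pertuzumab",)),
                np.linspace(0, 240, 30), x0=x0)
            assert np.all(traj.states >= 0)

    def test_event_continuity_at_ligand_addition(self, comp, mcf7_params,
                                                 mcf7_x0):
        cond = e.ConditionSpec("MCF7", "EGF", ())
        traj = e.simulate_condition(
            comp, mcf7_params, cond, (0.0, 59.99, 60.0, 60.01), x0=mcf7_x0)
        # crossing the ligand switch changes rates, not states: the jump
        # over a 0.01-min gap is bounded by the kinetic slope
        assert np.abs(traj.states[2] - traj.states[1]).max() < 5e-3
        assert np.abs(traj.states[3] - traj.states[2]).max() < 5e-3


class TestConservation:
    def test_egfr_material_conserved_without_turnover(self, comp, mcf7_params,
                                                      mcf7_x0):
        p = dict(mcf7_params)
        for name in ("syn_EGFR", "syn_ERBB2", "syn_ERBB3", "deg_EGFR",
                     "deg_ERBB2", "deg_ERBB3", "deg_D_EE", "deg_D_E2",
                     "deg_D_E3", "deg_D_23", "lumdeg_ERBB3"):
            p[name] = 0.0
        cond = e.ConditionSpec("MCF7", "EGF", ("trastuzumab",))
        traj = e.simulate_condition(comp, p, cond, np.linspace(0, 240, 20),
                                    x0=mcf7_x0, rtol=1e-10, atol=1e-12)
        total = (traj.state("EGFR") + traj.state("pEGFR_i")
                 + 2 * traj.state("D_EE") + traj.state("D_E2")
                 + traj.state("D_E3"))
        np.testing.assert_allclose(total, total[0], rtol=1e-8)


class TestDrugMonotonicity:
    """Stronger inhibition monotonically suppresses dimer-driven signaling.

    The inhibition factor is strictly decreasing in k.  At the state
    level, monomer competition means a single dimer species can rise
    when its partners are suppressed (freed monomers re-route), so the
    monotone quantities are the total active-dimer pool and the
    downstream response.
    """

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0, 1e3), st.floats(0.01, 1e3))
    def test_inhibition_factor_strictly_decreasing(self, k, dk):
        assert e.drug_inhibition_factor([k + dk]) < e.drug_inhibition_factor([k])

    @pytest.mark.parametrize("drug,param", [("cetuximab", "k_cetuximab"),
                                            ("lumretuzumab", "k_lumretuzumab")])
    def test_stronger_inhibition_never_raises_dimer_pool_auc(
            self, comp, mcf7_params, mcf7_x0, drug, param):
        times = np.arange(60.0, 241.0, 5.0)
        lig = "EGF" if drug == "cetuximab" else "NRG1"
        pool_aucs, pperk_aucs = [], []
        for k in (0.5, 2.0, 8.0, 32.0):
            p = dict(mcf7_params)
            p[param] = k
            traj = e.simulate_condition(comp, p,
                                        e.ConditionSpec("MCF7", lig, (drug,)),
                                        times, x0=mcf7_x0)
            pool = np.sum([traj.state(d) for d in DIMERS], axis=0)
            pool_aucs.append(np.trapezoid(pool, times))
            pperk_aucs.append(np.trapezoid(traj.state("ppERK"), times))
        assert np.all(np.diff(pool_aucs) <= 1e-9)
        assert np.all(np.diff(pperk_aucs) <= 1e-9)


class TestObserve:
    def test_unit_state_gives_zero(self, comp):
        traj = e.Trajectory(times=np.array([0.0, 1.0]),
                            states=np.ones((2, 22)),
                            species=comp.network.species)
        om = e.ObservationMap(states={"x": {"ppERK": 1.0}})
        y = e.observe(traj, om)
        np.testing.assert_allclose(y["x"], 0.0)

    def test_terbb3_state_set(self):
        om = e.default_observation_map()
        assert om.states["tERBB3"] == {"ERBB3": 1, "pERBB3_i": 1, "D_E3": 1,
                                       "D_23": 1}

    def test_doubling_scale_adds_log10_two(self, comp, mcf7_params, mcf7_x0):
        traj = e.simulate_condition(comp, mcf7_params,
                                    e.ConditionSpec("MCF7", "NRG1"),
                                    (0, 90, 240), x0=mcf7_x0)
        om1 = e.default_observation_map()
        om2 = e.default_observation_map()
        for o in om2.observables:
            om1.offset[o] = 0.0
            om2.offset[o] = 0.0
            om2.scale[o] = 2.0 * om1.scale[o]
        y1, y2 = e.observe(traj, om1), e.observe(traj, om2)
        for o in om1.observables:
            np.testing.assert_allclose(y2[o] - y1[o], np.log10(2), atol=1e-12)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            e.ObservationMap(states={"x": {"ppERK": 1.0}}, scale={"x": 0.0})
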
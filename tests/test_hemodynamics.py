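"""Domain solver, stenosis loss model, 0D model, and the coupled iteration."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from coroffr import (
    BloodProperties,
    CouplingConfig,
    CouplingError,
    PatientParameters,
    Segment,
    Stenosis,
    build_lpm,
    couple,
    generate_synthetic_tree,
    mean_aortic_pressure,
    segment_viscous_resistance,
    solve_0d,
    solve_domain,
    solve_monolithic,
    stenosis_pressure_drop,
    subdivide_segment,
)
from coroffr.units import resistance_si_to_mmhg_ml

BLOOD = BloodProperties()


def _seg(rp=2.0, rd=2.0, length=10.0, stenoses=()):
    return Segment(
        id="s",
        proximal_node="a",
        distal_node="b",
        length=length,
        radius_proximal=rp,
        radius_distal=rd,
        stenoses=list(stenoses),
        branch_label="LAD",
    )


class TestViscousResistance:
    def test_uniform_tube_closed_form(self):
        # 8 mu L / (pi r^4), r=2 mm, L=10 mm, mu=0.0035 -> 5.5704e6 Pa.s/m^3
        r = segment_viscous_resistance(_seg(), BLOOD)
        assert r == pytest.approx(8 * 0.0035 * 0.01 / (math.pi * 0.002**4), rel=1e-12)
        assert r == pytest.approx(5.5704e6, rel=1e-4)

    def test_taper_limit_reduces_to_uniform(self):
        assert segment_viscous_resistance(
            _seg(rp=1.5, rd=1.5), BLOOD
        ) == pytest.approx(8 * 0.0035 * 0.01 / (math.pi * 0.0015**4), rel=1e-12)

    def test_inverse_fourth_power_scaling(self):
        assert segment_viscous_resistance(_seg(rp=1.0, rd=1.0), BLOOD) == pytest.approx(
            16.0 * segment_viscous_resistance(_seg(rp=2.0, rd=2.0), BLOOD), rel=1e-12
        )

    @pytest.mark.parametrize("rp,rd", [(2.0, 1.5), (3.0, 1.0), (1.2, 1.19)])
    def test_tapered_closed_form_matches_quadrature(self, rp, rd):
        seg = _seg(rp=rp, rd=rd, length=12.0)

        def integrand(s):
            r = (rp + (rd - rp) * s / 12.0) * 1e-3
            return 8 * BLOOD.viscosity / (math.pi * r**4) * 1e-3

        oracle, _ = quad(integrand, 0.0, 12.0)
        assert segment_viscous_resistance(seg, BLOOD) == pytest.approx(
            oracle, rel=1e-9
        )


class TestStenosisPressureDrop:
    def test_vanishes_without_lesion(self):
        st = Stenosis(position=0.5, severity=0.0, length=1e-9)
        assert stenosis_pressure_drop(st, _seg(), 5.0) == pytest.approx(0.0, abs=1e-9)

    def test_zero_flow_zero_drop(self):
        st = Stenosis(position=0.5, severity=0.6, length=5.0)
        assert stenosis_pressure_drop(st, _seg(), 0.0) == 0.0

    def test_odd_symmetry_and_monotonicity(self):
        st = Stenosis(position=0.5, severity=0.6, length=5.0)
        seg = _seg()
        qs = np.linspace(0.1, 10.0, 40)
        drops = np.array([stenosis_pressure_drop(st, seg, q) for q in qs])
        assert np.all(np.diff(drops) > 0)
        for q in qs[::10]:
            assert stenosis_pressure_drop(st, seg, -q) == pytest.approx(
                -stenosis_pressure_drop(st, seg, q), rel=1e-12
            )

    def test_drop_grows_with_severity(self):
        seg = _seg()
        drops = [
            stenosis_pressure_drop(
                Stenosis(position=0.5, severity=s, length=5.0), seg, 3.0
            )
            for s in (0.4, 0.5, 0.6, 0.7, 0.8)
        ]
        assert np.all(np.diff(drops) > 0)

    def test_near_occlusion_rejected(self):
        with pytest.raises(ValueError):
            Stenosis(position=0.5, severity=1.0, length=5.0)


class TestSolveDomain:
    def test_single_tube_poiseuille_limit(self, single_tube):
        # with the ostium clamped, coronary flow is dP over the tube's R
        p_in, p_out = 100.0, 60.0
        outlet = single_tube.coronary_outlet_nodes[0]
        sol = solve_domain(
            single_tube,
            p_in,
            {outlet: p_out, single_tube.systemic_outlet_node: p_in},
        )
        r_tube = sum(
            resistance_si_to_mmhg_ml(segment_viscous_resistance(s, BLOOD))
            for s in single_tube.segments
            if s.is_coronary
        )
        assert sol.interface_flows[outlet] == pytest.approx(
            (p_in - p_out) / r_tube, rel=1e-9
        )

    def test_equilibrium_when_all_pressures_equal(self, healthy_tree):
        bcs = {n: 100.0 for n in healthy_tree.interface_nodes()}
        sol = solve_domain(healthy_tree, 100.0, bcs)
        assert all(abs(q) < 1e-12 for q in sol.segment_flows.values())

    def test_symmetric_bifurcation_equal_flows(self):
        # hand-built Y: identical daughters at identical outlet pressure
        from coroffr import CoronaryTree

        segs = [
            Segment(id="AO", proximal_node="in", distal_node="j", length=40,
                    radius_proximal=12.5, radius_distal=12.5, branch_label="AORTA"),
            Segment(id="P", proximal_node="j", distal_node="b", length=20,
                    radius_proximal=2.5, radius_distal=2.0, branch_label="LAD"),
            Segment(id="L", proximal_node="b", distal_node="l", length=15,
                    radius_proximal=1.6, radius_distal=1.5, branch_label="LAD"),
            Segment(id="R", proximal_node="b", distal_node="r", length=15,
                    radius_proximal=1.6, radius_distal=1.5, branch_label="LCX"),
        ]
        tree = CoronaryTree(
            nodes={n: None for n in ("in", "j", "b", "l", "r")},
            segments=segs,
            inlet_node="in",
            systemic_outlet_node="j",
            coronary_outlet_nodes=["l", "r"],
        )
        tree.validate()
        sol = solve_domain(tree, 100.0, {"l": 80.0, "r": 80.0, "j": 100.0})
        assert sol.segment_flows["L"] == pytest.approx(sol.segment_flows["R"], rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_mass_conservation(self, seed, mean_patient):
        tree = generate_synthetic_tree(
            stenosis_spec=[("LAD", 0.6, 0.5)], seed=seed
        )
        bcs = {n: 70.0 + seed for n in tree.interface_nodes()}
        sol = solve_domain(tree, 103.0, bcs)
        assert sol.max_mass_residual() < 1e-9

    def test_grid_refinement_invariance(self, healthy_tree):
        bcs = {n: 75.0 for n in healthy_tree.interface_nodes()}
        coarse = solve_domain(healthy_tree, 103.0, bcs)
        fine_tree = healthy_tree
        for seg in healthy_tree.segments:
            fine_tree = subdivide_segment(fine_tree, seg.id, 3)
        fine = solve_domain(fine_tree, 103.0, bcs)
        for n in healthy_tree.interface_nodes():
            assert fine.interface_flows[n] == pytest.approx(
                coarse.interface_flows[n], rel=1e-10
            )

    def test_missing_outlet_pressure_rejected(self, healthy_tree):
        with pytest.raises(ValueError, match="missing interfaces"):
            solve_domain(healthy_tree, 100.0, {})


class TestSolve0D:
    def test_ohm_analogy(self, single_tube, mean_patient):
        lpm = build_lpm(single_tube, mean_patient, hyperemia=False)
        node = single_tube.coronary_outlet_nodes[0]
        r = lpm.resistance(node)
        flows = {node: 1.0, lpm.systemic_node: 0.0}
        p = solve_0d(lpm, flows)
        assert p[node] == pytest.approx(r)
        assert p[lpm.systemic_node] == 0.0
        # linearity
        p2 = solve_0d(lpm, {node: 2.0, lpm.systemic_node: 0.0})
        assert p2[node] == pytest.approx(2 * p[node])

    def test_missing_flow_rejected(self, single_tube, mean_patient):
        lpm = build_lpm(single_tube, mean_patient)
        with pytest.raises(KeyError):
            solve_0d(lpm, {})


class TestCoupling:
    def test_single_tube_closed_form(self, single_tube, mean_patient):
        lpm = build_lpm(single_tube, mean_patient)
        pa = mean_aortic_pressure(mean_patient)
        sol = couple(single_tube, lpm, pa)
        outlet = single_tube.coronary_outlet_nodes[0]
        r_net = sum(
            resistance_si_to_mmhg_ml(segment_viscous_resistance(s, BLOOD))
            for s in single_tube.segments
            if s.is_coronary
        )
        q_expected = pa / (r_net + lpm.resistance(outlet))
        assert sol.interface_flows[outlet] == pytest.approx(q_expected, rel=2e-3)

    @pytest.mark.parametrize("seed", range(20))
    def test_partitioned_matches_monolithic(self, seed, mean_patient):
        sev = [("LAD", 0.40 + 0.02 * seed, 0.5)] if seed % 2 else []
        tree = generate_synthetic_tree(stenosis_spec=sev, seed=seed)
        lpm = build_lpm(tree, mean_patient)
        pa = mean_aortic_pressure(mean_patient)
        part = couple(tree, lpm, pa)
        mono = solve_monolithic(tree, lpm, pa)
        for n in tree.interface_nodes():
            assert part.interface_flows[n] == pytest.approx(
                mono.interface_flows[n],
                rel=1e-3,
                abs=1e-6,
            )
            assert part.node_pressures[n] == pytest.approx(
                mono.node_pressures[n], rel=1e-3
            )

    def test_exit_residual_below_epsilon(self, stenosed_tree, mean_patient):
        cfg = CouplingConfig(epsilon=1e-4)
        lpm = build_lpm(stenosed_tree, mean_patient)
        sol = couple(stenosed_tree, lpm, mean_aortic_pressure(mean_patient), cfg)
        assert sol.converged
        assert sol.coupling_trace[-1].residual < cfg.epsilon
        assert all(st.residual >= 0 or math.isinf(st.residual) for st in sol.coupling_trace)

    def test_nonconvergence_raises_with_trace(self, stenosed_tree, mean_patient):
        lpm = build_lpm(stenosed_tree, mean_patient)
        with pytest.raises(CouplingError) as exc:
            couple(
                stenosed_tree,
                lpm,
                mean_aortic_pressure(mean_patient),
                CouplingConfig(max_iterations=2),
            )
        assert len(exc.value.trace) == 2

    def test_monotone_response_to_outlet_resistance(self, healthy_tree, mean_patient):
        from dataclasses import replace

        pa = mean_aortic_pressure(mean_patient)
        lpm = build_lpm(healthy_tree, mean_patient)
        base = couple(healthy_tree, lpm, pa)
        target = lpm.outlets[0].outlet_node
        bumped = replace(
            lpm.outlets[0],
            r_resting=lpm.outlets[0].r_resting * 1.5,
            r_hyperemia=lpm.outlets[0].r_hyperemia * 1.5,
        )
        lpm.outlets[0] = bumped
        perturbed = couple(healthy_tree, lpm, pa)
        assert perturbed.interface_flows[target] < base.interface_flows[target]

    def test_mass_conserved_in_coupled_solution(self, stenosed_tree, mean_patient):
        lpm = build_lpm(stenosed_tree, mean_patient)
        sol = couple(stenosed_tree, lpm, mean_aortic_pressure(mean_patient))
        assert sol.max_mass_residual() < 1e-9

    def test_monolithic_mass_conserved(self, stenosed_tree, mean_patient):
        lpm = build_lpm(stenosed_tree, mean_patient)
        sol = solve_monolithic(stenosed_tree, lpm, 103.0)
        assert sol.max_mass_residual() < 1e-9
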
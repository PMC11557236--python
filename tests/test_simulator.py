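"""1-D confined-compression solver: protocol grid, oracles, invariants."""

import dataclasses

import numpy as np
import pytest

from poroident import (BiphasicParameters, Grid1D, Protocol, build_protocol,
                       effective_axial_stress, grid_convergence,
                       solve_confined_compression, validate_simulation)

from _oracles import bisect_root, linear_confined_compression_force


class TestProtocol:
    def test_default_output_grid_has_72_points(self, default_protocol):
        t = default_protocol.output_times()
        assert t.size == 72 == default_protocol.n_output_points
        assert np.all(np.diff(t) > 0)

    def test_hold_points_log_uniform(self, default_protocol):
        t = default_protocol.output_times()
        hold1 = t[9:24] - default_protocol.ramp_duration
        ratios = hold1[1:] / hold1[:-1]
        assert np.allclose(ratios, ratios[0])
        assert hold1[0] == pytest.approx(default_protocol.hold_duration / 1000)
        assert hold1[-1] == pytest.approx(default_protocol.hold_duration)

    def test_increment_displacement_targets(self, default_protocol):
        # 5 % of 1.1 mm per increment
        assert default_protocol.increment_displacement == pytest.approx(0.055)
        period = (default_protocol.ramp_duration
                  + default_protocol.hold_duration)
        for m in (1, 2, 3):
            end_of_ramp = (m - 1) * period + default_protocol.ramp_duration
            assert default_protocol.displacement(end_of_ramp) == pytest.approx(
                0.055 * m)

    def test_ramp_points_exclude_start_include_end(self, default_protocol):
        t = default_protocol.output_times()
        assert t[0] > 0
        assert t[8] == pytest.approx(default_protocol.ramp_duration)

    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            build_protocol({"ramp_duration": -1.0})
        with pytest.raises(ValueError):
            build_protocol({"increment_strain": 0.4})  # 3 x 0.4 >= 1

    def test_segment_labels_partition_grid(self, default_protocol):
        labels = default_protocol.segment_labels()
        assert len(labels) == 72
        assert labels[:9] == ["ramp 1"] * 9
        assert labels[9:24] == ["hold 1"] * 15


class TestSolverOracles:
    def test_long_hold_reaches_static_equilibrium(self, midpoint_params, env):
        # 0-D oracle: at equilibrium the stretch is uniform and fixed by the
        # prescribed height, so F = -sigma_e(h/H_ref) * A
        proto = Protocol(n_increments=1, hold_duration=80000.0)
        res = solve_confined_compression(midpoint_params, proto, Grid1D(31),
                                         env, substeps=2)
        lam0 = res.lam0
        H_ref = proto.initial_height / lam0
        lz_eq = (proto.initial_height - proto.increment_displacement) / H_ref
        sig_eq = effective_axial_stress(lz_eq, lam0, midpoint_params, env)
        F_eq = -sig_eq * proto.area * 1e-3
        assert res.force[-1] == pytest.approx(F_eq, rel=5e-3)

    def test_linear_limit_matches_series_solution(self, linear_params):
        # small increments keep the kinematics in the linear regime; the
        # independent oracle is the classical consolidation series solution
        proto = Protocol(increment_strain=0.0025)
        res = solve_confined_compression(linear_params, proto, Grid1D(101),
                                         substeps=8)
        HA = 300.0  # E(1-nu)/((1+nu)(1-2nu)) at E=300, nu=0
        F_lin = linear_confined_compression_force(
            res.times, HA_kPa=HA, k0=linear_params.k0, area=proto.area,
            height=proto.initial_height,
            increment_disp=proto.increment_displacement,
            ramp=proto.ramp_duration, hold=proto.hold_duration, n_inc=3)
        peak = np.abs(F_lin).max()
        assert np.all(np.abs(res.force - F_lin) <= 0.01 * peak)

    def test_undisturbed_state_gives_zero_force(self, uncharged_params):
        proto = Protocol(increment_strain=0.0)
        res = solve_confined_compression(uncharged_params, proto, Grid1D(11))
        assert np.allclose(res.force, 0.0, atol=1e-9)
        assert validate_simulation(res, proto).passed


@pytest.fixture(scope="module")
def midpoint_run(midpoint_params, env):
    return solve_confined_compression(midpoint_params, Protocol(),
                                      Grid1D(21), env, substeps=2)


class TestSolverInvariants:
    def test_determinism_bit_identical(self, midpoint_params, env):
        a = solve_confined_compression(midpoint_params, Protocol(), Grid1D(11),
                                       env)
        b = solve_confined_compression(midpoint_params, Protocol(), Grid1D(11),
                                       env)
        assert np.array_equal(a.force, b.force)
        assert np.array_equal(a.lambda_z, b.lambda_z)

    def test_fluid_content_tracks_prescribed_height(self, midpoint_run):
        # the only open boundary is the draining face, so the total fluid
        # content (per unit area, = lam0^2 * integral of lam_z dZ) must track
        # the prescribed height exactly; during holds it is constant while
        # the stretch field redistributes internally
        res = midpoint_run
        proto = res.protocol
        dZ = res.node_coords[1] - res.node_coords[0]
        integ = np.trapezoid(res.lambda_z, dx=dZ, axis=1)
        h_t = proto.height(res.times)
        assert np.max(np.abs(integ - h_t)) < 1e-8
        segs = np.array(res.segments)
        hold1 = res.lambda_z[segs == "hold 1"]
        assert np.ptp(integ[segs == "hold 1"]) < 1e-9  # content constant
        assert np.max(np.abs(hold1[-1] - hold1[0])) > 1e-3  # field evolves

    def test_compression_reaction_nonnegative_without_swelling(
            self, uncharged_params):
        res = solve_confined_compression(uncharged_params, Protocol(),
                                         Grid1D(21), substeps=2)
        assert np.all(res.force >= -1e-12)

    def test_hold_relaxation_monotone(self, uncharged_params):
        res = solve_confined_compression(uncharged_params, Protocol(),
                                         Grid1D(21), substeps=2)
        segs = np.array(res.segments)
        for m in (1, 2, 3):
            F = res.force[segs == f"hold {m}"]
            assert np.all(np.diff(F) <= 1e-9 * np.abs(F[:-1]) + 1e-12)

    def test_pore_space_stays_open(self, midpoint_run, midpoint_params):
        assert midpoint_run.min_J > 1.0 - midpoint_params.phi_w0

    def test_draining_face_pressure_zero(self, midpoint_run):
        assert np.allclose(midpoint_run.pressure[:, 0], 0.0, atol=1e-6)

    def test_pressure_vanishes_at_long_hold_end(self, midpoint_params, env):
        proto = Protocol(n_increments=1, hold_duration=80000.0)
        res = solve_confined_compression(midpoint_params, proto, Grid1D(21),
                                         env, substeps=2)
        peak_p = np.abs(res.pressure).max()
        assert np.abs(res.pressure[-1]).max() < 1e-3 * peak_p


class TestValidation:
    def test_clean_run_passes_all_checks(self, midpoint_params):
        res = solve_confined_compression(midpoint_params, Protocol(),
                                         Grid1D(11))
        rep = validate_simulation(res)
        assert rep.passed
        assert (rep.all_times_present and rep.displacement_ok
                and rep.solver_converged and rep.invariants_ok)

    def test_truncated_result_fails_time_check(self, midpoint_params):
        res = solve_confined_compression(midpoint_params, Protocol(),
                                         Grid1D(11))
        cut = dataclasses.replace(
            res, times=res.times[:-15], force=res.force[:-15],
            converged=res.converged[:-15], segments=res.segments[:-15])
        rep = validate_simulation(cut, Protocol())
        assert not rep.all_times_present
        assert not rep.passed

    def test_forced_divergence_flags_solver(self, midpoint_params):
        res = solve_confined_compression(midpoint_params, Protocol(),
                                         Grid1D(11), max_newton=1,
                                         max_halve=0)
        rep = validate_simulation(res)
        assert not rep.solver_converged
        assert not rep.passed


class TestGridConvergence:
    def test_refinement_differences_decrease(self, midpoint_params):
        table = grid_convergence(midpoint_params, node_counts=(11, 21, 41),
                                 substeps=2)
        diffs = table["max_rel_diff"].to_numpy()
        assert np.isnan(diffs[0])
        assert diffs[2] < diffs[1]

    def test_identical_node_counts_give_zero_difference(self, midpoint_params):
        table = grid_convergence(midpoint_params, node_counts=(11, 11))
        assert table["max_rel_diff"].iloc[1] == 0.0

    def test_linear_limit_converges_to_series_solution(self, linear_params):
        proto = Protocol(increment_strain=0.0025, n_increments=1)
        errs = []
        for nodes, subs in [(11, 2), (41, 8)]:
            res = solve_confined_compression(linear_params, proto,
                                             Grid1D(nodes), substeps=subs)
            F_lin = linear_confined_compression_force(
                res.times, HA_kPa=300.0, k0=linear_params.k0,
                area=proto.area, height=proto.initial_height,
                increment_disp=proto.increment_displacement,
                ramp=proto.ramp_duration, hold=proto.hold_duration, n_inc=1)
            errs.append(np.abs(res.force - F_lin).max())
        assert errs[1] < errs[0]
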
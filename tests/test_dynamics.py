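import math

import numpy as np
import pytest

from axonzip import dynamics as dyn
from axonzip import statics as st
from axonzip.dynamics import (FrictionParams, PerturbationProtocol,
                              assemble_friction_tensor, dissipation_rate,
                              fit_velocity_vs_angle, infer_ST_ratio,
                              infer_etaZ, simulate_general,
                              symmetric_velocity)
from axonzip.statics import ZipperGeometry, ZipperMechanics

from conftest import random_valid_config

SYM = dict(A=(-10.0, 10.0), B=(10.0, 10.0), C=(0.0, -40.0))


def test_friction_params_validation():
    with pytest.raises(ValueError):
        FrictionParams()
    with pytest.raises(ValueError):
        FrictionParams(eta_z=-1.0)


class TestSymmetricVelocity:
    def test_zero_at_equilibrium(self):
        T, S = 1.0, 0.2
        beta = st.equilibrium_angle_symmetric(T, S)
        assert symmetric_velocity(beta, 50.0, T, S, 3000.0, 1.0) \
            == pytest.approx(0.0, abs=1e-12)

    def test_sign_follows_drive(self):
        T, S = 1.0, 0.2
        beta_eq = st.equilibrium_angle_symmetric(T, S)
        assert symmetric_velocity(beta_eq - 10, 50.0, T, S, 3000.0, 1.0) > 0
        assert symmetric_velocity(beta_eq + 10, 50.0, T, S, 3000.0, 1.0) < 0

    def test_independent_rederivation(self):
        # oracle: direct evaluation written out separately
        T, S, beta, L, ee, ez = 1.0, 0.2, 80.0, 50.0, 3000.0, 1.0
        c = math.cos(math.radians(beta) / 2.0)
        expect = (S - 2 * T * (1 - c)) / (2 * ee * (c - 1) ** 2 / L + ez)
        assert symmetric_velocity(beta, L, T, S, ee, ez) \
            == pytest.approx(expect, rel=1e-12)

    def test_affine_in_phi_without_elongation(self):
        # with eta_elong = 0: ydot = S/eta_z - (2T/eta_z) * (1 - cos b/2)
        T, S, ez = 1.3, 0.25, 2.0
        for beta in (20.0, 60.0, 110.0):
            phi = 1 - math.cos(math.radians(beta) / 2)
            v = symmetric_velocity(beta, 77.0, T, S, 0.0, ez)
            assert v == pytest.approx(S / ez - (2 * T / ez) * phi, rel=1e-12)

    def test_zero_friction_rejected(self):
        with pytest.raises(ValueError):
            symmetric_velocity(60.0, 50.0, 1.0, 0.2, 0.0, 0.0)


class TestFrictionTensor:
    def test_vertex_only_rank_one_along_axis(self):
        geom = ZipperGeometry(V=(0.0, 0.0), **SYM)
        H = assemble_friction_tensor(geom, FrictionParams(eta_z=2.5))
        uc = geom.unit("C")
        assert H == pytest.approx(2.5 * np.outer(uc, uc))
        assert np.linalg.matrix_rank(H, tol=1e-12) == 1

    def test_substrate_straight_segment_L_over_3(self):
        # closed form: per-segment dissipation per unit velocity^2 is
        # eta * L / 3 when eta_par == eta_perp
        geom = ZipperGeometry(V=(0.0, 0.0), **SYM)
        eta = 100.0  # Pa*s
        H = assemble_friction_tensor(geom,
                                     FrictionParams(eta_par=eta,
                                                    eta_perp=eta))
        total_L = geom.len_va + geom.len_vb + geom.len_vc
        # isotropic: H = eta * (sum L/3) * I, in internal units
        assert H == pytest.approx(eta * 1e-3 * total_L / 3.0 * np.eye(2))

    def test_dissipation_matches_quadrature(self, rng):
        # oracle: numerically integrate the dissipation density along the
        # three segments with the linear velocity profile
        for geom, _ in random_valid_config(rng, 5):
            fric = FrictionParams(eta_par=150.0, eta_perp=40.0)
            H = assemble_friction_tensor(geom, fric)
            u = rng.uniform(-1, 1, 2)
            quad = 0.0
            for which in "ABC":
                P = getattr(geom, which)
                L = float(np.linalg.norm(P - geom.V))
                t_hat = geom.unit(which)
                ls = np.linspace(0, L, 20001)
                v = np.outer(1.0 - ls / L, u)  # zero at fixed point P
                v_par = v @ t_hat
                v_perp2 = np.einsum("ij,ij->i", v, v) - v_par ** 2
                dens = (fric.eta_par * v_par ** 2
                        + fric.eta_perp * v_perp2) * 1e-3
                quad += np.trapezoid(dens, ls)
            assert float(u @ H @ u) == pytest.approx(quad, rel=1e-4)

    def test_rotation_covariance(self):
        geom = ZipperGeometry(V=(0.3, -0.2), **SYM)
        fric = FrictionParams(eta_elong=3000.0, eta_z=1.0, eta_par=200.0,
                              eta_perp=50.0)
        H = assemble_friction_tensor(geom, fric)
        ang = math.radians(30.0)
        R = np.array([[math.cos(ang), -math.sin(ang)],
                      [math.sin(ang), math.cos(ang)]])
        rot = ZipperGeometry(*(R @ np.asarray(p) for p in
                               (geom.A, geom.B, geom.C, geom.V)))
        H_rot = assemble_friction_tensor(rot, fric)
        assert H_rot == pytest.approx(R @ H @ R.T, rel=1e-10)

    def test_symmetric_psd(self, rng):
        for geom, _ in random_valid_config(rng, 10):
            H = assemble_friction_tensor(
                geom, FrictionParams(eta_elong=500.0, eta_z=0.5,
                                     eta_par=10.0, eta_perp=10.0))
            assert H == pytest.approx(H.T)
            assert np.all(np.linalg.eigvalsh(H) >= -1e-12)


REGIMES = {
    "elongation": FrictionParams(eta_elong=3000.0, eta_par=1.0,
                                 eta_perp=1.0),
    "vertex": FrictionParams.vertex_dominated(eta_z=1.0),
    "substrate": FrictionParams(eta_par=200.0, eta_perp=200.0),
}


class TestSimulateGeneral:
    def test_stationary_at_equilibrium(self):
        mech = ZipperMechanics(1.0, 1.5, 0.2)
        eq = st.find_equilibrium_vertex(SYM["A"], SYM["B"], SYM["C"], mech)
        proto = PerturbationProtocol.constant(1.0, 1.5, 0.2)
        traj = simulate_general(SYM["A"], SYM["B"], SYM["C"], eq.V, proto,
                                REGIMES["vertex"], dt=0.1, t_end=50.0)
        assert traj.termination == "converged"
        assert np.linalg.norm(traj.xy[-1] - eq.V) < 1e-6

    @pytest.mark.parametrize("regime", list(REGIMES))
    def test_energy_lyapunov_and_terminal_residual(self, regime):
        # paths differ between regimes but all end at the same equilibrium
        proto = PerturbationProtocol.constant(1.0, 1.5, 0.2)
        traj = simulate_general(SYM["A"], SYM["B"], SYM["C"], (0.0, 0.0),
                                proto, REGIMES[regime], dt=0.1,
                                t_end=50000.0, force_tol=1e-8)
        assert traj.termination == "converged"
        assert np.all(np.diff(traj.energy) <= 1e-9)
        geom = ZipperGeometry(SYM["A"], SYM["B"], SYM["C"], traj.xy[-1])
        F = st.vertex_force(geom, ZipperMechanics(1.0, 1.5, 0.2))
        assert np.linalg.norm(F) < 1e-6

    def test_regime_endpoints_agree(self):
        ends = []
        proto = PerturbationProtocol.constant(1.0, 1.5, 0.2)
        for fric in REGIMES.values():
            traj = simulate_general(SYM["A"], SYM["B"], SYM["C"],
                                    (0.0, 0.0), proto, fric, dt=0.1,
                                    t_end=50000.0)
            ends.append(traj.xy[-1])
        for e in ends[1:]:
            assert np.linalg.norm(e - ends[0]) < 1e-4

    def test_symmetric_reduction_equivalence(self):
        # mirror-symmetric run must match the scalar integration of the
        # symmetric equation of motion
        T, S = 1.0, 0.25
        fric = FrictionParams(eta_elong=3000.0, eta_z=1.0)
        proto = PerturbationProtocol.constant(T, T, S)
        traj = simulate_general(SYM["A"], SYM["B"], SYM["C"], (0.0, 0.0),
                                proto, fric, dt=0.05, t_end=2000.0)
        assert np.max(np.abs(traj.xy[:, 0])) < 1e-9  # stays on the axis

        # scalar oracle on the vertex y-coordinate
        C = np.array(SYM["C"])
        A = np.array(SYM["A"])
        y = 0.0
        ts = traj.t
        ys = [y]
        for t0, t1 in zip(ts[:-1], ts[1:]):
            geom = ZipperGeometry(SYM["A"], SYM["B"], SYM["C"], (0.0, y))
            L = geom.len_va + geom.len_vc
            v = symmetric_velocity(geom.beta_deg, L, T, S,
                                   fric.eta_elong, fric.eta_z)
            y += v * (t1 - t0)
            ys.append(y)
        assert np.max(np.abs(traj.xy[:, 1] - np.array(ys))) < 0.1

    def test_gradual_ramp_near_constant_speed(self):
        proto = PerturbationProtocol.ramp(1.0, 1.0, 1.5, 0.2,
                                          t_ramp_start=0.0,
                                          t_ramp_end=500.0)
        mech0 = ZipperMechanics(1.0, 1.0, 0.2)
        eq0 = st.find_equilibrium_vertex(SYM["A"], SYM["B"], SYM["C"],
                                         mech0)
        traj = simulate_general(SYM["A"], SYM["B"], SYM["C"], eq0.V, proto,
                                REGIMES["vertex"], dt=0.5, t_end=1000.0)
        speeds = np.linalg.norm(traj.u, axis=1)
        window = (traj.t > 100) & (traj.t < 400)
        mid = speeds[window]
        assert mid.std() / mid.mean() < 0.35  # approximately constant

    def test_abrupt_step_fast_lateral_then_axial(self):
        # after a rapid tension step with dominant vertex friction the
        # early motion has a strong transverse component, the late motion
        # runs parallel to the zippered segment
        proto = PerturbationProtocol(
            times=[0.0, 5.0], T1=[1.0, 1.0], T2=[1.0, 1.5], S=[0.2, 0.2])
        mech0 = ZipperMechanics(1.0, 1.0, 0.2)
        eq0 = st.find_equilibrium_vertex(SYM["A"], SYM["B"], SYM["C"],
                                         mech0)
        traj = simulate_general(SYM["A"], SYM["B"], SYM["C"], eq0.V, proto,
                                REGIMES["vertex"], dt=0.1, t_end=20000.0)
        axis = np.array([0.0, 1.0])
        early = traj.u[(traj.t > 5) & (traj.t < 30)]
        late = traj.u[-min(100, len(traj.u) // 4):]
        frac_axial = lambda u: np.abs(u @ axis) / (
            np.linalg.norm(u, axis=1) + 1e-30)
        assert np.median(frac_axial(late)) > 0.99
        assert np.median(frac_axial(early)) < np.median(frac_axial(late))

    def test_detached_terminal_state(self):
        # adhesion too weak for the wide anchor angle: vertex slides to C
        proto = PerturbationProtocol.constant(1.0, 1.5, 0.2)
        traj = simulate_general((-10, 10), (10, 10), (0, -10), (0, 0),
                                proto, REGIMES["vertex"], dt=0.5,
                                t_end=100000.0)
        assert traj.termination == "detached"


class TestFitAndInference:
    def _vertex_friction_traj(self, T=1.0, S=0.2, eta_z=1.0):
        proto = PerturbationProtocol.constant(T, T, S)
        fric = FrictionParams(eta_z=eta_z, eta_par=0.01, eta_perp=0.01)
        return simulate_general((-30, 30), (30, 30), (0, -80), (0.0, 10.0),
                                proto, fric, dt=0.5, t_end=4000.0,
                                dt_max=0.5)

    def test_recover_slope_intercept(self):
        T, S, ez = 1.0, 0.2, 1.0
        traj = self._vertex_friction_traj(T, S, ez)
        slope, intercept, r2 = fit_velocity_vs_angle(traj,
                                                     smoothing_halfwidth=2.0)
        assert slope == pytest.approx(-2 * T / ez, rel=0.02)
        assert intercept == pytest.approx(S / ez, rel=0.02)
        assert r2 > 0.999
        assert infer_ST_ratio(slope, intercept) == pytest.approx(S / T,
                                                                 rel=0.02)
        assert infer_etaZ(slope, T) == pytest.approx(ez, rel=0.02)

    def test_elongation_curvature_lowers_r2(self):
        proto = PerturbationProtocol.constant(1.0, 1.0, 0.2)
        fric = FrictionParams(eta_elong=50000.0, eta_z=0.05, eta_par=0.01,
                              eta_perp=0.01)
        traj = simulate_general((-30, 30), (30, 30), (0, -80), (0.0, 10.0),
                                proto, fric, dt=0.5, t_end=4000.0,
                                dt_max=0.5)
        _, _, r2 = fit_velocity_vs_angle(traj, smoothing_halfwidth=2.0)
        assert r2 < 0.999  # model mismatch visible, not hidden

    def test_paper_fit_numbers(self):
        assert infer_ST_ratio(-4.1692, 0.0825) == pytest.approx(0.04,
                                                                abs=0.005)
        eta = infer_etaZ(-4.1692, 2.0)  # nN*s/um = 1e-3 N*s/m
        assert 0.1 < eta < 10.0  # order 1e-3 N*s/m

    def test_unphysical_slope_rejected(self):
        with pytest.raises(ValueError):
            infer_ST_ratio(0.5, 0.1)
        with pytest.raises(ValueError):
            infer_etaZ(1.0, 1.0)

    def test_zero_intercept(self):
        assert infer_ST_ratio(-1.0, 0.0) == 0.0


class TestDissipationRate:
    def test_order_of_magnitude(self):
        p = dissipation_rate(1.0, 1.0)  # 1e-3 N*s/m at 1 um/min
        assert 1e-18 < p < 1e-16

    def test_zero_velocity(self):
        assert dissipation_rate(1.0, 0.0) == 0.0

    def test_quadratic_in_velocity(self):
        assert dissipation_rate(2.0, 2.0) \
            == pytest.approx(4 * dissipation_rate(2.0, 1.0))


def test_step_general_moves_downhill(wide_zipper):
    from axonzip.dynamics import step_general
    geom, mech = wide_zipper
    fric = REGIMES["vertex"]
    new_geom, u = step_general(geom, mech, fric, dt=0.1)
    assert np.allclose(new_geom.V, geom.V + 0.1 * u)
    from axonzip.statics import config_energy
    assert config_energy(new_geom, mech) < config_energy(geom, mech)
    with pytest.raises(ValueError):
        step_general(geom, mech, fric, dt=-1.0)


def test_protocol_from_csv(tmp_path):
    p = tmp_path / "proto.csv"
    p.write_text("time,T1,T2,S\n0,1.0,1.0,0.2\n500,1.0,1.5,0.2\n")
    proto = PerturbationProtocol.from_csv(p)
    m = proto.mechanics_at(250.0)
    assert m.T2 == pytest.approx(1.25)
    assert proto.constant_at(600.0)
    assert not proto.constant_at(100.0)
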
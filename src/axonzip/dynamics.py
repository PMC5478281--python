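"""Overdamped dynamics of the zipper vertex.

The vertex moves so that the conservative force F (negative gradient of the
configuration energy) is balanced by friction linear in the vertex velocity,
F = H u, with a symmetric positive-semidefinite friction tensor H built from
up to three dissipation channels:

* elongation viscosity of each axon (resists strain rate L'/L),
* vertex-localized friction (resists the zippering velocity, i.e. the
  velocity component along the advancing-zipper direction),
* axon-substrate friction (distributed along the segments, axial and
  transverse components weighted separately; each material element moves
  with a linearly interpolated velocity, zero at the fixed point).

In the mirror-symmetric case the motion reduces to the scalar equation

    dy/dt = [S - 2T(1 - cos(b/2))] / [2 eta_elong (cos(b/2) - 1)^2 / L + eta_Z]

which is also used to infer S/T and eta_Z from a linear fit of the zippering
velocity against 1 - cos(b/2): slope = -2T/eta_Z, intercept = S/eta_Z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .statics import ZipperGeometry, ZipperMechanics, config_energy, vertex_force
from .units import NN_PER_PAS_UM2, deg2rad

__all__ = [
    "FrictionParams",
    "PerturbationProtocol",
    "VertexTrajectory",
    "symmetric_velocity",
    "assemble_friction_tensor",
    "step_general",
    "simulate_general",
    "fit_velocity_vs_angle",
    "infer_ST_ratio",
    "infer_etaZ",
    "dissipation_rate",
]


@dataclass(frozen=True)
class FrictionParams:
    """Dissipation constants selecting the dynamic regime.

    eta_elong : elongation viscosity, nN*s
    eta_z     : vertex-localized friction, nN*s/um (1 nN*s/um = 1e-3 N*s/m)
    eta_par   : axial substrate friction density, Pa*s
    eta_perp  : transverse substrate friction density, Pa*s
    """

    eta_elong: float = 0.0
    eta_z: float = 0.0
    eta_par: float = 0.0
    eta_perp: float = 0.0

    def __post_init__(self):
        vals = (self.eta_elong, self.eta_z, self.eta_par, self.eta_perp)
        if any(v < 0 for v in vals):
            raise ValueError("friction constants must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one friction constant must be positive")

    @classmethod
    def vertex_dominated(cls, eta_z: float = 1.0,
                         regularize: float = 1.0) -> "FrictionParams":
        """Vertex friction plus a small substrate term; the substrate term
        removes the singularity of the rank-1 vertex-friction tensor for
        motion transverse to the zipper axis."""
        return cls(eta_z=eta_z, eta_par=regularize, eta_perp=regularize)


@dataclass(frozen=True)
class PerturbationProtocol:
    """Piecewise-linear schedules for T1(t), T2(t), S(t).

    Values are held at the first/last breakpoint outside the time range.
    """

    times: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        for name in ("times", "T1", "T2", "S"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if not (self.T1.size == self.T2.size == self.S.size == n):
            raise ValueError("schedule arrays must share one length")
        if n == 0:
            raise ValueError("empty protocol")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if np.any(self.T1 <= 0) or np.any(self.T2 <= 0) or np.any(self.S < 0):
            raise ValueError("schedules must keep T positive and S >= 0")

    @classmethod
    def constant(cls, T1: float, T2: float, S: float) -> "PerturbationProtocol":
        return cls(np.array([0.0]), np.array([T1]), np.array([T2]),
                   np.array([S]))

    @classmethod
    def ramp(cls, T1, T2_start, T2_end, S, t_ramp_start=0.0, t_ramp_end=500.0):
        """Tension in the second axon grows linearly over the ramp window."""
        t = np.array([t_ramp_start, t_ramp_end])
        return cls(t, np.array([T1, T1]), np.array([T2_start, T2_end]),
                   np.array([S, S]))

    @classmethod
    def from_csv(cls, path) -> "PerturbationProtocol":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["T1"].to_numpy(),
                   df["T2"].to_numpy(), df["S"].to_numpy())

    def mechanics_at(self, t: float) -> ZipperMechanics:
        T1 = float(np.interp(t, self.times, self.T1))
        T2 = float(np.interp(t, self.times, self.T2))
        S = float(np.interp(t, self.times, self.S))
        return ZipperMechanics(T1, T2, S)

    def constant_at(self, t: float) -> bool:
        """True when the schedule no longer changes at and after time t."""
        return t >= float(self.times[-1])


@dataclass
class VertexTrajectory:
    """Sampled vertex path: times (s), positions (um), velocities (um/s),
    zipper angle (deg), zippered length (um) and configuration energy."""

    t: np.ndarray
    xy: np.ndarray
    u: np.ndarray
    beta_deg: np.ndarray
    zip_len: np.ndarray
    energy: np.ndarray
    termination: str = "converged"
    meta: dict = field(default_factory=dict)

    @property
    def u_z(self) -> np.ndarray:
        """Zippering velocity: rate of change of the zippered length."""
        return np.gradient(self.zip_len, self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "x": self.xy[:, 0], "y": self.xy[:, 1],
            "ux": self.u[:, 0], "uy": self.u[:, 1],
            "beta_deg": self.beta_deg,
            "zip_len": self.zip_len,
            "energy": self.energy,
        })


def symmetric_velocity(beta_deg: float, L: float, T: float, S: float,
                       eta_elong: float, eta_z: float) -> float:
    """Zippering velocity dy/dt (um/s) of a mirror-symmetric zipper.

    L is the instantaneous total free length of each axon (fixed point to
    vertex plus the zippered segment).
    """
    if eta_elong == 0.0 and eta_z == 0.0:
        raise ValueError("undefined friction: eta_elong and eta_z both zero")
    if L <= 0:
        raise ValueError("axon length must be positive")
    half = deg2rad(beta_deg) / 2.0
    drive = S - 2.0 * T * (1.0 - math.cos(half))
    drag = 2.0 * eta_elong * (math.cos(half) - 1.0) ** 2 / L + eta_z
    return drive / drag


def assemble_friction_tensor(geom: ZipperGeometry,
                             friction: FrictionParams) -> np.ndarray:
    """2x2 symmetric PSD friction tensor H (nN per um/s) at the vertex."""
    H = np.zeros((2, 2))
    ua, ub, uc = geom.unit("A"), geom.unit("B"), geom.unit("C")

    if friction.eta_z > 0:
        # acts only along the zipper axis, independent of geometry otherwise
        H += friction.eta_z * np.outer(uc, uc)

    if friction.eta_elong > 0:
        # axon 1 spans V->A plus the zippered segment; strain-rate coupling
        # vector is the sum of the two unit vectors at the vertex
        for uf, L in ((ua, geom.len_va + geom.len_vc),
                      (ub, geom.len_vb + geom.len_vc)):
            w = uf + uc
            H += (friction.eta_elong / L) * np.outer(w, w)

    if friction.eta_par > 0 or friction.eta_perp > 0:
        eye = np.eye(2)
        for uf, L in ((ua, geom.len_va), (ub, geom.len_vb),
                      (uc, geom.len_vc)):
            tt = np.outer(uf, uf)
            # linear velocity profile along the segment: integral of
            # (l/L)^2 dl = L/3 per unit squared vertex velocity
            H += (L / 3.0) * NN_PER_PAS_UM2 * (
                friction.eta_par * tt + friction.eta_perp * (eye - tt))
    return H


def step_general(geom: ZipperGeometry, mech: ZipperMechanics,
                 friction: FrictionParams, dt: float):
    """One explicit step of the overdamped motion; returns (geom', u)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    F = vertex_force(geom, mech)
    H = assemble_friction_tensor(geom, friction)
    u = np.linalg.solve(H, F)
    return geom.with_vertex(geom.V + dt * u), u


def simulate_general(A, B, C, V0, protocol: PerturbationProtocol,
                     friction: FrictionParams, dt: float = 0.1,
                     t_end: float = 1000.0, force_tol: float = 1e-8,
                     speed_tol: float = 1e-8, dt_max: float | None = None,
                     min_zip_len: float = 1e-3,
                     max_step_um: float = 0.05) -> VertexTrajectory:
    """Integrate the vertex equation of motion F = H u.

    Explicit adaptive stepping: under constant mechanics a step that raises
    the energy is rejected and dt halved; accepted steps slowly re-expand dt.
    Terminates when the force residual or speed drops below tolerance
    ("converged"), the zippered length shrinks to zero ("detached", the
    vertex reaches C and the axons separate), a free segment is consumed
    ("fully_zippered", the vertex recedes to A or B), or at t_end ("t_end").
    """
    geom = ZipperGeometry(A, B, C, V0)
    if dt_max is None:
        dt_max = 50.0 * dt
    dt0 = dt

    ts, xys, us, betas, lens, energies = [], [], [], [], [], []
    t = 0.0
    termination = "t_end"

    def record(geom, u, mech):
        ts.append(t)
        xys.append(geom.V.copy())
        us.append(u.copy())
        betas.append(geom.beta_deg)
        lens.append(geom.len_vc)
        energies.append(config_energy(geom, mech))

    mech = protocol.mechanics_at(t)
    F = vertex_force(geom, mech)
    H = assemble_friction_tensor(geom, friction)
    u = np.linalg.solve(H, F)
    record(geom, u, mech)

    while t < t_end:
        mech = protocol.mechanics_at(t)
        F = vertex_force(geom, mech)
        H = assemble_friction_tensor(geom, friction)
        u = np.linalg.solve(H, F)
        fmag = float(np.linalg.norm(F))
        umag = float(np.linalg.norm(u))
        if (fmag < force_tol or umag < speed_tol) \
                and protocol.constant_at(t):
            termination = "converged"
            break

        constant = protocol.constant_at(t)
        e_old = config_energy(geom, mech)
        step_dt = min(dt, t_end - t)
        if umag * step_dt > max_step_um:
            # keep individual displacements small; this also damps the
            # explicit-Euler ringing when one friction channel is weak
            step_dt = max_step_um / umag
        accepted = False
        for _ in range(60):
            trial = geom.with_vertex(geom.V + step_dt * u)
            if trial.len_vc < min_zip_len:
                t += step_dt
                geom = trial
                record(geom, u, mech)
                termination = "detached"
                accepted = None
                break
            if min(trial.len_va, trial.len_vb) < min_zip_len:
                t += step_dt
                geom = trial
                record(geom, u, mech)
                termination = "fully_zippered"
                accepted = None
                break
            e_new = config_energy(trial, mech)
            if constant and e_new > e_old + 1e-12 * max(abs(e_old), 1.0):
                step_dt *= 0.5
                dt = max(dt * 0.5, 1e-9)
                continue
            accepted = True
            break
        if accepted is None:
            break
        if not accepted:
            termination = "stalled"
            break
        t += step_dt
        geom = trial
        if constant:
            dt = min(dt * 1.2, dt_max, max(dt0, dt))
        else:
            dt = min(dt, dt0)  # keep fine steps while the schedule moves
        record(geom, u, mech)

    traj = VertexTrajectory(
        t=np.array(ts), xy=np.array(xys), u=np.array(us),
        beta_deg=np.array(betas), zip_len=np.array(lens),
        energy=np.array(energies), termination=termination,
        meta={"friction": friction, "dt0": dt0})
    return traj


def fit_velocity_vs_angle(traj: VertexTrajectory,
                          smoothing_halfwidth: float = 10.0):
    """OLS fit of the smoothed zippering velocity against 1 - cos(beta/2).

    The trajectory is resampled on a uniform time grid; the zippering
    velocity is obtained by convolving the zippered-length series with the
    derivative of a Gaussian kernel of the given half-width (s), and the
    angle series is smoothed with the same kernel.  Returns
    (slope, intercept, r_squared).
    """
    if traj.t.size < 3:
        raise ValueError("trajectory too short to fit")
    dt = float(np.median(np.diff(traj.t)))
    tu = np.arange(traj.t[0], traj.t[-1], dt)
    zl = np.interp(tu, traj.t, traj.zip_len)
    beta = np.interp(tu, traj.t, traj.beta_deg)

    sigma = max(smoothing_halfwidth / dt, 1e-9)
    uz = ndimage.gaussian_filter1d(zl, sigma, order=1, mode="nearest") / dt
    beta_s = ndimage.gaussian_filter1d(beta, sigma, order=0, mode="nearest")

    # discard the kernel-support edges
    margin = int(math.ceil(3 * sigma))
    if tu.size - 2 * margin < 10:
        raise ValueError("fewer than 10 samples remain after smoothing")
    uz = uz[margin:-margin]
    beta_s = beta_s[margin:-margin]

    x = 1.0 - np.cos(np.deg2rad(beta_s) / 2.0)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate fit: no variance in 1 - cos(beta/2)")
    res = stats.linregress(x, uz)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def infer_ST_ratio(slope: float, intercept: float) -> float:
    """Adhesion-to-tension ratio S/T from the velocity-vs-angle fit.

    With vertex friction dominant, slope = -2T/eta_Z and intercept =
    S/eta_Z, so S/T = 2 |intercept / slope|.
    """
    if slope >= 0:
        raise ValueError("unphysical fit: slope must be negative")
    return 2.0 * abs(intercept / slope)


def infer_etaZ(slope: float, T: float) -> float:
    """Vertex friction constant eta_Z (nN*s/um) from the fit slope and an
    assumed tension T (nN)."""
    if slope >= 0:
        raise ValueError("unphysical fit: slope must be negative")
    if T <= 0:
        raise ValueError("tension must be positive")
    return 2.0 * T / abs(slope)


def dissipation_rate(eta_z: float, u_um_per_min: float) -> float:
    """Rate of frictional energy dissipation eta_Z * u^2, in J/min.

    eta_z in nN*s/um, u in um/min.
    """
    if eta_z < 0:
        raise ValueError("eta_z must be non-negative")
    eta_si = eta_z * 1e-3            # N*s/m
    u_si = u_um_per_min * 1e-6 / 60  # m/s
    watts = eta_si * u_si ** 2
    return watts * 60.0
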
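"""Static force balance of two-axon zippers.

A zipper is described by three fixed points A, B, C and a mobile vertex V.
The segments VA and VB are the free portions of the two axons, VC is the
segment along which they adhere.  The configuration energy is

    E(V) = T1 (|VA| + |VC|) + T2 (|VB| + |VC|) - S |VC|

with tensions T1, T2 and adhesion strength S (all nN; lengths um).  The
conservative force acting on the vertex is the negative energy gradient,

    F = T1 va + T2 vb + (T1 + T2 - S) vc

where va, vb, vc are unit vectors from V toward A, B, C.  Equilibrium
requires both the axial balance -(T1+T2-S) + T1 cos(a1) + T2 cos(a2) = 0
and the transverse balance T1 sin(a1) = T2 sin(a2), where a1, a2 are the
angles each free segment makes with the extension of the zipper axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .units import rad2deg, deg2rad

__all__ = [
    "FULL_ZIPPERING",
    "ZipperGeometry",
    "ZipperMechanics",
    "EquilibriumResult",
    "equilibrium_angle_symmetric",
    "adhesion_from_angle",
    "equilibrium_angles_asymmetric",
    "config_energy",
    "vertex_force",
    "find_equilibrium_vertex",
    "loop_mean_angle",
    "classify_loop",
    "adhesion_energy_density",
    "load_params",
]


class _FullZippering:
    """Sentinel state: adhesion wins everywhere, no interior equilibrium."""

    def __repr__(self) -> str:  # pragma: no cover
        return "FULL_ZIPPERING"

    def __bool__(self) -> bool:
        return False


#: Returned (not raised) when S exceeds the tensile bound and the zippered
#: segment grows without an interior equilibrium; network-level callers use
#: it to merge vertices.
FULL_ZIPPERING = _FullZippering()


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-D point, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class ZipperGeometry:
    """Fixed endpoints A, B, C and mobile vertex V, all in um."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        for name in ("A", "B", "C", "V"):
            object.__setattr__(self, name, _as_point(getattr(self, name)))
        for name, length in (("VA", self.len_va), ("VB", self.len_vb),
                             ("VC", self.len_vc)):
            if length <= 0.0:
                raise ValueError(f"degenerate geometry: |{name}| = 0")

    @property
    def len_va(self) -> float:
        return float(np.linalg.norm(self.A - self.V))

    @property
    def len_vb(self) -> float:
        return float(np.linalg.norm(self.B - self.V))

    @property
    def len_vc(self) -> float:
        return float(np.linalg.norm(self.C - self.V))

    def unit(self, which: str) -> np.ndarray:
        """Unit vector from V toward fixed point `which` in {'A','B','C'}."""
        target = getattr(self, which)
        d = target - self.V
        n = np.linalg.norm(d)
        if n == 0.0:
            raise ValueError(f"vertex coincides with {which}")
        return d / n

    @property
    def alpha1(self) -> float:
        """Angle (rad) between VA and the zipper-axis extension beyond V."""
        return _angle_between(self.unit("A"), -self.unit("C"))

    @property
    def alpha2(self) -> float:
        return _angle_between(self.unit("B"), -self.unit("C"))

    @property
    def beta(self) -> float:
        """Full zipper angle a1 + a2 (rad)."""
        return self.alpha1 + self.alpha2

    @property
    def beta_deg(self) -> float:
        return rad2deg(self.beta)

    def with_vertex(self, V) -> "ZipperGeometry":
        return ZipperGeometry(self.A, self.B, self.C, _as_point(V))


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return math.acos(c)


@dataclass(frozen=True)
class ZipperMechanics:
    """Tensions T1, T2 and axon-axon adhesion strength S (nN)."""

    T1: float
    T2: float
    S: float

    def __post_init__(self):
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("tensions must be positive")
        if self.S < 0:
            raise ValueError("adhesion strength must be non-negative")

    @property
    def symmetric(self) -> bool:
        return math.isclose(self.T1, self.T2, rel_tol=1e-12)

    @classmethod
    def symmetric_case(cls, T: float, S: float) -> "ZipperMechanics":
        return cls(T, T, S)


def equilibrium_angle_symmetric(T: float, S: float):
    """Equilibrium zipper angle beta (degrees) for a symmetric zipper.

    Solves S = 2 T (1 - cos(beta/2)).  Returns ``FULL_ZIPPERING`` when
    S > 2T (no static equilibrium below 180 degrees).
    """
    if T <= 0:
        raise ValueError("tension must be positive")
    if S < 0:
        raise ValueError("adhesion strength must be non-negative")
    if S > 2.0 * T:
        return FULL_ZIPPERING
    return rad2deg(2.0 * math.acos(1.0 - S / (2.0 * T)))


def adhesion_from_angle(T: float, beta_deg: float) -> float:
    """Adhesion strength S (nN) balancing tension T at zipper angle beta."""
    if T <= 0:
        raise ValueError("tension must be positive")
    if not 0.0 <= beta_deg <= 180.0:
        raise ValueError(f"zipper angle must lie in [0, 180] deg, got {beta_deg}")
    return 2.0 * T * (1.0 - math.cos(deg2rad(beta_deg) / 2.0))


def equilibrium_angles_asymmetric(T1: float, T2: float, S: float):
    """Equilibrium half-angles (a1, a2) in degrees for unequal tensions.

    Reduces the two balance equations to one: the transverse condition
    gives sin(a2) = (T1/T2) sin(a1), substituted into the axial condition,
    which is then solved by bracketed root finding on a1.  Returns
    ``FULL_ZIPPERING`` when no solution with a1, a2 in (0, 90) deg exists.
    """
    if T1 <= 0 or T2 <= 0:
        raise ValueError("tensions must be positive")
    if S < 0:
        raise ValueError("adhesion strength must be non-negative")
    if S == 0.0:
        return (0.0, 0.0)

    # sin(a1) may not exceed T2/T1 (else the transverse balance is unsolvable)
    a1_max = math.pi / 2.0
    if T1 > T2:
        a1_max = min(a1_max, math.asin(T2 / T1))

    def axial(a1: float) -> float:
        a2 = math.asin(min(1.0, (T1 / T2) * math.sin(a1)))
        return -(T1 + T2 - S) + T1 * math.cos(a1) + T2 * math.cos(a2)

    # axial(0) = S > 0 and axial is strictly decreasing on (0, a1_max)
    if axial(a1_max) > 0.0:
        return FULL_ZIPPERING
    a1 = optimize.brentq(axial, 0.0, a1_max, xtol=1e-14, rtol=8.9e-16)
    a2 = math.asin(min(1.0, (T1 / T2) * math.sin(a1)))
    return (rad2deg(a1), rad2deg(a2))


def config_energy(geom: ZipperGeometry, mech: ZipperMechanics) -> float:
    """Total tensile + adhesive energy of the configuration (nN*um)."""
    return (mech.T1 * (geom.len_va + geom.len_vc)
            + mech.T2 * (geom.len_vb + geom.len_vc)
            - mech.S * geom.len_vc)


def vertex_force(geom: ZipperGeometry, mech: ZipperMechanics) -> np.ndarray:
    """Conservative force on the vertex, -grad E (nN)."""
    return (mech.T1 * geom.unit("A")
            + mech.T2 * geom.unit("B")
            + (mech.T1 + mech.T2 - mech.S) * geom.unit("C"))


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of the equilibrium vertex search.

    state is "interior" (strict local energy minimum between the fixed
    points), "full_zippering" (adhesion wins and the vertex recedes from C
    without an interior equilibrium) or "detached" (the minimum sits at C:
    the zippered segment length shrinks to zero).
    """

    V: np.ndarray
    state: str
    residual: float
    energy: float

    @property
    def full_zippering(self) -> bool:
        return self.state == "full_zippering"

    def __bool__(self) -> bool:
        return self.state == "interior"


def find_equilibrium_vertex(A, B, C, mech: ZipperMechanics,
                            tol: float = 1e-12) -> EquilibriumResult:
    """Locate the vertex position minimizing the configuration energy.

    Derivative-based minimization started from the segment-midpoint
    heuristic, polished by Newton iteration on the force.  Boundary
    outcomes are flagged via ``EquilibriumResult.state`` instead of raising.
    """
    A, B, C = _as_point(A), _as_point(B), _as_point(C)
    u, w = A - C, B - C
    cross = abs(float(u[0] * w[1] - u[1] * w[0]))
    if cross < 1e-12 * max(np.linalg.norm(A - C), np.linalg.norm(B - C), 1.0):
        raise ValueError("degenerate configuration: A, B, C are collinear")

    mid = 0.5 * (A + B)

    # no interior equilibrium angle pair: adhesion exceeds the tensile bound
    if equilibrium_angles_asymmetric(mech.T1, mech.T2, mech.S) is FULL_ZIPPERING:
        geom = ZipperGeometry(A, B, C, mid)
        return EquilibriumResult(mid, "full_zippering", math.nan,
                                 config_energy(geom, mech))

    # interior equilibrium exists only if the equilibrium angle exceeds
    # the angle subtended at C; otherwise the minimum sits at C (detached)
    a1, a2 = equilibrium_angles_asymmetric(mech.T1, mech.T2, mech.S)
    ca = (A - C) / np.linalg.norm(A - C)
    cb = (B - C) / np.linalg.norm(B - C)
    angle_at_C = math.degrees(math.acos(float(np.clip(np.dot(ca, cb),
                                                      -1.0, 1.0))))
    if a1 + a2 <= angle_at_C + 1e-9:
        geom = ZipperGeometry(A, B, C, mid)
        return EquilibriumResult(C.copy(), "detached", math.nan,
                                 config_energy(geom, mech))

    v0 = mid + 0.25 * (C - mid)
    eps = 1e-9

    def fun(v):
        if min(np.linalg.norm(v - P) for P in (A, B, C)) < eps:
            return np.inf
        geom = ZipperGeometry(A, B, C, v)
        return config_energy(geom, mech)

    def jac(v):
        if min(np.linalg.norm(v - P) for P in (A, B, C)) < eps:
            return np.zeros(2)
        geom = ZipperGeometry(A, B, C, v)
        return -vertex_force(geom, mech)

    res = optimize.minimize(fun, v0, jac=jac, method="BFGS",
                            options={"gtol": 1e-13, "maxiter": 500})
    V = res.x
    if np.linalg.norm(V - C) < 1e-4:
        geom = ZipperGeometry(A, B, C, mid)
        return EquilibriumResult(C.copy(), "detached", math.nan,
                                 config_energy(geom, mech))
    geom = ZipperGeometry(A, B, C, V)
    residual = float(np.linalg.norm(vertex_force(geom, mech)))
    if residual > 1e-10:
        # polish with Newton on the force
        sol = optimize.root(
            lambda v: -vertex_force(ZipperGeometry(A, B, C, v), mech),
            V, tol=tol)
        if sol.success:
            V = sol.x
            geom = ZipperGeometry(A, B, C, V)
            residual = float(np.linalg.norm(vertex_force(geom, mech)))
    return EquilibriumResult(V, "interior", residual,
                             config_energy(geom, mech))


def loop_mean_angle(n_sides: int) -> float:
    """Mean vertex angle (deg) of a closed loop with n straight sides."""
    if n_sides < 3:
        raise ValueError("a loop needs at least 3 sides")
    return (n_sides - 2) * 180.0 / n_sides


def classify_loop(current_angle_deg: float, beta_eq_deg: float) -> str:
    """Stability of a loop: vertices advance (loop shrinks) when the
    equilibrium angle exceeds the current one."""
    if beta_eq_deg > current_angle_deg:
        return "shrink"
    if beta_eq_deg < current_angle_deg:
        return "expand"
    return "stable"


def adhesion_energy_density(S_nN: float, d_um: float, f: float) -> float:
    """Adhesion energy per unit membrane area (J/um^2).

    S is spread over the adhered strip of width f * pi * d, the contacting
    fraction f of the circumference of an axon of diameter d.
    """
    if S_nN < 0:
        raise ValueError("adhesion strength must be non-negative")
    if d_um <= 0:
        raise ValueError("diameter must be positive")
    if not 0.0 < f < 1.0:
        raise ValueError("contact fraction must lie in (0, 1)")
    # nN/um = 1e-3 J/m^2 = 1e-15 J/um^2
    return S_nN / (f * math.pi * d_um) * 1e-15


def load_params(path) -> dict:
    """Read a plain key=value parameter file.

    Lines look like ``T1 = 0.68  # nN``; blank lines and '#' comments are
    ignored; values parse as floats where possible.
    """
    params: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed parameter line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            try:
                params[key] = float(value)
            except ValueError:
                params[key] = value
    return params
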
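"""Biomembrane Force Probe (BFP) tension analysis.

An aspirated red blood cell acts as a linear spring of stiffness k set by
the probe geometry and aspiration pressure.  A recording of probe force and
axon deflection angle is segmented into stable plateaux; the regression of
the perpendicular force against sin(deflection) has slope 2T, giving the
axon tension and its uncertainty.  Per-axon estimates combine into a
population tension density as an equal-weight Gaussian mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import EmpiricalPDF

__all__ = [
    "BFPProbe",
    "BFPRecording",
    "Plateau",
    "TensionEstimate",
    "probe_stiffness",
    "detect_plateaux",
    "fit_tension",
    "analyze_recording",
    "population_tension_pdf",
]


@dataclass(frozen=True)
class BFPProbe:
    """Probe geometry and aspiration pressure.

    Rp : internal pipette radius (um)
    Rc : RBC-bead contact radius (um)
    R0 : unstrained aspirated RBC radius (um)
    dP : aspiration pressure (Pa)
    """

    Rp: float
    Rc: float
    R0: float
    dP: float

    def __post_init__(self):
        if not 0 < self.Rp < self.R0:
            raise ValueError("require 0 < Rp < R0")
        if not 0 < self.Rc < self.R0:
            raise ValueError("require 0 < Rc < R0")
        if self.dP <= 0:
            raise ValueError("aspiration pressure must be positive")

    @property
    def rp_hat(self) -> float:
        return self.Rp / self.R0

    @property
    def rc_hat(self) -> float:
        return self.Rc / self.R0

    @property
    def stiffness(self) -> float:
        return probe_stiffness(self)


def probe_stiffness(probe: BFPProbe) -> float:
    """RBC spring stiffness k in pN/um.

    k = Rp dP pi (1 - rp) / [ln(4 / (rp rc)) - (1 - rp/4 - 3 rp^2/8 + rc^2)]

    with rp = Rp/R0, rc = Rc/R0.  Strictly linear in the pressure dP
    (Pa = pN/um^2, so Rp*dP is already pN/um).
    """
    rp, rc = probe.rp_hat, probe.rc_hat
    denom = math.log(4.0 / (rp * rc)) - (1.0 - rp / 4.0
                                         - 3.0 * rp ** 2 / 8.0 + rc ** 2)
    if denom <= 0:
        raise ValueError("invalid probe geometry: non-positive denominator")
    return probe.Rp * probe.dP * math.pi * (1.0 - rp) / denom


@dataclass
class BFPRecording:
    """Per-frame probe force and angles.

    t         : time (s), monotone
    force_pN  : probe force F_BFP
    delta_deg : axon deflection angle; negative values mean pushing
    phi_deg   : pipette-axon angle (projection of the force onto the
                direction normal to the axon uses sin(phi))
    """

    t: np.ndarray
    force_pN: np.ndarray
    delta_deg: np.ndarray
    phi_deg: np.ndarray
    fps: float = 65.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("t", "force_pN", "delta_deg", "phi_deg"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.abs(self.delta_deg) >= 90):
            raise ValueError("deflection angle must satisfy |delta| < 90 deg")

    @property
    def f_perp(self) -> np.ndarray:
        """Probe force projected perpendicular to the axon."""
        return self.force_pN * np.sin(np.deg2rad(self.phi_deg))

    @classmethod
    def from_csv(cls, path, fps: float = 65.0) -> "BFPRecording":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df["force_pN"].to_numpy(),
                   df["delta_deg"].to_numpy(), df["phi_deg"].to_numpy(),
                   fps=fps)


@dataclass(frozen=True)
class Plateau:
    """Summary of one stable interval of the recording."""

    start: int                 # first frame index
    stop: int                  # one past the last frame index
    t_start: float
    t_end: float
    mean_force: float
    sd_force: float
    mean_delta_deg: float
    mean_sin_delta: float
    sd_sin_delta: float
    mean_f_perp: float
    sd_f_perp: float
    n_frames: int = 0

    @property
    def pulling(self) -> bool:
        return self.mean_delta_deg > 0


def detect_plateaux(rec: BFPRecording, window: float = 2.0,
                    sd_threshold: float = 5.0,
                    min_duration: float = 3.0) -> list:
    """Stable force plateaux: maximal runs where the centred rolling
    standard deviation of the force stays below the threshold, lasting at
    least min_duration seconds.  Returns a (possibly empty) ordered list of
    disjoint Plateau summaries.
    """
    dt = float(np.median(np.diff(rec.t)))
    nwin = max(int(round(window / dt)), 2)
    roll = (pd.Series(rec.force_pN)
            .rolling(nwin, center=True, min_periods=max(nwin // 2, 2))
            .std())
    stable = roll.to_numpy() < sd_threshold

    plateaux = []
    n = stable.size
    i = 0
    while i < n:
        if not stable[i]:
            i += 1
            continue
        j = i
        while j < n and stable[j]:
            j += 1
        if rec.t[j - 1] - rec.t[i] >= min_duration:
            plateaux.append(_summarize(rec, i, j))
        i = j
    return plateaux


def _summarize(rec: BFPRecording, i: int, j: int) -> Plateau:
    sl = slice(i, j)
    sin_d = np.sin(np.deg2rad(rec.delta_deg[sl]))
    fperp = rec.f_perp[sl]
    return Plateau(
        start=i, stop=j, t_start=float(rec.t[i]), t_end=float(rec.t[j - 1]),
        mean_force=float(rec.force_pN[sl].mean()),
        sd_force=float(rec.force_pN[sl].std(ddof=1)),
        mean_delta_deg=float(rec.delta_deg[sl].mean()),
        mean_sin_delta=float(sin_d.mean()),
        sd_sin_delta=float(sin_d.std(ddof=1)),
        mean_f_perp=float(fperp.mean()),
        sd_f_perp=float(fperp.std(ddof=1)),
        n_frames=j - i)


@dataclass(frozen=True)
class TensionEstimate:
    """Linear-fit tension: slope of F_perp vs sin(delta) equals 2T.

    Two slope uncertainties are carried: ``slope_sd`` is the usual
    residual-based standard error of the regression, while ``sigma_T``
    propagates the per-plateau measurement variances (standard deviations
    of force and deflection during each plateau, divided by the frame
    count) through the least-squares weights.  The propagated value is
    preferred for coverage statements because with only a handful of
    plateaux the residual-based error has very few degrees of freedom.
    """

    T: float                   # pN
    sigma_T: float             # pN, propagated plateau uncertainty
    slope: float
    intercept: float
    slope_sd: float            # residual-based standard error
    r_squared: float
    n_plateaux: int


def fit_tension(plateaux, pulling_only: bool = True) -> TensionEstimate:
    """Ordinary least squares of plateau-mean F_perp on sin(delta).

    The intercept is free: a reference-length offset shifts all forces
    equally and must not bias the slope.  Requires at least three plateaux
    (pushing plateaux, delta < 0, are excluded by default).
    """
    pts = [p for p in plateaux if (p.pulling or not pulling_only)]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 plateaux for a tension fit, got {len(pts)}")
    x = np.array([p.mean_sin_delta for p in pts])
    y = np.array([p.mean_f_perp for p in pts])
    if np.ptp(x) < 1e-12:
        raise ValueError("no variance in sin(delta) across plateaux")
    res = stats.linregress(x, y)
    slope_sd = float(res.stderr) if np.isfinite(res.stderr) else 0.0

    # propagate plateau-mean measurement variances through the OLS weights
    n = np.array([max(p.n_frames, 1) for p in pts], dtype=float)
    var_y = np.array([p.sd_f_perp for p in pts]) ** 2 / n
    var_x = np.array([p.sd_sin_delta for p in pts]) ** 2 / n
    cx = x - x.mean()
    sxx = float((cx ** 2).sum())
    if sxx > 0:
        w = cx / sxx
        var_slope = float((w ** 2 * (var_y + res.slope ** 2 * var_x)).sum())
        sigma_slope = math.sqrt(var_slope)
    else:  # pragma: no cover
        sigma_slope = slope_sd
    return TensionEstimate(
        T=float(res.slope) / 2.0, sigma_T=sigma_slope / 2.0,
        slope=float(res.slope), intercept=float(res.intercept),
        slope_sd=slope_sd, r_squared=float(res.rvalue ** 2),
        n_plateaux=len(pts))


def analyze_recording(rec: BFPRecording, window: float = 2.0,
                      sd_threshold: float = 5.0, min_duration: float = 3.0,
                      pulling_only: bool = True):
    """detect_plateaux + fit_tension in one call; returns
    (plateaux, TensionEstimate)."""
    plateaux = detect_plateaux(rec, window=window, sd_threshold=sd_threshold,
                               min_duration=min_duration)
    return plateaux, fit_tension(plateaux, pulling_only=pulling_only)


def population_tension_pdf(estimates, grid_step: float = 1.0) -> EmpiricalPDF:
    """Population tension density from per-axon (T, sigma) pairs in pN.

    Each estimate contributes a Normal(T, sigma); the equal-weight sum is
    normalized on a grid with 1 pN spacing spanning [0, Tmax + 5 sigma_max].
    """
    pairs = [(float(t), float(s)) for t, s in estimates]
    if not pairs:
        raise ValueError("need at least one tension estimate")
    if any(s <= 0 for _, s in pairs):
        raise ValueError("all uncertainties must be positive")
    hi = max(t for t, _ in pairs) + 5.0 * max(s for _, s in pairs)
    grid = np.arange(0.0, hi + grid_step, grid_step)
    dens = np.zeros_like(grid)
    for t, s in pairs:
        dens += np.exp(-0.5 * ((grid - t) / s) ** 2) / (
            s * math.sqrt(2 * math.pi))
    pdf = EmpiricalPDF(grid, dens, name="T", units="pN",
                       meta={"n_estimates": len(pairs)})
    return pdf.normalized()
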
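"""Empirical densities and the tension <-> zipper-angle inference.

The static balance S = 2T(1 - cos(beta/2)) maps a tension distribution
p(T) to an equilibrium-angle distribution

    q(beta) = p(S / (2 Phi)) * (S/4) * sqrt(2 - Phi) / Phi^(3/2),
    Phi = 1 - cos(beta/2),

which underpins two ways of estimating the adhesion strength S from the
measured tension and angle distributions: a correlation match over a 1 pN
grid of S, and a screening of the independent joint (T, beta) distribution
into 1 pN bins of S.  Fascicles of mean size n enter through the scaling
mean ~ n, sd ~ sqrt(n), S ~ sqrt(n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import RAD_PER_DEG

__all__ = [
    "EmpiricalPDF",
    "FascicleParams",
    "kde",
    "transform_tension_to_angle",
    "match_adhesion",
    "joint_screening",
    "lognormal_from_moments",
    "lognormal_pdf",
    "fascicle_scale",
    "median_angle_shift",
    "crossing_probability",
    "rescale_factor_from_length",
    "default_angle_grid",
]

#: 1 pN expressed in nN; bin width of the adhesion screening and grids.
PN = 1e-3


def default_angle_grid(step_deg: float = 0.05) -> np.ndarray:
    """Angle grid on the open interval (0, 180) degrees."""
    return np.arange(step_deg, 180.0, step_deg)


@dataclass
class EmpiricalPDF:
    """A density sampled on a strictly increasing grid.

    Normalization is by the trapezoidal rule; summary statistics (median,
    quantiles) use inverse-CDF interpolation on the grid.
    """

    grid: np.ndarray
    density: np.ndarray
    name: str = ""
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be a 1-D array with >= 2 points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.density.shape != self.grid.shape:
            raise ValueError("density and grid shapes differ")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")
        self.density = np.clip(self.density, 0.0, None)

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def normalized(self) -> "EmpiricalPDF":
        z = self.integral
        if z <= 0:
            raise ValueError("cannot normalize a zero density")
        return EmpiricalPDF(self.grid, self.density / z, self.name,
                            self.units, dict(self.meta))

    def evaluate(self, x) -> np.ndarray:
        """Linear interpolation of the density; zero outside the grid."""
        return np.interp(np.asarray(x, dtype=float), self.grid, self.density,
                         left=0.0, right=0.0)

    def cdf(self) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(
            0.5 * (self.density[1:] + self.density[:-1]) * np.diff(self.grid))])
        return c / c[-1] if c[-1] > 0 else c

    def quantile(self, q: float) -> float:
        if not 0.0 <= q <= 1.0:
            raise ValueError("quantile level must lie in [0, 1]")
        c = self.cdf()
        # strip flat leading/trailing stretches so interp is well defined
        return float(np.interp(q, c, self.grid))

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    @property
    def mean(self) -> float:
        p = self.normalized()
        return float(np.trapezoid(p.grid * p.density, p.grid))

    @property
    def iqr(self) -> tuple:
        return (self.quantile(0.25), self.quantile(0.75))


def kde(samples, bandwidth: float | None = None,
        grid: np.ndarray | None = None, name: str = "",
        units: str = "") -> EmpiricalPDF:
    """Gaussian-kernel density of a 1-D sample, normalized on the grid.

    Bandwidth defaults to Silverman's rule on the raw samples.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two samples")
    if bandwidth is None:
        sd = float(np.std(x, ddof=1))
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        scale = min(sd, iqr / 1.349) if iqr > 0 else sd
        if scale <= 0:
            scale = max(abs(x[0]), 1.0) * 1e-3
        bandwidth = 0.9 * scale * x.size ** (-0.2)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        lo, hi = x.min() - 4 * bandwidth, x.max() + 4 * bandwidth
        grid = np.linspace(lo, hi, 2048)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z ** 2).sum(axis=1) / (
        x.size * bandwidth * math.sqrt(2 * math.pi))
    pdf = EmpiricalPDF(grid, dens, name=name, units=units,
                       meta={"kernel": "gaussian", "bandwidth": bandwidth})
    return pdf.normalized()


def transform_tension_to_angle(p_T: EmpiricalPDF, S: float,
                               grid_deg: np.ndarray | None = None
                               ) -> EmpiricalPDF:
    """Push the tension density through the static balance to angles.

    Tensions below S/2 have no equilibrium below 180 degrees; their mass is
    reported as ``meta['full_zippering_mass']`` and the returned density is
    normalized on (0, 180) degrees.
    """
    if S <= 0:
        raise ValueError("adhesion strength must be positive")
    if grid_deg is None:
        grid_deg = default_angle_grid()
    beta = grid_deg * RAD_PER_DEG
    phi = 1.0 - np.cos(beta / 2.0)
    T = S / (2.0 * phi)
    jac = (S / 4.0) * np.sqrt(2.0 - phi) / phi ** 1.5  # |dT/dbeta|, per rad
    dens = p_T.evaluate(T) * jac * RAD_PER_DEG

    # mass of the branch with no interior equilibrium (T < S/2)
    mask = p_T.grid < S / 2.0
    atom = 0.0
    if mask.sum() >= 2:
        atom = float(np.trapezoid(p_T.density[mask], p_T.grid[mask]))
    out = EmpiricalPDF(grid_deg, dens, name="beta", units="deg",
                       meta={"S": S, "full_zippering_mass": atom})
    return out.normalized()


def match_adhesion(p_T: EmpiricalPDF, q_obs: EmpiricalPDF,
                   S_grid: np.ndarray | None = None):
    """Adhesion strength maximizing the correlation between the transformed
    tension density and an observed angle density.

    Exhaustive search over a 1 pN grid; returns (S_star, r_star) in the
    units of p_T (nN) and the Pearson correlation at the optimum.
    """
    if S_grid is None:
        upper = 2.0 * p_T.quantile(0.05)
        S_grid = np.arange(PN, upper + PN / 2, PN)
    rs = np.empty(S_grid.size)
    q_ref = q_obs.density
    for i, S in enumerate(S_grid):
        q = transform_tension_to_angle(p_T, float(S), grid_deg=q_obs.grid)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(q.density, q_ref)[0, 1]
        rs[i] = r if np.isfinite(r) else -np.inf
    if np.ptp(rs[np.isfinite(rs)]) < 1e-12:
        warnings.warn("flat correlation profile: S is not identifiable")
    i = int(np.argmax(rs))
    return float(S_grid[i]), float(rs[i])


def joint_screening(p_T: EmpiricalPDF, q_beta: EmpiricalPDF,
                    bin_nN: float = PN) -> EmpiricalPDF:
    """Distribution of S = 2T(1 - cos(beta/2)) under independent T, beta.

    The product measure of the two marginals is screened cell by cell into
    bins of the stated width (default 1 pN).  The independence assumption
    makes the spread an upper bound; it is recorded in the metadata.
    """
    wT = _cell_masses(p_T)
    wB = _cell_masses(q_beta)
    phi = 1.0 - np.cos(q_beta.grid * RAD_PER_DEG / 2.0)
    S_cells = 2.0 * np.outer(p_T.grid, phi)
    weights = np.outer(wT, wB)

    s_max = float(S_cells.max())
    edges = np.arange(0.0, s_max + 2 * bin_nN, bin_nN)
    hist, _ = np.histogram(S_cells.ravel(), bins=edges,
                           weights=weights.ravel())
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = hist / bin_nN
    pdf = EmpiricalPDF(centers, dens, name="S", units="nN",
                       meta={"bin_nN": bin_nN,
                             "assumption": "T and beta independent"})
    return pdf.normalized()


def _cell_masses(p: EmpiricalPDF) -> np.ndarray:
    """Per-grid-point probability masses (trapezoid weights)."""
    dg = np.gradient(p.grid)
    w = p.density * dg
    return w / w.sum()


def lognormal_from_moments(mean: float, sd: float) -> tuple:
    """(mu, sigma) of the lognormal with the given arithmetic mean and sd."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def lognormal_pdf(mean: float, sd: float,
                  grid: np.ndarray | None = None) -> EmpiricalPDF:
    """Lognormal density with the given moments, sampled on a tension grid
    (default 1 pN spacing up to mean + 12 sd)."""
    mu, sigma = lognormal_from_moments(mean, sd)
    if grid is None:
        grid = np.arange(PN, mean + 12.0 * sd, PN)
    with np.errstate(divide="ignore"):
        logg = np.log(grid)
    dens = np.exp(-0.5 * ((logg - mu) / sigma) ** 2) / (
        grid * sigma * math.sqrt(2 * math.pi))
    return EmpiricalPDF(grid, dens, name="T", units="nN",
                        meta={"mu": mu, "sigma": sigma}).normalized()


@dataclass(frozen=True)
class FascicleParams:
    """Tension-law moments and adhesion strength of a fascicle of mean
    size n (n = 1 is a single axon)."""

    mean_T: float
    sd_T: float
    S: float
    n: float = 1.0

    def __post_init__(self):
        if min(self.mean_T, self.sd_T, self.S) <= 0:
            raise ValueError("all parameters must be positive")
        if self.n < 1:
            raise ValueError("fascicle size must be >= 1")


def fascicle_scale(base: FascicleParams, n: float) -> FascicleParams:
    """Rescale to mean fascicle size n: tension mean scales linearly with
    the number of axons, its sd with sqrt(n) (independent contributions),
    and the adhesion with sqrt(n) (circular cross-section surface)."""
    if n < 1:
        raise ValueError("fascicle size must be >= 1")
    m = n / base.n
    return FascicleParams(base.mean_T * m, base.sd_T * math.sqrt(m),
                          base.S * math.sqrt(m), n)


def median_angle_shift(base: FascicleParams, n: float,
                       grid_deg: np.ndarray | None = None) -> float:
    """Decrease (deg) of the median equilibrium angle when the fascicle
    parameters are rescaled from `base` to mean size n."""
    scaled = fascicle_scale(base, n)
    medians = []
    for p in (base, scaled):
        pdf_T = lognormal_pdf(p.mean_T, p.sd_T)
        q = transform_tension_to_angle(pdf_T, p.S, grid_deg=grid_deg)
        medians.append(q.median)
    return medians[0] - medians[1]


def crossing_probability(q_beta: EmpiricalPDF, beta_inc_deg: float) -> float:
    """Probability that the equilibrium angle falls below the incidence
    angle, i.e. that an encounter at beta_inc crosses instead of zippering
    (the CDF of the angle density at beta_inc)."""
    if not 0.0 <= beta_inc_deg <= 180.0:
        raise ValueError("incidence angle must lie in [0, 180] degrees")
    p = q_beta.normalized()
    if beta_inc_deg <= p.grid[0]:
        return 0.0
    if beta_inc_deg >= p.grid[-1]:
        return 1.0
    return float(np.interp(beta_inc_deg, p.grid, p.cdf()))


def rescale_factor_from_length(L_before: float, L_after: float) -> float:
    """Mean fascicle-size ratio implied by a change in total network length
    at a fixed field of view (n scales inversely with length density)."""
    if L_before <= 0 or L_after <= 0:
        raise ValueError("lengths must be positive")
    return L_before / L_after
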
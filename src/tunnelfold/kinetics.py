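"""Force-dependent kinetics: the Dudko-Hummer-Szabo rate law and
rupture/refolding force distributions under a force ramp.

The rate of escape over a single barrier under force F is

    k(F) = k0 (1 - nu F x' / dG')^(1/nu - 1)
              * exp{ dG' [1 - (1 - nu F x' / dG')^(1/nu)] }

with x' the distance to the transition state (nm), dG' the barrier height
(kBT) and shape parameter nu (2/3 for a linear-cubic free-energy surface;
nu = 1 recovers the Bell law k0 exp(F x'/kBT)).  Under a ramp at loading
rate Fdot the rupture-force density is

    p(F) = k(F)/Fdot * exp(-int_0^F k(F')/Fdot dF').

Refolding during relaxation uses the same expressions with the force sign
reversed in k and the integral running downward from a start force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .units import KBT_PN_NM

__all__ = [
    "DHSParams",
    "ForceDistribution",
    "dhs_rate",
    "fit_dhs",
    "force_distribution",
    "compare_distributions",
    "sample_rupture_forces",
]


@dataclass
class DHSParams:
    """Parameters of the force-dependent rate law.

    ``direction`` is "unfolding" (rate grows with force) or "refolding"
    (force opposes the transition, rate falls with force).
    """

    k0: float  # zero-force rate, 1/s
    x_dagger: float  # transition-state distance, nm
    dG_dagger: float  # barrier, kBT
    nu: float = 2.0 / 3.0
    direction: str = "unfolding"

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.x_dagger <= 0:
            raise ValueError("x_dagger must be positive")
        if self.dG_dagger <= 0:
            raise ValueError("dG_dagger must be positive")
        if not (0.0 < self.nu <= 1.0):
            raise ValueError("nu must lie in (0, 1]")
        if self.direction not in ("unfolding", "refolding"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class ForceDistribution:
    """Rupture (or refolding) force density on a grid.

    ``survival`` is the probability mass beyond the grid end (molecules that
    never ruptured inside the scanned force range).
    """

    force: np.ndarray  # pN
    density: np.ndarray  # 1/pN
    loading_rate: float  # pN/s
    direction: str = "unfolding"
    survival: float = 0.0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.density = np.asarray(self.density, dtype=float)

    @property
    def mean(self) -> float:
        w = np.trapezoid(self.density, self.force)
        return float(np.trapezoid(self.force * self.density, self.force) / w)

    @property
    def mode(self) -> float:
        return float(self.force[int(np.argmax(self.density))])


def dhs_rate(F, params: DHSParams):
    """Evaluate k(F) (same time units as ``params.k0``); F in pN.

    For the unfolding direction the formula is only defined while the barrier
    survives (nu F x' < dG'); beyond that a ``ValueError`` is raised rather
    than silently clamping.  The refolding direction maps F -> -F, which is
    defined for all F >= 0.
    """
    F = np.asarray(F, dtype=float)
    sign = 1.0 if params.direction == "unfolding" else -1.0
    fx = sign * F * params.x_dagger / KBT_PN_NM  # kBT
    u = 1.0 - params.nu * fx / params.dG_dagger
    if np.any(u <= 0.0):
        raise ValueError(
            "barrier vanished: nu*F*x_dagger >= dG_dagger at "
            f"F={np.max(F):.3g} pN; the rate law is undefined there"
        )
    inv = 1.0 / params.nu
    out = params.k0 * u ** (inv - 1.0) * np.exp(params.dG_dagger * (1.0 - u**inv))
    return float(out) if out.ndim == 0 else out


def critical_force(params: DHSParams) -> float:
    """Force (pN) at which the barrier vanishes (unfolding direction)."""
    return params.dG_dagger * KBT_PN_NM / (params.nu * params.x_dagger)


def fit_dhs(
    forces,
    rates,
    direction: str = "unfolding",
    rate_errors=None,
    nu: float | None = 2.0 / 3.0,
) -> tuple[DHSParams, np.ndarray]:
    """Fit the rate law to measured (F, k) points.

    Weighted least squares on log k (weights from relative rate errors when
    given).  ``nu`` is fixed at 2/3 by default; pass ``nu=None`` to free it
    for sensitivity checks.  Returns the parameters and the covariance of
    (log k0, x_dagger, dG_dagger[, nu]).  Requires at least 4 force points
    (5 with free nu) and positive rates; raises on non-identifiable fits.
    """
    forces = np.asarray(forces, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n_par = 3 if nu is not None else 4
    if len(forces) < n_par + 1:
        raise ValueError(
            f"need at least {n_par + 1} force points to identify {n_par} parameters"
        )
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    logk = np.log(rates)
    sigma = None
    if rate_errors is not None:
        sigma = np.asarray(rate_errors, dtype=float) / rates  # log-space errors

    sign = 1.0 if direction == "unfolding" else -1.0

    def model(F, log_k0, x_d, dG, nu_v):
        # clamped variant of the rate law: trial parameters that lose the
        # barrier inside the force range get a steep penalty instead of an
        # exception, keeping the optimiser inside the valid region
        fx = sign * np.asarray(F, dtype=float) * x_d / KBT_PN_NM
        u = np.maximum(1.0 - nu_v * fx / dG, 1e-10)
        inv = 1.0 / nu_v
        return log_k0 + (inv - 1.0) * np.log(u) + dG * (1.0 - u**inv)

    k0_guess = float(rates[np.argmin(np.abs(forces))])
    span = max(np.ptp(forces), 1.0)
    slope_guess = abs((logk[-1] - logk[0]) / span) * KBT_PN_NM  # Bell x' estimate
    x_guess = min(max(slope_guess, 0.05), 5.0)
    p0 = [np.log(k0_guess), x_guess, 10.0]
    bounds_lo = [-50.0, 1e-4, 1e-2]
    bounds_hi = [50.0, 50.0, 200.0]
    if nu is None:
        fun = lambda F, a, b, c, d: model(F, a, b, c, d)
        p0 += [2.0 / 3.0]
        bounds_lo += [0.05]
        bounds_hi += [1.0]
    else:
        fun = lambda F, a, b, c: model(F, a, b, c, nu)
    try:
        popt, pcov = curve_fit(
            fun, forces, logk, p0=p0, sigma=sigma, bounds=(bounds_lo, bounds_hi),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise ValueError(f"rate-law fit did not converge: {err}") from err
    if not np.all(np.isfinite(pcov)):
        raise ValueError(
            "non-identifiable fit (singular covariance); widen the force range"
        )
    nu_fit = popt[3] if nu is None else nu
    params = DHSParams(float(np.exp(popt[0])), float(popt[1]), float(popt[2]), nu_fit, direction)
    return params, pcov


def force_distribution(
    k,
    loading_rate: float,
    grid,
    direction: str = "unfolding",
    start_force: float | None = None,
    max_mass_error: float = 0.02,
) -> ForceDistribution:
    """Rupture-force density from a rate law under a linear force ramp.

    ``k`` is a :class:`DHSParams` or a callable F -> rate.  For unfolding the
    hazard integral runs upward from the grid start; for refolding it runs
    downward from ``start_force`` (default: grid maximum) with the magnitude
    of the loading rate.  The density and the survival mass at the grid end
    sum to 1; a grid too coarse to conserve mass to ``max_mass_error`` is
    rejected.
    """
    if loading_rate <= 0:
        raise ValueError("loading rate must be positive")
    grid = np.sort(np.asarray(grid, dtype=float))
    if isinstance(k, DHSParams):
        if k.direction != direction:
            k = DHSParams(k.k0, k.x_dagger, k.dG_dagger, k.nu, direction)
        rates = dhs_rate(grid, k)
    else:
        rates = np.asarray([k(F) for F in grid], dtype=float)

    if direction == "unfolding":
        hazard = cumulative_trapezoid(rates / loading_rate, grid, initial=0.0)
        dens = rates / loading_rate * np.exp(-hazard)
        survival = float(np.exp(-hazard[-1]))
    elif direction == "refolding":
        if start_force is None:
            start_force = float(grid[-1])
        mask = grid <= start_force
        g, r = grid[mask], rates[mask]
        # integrate downward from the start force
        haz_rev = cumulative_trapezoid((r / loading_rate)[::-1], g[::-1], initial=0.0)
        hazard = -haz_rev[::-1]  # ∫_F^{Fstart} k/|Fdot| dF'
        dens = np.zeros_like(grid)
        dens[mask] = r / loading_rate * np.exp(-hazard)
        survival = float(np.exp(-hazard[0]))
    else:
        raise ValueError(f"unknown direction {direction!r}")

    mass = float(np.trapezoid(dens, grid))
    err = abs(mass + survival - 1.0)
    if err > max_mass_error:
        raise ValueError(
            f"force grid too coarse: density + survival misses 1 by {err:.3g}; "
            "refine the grid"
        )
    return ForceDistribution(grid, dens, loading_rate, direction, survival)


def compare_distributions(a: ForceDistribution, b: ForceDistribution) -> dict[str, float]:
    """Mean/mode comparison of two force distributions (b relative to a).

    ``shift`` is sign(mean_b - mean_a); positive means b sits at higher
    force.  Warns (via the returned ``overlap`` field being 0) when the
    supports are disjoint.
    """
    import warnings

    lo = max(a.force[0], b.force[0])
    hi = min(a.force[-1], b.force[-1])
    overlap = 1.0
    if hi <= lo:
        warnings.warn("force distributions have disjoint supports")
        overlap = 0.0
    d_mean = b.mean - a.mean
    return {
        "mean_a": a.mean,
        "mean_b": b.mean,
        "mode_a": a.mode,
        "mode_b": b.mode,
        "mean_shift": d_mean,
        "mode_shift": b.mode - a.mode,
        "shift": float(np.sign(d_mean)),
        "overlap": overlap,
    }


def sample_rupture_forces(
    dist: ForceDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw rupture forces by inverse CDF; censored draws come back as NaN.

    A draw landing in the survival mass (no rupture inside the grid) is
    returned as NaN, mirroring a ramp that tops out before the event.
    """
    if dist.direction == "unfolding":
        cdf = cumulative_trapezoid(dist.density, dist.force, initial=0.0)
        grid = dist.force
    else:
        # refolding: events accumulate as force decreases
        cdf = -cumulative_trapezoid(dist.density[::-1], dist.force[::-1], initial=0.0)
        grid = dist.force[::-1]
    u = rng.uniform(0.0, 1.0, size=n)
    total = cdf[-1]
    out = np.interp(u, cdf, grid, left=np.nan, right=np.nan)
    out[u > total] = np.nan
    return out
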
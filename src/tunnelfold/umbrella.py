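"""Umbrella sampling along Q, WHAM, and thermodynamic decomposition.

Free-energy profiles G(Q) are obtained by biasing the smooth fraction of
native contacts with harmonic windows 0.5 k_w (Q - Q0)^2 and recombining the
window histograms with the weighted-histogram analysis method (WHAM):
self-consistent iteration of

    P(b) = sum_w n_w(b) / sum_w N_w f_w c_w(b),    1/f_w = sum_b c_w(b) P(b)

with c_w(b) = exp(-U_w(Q_b)/T).  Folding stability is the log population
ratio of the folded and unfolded regions; fitting stabilities across
temperatures to dG = dE - T dS separates the energetic and (configurational)
entropic contributions — in a solvent-free coarse-grained model all solvent
effects live in dE and the entropy is purely configurational.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cg import BeadChain, EnergyParams, RibosomeEnvironment
from .dynamics import PullProtocol, run_trajectory

__all__ = [
    "FESProfile",
    "ThermoDecomposition",
    "UmbrellaWindow",
    "run_umbrella",
    "wham",
    "stability_from_fes",
    "barrier_height",
    "decompose_thermo",
]


@dataclass
class UmbrellaWindow:
    """One biased window: samples of the (smooth) Q coordinate."""

    center: float
    spring: float  # k_w, kBT per unit Q^2
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class FESProfile:
    """Free energy vs Q, min-shifted to zero, in kBT at ``temperature``."""

    q: np.ndarray  # bin centres
    g: np.ndarray  # kBT, min-shifted
    counts: np.ndarray  # total samples per bin
    temperature: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.counts = np.asarray(self.counts)

    @property
    def empty_bins(self) -> np.ndarray:
        """Mask of bins with no samples (G there is NaN, never interpolated)."""
        return self.counts == 0


@dataclass
class ThermoDecomposition:
    """Linear fit dG(T) = dE - T dS with residuals."""

    temperatures: np.ndarray
    dG: np.ndarray
    dE: float
    dS: float
    residuals: np.ndarray
    se_dE: float
    se_dS: float


def run_umbrella(
    chain: BeadChain,
    environment: RibosomeEnvironment | None,
    params: EnergyParams,
    centers,
    spring: float = 200.0,
    steps_per_window: int = 50_000,
    burn_in: float = 0.2,
    seed: int = 0,
    protocol: PullProtocol | None = None,
    check_overlap: bool = True,
) -> list[UmbrellaWindow]:
    """Sample harmonic umbrella windows along the smooth Q coordinate.

    Windows run in descending-centre order, each starting from the final
    configuration of the previous one (the first starts from the native
    structure); this steers the chain gradually from folded to unfolded so
    every window equilibrates near its centre.  The burn-in fraction of each
    window is discarded.  After sampling, neighbouring windows are checked
    for histogram overlap; a gap raises a ``ValueError`` naming the
    offending pair.
    """
    if not (0.0 < burn_in < 1.0):
        raise ValueError("burn_in must be a fraction in (0, 1)")
    centers = np.asarray(centers, dtype=float)
    base = protocol or PullProtocol(dt=5e-5, stride=20)
    order = np.argsort(centers)[::-1]  # native-like first
    windows: list[UmbrellaWindow | None] = [None] * len(centers)
    start = chain.positions.copy()
    for wi in order:
        q0 = centers[wi]
        proto = PullProtocol(
            force=base.force,
            pulled_bead=base.pulled_bead,
            fixed_axis=base.fixed_axis,
            max_steps=steps_per_window,
            dt=base.dt,
            stride=base.stride,
            seed=seed + 7717 * int(wi),
        )
        traj = run_trajectory(
            chain, environment, params, proto,
            umbrella=(spring, float(q0)), positions=start,
        )
        start = traj.final_positions
        n_skip = int(burn_in * len(traj.q_smooth))
        windows[wi] = UmbrellaWindow(float(q0), spring, traj.q_smooth[n_skip:])
    if check_overlap and len(windows) > 1:
        order = np.argsort(centers)
        for a, b in zip(order[:-1], order[1:]):
            lo = max(windows[a].samples.min(), windows[b].samples.min())
            hi = min(windows[a].samples.max(), windows[b].samples.max())
            n_shared = min(
                np.count_nonzero((windows[a].samples >= lo) & (windows[a].samples <= hi)),
                np.count_nonzero((windows[b].samples >= lo) & (windows[b].samples <= hi)),
            )
            if hi <= lo or n_shared < 5:
                raise ValueError(
                    f"umbrella windows at Q0={centers[a]:.2f} and "
                    f"Q0={centers[b]:.2f} do not overlap; add windows or "
                    "soften the springs"
                )
    return windows


def wham(
    windows: list[UmbrellaWindow],
    temperature: float = 1.0,
    n_bins: int = 50,
    q_range: tuple[float, float] = (0.0, 1.0),
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> FESProfile:
    """Combine biased windows into one free-energy profile.

    Deterministic self-consistent iteration on the window free energies to
    relative tolerance ``tol``; invariant to window order and to additive
    constants on the biases.  A single unbiased window degenerates to
    G = -ln(histogram) + const.  Raises on non-convergence with the last
    residual.
    """
    if len(windows) == 0:
        raise ValueError("no umbrella windows given")
    edges = np.linspace(q_range[0], q_range[1], n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    n_w = len(windows)
    counts = np.zeros((n_w, n_bins))
    for w, win in enumerate(windows):
        counts[w], _ = np.histogram(win.samples, bins=edges)
    N_w = counts.sum(axis=1)
    total = counts.sum(axis=0)

    # bias Boltzmann factors per window and bin
    u = np.array(
        [0.5 * win.spring * (centres - win.center) ** 2 for win in windows]
    )  # kBT(ref)
    c = np.exp(-u / temperature)

    f = np.ones(n_w)
    last = np.inf
    for _ in range(max_iter):
        denom = (N_w * f) @ c  # sum_w N_w f_w c_w(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        f_new = 1.0 / (c @ p)
        f_new /= f_new[0]
        last = float(np.max(np.abs(np.log(f_new / f))))
        f = f_new
        if last < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {last:.2e})"
        )
    with np.errstate(divide="ignore"):
        g = np.where(p > 0, -np.log(p), np.nan)
    g = g - np.nanmin(g)
    return FESProfile(q=centres, g=g, counts=total.astype(int), temperature=temperature)


def _region_mask(q: np.ndarray, region: tuple[float, float]) -> np.ndarray:
    lo, hi = min(region), max(region)
    return (q >= lo) & (q <= hi)


def stability_from_fes(
    fes: FESProfile,
    folded: tuple[float, float] = (0.7, 1.0),
    unfolded: tuple[float, float] = (0.0, 0.3),
) -> float:
    """Folding stability dG = G_folded - G_unfolded in kBT at fes.temperature.

    Population-ratio estimate: dG = -ln sum_folded e^-G + ln sum_unfolded
    e^-G over the bins of each region.  Negative dG means the folded state
    is more stable.  Rejects empty or overlapping regions.
    """
    mf = _region_mask(fes.q, folded)
    mu = _region_mask(fes.q, unfolded)
    if np.any(mf & mu):
        raise ValueError("folded and unfolded regions overlap")
    for name, m in (("folded", mf), ("unfolded", mu)):
        if not np.any(m) or np.all(np.isnan(fes.g[m])):
            raise ValueError(f"{name} region contains no sampled bins")
    gf = fes.g[mf]
    gu = fes.g[mu]
    zf = np.nansum(np.exp(-gf[~np.isnan(gf)]))
    zu = np.nansum(np.exp(-gu[~np.isnan(gu)]))
    return float(-np.log(zf) + np.log(zu))


def barrier_height(
    fes: FESProfile,
    folded: tuple[float, float] = (0.7, 1.0),
    unfolded: tuple[float, float] = (0.0, 0.3),
) -> tuple[float, bool]:
    """(barrier in kBT, barrierless flag) between the two region minima.

    The barrier is the highest sampled point on the profile between the
    minima of the unfolded and folded regions, measured from the unfolded
    minimum.  A monotone profile returns (0, True).
    """
    mf = _region_mask(fes.q, folded)
    mu = _region_mask(fes.q, unfolded)
    for name, m in (("folded", mf), ("unfolded", mu)):
        if not np.any(m) or np.all(np.isnan(fes.g[m])):
            raise ValueError(f"{name} region contains no sampled bins")
    i_u = np.where(mu)[0][np.nanargmin(fes.g[mu])]
    i_f = np.where(mf)[0][np.nanargmin(fes.g[mf])]
    lo, hi = sorted((i_u, i_f))
    between = fes.g[lo : hi + 1]
    g_top = np.nanmax(between)
    g_start = fes.g[i_u]
    barrier = float(g_top - g_start)
    interior = between[1:-1]
    has_max = interior.size > 0 and np.nanmax(interior) > max(fes.g[i_u], fes.g[i_f])
    if not has_max or barrier <= 0:
        return 0.0, True
    return barrier, False


def decompose_thermo(temperatures, dG_values) -> ThermoDecomposition:
    """Least-squares fit of dG(T) = dE - T dS over >= 3 temperatures.

    ``dG_values`` must be in energy units consistent across temperatures
    (e.g. kBT at the reference temperature, i.e. T * the dimensionless log
    population ratio).  Returns dE, dS, their standard errors and the fit
    residuals.  Rejects < 3 distinct temperatures.
    """
    T = np.asarray(temperatures, dtype=float)
    dG = np.asarray(dG_values, dtype=float)
    if len(T) != len(dG):
        raise ValueError("temperatures and dG lists differ in length")
    if len(np.unique(T)) < 3:
        raise ValueError("need at least 3 distinct temperatures")
    A = np.column_stack([np.ones_like(T), -T])
    coef, res_ss, rank, _ = np.linalg.lstsq(A, dG, rcond=None)
    if rank < 2:
        raise ValueError("degenerate temperature design; cannot separate dE and dS")
    dE, dS = float(coef[0]), float(coef[1])
    resid = dG - A @ coef
    n, p = len(T), 2
    if n > p:
        s2 = float(resid @ resid) / (n - p)
        cov = s2 * np.linalg.inv(A.T @ A)
        se_dE, se_dS = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    else:
        se_dE = se_dS = float("nan")
    return ThermoDecomposition(
        temperatures=T, dG=dG, dE=dE, dS=dS, residuals=resid, se_dE=se_dE, se_dS=se_dS
    )
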
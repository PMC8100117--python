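"""Overdamped Langevin dynamics of the tethered chain under constant force.

First-order Brownian integrator in reduced units: friction coefficient 1 per
bead, so the diffusion constant equals the reduced temperature and time is
measured in units of (friction x nm^2 / kBT).  The mapping of the reduced
time unit to seconds is left symbolic; rates carry 1/reduced-time units.
A constant pulling force acts on the chain N-terminus along the instantaneous
anchor-to-bead direction (or a fixed axis), mimicking the optical-tweezers
tether geometry.  Folding/unfolding rates come from mean first passage times
between Q-defined states over replica simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .cg import BeadChain, EnergyParams, RibosomeEnvironment
from .units import KBT_PN_NM, COULOMB_KBT_NM

__all__ = [
    "PullProtocol",
    "Trajectory",
    "RateEstimate",
    "run_trajectory",
    "first_passage_time",
    "estimate_rate",
    "rate_vs_force",
    "Q_FOLD",
    "Q_UNFOLD",
]

#: Default state thresholds on Q; widely separated to suppress recrossings.
Q_FOLD = 0.8
Q_UNFOLD = 0.2


@dataclass
class PullProtocol:
    """Constant-force pulling protocol.

    ``force`` in pN acts on ``pulled_bead`` (the chain N-terminus by
    default), directed away from the environment anchor bead, recomputed
    every step; set ``fixed_axis`` to pull along a constant direction
    instead (used for free-chain tests).  ``dt`` is the reduced timestep.
    """

    force: float = 0.0  # pN
    pulled_bead: int = 0
    fixed_axis: np.ndarray | None = None
    max_steps: int = 200_000
    dt: float = 2.0e-4
    stride: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.force < 0:
            raise ValueError("force must be >= 0")
        if self.fixed_axis is not None:
            ax = np.asarray(self.fixed_axis, dtype=float)
            self.fixed_axis = ax / np.linalg.norm(ax)


@dataclass
class Trajectory:
    """Recorded observables of one Langevin run (one frame per stride)."""

    q: np.ndarray  # hard fraction of native contacts
    q_smooth: np.ndarray
    end_to_end: np.ndarray  # nm, pulled bead to tether bead
    dt: float
    stride: int
    termination: str  # "reached-state" | "max-steps"
    n_steps: int  # steps actually integrated
    final_positions: np.ndarray

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.q)) * self.dt * self.stride


@dataclass
class RateEstimate:
    """Rate from mean first passage times with a bootstrap CI."""

    rate: float  # 1/reduced-time
    n_events: int
    n_censored: int
    ci: tuple[float, float]
    mfpt: float
    degenerate_ci: bool = False  # single event: CI carries no information


# termination codes shared with the kernel
_TERM_MAX, _TERM_REACHED, _TERM_BLOWUP = 0, 1, 2


@njit(cache=True)
def _integrate(
    pos,
    fixed_idx,
    n_steps,
    stride,
    dt,
    temp,
    seed,
    bond_k,
    bond_r0,
    ci,
    cj,
    cr0,
    ceps,
    rep_i,
    rep_j,
    sigma_cc,
    eps_rep,
    cq_i,
    cq_j,
    cq_prod,
    elec_on,
    lam,
    eps_lo,
    eps_hi,
    r_m,
    sig_e,
    rcut_e,
    env_pos,
    env_sig,
    env_charge,
    ns_c,
    chain_charge,
    nl_every,
    skin,
    f_red,
    pulled,
    anchor,
    use_fixed_axis,
    axis,
    kw,
    q0,
    q_mult,
    q_width,
    stop_mode,
    q_hi,
    q_lo,
    out_q,
    out_qs,
    out_ee,
):
    np.random.seed(seed)
    n = pos.shape[0]
    n_env = env_pos.shape[0]
    n_con = ci.shape[0]
    frc = np.zeros((n, 3))
    sqrt_noise = np.sqrt(2.0 * temp * dt)

    # environment neighbour lists (flat arrays, rebuilt every nl_every steps)
    max_pairs = n * n_env if n_env > 0 else 1
    nl_rep_b = np.empty(max_pairs, dtype=np.int64)
    nl_rep_e = np.empty(max_pairs, dtype=np.int64)
    nl_el_b = np.empty(max_pairs, dtype=np.int64)
    nl_el_e = np.empty(max_pairs, dtype=np.int64)
    n_rep_nl = 0
    n_el_nl = 0

    cdist = np.empty(n_con)
    csig = np.empty(n_con)
    frame = 0
    status = _TERM_MAX
    step = 0
    for step in range(n_steps):
        if n_env > 0 and step % nl_every == 0:
            n_rep_nl = 0
            n_el_nl = 0
            for i in range(n):
                qi = chain_charge[i]
                for e in range(n_env):
                    dx = pos[i, 0] - env_pos[e, 0]
                    dy = pos[i, 1] - env_pos[e, 1]
                    dz = pos[i, 2] - env_pos[e, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    rr = 2.5 * env_sig[e] + skin
                    if r2 < rr * rr:
                        nl_rep_b[n_rep_nl] = i
                        nl_rep_e[n_rep_nl] = e
                        n_rep_nl += 1
                    if elec_on == 1 and qi != 0.0 and env_charge[e] != 0.0:
                        re = rcut_e + skin
                        if r2 < re * re:
                            nl_el_b[n_el_nl] = i
                            nl_el_e[n_el_nl] = e
                            n_el_nl += 1

        for i in range(n):
            frc[i, 0] = 0.0
            frc[i, 1] = 0.0
            frc[i, 2] = 0.0

        # bonds
        for i in range(n - 1):
            dx = pos[i + 1, 0] - pos[i, 0]
            dy = pos[i + 1, 1] - pos[i, 1]
            dz = pos[i + 1, 2] - pos[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            f = bond_k * (r - bond_r0) / r
            frc[i, 0] += f * dx
            frc[i, 1] += f * dy
            frc[i, 2] += f * dz
            frc[i + 1, 0] -= f * dx
            frc[i + 1, 1] -= f * dy
            frc[i + 1, 2] -= f * dz

        # native contacts (12-10 wells); cache distances for Q
        need_qs = kw > 0.0 or (step + 1) % stride == 0
        qs = 0.0
        for c in range(n_con):
            i = ci[c]
            j = cj[c]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            cdist[c] = r
            r_eff = r if r > 0.4 * cr0[c] else 0.4 * cr0[c]
            x2 = (cr0[c] / r_eff) ** 2
            x10 = x2 * x2 * x2 * x2 * x2
            x12 = x10 * x2
            # -dV/dr / r with V = eps (5 x^12 - 6 x^10)
            fmag = 60.0 * ceps[c] * (x12 - x10) / (r_eff * r_eff)
            frc[i, 0] += fmag * dx
            frc[i, 1] += fmag * dy
            frc[i, 2] += fmag * dz
            frc[j, 0] -= fmag * dx
            frc[j, 1] -= fmag * dy
            frc[j, 2] -= fmag * dz
            if need_qs:
                s = 1.0 / (1.0 + np.exp((r - q_mult * cr0[c]) / q_width))
                csig[c] = s
                qs += s
        if n_con > 0 and need_qs:
            qs /= n_con

        # umbrella bias on the smooth Q
        if kw > 0.0 and n_con > 0:
            pref = -kw * (qs - q0) / n_con
            for c in range(n_con):
                i = ci[c]
                j = cj[c]
                r = cdist[c]
                s = csig[c]
                dsdr = -s * (1.0 - s) / q_width
                fmag = pref * dsdr / r  # force = -dU/dx
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                frc[i, 0] += fmag * dx
                frc[i, 1] += fmag * dy
                frc[i, 2] += fmag * dz
                frc[j, 0] -= fmag * dx
                frc[j, 1] -= fmag * dy
                frc[j, 2] -= fmag * dz

        # chain-chain excluded volume
        rng_rep = 2.5 * sigma_cc
        for p in range(rep_i.shape[0]):
            i = rep_i[p]
            j = rep_j[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rng_rep * rng_rep:
                r = np.sqrt(r2)
                r_eff = r if r > 0.4 * sigma_cc else 0.4 * sigma_cc
                x2 = (sigma_cc / r_eff) ** 2
                x12 = x2 * x2 * x2 * x2 * x2 * x2
                fmag = 12.0 * eps_rep * x12 / (r_eff * r_eff)
                frc[i, 0] += fmag * dx
                frc[i, 1] += fmag * dy
                frc[i, 2] += fmag * dz
                frc[j, 0] -= fmag * dx
                frc[j, 1] -= fmag * dy
                frc[j, 2] -= fmag * dz

        # chain-chain electrostatics (screened Coulomb, dielectric profile)
        if elec_on == 1:
            for p in range(cq_i.shape[0]):
                i = cq_i[p]
                j = cq_j[p]
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rcut_e * rcut_e:
                    r = np.sqrt(r2)
                    th = np.tanh((r - r_m) / sig_e)
                    eps_d = 0.5 * (eps_lo + eps_hi) + 0.5 * (eps_hi - eps_lo) * th
                    v = COULOMB_KBT_NM * cq_prod[p] * np.exp(-r / lam) / (eps_d * r)
                    deps = 0.5 * (eps_hi - eps_lo) * (1.0 - th * th) / sig_e
                    fmag = v * (1.0 / lam + 1.0 / r + deps / eps_d) / r
                    frc[i, 0] += fmag * dx
                    frc[i, 1] += fmag * dy
                    frc[i, 2] += fmag * dz
                    frc[j, 0] -= fmag * dx
                    frc[j, 1] -= fmag * dy
                    frc[j, 2] -= fmag * dz

        # chain-environment repulsion (+ optional non-specific attraction)
        for p in range(n_rep_nl):
            i = nl_rep_b[p]
            e = nl_rep_e[p]
            sig = env_sig[e]
            dx = pos[i, 0] - env_pos[e, 0]
            dy = pos[i, 1] - env_pos[e, 1]
            dz = pos[i, 2] - env_pos[e, 2]
            r2 = dx * dx + dy * dy + dz * dz
            rr = 2.5 * sig
            if r2 < rr * rr:
                r = np.sqrt(r2)
                r_eff = r if r > 0.4 * sig else 0.4 * sig
                x2 = (sig / r_eff) ** 2
                x6 = x2 * x2 * x2
                x12 = x6 * x6
                fmag = 12.0 * eps_rep * x12 / (r_eff * r_eff)
                if ns_c > 0.0:
                    fmag -= 12.0 * ns_c * x6 / (r_eff * r_eff)
                frc[i, 0] += fmag * dx
                frc[i, 1] += fmag * dy
                frc[i, 2] += fmag * dz

        # chain-environment electrostatics
        for p in range(n_el_nl):
            i = nl_el_b[p]
            e = nl_el_e[p]
            dx = pos[i, 0] - env_pos[e, 0]
            dy = pos[i, 1] - env_pos[e, 1]
            dz = pos[i, 2] - env_pos[e, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rcut_e * rcut_e:
                r = np.sqrt(r2)
                th = np.tanh((r - r_m) / sig_e)
                eps_d = 0.5 * (eps_lo + eps_hi) + 0.5 * (eps_hi - eps_lo) * th
                v = (
                    COULOMB_KBT_NM
                    * chain_charge[i]
                    * env_charge[e]
                    * np.exp(-r / lam)
                    / (eps_d * r)
                )
                deps = 0.5 * (eps_hi - eps_lo) * (1.0 - th * th) / sig_e
                fmag = v * (1.0 / lam + 1.0 / r + deps / eps_d) / r
                frc[i, 0] += fmag * dx
                frc[i, 1] += fmag * dy
                frc[i, 2] += fmag * dz

        # constant pulling force on the N-terminal bead
        if f_red > 0.0:
            if use_fixed_axis == 1:
                ux, uy, uz = axis[0], axis[1], axis[2]
            else:
                ux = pos[pulled, 0] - anchor[0]
                uy = pos[pulled, 1] - anchor[1]
                uz = pos[pulled, 2] - anchor[2]
                un = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux, uy, uz = ux / un, uy / un, uz / un
            frc[pulled, 0] += f_red * ux
            frc[pulled, 1] += f_red * uy
            frc[pulled, 2] += f_red * uz

        # Euler-Maruyama update; fixed bead skipped
        blow = False
        for i in range(n):
            if i == fixed_idx:
                continue
            for d in range(3):
                disp = dt * frc[i, d] + sqrt_noise * np.random.standard_normal()
                if disp > 1.0 or disp < -1.0:
                    blow = True
                pos[i, d] += disp
        if blow:
            status = _TERM_BLOWUP
            break

        if (step + 1) % stride == 0:
            # contact distances cached from the force pass (one step stale)
            nq = 0
            for c in range(n_con):
                if cdist[c] < q_mult * cr0[c]:
                    nq += 1
            qh = nq / n_con if n_con > 0 else 0.0
            out_q[frame] = qh
            out_qs[frame] = qs
            ref = fixed_idx if fixed_idx >= 0 else n - 1
            dx = pos[pulled, 0] - pos[ref, 0]
            dy = pos[pulled, 1] - pos[ref, 1]
            dz = pos[pulled, 2] - pos[ref, 2]
            out_ee[frame] = np.sqrt(dx * dx + dy * dy + dz * dz)
            frame += 1
            if stop_mode == 1 and qh >= q_hi:
                status = _TERM_REACHED
                break
            if stop_mode == 2 and qh <= q_lo:
                status = _TERM_REACHED
                break

    return frame, status, step + 1


def _kernel_args(
    chain: BeadChain,
    environment: RibosomeEnvironment | None,
    params: EnergyParams,
):
    """Static pair lists and parameter arrays for the integrator kernel."""
    n = chain.n_beads
    native = set(zip(chain.contact_i.tolist(), chain.contact_j.tolist()))
    rep_i, rep_j = [], []
    for i in range(n):
        for j in range(i + 2, n):
            if (i, j) not in native:
                rep_i.append(i)
                rep_j.append(j)
    cq_i, cq_j, cq_prod = [], [], []
    q = chain.charges
    for i in range(n):
        if q[i] == 0.0:
            continue
        for j in range(i + 1, n):
            if q[j] != 0.0:
                cq_i.append(i)
                cq_j.append(j)
                cq_prod.append(q[i] * q[j])
    if environment is not None:
        # the anchor is a pulling reference, not a physical bead
        keep = np.arange(environment.n_beads) != environment.anchor_index
        env_pos = environment.positions[keep]
        env_sig = (params.excluded_radius + environment.radii)[keep]
        env_charge = environment.charges[keep]
    else:
        env_pos = np.zeros((0, 3))
        env_sig = np.zeros(0)
        env_charge = np.zeros(0)
    return dict(
        bond_k=params.bond_k,
        bond_r0=chain.bond_r0,
        ci=chain.contact_i,
        cj=chain.contact_j,
        cr0=chain.contact_r0,
        ceps=chain.contact_eps,
        rep_i=np.array(rep_i, dtype=np.int64),
        rep_j=np.array(rep_j, dtype=np.int64),
        sigma_cc=2.0 * params.excluded_radius,
        eps_rep=params.repulsion_strength,
        cq_i=np.array(cq_i, dtype=np.int64),
        cq_j=np.array(cq_j, dtype=np.int64),
        cq_prod=np.array(cq_prod, dtype=float),
        elec_on=1 if params.electrostatics_on else 0,
        lam=params.debye_length,
        eps_lo=params.eps_limit,
        eps_hi=params.eps_solvent,
        r_m=params.r_midpoint,
        sig_e=params.sigma_eps,
        rcut_e=params.electrostatic_cutoff,
        env_pos=np.ascontiguousarray(env_pos, dtype=float),
        env_sig=np.ascontiguousarray(env_sig, dtype=float),
        env_charge=np.ascontiguousarray(env_charge, dtype=float),
        ns_c=float(np.sqrt(params.nonspecific_attraction * params.repulsion_strength)),
        chain_charge=np.ascontiguousarray(q, dtype=float),
        nl_every=20,
        skin=0.5,
    )


def run_trajectory(
    chain: BeadChain,
    environment: RibosomeEnvironment | None,
    params: EnergyParams,
    protocol: PullProtocol,
    *,
    stop: str | None = None,
    q_fold: float = Q_FOLD,
    q_unfold: float = Q_UNFOLD,
    positions: np.ndarray | None = None,
    umbrella: tuple[float, float] | None = None,
    q_width: float = 0.05,
) -> Trajectory:
    """Integrate the chain and record Q / end-to-end observables.

    ``stop`` may be "fold" (halt when Q >= q_fold) or "unfold" (halt when
    Q <= q_unfold); ``umbrella=(k_w, Q0)`` adds a harmonic bias
    0.5 k_w (Q_smooth - Q0)^2.  Reproducible for a fixed protocol seed.
    Raises on an unstable timestep or a diverging integration.
    """
    stability = 2.0 / max(params.bond_k, 1e-9)
    if protocol.dt >= stability:
        raise ValueError(
            f"timestep {protocol.dt} exceeds the bond stability bound {stability:.2e}"
        )
    if environment is None and protocol.fixed_axis is None and protocol.force > 0:
        raise ValueError("pulling without an environment anchor needs fixed_axis")
    pos = (chain.positions if positions is None else positions).astype(float).copy()
    args = _kernel_args(chain, environment, params)
    n_frames = protocol.max_steps // protocol.stride + 1
    out_q = np.zeros(n_frames)
    out_qs = np.zeros(n_frames)
    out_ee = np.zeros(n_frames)
    stop_mode = {"fold": 1, "unfold": 2, None: 0}[stop]
    kw, q0 = (0.0, 0.0) if umbrella is None else umbrella
    anchor = (
        environment.positions[environment.anchor_index]
        if environment is not None
        else np.zeros(3)
    )
    axis = protocol.fixed_axis if protocol.fixed_axis is not None else np.array([0.0, 0.0, 1.0])
    frame, status, steps = _integrate(
        pos,
        np.int64(chain.fixed_index),
        protocol.max_steps,
        protocol.stride,
        protocol.dt,
        params.temperature,
        protocol.seed,
        args["bond_k"],
        args["bond_r0"],
        args["ci"],
        args["cj"],
        args["cr0"],
        args["ceps"],
        args["rep_i"],
        args["rep_j"],
        args["sigma_cc"],
        args["eps_rep"],
        args["cq_i"],
        args["cq_j"],
        args["cq_prod"],
        args["elec_on"],
        args["lam"],
        args["eps_lo"],
        args["eps_hi"],
        args["r_m"],
        args["sig_e"],
        args["rcut_e"],
        args["env_pos"],
        args["env_sig"],
        args["env_charge"],
        args["ns_c"],
        args["chain_charge"],
        args["nl_every"],
        args["skin"],
        protocol.force / KBT_PN_NM,
        np.int64(protocol.pulled_bead),
        np.ascontiguousarray(anchor, dtype=float),
        1 if (protocol.fixed_axis is not None) else 0,
        np.ascontiguousarray(axis, dtype=float),
        kw,
        q0,
        1.2,
        q_width,
        stop_mode,
        q_fold,
        q_unfold,
        out_q,
        out_qs,
        out_ee,
    )
    if status == _TERM_BLOWUP:
        raise RuntimeError(
            f"integration diverged at step {steps} (displacement > 1 nm/step); "
            "reduce the timestep or check for overlapping beads"
        )
    return Trajectory(
        q=out_q[:frame],
        q_smooth=out_qs[:frame],
        end_to_end=out_ee[:frame],
        dt=protocol.dt,
        stride=protocol.stride,
        termination="reached-state" if status == _TERM_REACHED else "max-steps",
        n_steps=steps,
        final_positions=pos,
    )


def first_passage_time(
    traj: Trajectory,
    start: str,
    target: str,
    q_fold: float = Q_FOLD,
    q_unfold: float = Q_UNFOLD,
) -> tuple[float, bool]:
    """(time, censored) of the first entry into the target state.

    States: "folded" means Q >= q_fold, "unfolded" means Q <= q_unfold.  The
    trajectory must begin in the start state; censored=True when the target
    was never reached.
    """
    def in_state(qv: float, state: str) -> bool:
        if state == "folded":
            return qv >= q_fold
        if state == "unfolded":
            return qv <= q_unfold
        raise ValueError(f"unknown state {state!r}")

    if len(traj.q) == 0:
        raise ValueError("empty trajectory")
    if not in_state(traj.q[0], start):
        raise ValueError(
            f"trajectory starts at Q={traj.q[0]:.2f}, not in the {start!r} state"
        )
    hits = np.nonzero([in_state(v, target) for v in traj.q])[0]
    if len(hits) == 0:
        if traj.termination == "reached-state":
            # stopped exactly at the threshold crossing after the last frame
            return traj.n_steps * traj.dt, False
        return len(traj.q) * traj.stride * traj.dt, True
    return float(hits[0] * traj.stride * traj.dt), False


def estimate_rate(
    times,
    censored=None,
    method: str = "reciprocal-mfpt",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RateEstimate:
    """Rate constant from first passage times.

    Default: k = 1 / mean(uncensored passage times).  ``method="mle"`` uses
    the censoring-aware exponential maximum likelihood k = events / total
    observed time (censored runs contribute their full duration).  The CI is
    a seeded percentile bootstrap over the event list.
    """
    times = np.asarray(times, dtype=float)
    if censored is None:
        censored = np.zeros(len(times), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    unc = times[~censored]
    if len(unc) == 0:
        raise ValueError(
            "all replicas censored: no events observed; increase max_steps"
        )

    def point(t_unc, t_all, c_all):
        if method == "reciprocal-mfpt":
            return 1.0 / np.mean(t_unc)
        if method == "mle":
            return np.count_nonzero(~c_all) / np.sum(t_all)
        raise ValueError(f"unknown method {method!r}")

    k = float(point(unc, times, censored))
    rng = np.random.default_rng(seed)
    idx_all = np.arange(len(times))
    boots = []
    for _ in range(n_boot):
        pick = rng.choice(idx_all, size=len(times), replace=True)
        t_b, c_b = times[pick], censored[pick]
        if np.all(c_b):
            continue
        boots.append(point(t_b[~c_b], t_b, c_b))
    alpha = (1.0 - ci_level) / 2.0
    if boots:
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    else:
        lo = hi = k
    degenerate = len(unc) == 1
    return RateEstimate(
        rate=k,
        n_events=int(np.count_nonzero(~censored)),
        n_censored=int(np.count_nonzero(censored)),
        ci=(float(min(lo, k)), float(max(hi, k))),
        mfpt=float(np.mean(unc)),
        degenerate_ci=degenerate,
    )


def _extended_positions(chain: BeadChain, environment, spacing: float = 0.36) -> np.ndarray:
    """Straight configuration threading out of the tunnel from the tether."""
    n = chain.n_beads
    if environment is not None:
        axis = environment.tunnel_axis / np.linalg.norm(environment.tunnel_axis)
        origin = environment.tunnel_origin
    else:
        axis = np.array([0.0, 0.0, 1.0])
        origin = np.zeros(3)
    pos = np.empty((n, 3))
    for i in range(n):
        pos[i] = origin + axis * spacing * (n - 1 - i)
    return pos


def rate_vs_force(
    chain: BeadChain,
    environment: RibosomeEnvironment | None,
    params: EnergyParams,
    forces,
    n_replicas: int = 20,
    direction: str = "unfolding",
    seed: int = 0,
    protocol: PullProtocol | None = None,
    n_equil_folded: int = 1_000,
    n_equil_unfolded: int = 150_000,
    q_fold: float = Q_FOLD,
    q_unfold: float = Q_UNFOLD,
    method: str = "reciprocal-mfpt",
) -> pd.DataFrame:
    """Force-dependent rate table from constant-force replica simulations.

    Unfolding runs start from the native coordinates, each replica briefly
    equilibrated at the target force.  Folding runs start from a straight
    chain relaxed at the target force for ``n_equil_unfolded`` steps per
    replica; the relaxation is long because the taut chain must first
    recoil (a Rouse-time process), and a replica whose relaxation already
    crossed the folded threshold counts as an immediate event.  Force
    points where every replica was censored are reported with NaN rate and
    a warning.  Returns columns
    (force_pN, rate, ci_lo, ci_hi, n_events, n_censored).
    """
    import warnings

    if direction not in ("unfolding", "folding"):
        raise ValueError(f"unknown direction {direction!r}")
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        raise ValueError("force grid is empty")
    base = protocol or PullProtocol()
    rows = []
    for fi, F in enumerate(forces):
        times, cens = [], []
        for rep in range(n_replicas):
            rep_seed = seed + 100_003 * fi + 7919 * rep
            if direction == "unfolding":
                n_equil = n_equil_folded
                stop = "unfold"
                start_state = "folded"
                start_from = chain.positions.copy()
            else:
                n_equil = n_equil_unfolded
                stop = "fold"
                start_state = "unfolded"
                start_from = _extended_positions(chain, environment)
            eq_proto = PullProtocol(
                force=F,
                pulled_bead=base.pulled_bead,
                fixed_axis=base.fixed_axis,
                max_steps=n_equil,
                dt=base.dt,
                stride=max(n_equil, 1),
                seed=rep_seed + 1,
            )
            eq = run_trajectory(
                chain, environment, params, eq_proto, positions=start_from
            )
            start_pos = eq.final_positions
            proto = PullProtocol(
                force=F,
                pulled_bead=base.pulled_bead,
                fixed_axis=base.fixed_axis,
                max_steps=base.max_steps,
                dt=base.dt,
                stride=base.stride,
                seed=rep_seed,
            )
            traj = run_trajectory(
                chain,
                environment,
                params,
                proto,
                stop=stop,
                q_fold=q_fold,
                q_unfold=q_unfold,
                positions=start_pos,
            )
            # equilibration may already have crossed; count as immediate
            try:
                t, c = first_passage_time(traj, start_state,
                    "unfolded" if direction == "unfolding" else "folded",
                    q_fold=q_fold, q_unfold=q_unfold)
            except ValueError:
                t, c = traj.stride * traj.dt, False
            times.append(t)
            cens.append(c)
        times = np.asarray(times)
        cens = np.asarray(cens)
        if np.all(cens):
            warnings.warn(f"all replicas censored at F={F:.2f} pN; rate missing")
            rows.append(
                {"force_pN": F, "rate": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                 "n_events": 0, "n_censored": int(len(cens))}
            )
            continue
        est = estimate_rate(times, cens, method=method, seed=seed + fi)
        rows.append(
            {
                "force_pN": F,
                "rate": est.rate,
                "ci_lo": est.ci[0],
                "ci_hi": est.ci[1],
                "n_events": est.n_events,
                "n_censored": est.n_censored,
            }
        )
    return pd.DataFrame(rows)
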
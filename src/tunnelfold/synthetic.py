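"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here: a toy
29-residue zinc-finger fold (a procedural helix-plus-hairpin stand-in for a
real zinc-finger domain, so no structure download is needed), a charged
cylindrical surrogate of the ribosomal exit tunnel, pull-relax
force-extension traces with planted two-state transitions, and donor-quench
kymographs.  All generators are seed-deterministic and return the planted
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .cg import RibosomeEnvironment, assign_charges, extract_contacts
from .kinetics import DHSParams, ForceDistribution, force_distribution, sample_rupture_forces
from .pulling import PullTrace, TetherModel, fret_efficiency, series_extension
from .units import KBT_PN_NM, NM_PER_AA

__all__ = [
    "ToyStructure",
    "SyntheticTraceConfig",
    "make_toy_zincfinger",
    "make_tunnel",
    "simulate_trace",
    "simulate_kymograph",
    "tunnel_bead_count",
]


@dataclass
class ToyStructure:
    """Procedural 29-residue zinc-finger surrogate.

    A beta-hairpin packed against an alpha-helix; two cysteines in the
    hairpin turn and two histidines on the helix face form the coordination
    quadruple that a Zn2+ ion would bridge.
    """

    sequence: str
    positions: np.ndarray  # (29, 3) nm, Cα beads
    contacts: list[tuple[int, int, float]]  # (i, j, distance nm)
    coordination: tuple[int, int, int, int]  # two Cys, two His

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


# template without C/H; the coordination positions are substituted in after
# the geometry fixes where the Cys/Cys/His/His quadruple can sit
_TOY_TEMPLATE = "GSKAGLVRDAGTKLEANSRGKQIGTLSAG"


def _chord_walk(curve, t_end: float, n: int, step: float, t0: float = 0.0) -> np.ndarray:
    """Place n points along a parametric curve with exact chord length."""
    pts = [np.asarray(curve(t0), dtype=float)]
    t = t0
    for _ in range(n - 1):
        lo, hi = t, t
        d = 0.0
        while d < step:  # the curve is unbounded, so this always terminates
            hi += 0.05
            d = np.linalg.norm(curve(hi) - pts[-1])
        for _ in range(60):  # bisect chord length to machine precision
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(curve(mid) - pts[-1]) < step:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
        pts.append(np.asarray(curve(t), dtype=float))
    return np.array(pts)


def _toy_curve(t: float) -> np.ndarray:
    """Hairpin (two strands + turn) followed by a packed helix.

    Piecewise by parameter t: strand out along +x, semicircular turn,
    strand back, short riser, then an alpha-helix (radius 0.23 nm, rise
    0.15 nm/residue equivalent) running +x above the hairpin plane.
    """
    L1 = 1.9  # strand length, nm
    sep = 0.55  # strand separation
    R = sep / 2.0
    turn = np.pi * R
    L2 = L1 - 0.3
    rise_len = 0.9
    if t < L1:
        return np.array([t, 0.0, 0.0])
    t -= L1
    if t < turn:
        a = t / R  # 0..pi
        return np.array([L1 + R * np.sin(a), R - R * np.cos(a), 0.0])
    t -= turn
    if t < L2:
        return np.array([L1 - t, sep, 0.0])
    t -= L2
    p0 = np.array([L1 - L2, sep, 0.0])
    helix_start = np.array([0.45, 0.27, 0.62 - 0.23])  # bottom of first turn
    if t < rise_len:
        return p0 + (helix_start - p0) * (t / rise_len)
    t -= rise_len
    # helix: axis +x at (y=0.27, z=0.62), radius 0.23 nm, first turn
    # pointing down toward the hairpin plane
    r_h, pitch_per_rad = 0.23, 0.15 / (100.0 * np.pi / 180.0)
    arc_per_rad = np.sqrt(r_h**2 + pitch_per_rad**2)
    phi = t / arc_per_rad - np.pi / 2.0
    return np.array(
        [
            helix_start[0] + pitch_per_rad * (phi + np.pi / 2.0),
            0.27 + r_h * np.cos(phi),
            0.62 + r_h * np.sin(phi),
        ]
    )


def make_toy_zincfinger(seed: int = 0) -> ToyStructure:
    """Deterministic 29-residue helix-hairpin fold with a coordination site.

    The seed is accepted for interface symmetry with the other generators;
    the fold itself is fully deterministic.  Invariants: consecutive beads
    0.38 +/- 0.01 nm apart, at least 15 native contacts at the 0.8 nm
    cutoff, and the four coordination residues mutually within 0.8 nm.
    """
    n = 29
    pos = _chord_walk(_toy_curve, 12.0, n, 0.38)
    contacts = extract_contacts(pos, cutoff=0.8, min_sep=3)

    # choose the Cys/Cys/His/His quadruple: two turn-region residues and two
    # early-helix residues with minimal worst pairwise distance
    turn_idx = [i for i in range(4, 10)]
    helix_idx = [i for i in range(14, 24)]
    best, best_d = None, np.inf
    for c1, c2 in combinations(turn_idx, 2):
        if c2 - c1 < 2:
            continue
        for h1, h2 in combinations(helix_idx, 2):
            if h2 - h1 < 3:
                continue
            quad = (c1, c2, h1, h2)
            dmax = max(
                np.linalg.norm(pos[a] - pos[b]) for a, b in combinations(quad, 2)
            )
            if dmax < best_d:
                best, best_d = quad, dmax
    seq = list(_TOY_TEMPLATE[:n])
    c1, c2, h1, h2 = best
    seq[c1] = seq[c2] = "C"
    seq[h1] = seq[h2] = "H"
    return ToyStructure(
        sequence="".join(seq),
        positions=pos,
        contacts=contacts,
        coordination=best,
    )


def _ring_counts(spacing: float, length: float, radius: float,
                 vestibule_radius: float, vestibule_length: float):
    """Analytic tiling plan for the tunnel wall: (z, ring radius, n beads)."""
    rings = []
    z = 0.0
    while z <= length + 1e-9:
        if z < length - vestibule_length:
            r = radius
        else:
            frac = (z - (length - vestibule_length)) / vestibule_length
            r = radius + frac * (vestibule_radius - radius)
        n = max(3, int(round(2.0 * np.pi * r / spacing)))
        rings.append((z, r, n))
        z += spacing
    return rings


def tunnel_bead_count(
    length: float = 8.0,
    radius: float = 1.0,
    vestibule_radius: float = 1.8,
    vestibule_length: float = 2.0,
    spacing: float = 0.47,
) -> int:
    """Closed-form bead count of the surrogate (walls + base + anchor)."""
    rings = _ring_counts(spacing, length, radius, vestibule_radius, vestibule_length)
    n = sum(nb for _, _, nb in rings)
    r = spacing
    while r < radius - 1e-9:  # base disc, with a gap at the tether point
        n += max(3, int(round(2.0 * np.pi * r / spacing)))
        r += spacing
    return n + 1  # anchor bead


def make_tunnel(
    length: float = 8.0,
    radius: float = 1.0,
    vestibule_radius: float = 1.8,
    vestibule_length: float = 2.0,
    spacing: float = 0.47,
    charged_fraction: float = 0.3,
    bead_radius: float = 0.25,
    chain_bead_radius: float = 0.25,
    seed: int = 0,
) -> RibosomeEnvironment:
    """Cylindrical exit-tunnel surrogate with a charged wall lining.

    Wall beads tile a cylinder of the given radius that widens linearly to
    ``vestibule_radius`` over the last ``vestibule_length`` nm (the
    vestibule); a flat base closes the far end around the tether point at
    the origin, and one external anchor bead (the uL4 N-terminus surrogate)
    sits beyond the exit on the axis.  A seeded random ``charged_fraction``
    of wall beads carries -1, standing in for the rRNA phosphate lining.
    """
    if radius <= chain_bead_radius:
        raise ValueError(
            f"tunnel radius {radius} nm leaves no room for chain beads of "
            f"radius {chain_bead_radius} nm"
        )
    pts, roles = [], []
    for z, r, nb in _ring_counts(spacing, length, radius, vestibule_radius, vestibule_length):
        ang = 2.0 * np.pi * np.arange(nb) / nb + (0.5 if int(z / spacing) % 2 else 0.0)
        for a in ang:
            pts.append([r * np.cos(a), r * np.sin(a), z])
            roles.append("wall")
    r = spacing
    while r < radius - 1e-9:
        nb = max(3, int(round(2.0 * np.pi * r / spacing)))
        ang = 2.0 * np.pi * np.arange(nb) / nb
        for a in ang:
            pts.append([r * np.cos(a), r * np.sin(a), 0.0])
            roles.append("base")
        r += spacing
    n_wall = sum(1 for x in roles if x == "wall")
    pts.append([0.0, 0.0, length + 2.0])
    roles.append("anchor")
    pts = np.array(pts)
    charges = np.zeros(len(pts))
    rng = np.random.default_rng(seed)
    wall_ids = np.array([i for i, x in enumerate(roles) if x == "wall"])
    n_charged = int(round(charged_fraction * n_wall))
    if n_charged > 0:
        charges[rng.choice(wall_ids, size=n_charged, replace=False)] = -1.0
    return RibosomeEnvironment(
        positions=pts,
        radii=np.full(len(pts), bead_radius),
        charges=charges,
        anchor_index=len(pts) - 1,
        tunnel_axis=np.array([0.0, 0.0, 1.0]),
        tunnel_origin=np.zeros(3),
        roles=np.array(roles, dtype=object),
    )


@dataclass
class SyntheticTraceConfig:
    """Ground-truth settings for the pull-relax trace generator.

    Default rupture kinetics (k0 = 1e-4/s, x' = 1.0 nm, dG' = 12 kBT for
    unfolding; a mirrored fast-refolder for relaxation) together with the
    default loading rate put rupture forces in the experimentally familiar
    10-40 pN window (mean unfolding ~27 pN, mean refolding ~19 pN).  ``zinc=False`` drops the per-cycle refolding
    probability to ~17%, emulating the rarely-refolding ion-free domain.
    """

    delta_Lc: float = 31.0 * NM_PER_AA  # nm, planted contour change
    unfold: DHSParams = field(
        default_factory=lambda: DHSParams(1e-4, 1.0, 12.0, direction="unfolding")
    )
    refold: DHSParams = field(
        default_factory=lambda: DHSParams(5.0, 1.0, 12.0, direction="refolding")
    )
    loading_rate: float = 0.25  # pN/s
    noise_sigma_f: float = 0.5  # pN
    noise_sigma_x: float = 1.0  # nm
    samples_per_cycle: int = 300  # per pull or relax ramp
    n_cycles: int = 50
    zinc: bool = True
    refold_prob: float | None = None  # default: 1.0 with zinc, 0.17 without
    f_min: float = 3.0  # pN, ramp bottom
    f_max: float = 45.0  # pN, ramp top
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_f < 0 or self.noise_sigma_x < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.refold_prob is None:
            self.refold_prob = 1.0 if self.zinc else 0.17


def _extension_tables(model: TetherModel, f_lo: float, f_hi: float):
    F = np.linspace(max(f_lo * 0.5, 0.2), f_hi * 1.4, 4000)
    xf = np.array(series_extension(F, model, "folded"))
    xu = np.array(series_extension(F, model, "unfolded"))
    return F, xf, xu


def simulate_trace(
    config: SyntheticTraceConfig, tether: TetherModel | None = None
) -> tuple[PullTrace, list[dict]]:
    """Generate pull-relax cycles with planted two-state transitions.

    Each cycle ramps the commanded extension linearly up and back down; the
    force follows the series tether model in the current state, so an
    unfolding rupture appears as a simultaneous extension-residual jump and
    force drop.  Rupture forces are drawn by inverse CDF from the ramp
    rupture-force density with the configured rate law and loading rate
    (a draw beyond the ramp top is a no-event cycle, i.e. censoring).
    Returns the trace and the ground-truth event log
    (cycle / kind / force / delta_Lc entries).
    """
    if tether is None:
        tether = TetherModel(delta_Lc=config.delta_Lc)
    elif abs(tether.delta_Lc - config.delta_Lc) > 1e-9:
        tether = TetherModel(
            **{**tether.__dict__, "delta_Lc": config.delta_Lc}
        )
    rng = np.random.default_rng(config.seed)
    Fg, xf, xu = _extension_tables(tether, config.f_min, config.f_max)

    grid = np.linspace(config.f_min, config.f_max, 800)
    p_unfold = force_distribution(config.unfold, config.loading_rate, grid, "unfolding")
    p_refold = force_distribution(
        config.refold, config.loading_rate, grid, "refolding", start_force=config.f_max
    )

    x_lo = float(np.interp(config.f_min, Fg, xf))
    x_hi = float(np.interp(config.f_max, Fg, xf))
    nspc = config.samples_per_cycle
    # map loading rate to ramp speed via the folded stiffness at 20 pN
    k_eff = 1.0 / float(np.gradient(xf, Fg)[np.argmin(np.abs(Fg - 20.0))])
    speed = config.loading_rate / k_eff  # nm/s
    dt = (x_hi - x_lo) / speed / nspc

    rows_t, rows_x, rows_f, rows_c, rows_d = [], [], [], [], []
    truth: list[dict] = []
    t = 0.0
    for cyc in range(config.n_cycles):
        f_rup = float(sample_rupture_forces(p_unfold, 1, rng)[0])
        x_cmd_up = np.linspace(x_lo, x_hi, nspc)
        F_folded = np.interp(x_cmd_up, xf, Fg)
        state_unfolded = ~np.isnan(f_rup) & (F_folded >= f_rup)
        if np.isnan(f_rup):
            state_unfolded = np.zeros(nspc, dtype=bool)
        F_true = np.where(state_unfolded, np.interp(x_cmd_up, xu, Fg), F_folded)
        times = t + dt * np.arange(nspc)
        rows_t.append(times)
        rows_x.append(x_cmd_up + rng.normal(0.0, config.noise_sigma_x, nspc))
        rows_f.append(F_true + rng.normal(0.0, config.noise_sigma_f, nspc))
        rows_c.append(np.full(nspc, cyc))
        rows_d.append(np.full(nspc, "pull", dtype=object))
        unfolded_at_top = bool(state_unfolded[-1])
        if unfolded_at_top:
            truth.append(
                {"cycle": cyc, "kind": "unfold", "force": f_rup, "delta_Lc": config.delta_Lc}
            )
        t = times[-1] + dt

        # relax: refold (state returns to folded) at a drawn force, if any
        x_cmd_dn = np.linspace(x_hi, x_lo, nspc)
        if unfolded_at_top and rng.uniform() < config.refold_prob:
            f_ref = float(sample_rupture_forces(p_refold, 1, rng)[0])
        else:
            f_ref = np.nan
        F_unf = np.interp(x_cmd_dn, xu, Fg)
        if np.isnan(f_ref) or not unfolded_at_top:
            still_unfolded = np.full(nspc, unfolded_at_top)
        else:
            still_unfolded = F_unf > f_ref
        F_true = np.where(still_unfolded, F_unf, np.interp(x_cmd_dn, xf, Fg))
        if unfolded_at_top and not np.isnan(f_ref) and not still_unfolded[-1]:
            truth.append(
                {"cycle": cyc, "kind": "refold", "force": f_ref, "delta_Lc": -config.delta_Lc}
            )
        times = t + dt * np.arange(nspc)
        rows_t.append(times)
        rows_x.append(x_cmd_dn + rng.normal(0.0, config.noise_sigma_x, nspc))
        rows_f.append(F_true + rng.normal(0.0, config.noise_sigma_f, nspc))
        rows_c.append(np.full(nspc, cyc))
        rows_d.append(np.full(nspc, "relax", dtype=object))
        t = times[-1] + dt

    trace = PullTrace(
        time=np.concatenate(rows_t),
        extension=np.concatenate(rows_x),
        force=np.concatenate(rows_f),
        cycle=np.concatenate(rows_c),
        direction=np.concatenate(rows_d),
    )
    return trace, truth


def simulate_kymograph(
    dye_distances: np.ndarray,
    scan_period: float = 1.0,
    background: float = 2.0,
    amplitude: float = 50.0,
    R0: float = 65.0,
    n_pixels: int = 120,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Donor-fluorescence kymograph for a series of inter-dye distances (Å).

    Donor intensity in the inter-bead band is proportional to 1 - E(r): the
    folded state (~20 Å separation against R0 = 65 Å) quenches the donor
    almost completely, the extended chain (>= 100 Å) lights it up.  Two
    constant bead-autofluorescence bands frame the signal; Poisson counting
    noise throughout.  Returns (pixels x scans) counts and the
    (top band, signal band, bottom band) row slices.
    """
    dye_distances = np.asarray(dye_distances, dtype=float)
    n_scans = len(dye_distances)
    rng = np.random.default_rng(seed)
    lam = np.full((n_pixels, n_scans), background)
    top = slice(8, 24)
    bottom = slice(n_pixels - 24, n_pixels - 8)
    mid = slice(n_pixels // 2 - 5, n_pixels // 2 + 5)
    lam[top, :] += 6.0 * amplitude  # bead autofluorescence bars
    lam[bottom, :] += 6.0 * amplitude
    donor = amplitude * (1.0 - fret_efficiency(dye_distances, R0))
    lam[mid, :] += donor[None, :]
    counts = rng.poisson(lam).astype(float)
    return counts, (top, mid, bottom)
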
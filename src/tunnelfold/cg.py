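"""Coarse-grained representation of a ribosome-tethered nascent chain.

One bead per protein residue (at the Cα position), three beads per RNA
nucleotide (P, C4', N3) when real environment coordinates are loaded; the
packaged surrogate tunnel uses generic wall beads.  Attractive interactions
within the chain exist only between residue pairs in contact in the native
structure (a structure-based, Gō-type energy function); the environment acts
through short-range repulsion, screened electrostatics with a
distance-dependent dielectric, and an optional weak non-specific attraction.

Units: nm, kBT (298 K reference), elementary charges.  See
:mod:`tunnelfold.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import COULOMB_KBT_NM

__all__ = [
    "BeadChain",
    "RibosomeEnvironment",
    "EnergyParams",
    "GeometryError",
    "assign_charges",
    "dielectric_profile",
    "electrostatic_energy",
    "total_energy",
    "fraction_native",
    "smooth_fraction_native",
    "build_topology",
    "RESIDUE_CHARGES",
]

#: Charge per residue type: aspartate/glutamate -1, arginine/lysine +1,
#: histidine +0.5, all other standard residues 0.
RESIDUE_CHARGES = {
    "D": -1.0,
    "E": -1.0,
    "R": +1.0,
    "K": +1.0,
    "H": +0.5,
}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class GeometryError(ValueError):
    """Chain cannot be placed in the requested environment geometry."""


@dataclass
class RibosomeEnvironment:
    """Static environment beads (tunnel walls, surrogate or loaded).

    ``anchor_index`` marks the bead standing in for the N-terminus of
    ribosomal protein uL4, the fixed point the pulling force acts against.
    ``roles`` labels each bead ("P"/"C4'"/"N3" for RNA triplets, "wall"/"base"
    /"anchor" for the surrogate).  Environment beads are never integrated.
    """

    positions: np.ndarray  # (m, 3) nm
    radii: np.ndarray  # (m,) nm
    charges: np.ndarray  # (m,) e
    anchor_index: int
    tunnel_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    tunnel_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    roles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        m = len(self.positions)
        if not (0 <= self.anchor_index < m):
            raise ValueError(f"anchor_index {self.anchor_index} out of range for {m} beads")

    @property
    def n_beads(self) -> int:
        return len(self.positions)


@dataclass
class BeadChain:
    """Coarse-grained nascent chain: folded domain plus C-terminal linker.

    Bead 0 is the domain N-terminus (the pulled bead); the last bead is the
    linker C-terminus, held fixed at the tether point (the peptidyl
    transferase centre surrogate at the tunnel base).
    """

    sequence: str
    positions: np.ndarray  # (n, 3) nm
    charges: np.ndarray  # (n,) e
    bond_r0: float  # nm, rest length of consecutive-bead bonds
    contact_i: np.ndarray  # (m,) int
    contact_j: np.ndarray  # (m,) int
    contact_r0: np.ndarray  # (m,) nm reference distances
    contact_eps: np.ndarray  # (m,) kBT well depths
    linker_length: int
    domain_range: tuple[int, int]  # [start, stop) bead indices of the domain
    fixed_index: int  # tethered bead, not integrated

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.contact_i = np.asarray(self.contact_i, dtype=np.int64)
        self.contact_j = np.asarray(self.contact_j, dtype=np.int64)
        self.contact_r0 = np.asarray(self.contact_r0, dtype=float)
        self.contact_eps = np.asarray(self.contact_eps, dtype=float)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def native_contacts(self) -> list[tuple[int, int, float, float]]:
        return list(
            zip(
                self.contact_i.tolist(),
                self.contact_j.tolist(),
                self.contact_r0.tolist(),
                self.contact_eps.tolist(),
            )
        )

    def copy(self) -> "BeadChain":
        return replace(self, positions=self.positions.copy(), charges=self.charges.copy())


@dataclass
class EnergyParams:
    """Tunable parameters of the coarse-grained energy function.

    ``eps_limit``/``eps_solvent``/``r_midpoint``/``sigma_eps`` parameterise the
    distance-dependent dielectric: 5.2 is the limiting permittivity next to a
    charged residue, 80 the bulk water value at 298 K; the switch has its
    midpoint at 8 Å with a 10 Å scale.
    """

    contact_strength: float = 1.5  # kBT per native contact
    excluded_radius: float = 0.19  # nm per chain bead (pair sigma = sum of radii)
    repulsion_strength: float = 1.0  # kBT
    debye_length: float = 1.0  # nm (~100 mM monovalent salt)
    eps_solvent: float = 80.0
    eps_limit: float = 5.2
    r_midpoint: float = 0.8  # nm
    sigma_eps: float = 1.0  # nm
    temperature: float = 1.0  # reduced, 1.0 = 298 K reference
    electrostatics_on: bool = True
    nonspecific_attraction: float = 0.0  # well depth, kBT
    bond_k: float = 1000.0  # kBT/nm^2
    bond_r0: float = 0.38  # nm
    elec_cutoff: float | None = None  # nm; default 3 Debye lengths

    def __post_init__(self) -> None:
        if self.debye_length <= 0:
            raise ValueError("debye_length must be positive")
        if self.eps_solvent <= self.eps_limit:
            raise ValueError("eps_solvent must exceed eps_limit")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")
        if self.nonspecific_attraction < 0:
            raise ValueError("nonspecific_attraction must be >= 0")

    @property
    def electrostatic_cutoff(self) -> float:
        return self.elec_cutoff if self.elec_cutoff is not None else 3.0 * self.debye_length


def assign_charges(
    sequence: str, environment: RibosomeEnvironment | None = None
) -> np.ndarray:
    """Charge vector for a chain sequence (and, in place, the environment).

    Aspartate and glutamate carry -1, arginine and lysine +1, histidine +0.5;
    everything else is neutral.  If ``environment`` is given and carries RNA
    role labels, the phosphate-role bead of each nucleotide triplet is set to
    -1 and all other environment beads to 0 (in place).

    Raises ``ValueError`` naming the position of any non-standard residue.
    """
    charges = np.zeros(len(sequence))
    for pos, aa in enumerate(sequence):
        if aa not in _STANDARD_AA:
            raise ValueError(f"unknown residue code {aa!r} at position {pos}")
        charges[pos] = RESIDUE_CHARGES.get(aa, 0.0)
    if environment is not None and environment.roles is not None:
        env_charges = np.where(np.asarray(environment.roles) == "P", -1.0, 0.0)
        environment.charges = env_charges
    return charges


def dielectric_profile(r, params: EnergyParams | None = None):
    """Distance-dependent dielectric permittivity.

    eps_d(r) = (eps_lim + eps_s)/2 + (eps_s - eps_lim)/2 * tanh((r - r_m)/sigma),
    rising monotonically from the limiting value near a charge (5.2) to bulk
    water (80).  ``r`` in nm; scalar or array.
    """
    if params is None:
        params = EnergyParams()
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    lo, hi = params.eps_limit, params.eps_solvent
    out = (lo + hi) / 2.0 + (hi - lo) / 2.0 * np.tanh((r - params.r_midpoint) / params.sigma_eps)
    return float(out) if out.ndim == 0 else out


def _pair_elec(q1: float, q2: float, r: float, params: EnergyParams) -> float:
    eps_d = dielectric_profile(r, params)
    return COULOMB_KBT_NM * q1 * q2 * np.exp(-r / params.debye_length) / (eps_d * r)


def electrostatic_energy(
    positions: np.ndarray,
    charges: np.ndarray,
    params: EnergyParams,
    env_positions: np.ndarray | None = None,
    env_charges: np.ndarray | None = None,
) -> float:
    """Screened-Coulomb energy in kBT.

    V = sum_{i<j} q_i q_j exp(-d_ij/lambda_D) / (4 pi eps_d(d_ij) eps0 d_ij)
    over all charged chain pairs plus, if given, all chain-environment pairs
    (environment self-energy is a constant and excluded).  Returns 0 when
    electrostatics are switched off or all charges vanish.  Rejects coincident
    charged beads.
    """
    if not params.electrostatics_on:
        return 0.0
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    total = 0.0
    idx = np.nonzero(charges)[0]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            r = float(np.linalg.norm(positions[i] - positions[j]))
            if r == 0.0:
                raise ValueError(f"coincident charged beads {i} and {j}")
            total += _pair_elec(charges[i], charges[j], r, params)
    if env_positions is not None and env_charges is not None:
        env_positions = np.asarray(env_positions, dtype=float)
        env_charges = np.asarray(env_charges, dtype=float)
        jdx = np.nonzero(env_charges)[0]
        for i in idx:
            for j in jdx:
                r = float(np.linalg.norm(positions[i] - env_positions[j]))
                if r == 0.0:
                    raise ValueError(f"chain bead {i} coincides with environment bead {j}")
                total += _pair_elec(charges[i], env_charges[j], r, params)
    return float(total)


#: Hard cap on the excluded-volume reduced distance: below 0.4 sigma the
#: repulsion is held at its (large but finite) value there.
_REP_CAP_FRAC = 0.4


def _repulsion(r: float, sigma: float, eps_rep: float) -> float:
    r_eff = max(r, _REP_CAP_FRAC * sigma)
    return eps_rep * (sigma / r_eff) ** 12


def total_energy(
    chain: BeadChain,
    environment: RibosomeEnvironment | None,
    params: EnergyParams,
) -> dict[str, float]:
    """Per-term energy breakdown of the chain in its environment (kBT).

    Terms: ``bonded`` (harmonic consecutive-bead bonds), ``contacts``
    (12-10 structure-based wells on native pairs), ``excluded`` (r^-12
    repulsion on non-native chain pairs and all chain-environment pairs),
    ``electrostatic``, ``nonspecific`` (optional chain-environment r^-6
    attraction with well depth ``params.nonspecific_attraction``), and
    ``total``.  Overlapping beads produce a large finite repulsion, never an
    overflow.
    """
    pos = chain.positions
    n = chain.n_beads
    e_bond = 0.0
    for i in range(n - 1):
        r = float(np.linalg.norm(pos[i + 1] - pos[i]))
        e_bond += 0.5 * params.bond_k * (r - chain.bond_r0) ** 2

    # 12-10 well: eps * (5 (r0/r)^12 - 6 (r0/r)^10), minimum -eps at r0
    e_contact = 0.0
    native_pairs = set()
    for i, j, r0, eps in zip(chain.contact_i, chain.contact_j, chain.contact_r0, chain.contact_eps):
        native_pairs.add((int(i), int(j)))
        r = float(np.linalg.norm(pos[i] - pos[j]))
        r = max(r, _REP_CAP_FRAC * r0)
        x = r0 / r
        e_contact += eps * (5.0 * x**12 - 6.0 * x**10)

    sigma = 2.0 * params.excluded_radius
    e_rep = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if (i, j) in native_pairs or (j, i) in native_pairs:
                continue
            r = float(np.linalg.norm(pos[i] - pos[j]))
            if r < 2.5 * sigma:
                e_rep += _repulsion(r, sigma, params.repulsion_strength)

    e_ns = 0.0
    if environment is not None:
        a_ns = params.nonspecific_attraction
        c_ns = np.sqrt(a_ns * params.repulsion_strength)
        for i in range(n):
            for j in range(environment.n_beads):
                sig_ij = params.excluded_radius + environment.radii[j]
                r = float(np.linalg.norm(pos[i] - environment.positions[j]))
                if r < 2.5 * sig_ij:
                    e_rep += _repulsion(r, sig_ij, params.repulsion_strength)
                    if a_ns > 0.0:
                        r_eff = max(r, _REP_CAP_FRAC * sig_ij)
                        e_ns += -2.0 * c_ns * (sig_ij / r_eff) ** 6

    e_elec = electrostatic_energy(
        pos,
        chain.charges,
        params,
        environment.positions if environment is not None else None,
        environment.charges if environment is not None else None,
    )
    terms = {
        "bonded": e_bond,
        "contacts": e_contact,
        "excluded": e_rep,
        "electrostatic": e_elec,
        "nonspecific": e_ns,
    }
    terms["total"] = sum(terms.values())
    return terms


def fraction_native(
    positions: np.ndarray,
    contact_i: np.ndarray,
    contact_j: np.ndarray,
    contact_r0: np.ndarray,
    threshold: float = 1.2,
) -> float:
    """Fraction of native contacts Q in [0, 1].

    A contact is formed when its distance is below ``threshold`` times the
    native reference distance (default 1.2).
    """
    contact_i = np.asarray(contact_i, dtype=np.int64)
    if contact_i.size == 0:
        raise ValueError("native contact list is empty")
    positions = np.asarray(positions, dtype=float)
    d = np.linalg.norm(positions[contact_i] - positions[np.asarray(contact_j, dtype=np.int64)], axis=1)
    return float(np.mean(d < threshold * np.asarray(contact_r0, dtype=float)))


def smooth_fraction_native(
    positions: np.ndarray,
    contact_i: np.ndarray,
    contact_j: np.ndarray,
    contact_r0: np.ndarray,
    threshold: float = 1.2,
    width: float = 0.05,
) -> float:
    """Differentiable Q: logistic switch of width ``width`` nm per contact.

    Used as the biasing coordinate in umbrella sampling, where the hard-count
    Q has no gradient.
    """
    positions = np.asarray(positions, dtype=float)
    d = np.linalg.norm(
        positions[np.asarray(contact_i, dtype=np.int64)]
        - positions[np.asarray(contact_j, dtype=np.int64)],
        axis=1,
    )
    cut = threshold * np.asarray(contact_r0, dtype=float)
    return float(np.mean(1.0 / (1.0 + np.exp((d - cut) / width))))


def chain_fraction_native(chain: BeadChain, positions: np.ndarray | None = None) -> float:
    """Q of a BeadChain at its current (or supplied) coordinates."""
    pos = chain.positions if positions is None else positions
    return fraction_native(pos, chain.contact_i, chain.contact_j, chain.contact_r0)


def extract_contacts(
    positions: np.ndarray,
    cutoff: float = 0.8,
    min_sep: int = 3,
) -> list[tuple[int, int, float]]:
    """Native contact list from Cα coordinates.

    Residue pairs separated by at least ``min_sep`` in sequence whose Cα-Cα
    distance is below ``cutoff`` nm (default 8 Å).
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    out = []
    for i in range(n):
        for j in range(i + min_sep, n):
            d = float(np.linalg.norm(positions[i] - positions[j]))
            if d < cutoff:
                out.append((i, j, d))
    return out


#: Axial rise per linker residue when threading the linker down the tunnel
#: (nm).  Below the 0.38 nm bond length so the linker zig-zags, mimicking a
#: non-taut nascent chain; with this value an L=26 linker places the domain
#: inside the vestibule, L=34 at the tunnel mouth and L=40 clear of the exit.
LINKER_RISE = 0.26


def build_topology(
    native_positions: np.ndarray,
    sequence: str,
    linker_length: int,
    environment: RibosomeEnvironment | None = None,
    *,
    zinc: bool = True,
    coordination: tuple[int, int, int, int] | None = None,
    contact_cutoff: float = 0.8,
    params: EnergyParams | None = None,
) -> BeadChain:
    """Assemble a tethered chain: folded domain plus C-terminal linker.

    The domain (one bead per residue at the Cα position) is translated so its
    C-terminal residue sits on the tunnel axis at height ``linker_length *
    LINKER_RISE`` above the tether point; linker beads (Gly/Ser repeat)
    zig-zag down the axis to the tether point, where the final bead is fixed.
    Native contacts are extracted by cutoff scan; if ``zinc`` and a
    ``coordination`` quadruple (two His, two Cys) are given, the six pairwise
    coordination contacts get doubled well depth, and with ``zinc=False`` they
    are removed entirely (folding without the ion has a weaker native basin).

    Raises :class:`GeometryError` when the domain cannot be placed without
    penetrating the tunnel wall, and ``ValueError`` for negative
    ``linker_length`` or a sequence/coordinate mismatch.
    """
    if params is None:
        params = EnergyParams()
    if linker_length < 0:
        raise ValueError("linker_length must be >= 0")
    native_positions = np.asarray(native_positions, dtype=float)
    n_dom = len(native_positions)
    if len(sequence) != n_dom:
        raise ValueError(
            f"sequence length {len(sequence)} != structure residue count {n_dom}"
        )

    if environment is not None:
        axis = environment.tunnel_axis / np.linalg.norm(environment.tunnel_axis)
        origin = environment.tunnel_origin
    else:
        axis = np.array([0.0, 0.0, 1.0])
        origin = np.zeros(3)

    L = linker_length
    c_target = origin + axis * (L * LINKER_RISE)
    # orient the domain so it extends outward along the axis from its
    # C-terminus, then translate the C-terminus onto the axis
    centred = native_positions - native_positions[-1]
    v = centred.mean(axis=0)
    dom_pos = _rotate_align(centred, v, axis) + c_target

    # linker: alternating lateral offsets keep each bond at bond_r0
    bond_r0 = params.bond_r0
    lat = np.sqrt(max(bond_r0**2 - LINKER_RISE**2, 0.0))
    perp = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(perp, axis)) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    perp = perp - np.dot(perp, axis) * axis
    perp /= np.linalg.norm(perp)
    linker_pos = np.empty((L, 3))
    for k in range(L):
        z = (L - 1 - k) * LINKER_RISE
        # one-sided zig-zag: alternate on-axis / lat-offset beads so every
        # bond has length bond_r0; the tether bead stays exactly at the base
        off = lat * perp * (1 if k % 2 == 0 else 0)
        if k == L - 1:
            off = np.zeros(3)
        linker_pos[k] = origin + axis * z + off

    positions = np.vstack([dom_pos, linker_pos]) if L > 0 else dom_pos
    linker_seq = ("GS" * L)[:L]
    full_seq = sequence + linker_seq
    charges = assign_charges(full_seq)

    if environment is not None:
        _check_tunnel_fit(positions, environment, params)

    contacts = extract_contacts(dom_pos, cutoff=contact_cutoff)
    eps = params.contact_strength
    ci, cj, cr, ce = [], [], [], []
    coord_pairs = set()
    if coordination is not None:
        q = sorted(coordination)
        coord_pairs = {(q[a], q[b]) for a in range(4) for b in range(a + 1, 4)}
    for i, j, d in contacts:
        if (i, j) in coord_pairs:
            if not zinc:
                continue  # no ion, no coordination contact
            ci.append(i), cj.append(j), cr.append(d), ce.append(2.0 * eps)
        else:
            ci.append(i), cj.append(j), cr.append(d), ce.append(eps)
    if zinc and coordination is not None:
        # coordination pairs too close in sequence for the cutoff scan
        have = {(a, b) for a, b in zip(ci, cj)}
        for (i, j) in sorted(coord_pairs):
            if (i, j) not in have and j - i >= 3:
                d = float(np.linalg.norm(dom_pos[i] - dom_pos[j]))
                ci.append(i), cj.append(j), cr.append(d), ce.append(2.0 * eps)

    return BeadChain(
        sequence=full_seq,
        positions=positions,
        charges=charges,
        bond_r0=bond_r0,
        contact_i=np.array(ci, dtype=np.int64),
        contact_j=np.array(cj, dtype=np.int64),
        contact_r0=np.array(cr),
        contact_eps=np.array(ce),
        linker_length=L,
        domain_range=(0, n_dom),
        fixed_index=n_dom + L - 1,
    )


def _rotate_align(points: np.ndarray, v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Rotate ``points`` (about the origin) taking direction v_from to v_to."""
    a = v_from / np.linalg.norm(v_from)
    b = v_to / np.linalg.norm(v_to)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return points.copy()
    if c < -1.0 + 1e-12:  # antiparallel: rotate pi about any perpendicular
        perp = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(perp, a)) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        k = np.cross(a, perp)
        k /= np.linalg.norm(k)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + 2.0 * K @ K
        return points @ R.T
    k = np.cross(a, b)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + K + K @ K * (1.0 / (1.0 + c))
    return points @ R.T


def _check_tunnel_fit(
    positions: np.ndarray, environment: RibosomeEnvironment, params: EnergyParams
) -> None:
    """Reject placements that bury domain beads inside the tunnel wall."""
    axis = environment.tunnel_axis / np.linalg.norm(environment.tunnel_axis)
    rel = positions - environment.tunnel_origin
    z = rel @ axis
    radial = np.linalg.norm(rel - np.outer(z, axis), axis=1)
    # conservative wall estimate from the environment beads themselves
    env_rel = environment.positions - environment.tunnel_origin
    env_z = env_rel @ axis
    env_rad = np.linalg.norm(env_rel - np.outer(env_z, axis), axis=1)
    wall_mask = env_rad > 0.3
    if not np.any(wall_mask):
        return
    length = float(np.max(env_z[wall_mask]))
    bad = []
    for k in range(len(positions)):
        if 0.0 <= z[k] <= length:
            near = wall_mask & (np.abs(env_z - z[k]) < 0.5)
            if not np.any(near):
                continue
            local_radius = float(np.min(env_rad[near]))
            if radial[k] > local_radius + params.excluded_radius:
                bad.append((k, float(z[k]), float(radial[k]), local_radius))
    if bad:
        report = "; ".join(
            f"bead {k} at z={z:.2f} nm sits r={r:.2f} nm from the axis "
            f"(wall radius {w:.2f} nm)"
            for k, z, r, w in bad[:5]
        )
        raise GeometryError(
            f"domain does not fit the tunnel at this linker length: {report}"
        )
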
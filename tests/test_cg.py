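"""Coarse-grained model: charges, dielectric, energies, Q, topology."""

import numpy as np
import pytest

from tunnelfold.cg import (
    BeadChain,
    EnergyParams,
    GeometryError,
    RibosomeEnvironment,
    assign_charges,
    build_topology,
    chain_fraction_native,
    dielectric_profile,
    electrostatic_energy,
    extract_contacts,
    fraction_native,
    total_energy,
)
from tunnelfold.units import COULOMB_KBT_NM


class TestAssignCharges:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("R", [1.0]),
            ("H", [0.5]),
            ("GSGS", [0.0, 0.0, 0.0, 0.0]),
            ("DEK", [-1.0, -1.0, 1.0]),
        ],
    )
    def test_charge_table(self, seq, expected):
        assert assign_charges(seq).tolist() == expected

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            assign_charges("GGXG")

    def test_rna_phosphate_beads_get_minus_one(self):
        env = RibosomeEnvironment(
            positions=np.zeros((6, 3)) + np.arange(6)[:, None],
            radii=np.full(6, 0.25),
            charges=np.zeros(6),
            anchor_index=0,
            roles=np.array(["P", "C4'", "N3", "P", "C4'", "N3"], dtype=object),
        )
        assign_charges("G", env)
        assert env.charges.tolist() == [-1.0, 0.0, 0.0, -1.0, 0.0, 0.0]


class TestDielectric:
    def test_midpoint_is_mean_of_limits(self):
        assert dielectric_profile(0.8) == pytest.approx((5.2 + 80.0) / 2.0)

    def test_saturates_to_bulk_water(self):
        assert dielectric_profile(10.0) == pytest.approx(80.0, abs=1e-6)

    def test_printed_formula_at_one_sigma(self):
        expected = 42.6 + 37.4 * np.tanh(1.0)
        assert dielectric_profile(1.8) == pytest.approx(expected, rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            dielectric_profile(-0.1)

    def test_bounded_and_monotone_on_grid(self):
        r = np.linspace(0.0, 10.0, 2001)
        eps = dielectric_profile(r)
        assert np.all(eps > 5.2) and np.all(eps < 80.0 + 1e-9)
        assert np.all(np.diff(eps) >= 0)


class TestElectrostatics:
    def test_zero_charges_zero_energy(self):
        pos = np.random.default_rng(0).normal(size=(5, 3))
        assert electrostatic_energy(pos, np.zeros(5), EnergyParams()) == 0.0

    def test_switched_off_is_exactly_zero(self):
        pos = np.array([[0.0, 0, 0], [0.8, 0, 0]])
        p = EnergyParams(electrostatics_on=False)
        assert electrostatic_energy(pos, np.array([1.0, 1.0]), p) == 0.0

    def test_hand_computed_pair(self):
        # two +1 charges 0.8 nm apart, lambda_D = 1 nm: the dielectric sits
        # exactly at its midpoint value 42.6
        pos = np.array([[0.0, 0, 0], [0.8, 0, 0]])
        v = electrostatic_energy(pos, np.array([1.0, 1.0]), EnergyParams(debye_length=1.0))
        expected = COULOMB_KBT_NM * np.exp(-0.8) / (42.6 * 0.8)
        assert v == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("r", [0.3, 0.8, 1.5, 2.5])
    def test_screening_monotone_in_debye_length(self, r):
        pos = np.array([[0.0, 0, 0], [r, 0, 0]])
        q = np.array([1.0, -1.0])
        v1 = abs(electrostatic_energy(pos, q, EnergyParams(debye_length=1.0)))
        v2 = abs(electrostatic_energy(pos, q, EnergyParams(debye_length=2.0)))
        assert v2 >= v1

    def test_coincident_charges_rejected(self):
        pos = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            electrostatic_energy(pos, np.array([1.0, 1.0]), EnergyParams())


def _three_bead_chain():
    pos = np.array([[0.0, 0, 0], [0.38, 0, 0], [0.55, 0.3, 0]])
    return BeadChain(
        sequence="KGE",
        positions=pos,
        charges=assign_charges("KGE"),
        bond_r0=0.38,
        contact_i=np.array([], dtype=np.int64),
        contact_j=np.array([], dtype=np.int64),
        contact_r0=np.array([]),
        contact_eps=np.array([]),
        linker_length=0,
        domain_range=(0, 3),
        fixed_index=2,
    )


class TestTotalEnergy:
    def test_native_minimum_of_go_wells(self, free_domain, params):
        e = total_energy(free_domain, None, params)
        assert e["contacts"] == pytest.approx(-np.sum(free_domain.contact_eps), rel=1e-9)
        assert 0 <= e["excluded"] < 2.0  # weak residual repulsion only

    def test_electrostatics_off_term_exactly_zero(self, free_domain):
        p = EnergyParams(electrostatics_on=False)
        assert total_energy(free_domain, None, p)["electrostatic"] == 0.0

    def test_zeroed_charges_match_repulsion_only_model(self, free_domain, params):
        neutral = free_domain.copy()
        neutral.charges = np.zeros_like(neutral.charges)
        e_neutral = total_energy(neutral, None, params)
        e_off = total_energy(free_domain, None, EnergyParams(electrostatics_on=False))
        for term in ("bonded", "contacts", "excluded", "electrostatic", "total"):
            assert e_neutral[term] == pytest.approx(e_off[term], abs=1e-12)

    def test_three_bead_brute_force_oracle(self):
        chain = _three_bead_chain()
        p = EnergyParams()
        e = total_energy(chain, None, p)
        # independent brute force over explicit pairs
        pos, q = chain.positions, chain.charges
        r01 = np.linalg.norm(pos[1] - pos[0])
        r12 = np.linalg.norm(pos[2] - pos[1])
        r02 = np.linalg.norm(pos[2] - pos[0])
        e_bond = 0.5 * p.bond_k * ((r01 - 0.38) ** 2 + (r12 - 0.38) ** 2)
        sig = 2 * p.excluded_radius
        e_rep = p.repulsion_strength * (sig / r02) ** 12 if r02 < 2.5 * sig else 0.0
        eps_d = dielectric_profile(r02)
        e_el = COULOMB_KBT_NM * q[0] * q[2] * np.exp(-r02 / p.debye_length) / (eps_d * r02)
        # K-G adjacent pair (bonded) still counts as a charged pair: zero
        # product; K-E is the only charged pair
        assert e["bonded"] == pytest.approx(e_bond, abs=1e-10)
        assert e["excluded"] == pytest.approx(e_rep, abs=1e-10)
        assert e["electrostatic"] == pytest.approx(e_el, abs=1e-10)
        assert e["total"] == pytest.approx(e_bond + e_rep + e_el, abs=1e-10)

    def test_rigid_motion_invariance(self, free_domain, params):
        rng = np.random.default_rng(7)
        e0 = total_energy(free_domain, None, params)["total"]
        for _ in range(3):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(0, 2 * np.pi)
            K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
            moved = free_domain.copy()
            moved.positions = free_domain.positions @ R.T + rng.normal(size=3)
            assert total_energy(moved, None, params)["total"] == pytest.approx(e0, abs=1e-8)

    def test_overlapping_beads_finite(self, params):
        chain = _three_bead_chain()
        chain.positions[2] = chain.positions[0] + 1e-4
        chain.charges = np.zeros(3)
        e = total_energy(chain, None, params)
        assert np.isfinite(e["total"]) and e["excluded"] > 10.0


class TestFractionNative:
    def test_native_is_one(self, free_domain):
        assert chain_fraction_native(free_domain) == 1.0

    def test_extended_is_zero(self, free_domain):
        n = free_domain.n_beads
        pos = np.zeros((n, 3))
        pos[:, 2] = 0.38 * np.arange(n)
        assert chain_fraction_native(free_domain, pos) == 0.0

    def test_half_formed_constructed(self):
        # 4 contacts, exactly 2 within 1.2x reference
        pos = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [9, 0, 0]], float)
        ci = np.array([0, 0, 0, 0])
        cj = np.array([1, 2, 3, 4])
        r0 = np.array([1.0, 1.0, 3.0, 3.0])
        assert fraction_native(pos, ci, cj, r0) == 0.5

    def test_empty_contacts_rejected(self):
        with pytest.raises(ValueError):
            fraction_native(np.zeros((3, 3)), [], [], [])

    def test_q_decreases_under_affine_stretch(self, toy):
        contacts = extract_contacts(toy.positions)
        ci = np.array([c[0] for c in contacts])
        cj = np.array([c[1] for c in contacts])
        r0 = np.array([c[2] for c in contacts])
        centred = toy.positions - toy.positions.mean(axis=0)
        _, _, vt = np.linalg.svd(centred)
        qs = []
        for s in (1.0, 1.3, 1.6, 2.0, 3.0, 5.0):
            stretched = centred + (s - 1.0) * np.outer(centred @ vt[0], vt[0])
            qs.append(fraction_native(stretched, ci, cj, r0))
        assert qs[0] == 1.0
        assert all(a >= b for a, b in zip(qs, qs[1:]))
        assert qs[-1] < 0.5


class TestBuildTopology:
    def test_linker_26_bead_count_and_tether(self, toy, tunnel, params):
        chain = build_topology(
            toy.positions, toy.sequence, 26, tunnel,
            coordination=toy.coordination, params=params,
        )
        assert chain.n_beads == 29 + 26
        assert chain.fixed_index == chain.n_beads - 1
        assert np.allclose(chain.positions[chain.fixed_index], tunnel.tunnel_origin)
        bond_lengths = np.linalg.norm(np.diff(chain.positions, axis=0), axis=1)
        assert np.all(np.abs(bond_lengths - 0.38) < 0.02)

    def test_domain_only_when_linker_zero(self, toy, params):
        chain = build_topology(toy.positions, toy.sequence, 0, None, params=params)
        assert chain.n_beads == 29
        assert chain.fixed_index == 28

    def test_contacts_match_brute_force_scan(self, toy, params):
        chain = build_topology(toy.positions, toy.sequence, 0, None, params=params)
        got = set(zip(chain.contact_i.tolist(), chain.contact_j.tolist()))
        pos = chain.positions
        expected = {
            (i, j)
            for i in range(29)
            for j in range(i + 3, 29)
            if np.linalg.norm(pos[i] - pos[j]) < 0.8
        }
        assert got == expected

    def test_negative_linker_rejected(self, toy):
        with pytest.raises(ValueError):
            build_topology(toy.positions, toy.sequence, -1, None)

    def test_sequence_structure_mismatch_rejected(self, toy):
        with pytest.raises(ValueError, match="residue count"):
            build_topology(toy.positions, toy.sequence[:-2], 0, None)

    def test_domain_inside_narrow_tunnel_rejected(self, toy):
        from tunnelfold.synthetic import make_tunnel

        narrow = make_tunnel(radius=0.4, vestibule_radius=0.5)
        with pytest.raises(GeometryError, match="wall radius"):
            build_topology(toy.positions, toy.sequence, 0, narrow)

    def test_zinc_contacts_doubled_and_removable(self, toy, params):
        with_zn = build_topology(
            toy.positions, toy.sequence, 0, None,
            coordination=toy.coordination, zinc=True, params=params,
        )
        without = build_topology(
            toy.positions, toy.sequence, 0, None,
            coordination=toy.coordination, zinc=False, params=params,
        )
        assert len(with_zn.contact_i) > len(without.contact_i)
        assert with_zn.contact_eps.max() == pytest.approx(2 * params.contact_strength)
        assert without.contact_eps.max() == pytest.approx(params.contact_strength)
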
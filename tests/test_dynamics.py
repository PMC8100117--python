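"""Langevin integrator, first-passage machinery, rate estimation."""

import numpy as np
import pytest

from tunnelfold.cg import BeadChain, EnergyParams
from tunnelfold.dynamics import (
    PullProtocol,
    Trajectory,
    estimate_rate,
    first_passage_time,
    rate_vs_force,
    run_trajectory,
)

AXIS = np.array([0.0, 0.0, 1.0])


def single_bead():
    return BeadChain(
        sequence="G",
        positions=np.zeros((1, 3)),
        charges=np.zeros(1),
        bond_r0=0.38,
        contact_i=np.array([], dtype=np.int64),
        contact_j=np.array([], dtype=np.int64),
        contact_r0=np.array([]),
        contact_eps=np.array([]),
        linker_length=0,
        domain_range=(0, 1),
        fixed_index=-1,
    )


def dimer(bond_k=50.0):
    chain = BeadChain(
        sequence="GG",
        positions=np.array([[0.0, 0, 0], [0.38, 0, 0]]),
        charges=np.zeros(2),
        bond_r0=0.38,
        contact_i=np.array([], dtype=np.int64),
        contact_j=np.array([], dtype=np.int64),
        contact_r0=np.array([]),
        contact_eps=np.array([]),
        linker_length=0,
        domain_range=(0, 2),
        fixed_index=-1,
    )
    return chain, EnergyParams(bond_k=bond_k)


class TestIntegrator:
    def test_free_diffusion_msd(self):
        # <r^2> = 6 D t with D = T (friction 1); 200 independent walkers
        chain = single_bead()
        params = EnergyParams()
        n_steps, dt = 2000, 5e-4
        sq = []
        for seed in range(200):
            proto = PullProtocol(max_steps=n_steps, dt=dt, stride=n_steps,
                                 seed=seed, fixed_axis=AXIS)
            traj = run_trajectory(chain, None, params, proto)
            sq.append(np.sum(traj.final_positions[0] ** 2))
        msd = np.mean(sq)
        expected = 6.0 * params.temperature * n_steps * dt
        assert msd == pytest.approx(expected, rel=0.05)

    def test_dimer_equipartition(self):
        # bond-length variance -> kBT/k in the stiff-spring limit (the r^2
        # Jacobian of the radial coordinate adds a ~k-dependent correction,
        # ~3% at k=400, which the tolerance absorbs)
        chain, params = dimer(bond_k=400.0)
        proto = PullProtocol(max_steps=400_000, dt=1e-4, stride=20, seed=3,
                             fixed_axis=AXIS)
        traj = run_trajectory(chain, None, params, proto)
        b = traj.end_to_end[200:]
        assert b.var() == pytest.approx(1.0 / 400.0, rel=0.05)

    def test_boltzmann_sampling_of_contact_dimer(self):
        # two beads with one native contact: occupancy of the bound well
        # matches the 1D Boltzmann integral over r^2 exp(-V(r)/T)
        r0 = 0.5
        eps = 3.0
        chain = BeadChain(
            sequence="GG",
            positions=np.array([[0.0, 0, 0], [r0, 0, 0]]),
            charges=np.zeros(2),
            bond_r0=r0,
            contact_i=np.array([], dtype=np.int64),
            contact_j=np.array([], dtype=np.int64),
            contact_r0=np.array([]),
            contact_eps=np.array([]),
            linker_length=0,
            domain_range=(0, 2),
            fixed_index=-1,
        )
        params = EnergyParams(bond_k=20.0)  # soft tether
        proto = PullProtocol(max_steps=600_000, dt=2e-4, stride=20, seed=11,
                             fixed_axis=AXIS)
        traj = run_trajectory(chain, None, params, proto)
        r = traj.end_to_end[500:]
        cut = 0.7
        occupancy = np.mean(r < cut)
        rr = np.linspace(1e-3, 3.0, 4000)
        v = 0.5 * params.bond_k * (rr - r0) ** 2
        w = rr**2 * np.exp(-v / params.temperature)
        expected = np.trapezoid(w[rr < cut], rr[rr < cut]) / np.trapezoid(w, rr)
        assert occupancy == pytest.approx(expected, abs=0.03)

    def test_seed_determinism(self, free_domain, params):
        proto = PullProtocol(max_steps=5000, dt=5e-5, stride=50, seed=7, fixed_axis=AXIS)
        a = run_trajectory(free_domain, None, params, proto)
        b = run_trajectory(free_domain, None, params, proto)
        assert np.array_equal(a.q, b.q)
        assert np.array_equal(a.final_positions, b.final_positions)

    def test_unstable_timestep_rejected(self, free_domain, params):
        proto = PullProtocol(max_steps=100, dt=3e-3, seed=0, fixed_axis=AXIS)
        with pytest.raises(ValueError, match="stability"):
            run_trajectory(free_domain, None, params, proto)

    def test_divergence_reported(self):
        chain, params = dimer(bond_k=1000.0)
        chain.positions[1] = chain.positions[0] + 1e-5  # deep overlap via bond
        proto = PullProtocol(max_steps=10_000, dt=1.9e-3, stride=10, seed=0,
                             fixed_axis=AXIS)
        with pytest.raises(RuntimeError, match="diverged"):
            run_trajectory(chain, None, params, proto)

    def test_pulling_requires_anchor_or_axis(self, free_domain, params):
        with pytest.raises(ValueError, match="fixed_axis"):
            run_trajectory(
                free_domain, None, params,
                PullProtocol(force=5.0, max_steps=100, dt=5e-5),
            )


def make_traj(q_series, stride=1, dt=1.0, termination="max-steps"):
    q = np.asarray(q_series, dtype=float)
    return Trajectory(
        q=q,
        q_smooth=q,
        end_to_end=np.zeros_like(q),
        dt=dt,
        stride=stride,
        termination=termination,
        n_steps=len(q) * stride,
        final_positions=np.zeros((1, 3)),
    )


class TestFirstPassage:
    def test_direct_scan(self):
        traj = make_traj([1.0, 0.9, 0.15])
        t, censored = first_passage_time(traj, "folded", "unfolded")
        assert t == 2.0 and not censored

    def test_censored(self):
        traj = make_traj([1.0, 0.9, 0.85])
        t, censored = first_passage_time(traj, "folded", "unfolded")
        assert censored and t == 3.0

    def test_wrong_start_state_rejected(self):
        traj = make_traj([0.5, 0.2])
        with pytest.raises(ValueError, match="start"):
            first_passage_time(traj, "folded", "unfolded")

    def test_two_state_generator_ground_truth(self):
        # a synthetic Markov switch at a known frame is recovered exactly
        rng = np.random.default_rng(0)
        switch = 57
        q = np.concatenate([
            0.9 + 0.05 * rng.uniform(-1, 1, switch),
            0.1 + 0.05 * rng.uniform(-1, 1, 100 - switch),
        ])
        traj = make_traj(q, stride=10, dt=0.01)
        t, censored = first_passage_time(traj, "folded", "unfolded")
        assert not censored
        assert t == pytest.approx(switch * 10 * 0.01)


class TestRateEstimate:
    def test_reciprocal_mean(self):
        est = estimate_rate([2.0, 2.0, 2.0])
        assert est.rate == pytest.approx(0.5)
        assert est.n_events == 3 and est.n_censored == 0

    def test_exponential_recovery_and_coverage(self):
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(30):
            times = rng.exponential(10.0, size=500)
            est = estimate_rate(times, seed=rep)
            assert est.rate == pytest.approx(0.1, rel=0.1)
            if est.ci[0] <= 0.1 <= est.ci[1]:
                hits += 1
        assert hits >= 27  # 95% CI should cover in >= 90% of experiments

    def test_single_event_degenerate(self):
        est = estimate_rate([5.0])
        assert est.degenerate_ci
        assert est.rate == pytest.approx(0.2)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            estimate_rate([10.0, 10.0], censored=[True, True])

    def test_censoring_aware_mle(self):
        est = estimate_rate([2.0, 4.0, 8.0], censored=[False, False, True],
                            method="mle")
        assert est.rate == pytest.approx(2.0 / 14.0)
        assert est.n_censored == 1


class TestRateVsForce:
    def test_table_shape_and_unfolding_speedup(self, free_domain, params):
        # high force unfolds faster than the barely-perturbing one
        proto = PullProtocol(max_steps=150_000, dt=5e-5, stride=100, fixed_axis=AXIS)
        table = rate_vs_force(
            free_domain, None, params, [5.0, 40.0], n_replicas=4,
            direction="unfolding", seed=1, protocol=proto,
        )
        assert list(table.columns) == [
            "force_pN", "rate", "ci_lo", "ci_hi", "n_events", "n_censored"
        ]
        assert len(table) == 2
        ok = table.dropna(subset=["rate"])
        if len(ok) == 2:
            assert ok.rate.iloc[1] >= ok.rate.iloc[0]

    def test_empty_force_grid_rejected(self, free_domain, params):
        with pytest.raises(ValueError, match="empty"):
            rate_vs_force(free_domain, None, params, [], direction="folding")
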
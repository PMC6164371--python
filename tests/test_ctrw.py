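"""Monte-Carlo engine: sampling laws, boundary, bleach, recovery read-out."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from ctrw_oracle import ctrw_recovery_exact
from vrfrap.ctrw import (
    CtrwConfig,
    apply_bleach,
    compute_msd,
    propagate_particle,
    reflect,
    sample_jump,
    sample_waiting_time,
    simulate_recovery,
    vr_simulation,
)
from vrfrap.models import bleach_profile


class TestWaitingTime:
    def test_cdf_inverse_at_zero(self):
        for alpha in (0.3, 0.6, 1.0):
            assert sample_waiting_time(alpha, 0.0) == 0.0

    def test_exponent_one_median(self):
        assert sample_waiting_time(1.0, 0.5) == pytest.approx(1.0)

    def test_quartile_value(self):
        # numerically inverting the CDF 1 - (1+tau)^-alpha at u = 0.75,
        # alpha = 0.5 gives (0.25)^-2 - 1 = 15
        assert sample_waiting_time(0.5, 0.75) == pytest.approx(15.0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            sample_waiting_time(1.5, 0.5)

    @pytest.mark.parametrize("alpha", [0.6, 0.9])
    def test_empirical_ccdf_matches_levy_law(self, alpha, rng):
        draws = sample_waiting_time(alpha, rng.random(100_000))
        stat = kstest(draws, lambda x: 1 - (1 + x) ** (-alpha)).statistic
        assert stat < 0.01


class TestJump:
    def test_moments(self, rng):
        d = sample_jump(1.0, rng, size=100_000)
        se = np.sqrt(2.0 / d.shape[0])
        assert np.abs(d.mean(axis=0)).max() < 4 * np.sqrt(1.0 / d.shape[0])
        total_var = d.var(axis=0).sum()
        assert total_var == pytest.approx(2.0, abs=4 * se)
        assert d.var(axis=0)[0] / d.var(axis=0)[1] == pytest.approx(1.0, abs=0.05)

    def test_invalid_D(self, rng):
        with pytest.raises(ValueError):
            sample_jump(0.0, rng)


class TestReflect:
    def test_inside_unchanged(self):
        assert np.allclose(reflect([1.0, 1.0], 30.0, 0.03), [1.0, 1.0])

    def test_outside_reinserted_same_direction(self):
        out = reflect([31.0, 0.0], 30.0, 0.03)
        assert out == pytest.approx([29.97, 0.0])

    @settings(deadline=None, max_examples=60)
    @given(x=st.floats(-100, 100), y=st.floats(-100, 100))
    def test_magnitude_contract(self, x, y):
        out = reflect([x, y], 30.0, 0.03)
        assert np.linalg.norm(out) <= 30.0 + 1e-9


class TestApplyBleach:
    def test_no_bleach_all_survive(self, rng):
        pos = rng.normal(size=(1000, 2))
        assert not apply_bleach(pos, 0.0, 1.0, rng).any()

    def test_far_particles_survive(self, rng):
        pos = np.full((2000, 2), 50.0)
        assert apply_bleach(pos, 5.0, 1.0, rng).mean() < 0.01

    def test_annulus_survival_matches_profile(self, rng):
        # survival fraction per radial annulus follows the Gaussian law
        r = rng.uniform(0, 3, 100_000)
        theta = rng.uniform(0, 2 * np.pi, r.size)
        pos = np.c_[r * np.cos(theta), r * np.sin(theta)]
        bleached = apply_bleach(pos, 1.5, 1.0, rng)
        for lo in np.arange(0, 3, 0.5):
            sel = (r >= lo) & (r < lo + 0.5)
            expected = bleach_profile((lo + 0.25), 1.5, 1.0)
            n = sel.sum()
            tol = 4 * np.sqrt(expected * (1 - expected) / n) + 0.01
            assert (~bleached[sel]).mean() == pytest.approx(expected, abs=tol)


class TestPropagation:
    def test_immobile_until_first_jump(self):
        cfg = CtrwConfig(alpha=0.5, seed=3)
        rng = np.random.default_rng(0)

        class FirstWaitHuge:
            def __init__(self):
                self.calls = 0

            def random(self):
                self.calls += 1
                return 1 - 1e-12  # enormous first waiting time

            def normal(self, *a, **k):
                return rng.normal(*a, **k)

        traj = propagate_particle([1.0, 2.0], cfg, np.linspace(0.1, 50, 20),
                                  rng=FirstWaitHuge())
        assert np.allclose(traj, [1.0, 2.0])

    def test_positions_stay_in_domain(self):
        cfg = CtrwConfig(alpha=0.6, diffusion_coefficient=5.0,
                         domain_radius=5.0, bleach_radius=1.0, seed=5)
        traj = propagate_particle([4.0, 0.0], cfg, np.linspace(1, 2000, 60))
        assert np.all(np.linalg.norm(traj, axis=1) <= 5.0 + 1e-9)


class TestSimulateRecovery:
    def test_no_bleach_reads_one(self):
        for readout in ("weighted", "binary"):
            cfg = CtrwConfig(n_particles=100_000, bleach_constant=0.0,
                             bleach_radius=5.0, readout=readout, seed=2)
            c = simulate_recovery(cfg)
            tol = 1e-12 if readout == "weighted" else 0.1
            assert np.allclose(c.intensities, 1.0, atol=tol)

    def test_post_bleach_depth_below_one(self):
        cfg = CtrwConfig(n_particles=100_000, bleach_radius=2.0, seed=4)
        c = simulate_recovery(cfg)
        assert c.intensities[0] < 1.0

    def test_seed_reproducibility(self):
        cfg = CtrwConfig(n_particles=20_000, bleach_radius=2.0, seed=11)
        a = simulate_recovery(cfg)
        b = simulate_recovery(cfg)
        assert np.array_equal(a.intensities, b.intensities)

    def test_binary_unbleached_count_conserved(self):
        # the survivor population is fixed at the bleach pulse: no
        # particle appears or disappears during monitoring, so the disk
        # count never exceeds the survivor total, and with no bleach the
        # total is the whole ensemble
        cfg = CtrwConfig(n_particles=50_000, bleach_radius=2.0,
                         readout="binary", seed=9,
                         observation_times=np.logspace(-2, 2, 30))
        c = simulate_recovery(cfg)
        total = c.meta["unbleached_total"]
        counts = np.round(c.intensities * c.meta["prebleach_count"])
        assert np.all(counts <= total)
        unbleached = simulate_recovery(CtrwConfig(
            n_particles=20_000, bleach_radius=2.0, bleach_constant=0.0,
            readout="binary", seed=9))
        assert unbleached.meta["unbleached_total"] == 20_000

    def test_weighted_and_binary_estimators_agree(self):
        vals = {}
        for readout in ("weighted", "binary"):
            cfg = CtrwConfig(n_particles=400_000, bleach_radius=3.0,
                             alpha=0.7, diffusion_coefficient=0.5,
                             readout=readout, seed=21)
            vals[readout] = simulate_recovery(cfg).intensities
        # same expectation; binary carries a few-percent counting noise
        diff = np.abs(vals["weighted"] - vals["binary"])
        assert np.mean(diff) < 0.02
        assert np.max(diff) < 0.08

    def test_radius_must_fit_domain(self):
        with pytest.raises(ValueError):
            CtrwConfig(bleach_radius=31.0)

    def test_matches_montroll_weiss_oracle(self):
        """The simulated recovery agrees with the exact (propagator-level)
        CTRW expectation on the unbounded plane within Monte Carlo error."""
        alpha, D, K, R = 0.6, 0.5, 1.2, 2.0
        ts = np.array([0.05, 1.0, 20.0, 100.0, 400.0])
        exact = ctrw_recovery_exact(ts, R, D, alpha, K)
        cfg = CtrwConfig(n_particles=30_000_000, domain_radius=60.0,
                         alpha=alpha, diffusion_coefficient=D,
                         bleach_radius=R, bleach_constant=K,
                         observation_times=ts, seed=13)
        sim = simulate_recovery(cfg).intensities
        assert np.max(np.abs(sim - exact)) < 5e-3

    def test_vr_simulation_radii_and_determinism(self):
        cfg = CtrwConfig(n_particles=20_000, seed=3)
        curves = vr_simulation(cfg, [1.0, 2.0, 3.0])
        assert [c.bleach_radius for c in curves] == [1.0, 2.0, 3.0]
        again = vr_simulation(cfg, [1.0, 2.0, 3.0])
        assert np.array_equal(curves[1].intensities, again[1].intensities)


class TestMsd:
    def test_msd_zero_at_time_zero(self):
        cfg = CtrwConfig(n_particles=2_000, alpha=0.6, seed=1)
        msd, _ = compute_msd(cfg, np.array([0.0, 1.0, 10.0, 100.0]))
        assert msd[0] == 0.0

    def test_brownian_scaling(self):
        cfg = CtrwConfig(n_particles=20_000, alpha=1.0, mode="brownian",
                         diffusion_coefficient=1.0, seed=2)
        _, slope = compute_msd(cfg, np.logspace(-1, 2, 25))
        assert slope == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("alpha", [0.6, 0.8])
    def test_subdiffusive_exponent(self, alpha):
        cfg = CtrwConfig(n_particles=20_000, alpha=alpha,
                         diffusion_coefficient=1.0, seed=3)
        _, slope = compute_msd(cfg, np.logspace(0, 6, 40))
        assert slope == pytest.approx(alpha, abs=0.05)

    def test_needs_two_times(self):
        cfg = CtrwConfig(n_particles=100, seed=0)
        with pytest.raises(ValueError):
            compute_msd(cfg, np.array([1.0]))
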
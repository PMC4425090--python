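import math

import numpy as np
import pytest

from greenextract.kinetics import (
    CrankFit,
    KineticDataset,
    UnfittableError,
    WashingScenario,
    correct_for_sampling,
    crank_profile,
    crank_series_fraction,
    deff_from_k,
    extrapolate_residual,
    fit_crank,
    simulate_washes,
    starting_accessibility,
)

GRID = np.array([1.0, 3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 60.0, 90.0, 120.0])


def series_oracle(tau: float, n_terms: int = 1000) -> float:
    """Independent plain-loop partial sum of the sphere series."""
    total = 0.0
    for i in range(1, n_terms + 1):
        expo = -(i**2) * math.pi**2 * tau
        if expo < -745:
            break
        total += 6.0 / (i**2 * math.pi**2) * math.exp(expo)
    return total


def profile_oracle(deff, rd, x_inf, x0, t0_min, t_min, n_terms=1000) -> float:
    tau = deff * (t_min - t0_min) * 60.0 / rd**2
    return x_inf - (x_inf - x0) * series_oracle(tau, n_terms)


class TestCrankProfile:
    def test_value_at_t0_is_x0(self):
        assert crank_profile(1e-11, 1e-3, 0.46, 0.10, 5.0, [5.0])[0] == pytest.approx(
            0.10, abs=1e-15
        )

    def test_long_time_limit(self):
        x = crank_profile(1e-9, 1e-3, 0.46, 0.10, 5.0, [5000.0])
        assert x[0] == pytest.approx(0.46, abs=1e-9)

    def test_against_high_order_oracle(self):
        # frozen example: Deff = 0.122e-10 m2/s, rd = 1 mm, 60 min past t0
        got = crank_profile(0.122e-10, 1e-3, 0.4596, 0.100, 5.0, [65.0], n_terms=200)[0]
        want = profile_oracle(0.122e-10, 1e-3, 0.4596, 0.100, 5.0, 65.0, n_terms=1000)
        assert got == pytest.approx(want, abs=1e-12)

    def test_oracle_agreement_over_tau_grid(self):
        # dimensionless times down to 1e-4 agree with the 1000-term oracle
        rd = 1e-3
        for tau in np.geomspace(1e-4, 2.0, 25):
            t_min = 5.0 + tau * rd**2 / (1e-11 * 60.0)
            got = crank_profile(1e-11, rd, 1.0, 0.0, 5.0, [t_min], n_terms=200)[0]
            want = profile_oracle(1e-11, rd, 1.0, 0.0, 5.0, t_min)
            assert got == pytest.approx(want, abs=1e-10), f"tau={tau}"

    def test_nondecreasing(self):
        x = crank_profile(1e-11, 1e-3, 0.46, 0.10, 5.0, np.linspace(5, 500, 200))
        assert np.all(np.diff(x) >= -1e-15)

    def test_time_before_t0_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            crank_profile(1e-11, 1e-3, 0.46, 0.10, 5.0, [4.0])

    def test_bad_n_terms(self):
        with pytest.raises(ValueError):
            crank_series_fraction(0.1, n_terms=0)


class TestDeffFromK:
    def test_printed_diffusivity_inversion(self):
        # k back-solved from Deff = 0.122e-10 at rd = 1 mm
        assert deff_from_k(1.204e-4, 1e-3) == pytest.approx(1.22e-11, rel=1e-3)

    def test_radius_scaling(self):
        assert deff_from_k(0.5, 2e-3) == pytest.approx(4 * deff_from_k(0.5, 1e-3))

    def test_unit_case(self):
        assert deff_from_k(math.pi**2, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("k,rd", [(0.0, 1e-3), (-1.0, 1e-3), (1.0, 0.0)])
    def test_domain_errors(self, k, rd):
        with pytest.raises(ValueError):
            deff_from_k(k, rd)


def make_dataset(deff, x_inf=0.4596, x0=0.100, rd=1e-3, t0=5.0, grid=GRID, hint=True):
    mask = grid > t0
    x = np.empty_like(grid)
    x[~mask] = x0 * grid[~mask] / t0
    x[mask] = crank_profile(deff, rd, x_inf, x0, t0, grid[mask], n_terms=2000)
    return KineticDataset(
        times_min=grid, x=x, rd_m=rd, x_inf_hint=x_inf if hint else None
    )


class TestFitCrank:
    @pytest.mark.parametrize("deff", [0.034e-10, 0.122e-10])
    def test_recovers_printed_diffusivities(self, deff):
        ds = make_dataset(deff)
        fit = fit_crank(ds)
        assert fit.deff_m2_s == pytest.approx(deff, rel=0.05)
        assert fit.x0 == pytest.approx(0.100, rel=0.02)

    def test_single_exponential_recovered_exactly(self):
        # pure one-term data: the log-linear slope is an identity
        k = 5e-4
        t = np.array([10.0, 20.0, 40.0, 80.0])
        x_inf, x0 = 0.5, 0.1
        x = x_inf - (x_inf - x0) * np.exp(-k * (t - 5.0) * 60.0)
        ds = KineticDataset(t, x, rd_m=1e-3, x_inf_hint=x_inf)
        fit = fit_crank(ds, method="loglinear")
        assert fit.k_per_s == pytest.approx(k, rel=1e-10)
        assert fit.x0 == pytest.approx(x0, rel=1e-9)

    def test_fixed_x0_through_origin(self):
        k = 5e-4
        t = np.array([10.0, 20.0, 40.0])
        x = 0.5 - 0.4 * np.exp(-k * (t - 5.0) * 60.0)
        ds = KineticDataset(t, x, rd_m=1e-3, x_inf_hint=0.5)
        fit = fit_crank(ds, method="loglinear", x0=0.1)
        assert fit.k_per_s == pytest.approx(k, rel=1e-10)
        assert fit.x0 == 0.1

    def test_loglinear_biased_on_short_time_data(self):
        # the single-term route overestimates Deff in the multi-term regime;
        # this is why the series refinement is the default
        ds = make_dataset(0.034e-10)
        loglin = fit_crank(ds, method="loglinear")
        assert loglin.deff_m2_s > 1.5 * 0.034e-10

    def test_points_at_plateau_dropped(self):
        t = np.array([10.0, 20.0, 40.0, 80.0])
        x = np.array([0.2, 0.3, 0.5, 0.4])
        ds = KineticDataset(t, x, rd_m=1e-3, x_inf_hint=0.5)
        with pytest.warns(UserWarning, match="dropping"):
            fit = fit_crank(ds)
        assert fit.n_points_used == 3

    def test_unfittable_when_all_dropped(self):
        t = np.array([10.0, 20.0, 40.0])
        x = np.array([0.5, 0.55, 0.54])
        ds = KineticDataset(t, x, rd_m=1e-3)
        with pytest.warns(UserWarning):
            with pytest.raises(UnfittableError):
                fit_crank(ds, x_inf=0.5)

    def test_too_few_points(self):
        t = np.array([10.0, 20.0])
        x = np.array([0.2, 0.3])
        ds = KineticDataset(t, x, rd_m=1e-3, x_inf_hint=0.5)
        with pytest.raises(UnfittableError, match=">= 3"):
            fit_crank(ds)

    def test_noiseless_grid_recovery_property(self):
        # seeded grid over the diffusivity/accessibility plane
        rng = np.random.default_rng(7)
        for _ in range(10):
            deff = 10 ** rng.uniform(math.log10(0.01e-10), math.log10(1e-10))
            x0 = rng.uniform(0.0, 0.3 * 0.46)
            ds = make_dataset(deff, x0=x0)
            fit = fit_crank(ds)
            assert fit.deff_m2_s == pytest.approx(deff, rel=0.05)

    def test_noisy_recovery_within_15pct(self):
        # 2% multiplicative noise, 50 replicates, fixed seed; x0 known
        rng = np.random.default_rng(42)
        deffs = [0.034e-10, 0.122e-10]
        for deff in deffs:
            clean = make_dataset(deff)
            for _ in range(25):
                noisy = clean.x * (1.0 + 0.02 * rng.standard_normal(clean.x.size))
                ds = KineticDataset(
                    clean.times_min, np.clip(noisy, 0, None), rd_m=1e-3, x_inf_hint=0.4596
                )
                fit = fit_crank(ds, x0=0.100)
                assert abs(fit.deff_m2_s / deff - 1.0) <= 0.15

    def test_invariant_deff_equals_k_rd2_pi2(self):
        ds = make_dataset(0.122e-10)
        fit = fit_crank(ds)
        assert fit.deff_m2_s == pytest.approx(deff_from_k(fit.k_per_s, ds.rd_m), rel=1e-12)


class TestStartingAccessibility:
    def test_recovers_generator_value(self):
        ds = make_dataset(0.122e-10, x0=0.100)
        x0, pct = starting_accessibility(ds, total_oil=0.4634)
        assert x0 == pytest.approx(0.100, rel=0.02)
        assert pct == pytest.approx(100 * 0.100 / 0.4634, rel=0.02)
        assert round(pct, 1) == pytest.approx(21.6, abs=0.3)

    def test_zero_accessibility(self):
        ds = make_dataset(0.122e-10, x0=0.0)
        x0, pct = starting_accessibility(ds)
        assert x0 == pytest.approx(0.0, abs=1e-6)
        assert pct is None


class TestCorrectForSampling:
    def test_zero_draws_equal_naive_conversion(self):
        t = GRID
        f = np.linspace(0.01, 0.09, t.size)
        ds = correct_for_sampling(t, np.zeros_like(t), f, 120.0, 30.0, rd_m=1e-3)
        naive = f / (1 - f) * 120.0 / 30.0
        np.testing.assert_allclose(ds.x, naive, rtol=1e-12)

    def test_forward_simulation_round_trip(self):
        # forward-simulate draws from a known curve, then invert
        from greenextract.synthetic import KineticGenSpec, gen_kinetics

        spec = KineticGenSpec(
            deff=0.122e-10, rd=1e-3, x_inf=0.4596, x0=0.100,
            withdrawal_mass_g=1.0, solvent_mass_g=120.0, dry_matter_g=30.0,
        )
        run = gen_kinetics(spec)
        np.testing.assert_allclose(run.dataset.x, run.x_true, rtol=0.005)

    def test_overdraw_rejected(self):
        t = np.array([1.0, 2.0, 3.0])
        m = np.array([50.0, 50.0, 50.0])
        f = np.array([0.01, 0.01, 0.01])
        with pytest.raises(ValueError, match="mass balance"):
            correct_for_sampling(t, m, f, 100.0, 30.0, rd_m=1e-3)


def scenario(**kw):
    defaults = dict(
        n_washes=5, wash_duration_min=30.0, solvent_to_solid=1.5,
        retention=0.3, deff=0.034e-10, rd=0.45e-3, oil_content_initial=0.21,
    )
    defaults.update(kw)
    return WashingScenario(**defaults)


class TestSimulateWashes:
    def test_oil_conservation(self):
        sim = simulate_washes(scenario())
        assert np.all(np.abs(sim.table["mass_balance_error"]) <= 1e-9)

    def test_zero_washes(self):
        sim = simulate_washes(scenario(n_washes=0))
        assert len(sim.table) == 0

    def test_instantaneous_equilibrium_limit(self):
        # huge Deff: the first wash recovers the full drainage-limited amount
        sim = simulate_washes(scenario(deff=1e-6, n_washes=1))
        expected = 100.0 * 1.5 / (1.5 + 0.3)
        assert sim.cumulative_recovery_pct[0] == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_deff(self):
        recoveries = [
            simulate_washes(scenario(deff=d)).cumulative_recovery_pct
            for d in (0.02e-10, 0.05e-10, 0.2e-10, 1e-10)
        ]
        for lo, hi in zip(recoveries, recoveries[1:]):
            assert np.all(hi >= lo - 1e-12)

    def test_cumulative_nondecreasing(self):
        sim = simulate_washes(scenario())
        assert np.all(np.diff(sim.cumulative_recovery_pct) >= 0)

    def test_flooded_bed_rejected(self):
        with pytest.raises(ValueError, match="retention"):
            simulate_washes(scenario(retention=2.0))

    def test_volumetric_retention_mode(self):
        by_mass = simulate_washes(scenario())
        by_volume = simulate_washes(
            scenario(retention=300.0 / 0.675, retention_mode="volume", solvent_density=0.675)
        )
        np.testing.assert_allclose(
            by_mass.cumulative_recovery_pct, by_volume.cumulative_recovery_pct, rtol=1e-12
        )

    def test_faster_solvent_needs_fewer_washes(self):
        slow = simulate_washes(scenario(deff=0.034e-10))
        fast = simulate_washes(scenario(deff=0.122e-10))
        assert fast.washes_to_reach(95) <= 3
        assert slow.washes_to_reach(95) >= 4


class TestExtrapolateResidual:
    def test_printed_projection(self):
        projected, gain = extrapolate_residual(16.5, 1.8, 0.8)
        assert round(projected, 1) == 7.3
        assert round(gain, 1) == 9.2

    def test_no_improvement(self):
        _, gain = extrapolate_residual(16.5, 1.8, 1.8)
        assert gain == 0.0

    def test_perfect_extraction(self):
        projected, gain = extrapolate_residual(16.5, 1.8, 0.0)
        assert projected == 0.0
        assert gain == 16.5

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_residual(16.5, 0.0, 0.8)


class TestDatasetValidation:
    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            KineticDataset(np.array([1.0, 1.0]), np.array([0.1, 0.2]), rd_m=1e-3)

    def test_hint_bound(self):
        with pytest.raises(ValueError, match="plateau hint"):
            KineticDataset(np.array([1.0, 2.0]), np.array([0.1, 0.6]), rd_m=1e-3, x_inf_hint=0.5)
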
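import numpy as np
import pytest

from ppgsim.photon_transport import (
    DetectorSpec,
    SourceSpec,
    compute_weight_windows,
    detect_exit,
    fresnel_interface,
    launch_photon,
    move_and_deposit,
    roulette,
    run_simulation,
    sample_hg_scatter,
    sample_step,
    PhotonState,
)

from oracles import semi_infinite_reflectance


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestLaunch:
    def test_normal_launch_with_specular_deficit(self, rng):
        p = launch_photon(SourceSpec(), rng, n_tissue=1.47)
        assert np.allclose(p.direction, [0, 0, 1])
        r_expected = ((1.47 - 1.0) / (1.47 + 1.0)) ** 2
        assert p.weight == pytest.approx(1.0 - r_expected, rel=1e-12)
        assert p.weight == pytest.approx(1.0 - 0.0362, abs=2e-4)

    def test_flat_profile_radii_uniform_over_disc(self, rng):
        src = SourceSpec(profile="flat", beam_waist_radius_cm=0.06)
        radii = np.array([
            np.linalg.norm(launch_photon(src, rng).position[:2] - [src.x_cm, src.y_cm])
            for _ in range(10_000)
        ])
        # CDF of radius over a uniform disc is (r/R)^2
        from scipy.stats import kstest

        stat = kstest(radii, lambda r: np.clip((r / 0.06) ** 2, 0, 1))
        assert stat.pvalue > 1e-3

    def test_gaussian_radius_scale(self, rng):
        src = SourceSpec(profile="gaussian", beam_waist_radius_cm=0.06)
        r2 = np.array([
            np.sum((launch_photon(src, rng).position[:2] - [src.x_cm, src.y_cm]) ** 2)
            for _ in range(20_000)
        ])
        # for intensity ~ exp(-2 r^2 / w^2): E[r^2] = w^2 / 2
        assert r2.mean() == pytest.approx(0.06**2 / 2, rel=0.05)


class TestSampleStep:
    def test_moments_match_exponential(self, rng):
        mu_t = 100.0
        s = np.array([sample_step(mu_t, rng) for _ in range(60_000)])
        assert s.mean() == pytest.approx(1 / mu_t, rel=3 * 1 / np.sqrt(len(s)))
        assert s.var() == pytest.approx(1 / mu_t**2, rel=0.05)

    def test_non_positive_mu_t_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_step(0.0, rng)


class TestMoveAndDeposit:
    def test_transparent_medium_deposits_nothing(self):
        p = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.8)
        out = np.zeros(1)
        q = move_and_deposit(p, np.array([0.0]), np.array([0.5]), out)
        assert q.weight == 0.8
        assert out[0] == 0.0

    def test_single_segment_beer_lambert(self):
        p = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0)
        out = np.zeros(1)
        q = move_and_deposit(p, np.array([2.0]), np.array([0.3]), out)
        assert q.weight == pytest.approx(np.exp(-0.6))
        assert out[0] == pytest.approx(1 - np.exp(-0.6))

    def test_piecewise_equals_single_segment_over_total_optical_path(self):
        p = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0)
        q = move_and_deposit(p, np.array([2.0, 2.0]), np.array([0.1, 0.2]))
        assert q.weight == pytest.approx(np.exp(-2.0 * 0.3), rel=1e-12)


class TestHenyeyGreenstein:
    def test_isotropic_mean_cos_zero(self, rng):
        down = np.array([0.0, 0.0, 1.0])
        cos = np.array([
            sample_hg_scatter(0.0, rng, down) @ down for _ in range(30_000)
        ])
        assert abs(cos.mean()) < 3.5 / np.sqrt(len(cos))

    @pytest.mark.parametrize("g", [0.7, 0.9])
    def test_mean_cos_equals_g(self, rng, g):
        down = np.array([0.0, 0.0, 1.0])
        cos = np.array([
            sample_hg_scatter(g, rng, down) @ down for _ in range(30_000)
        ])
        sigma = cos.std() / np.sqrt(len(cos))
        assert cos.mean() == pytest.approx(g, abs=4 * sigma)

    def test_output_always_unit_norm(self, rng):
        d = np.array([0.6, 0.0, 0.8])
        for _ in range(200):
            out = sample_hg_scatter(0.9, rng, d)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)
            d = out

    def test_invalid_anisotropy_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_hg_scatter(1.0, rng)


class TestFresnel:
    def test_matched_boundary_transmits_unchanged(self, rng):
        d = np.array([0.0, 0.6, 0.8])
        out, reflected = fresnel_interface(d, 1.4, 1.4, np.array([0.0, 0.0, 1.0]), rng)
        assert not reflected
        assert np.allclose(out, d)

    def test_normal_incidence_reflectance(self, rng):
        d = np.array([0.0, 0.0, 1.0])
        n_hits = sum(
            fresnel_interface(d, 1.0, 1.47, np.array([0.0, 0.0, 1.0]), rng)[1]
            for _ in range(60_000)
        )
        expected = ((1.0 - 1.47) / (1.0 + 1.47)) ** 2
        assert expected == pytest.approx((0.47 / 2.47) ** 2)
        assert n_hits / 60_000 == pytest.approx(expected, abs=0.004)

    def test_total_internal_reflection(self, rng):
        theta = np.arcsin(1 / 1.47) + 0.05  # beyond the critical angle
        d = np.array([np.sin(theta), 0.0, np.cos(theta)])
        for _ in range(50):
            out, reflected = fresnel_interface(d, 1.47, 1.0, np.array([0.0, 0.0, 1.0]), rng)
            assert reflected
            assert out[2] == pytest.approx(-d[2])

    def test_snell_angle_on_refraction(self, rng):
        theta1 = 0.4
        d = np.array([np.sin(theta1), 0.0, np.cos(theta1)])
        normal = np.array([0.0, 0.0, 1.0])
        for _ in range(500):
            out, reflected = fresnel_interface(d, 1.0, 1.47, normal, rng)
            if not reflected:
                theta2 = np.arccos(out @ normal)
                assert np.sin(theta1) == pytest.approx(1.47 * np.sin(theta2), rel=1e-9)
                break
        else:
            pytest.fail("refraction never sampled")


class TestRoulette:
    def test_above_threshold_unchanged(self, rng):
        p = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.5)
        assert roulette(p, 1e-4, 10, rng) is p

    def test_unbiased_in_expectation(self, rng):
        w0 = 1e-5
        total = 0.0
        reps = 40_000
        for _ in range(reps):
            p = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), w0)
            q = roulette(p, 1e-4, 10, rng)
            total += q.weight if q.alive else 0.0
        assert total / reps == pytest.approx(w0, rel=0.08)

    def test_multiplier_one_always_survives(self, rng):
        p = PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1e-6)
        q = roulette(p, 1e-4, 1.0, rng)
        assert q.alive and q.weight == 1e-6


class TestDetectExit:
    def test_center_vertical_accepted(self):
        det = DetectorSpec()
        assert detect_exit((det.x_cm, det.y_cm), 1.0, det)

    def test_steep_angle_rejected(self):
        det = DetectorSpec()  # NA 0.866 -> 60 deg cone
        assert not detect_exit((det.x_cm, det.y_cm), np.cos(np.radians(75)), det)
        assert detect_exit((det.x_cm, det.y_cm), np.cos(np.radians(55)), det)

    def test_outside_aperture_rejected(self):
        det = DetectorSpec()
        edge = det.aperture_side_cm / 2
        assert not detect_exit((det.x_cm + edge + 0.3, det.y_cm), 1.0, det)
        assert detect_exit((det.x_cm + edge - 1e-9, det.y_cm), 1.0, det)


class TestRunSimulation:
    def test_energy_conservation(self, baseline_volume):
        res = run_simulation(baseline_volume, n_photons=20_000, seed=5)
        assert abs(res.conservation_residual) < 1e-6

    def test_same_seed_bit_identical(self, baseline_volume):
        a = run_simulation(baseline_volume, n_photons=5_000, seed=9)
        b = run_simulation(baseline_volume, n_photons=5_000, seed=9)
        assert a == b

    def test_partitioned_runs_merge_to_single_run(self, baseline_volume):
        whole = run_simulation(baseline_volume, n_photons=4_000, seed=3)
        first = run_simulation(baseline_volume, n_photons=2_000, seed=3)
        second = run_simulation(baseline_volume, n_photons=2_000, seed=3,
                                photon_offset=2_000)
        merged = first.merged_with(second)
        assert merged.detected_weight_fraction == pytest.approx(
            whole.detected_weight_fraction, rel=1e-12
        )
        assert merged.absorbed_fraction == pytest.approx(
            whole.absorbed_fraction, rel=1e-12
        )

    def test_no_absorption_conserves_without_deposit(self, homogeneous_volume):
        vol = homogeneous_volume
        props = vol.properties.copy()
        props[0, 0] = 0.0  # transparent
        from ppgsim.tissue_volume import VoxelGrid

        clear = VoxelGrid(grid=vol.grid, media=vol.media, properties=props)
        res = run_simulation(clear, n_photons=5_000, seed=2, internal_fresnel=False,
                             detection_estimator="analog")
        assert res.absorbed_fraction == 0.0
        total_escape = (res.total_diffuse_reflectance + res.transmitted_fraction
                        + res.side_escape_fraction + res.specular_reflectance
                        + res.roulette_residual)
        assert total_escape == pytest.approx(1.0, abs=1e-9)

    def test_detected_never_exceeds_diffuse(self, baseline_volume):
        res = run_simulation(baseline_volume, n_photons=20_000, seed=8)
        assert res.detected_weight_fraction <= res.total_diffuse_reflectance

    def test_absorption_map_totals_match_tally(self, baseline_volume):
        res = run_simulation(baseline_volume, n_photons=3_000, seed=4,
                             accumulate_map=True)
        assert res.absorption_map.sum() / res.n_photons == pytest.approx(
            res.absorbed_fraction, rel=1e-9
        )

    def test_semi_infinite_reflectance_matches_independent_oracle(
        self, homogeneous_volume
    ):
        # benchmark medium mu_a=10, mu_s=90, g=0.75, matched boundary
        n = 150_000
        blocks = np.array([
            run_simulation(homogeneous_volume, n_photons=n // 5, seed=21,
                           photon_offset=k * n // 5, internal_fresnel=False,
                           ).total_diffuse_reflectance
            for k in range(5)
        ])
        ours = blocks.mean()
        ours_se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        oracle, oracle_se = semi_infinite_reflectance(10.0, 90.0, 0.75, n, seed=77)
        combined = np.hypot(ours_se, oracle_se)
        assert ours == pytest.approx(oracle, abs=3 * combined)

    def test_weight_windows_change_variance_not_mean(self, baseline_volume):
        ww = compute_weight_windows(baseline_volume, n_photons=8_000, seed=13)
        n = 60_000
        plain = run_simulation(baseline_volume, n_photons=n, seed=31)
        windowed = run_simulation(baseline_volume, n_photons=n, seed=31,
                                  weight_window_map=ww)
        assert abs(windowed.conservation_residual) < 1e-6
        # same expectation: agree within generous Monte Carlo slack
        assert windowed.detected_weight_fraction == pytest.approx(
            plain.detected_weight_fraction, rel=0.6
        )

    def test_analog_and_shadow_ray_estimators_agree(self, baseline_volume):
        ww = compute_weight_windows(baseline_volume, n_photons=8_000, seed=13)
        nee = run_simulation(baseline_volume, n_photons=50_000, seed=17,
                             weight_window_map=ww)
        blocks = np.array([
            run_simulation(baseline_volume, n_photons=100_000, seed=19,
                           photon_offset=k * 100_000,
                           detection_estimator="analog").detected_weight_fraction
            for k in range(4)
        ])
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert nee.detected_weight_fraction == pytest.approx(
            blocks.mean(), abs=4 * se + 0.15 * blocks.mean()
        )

    def test_stderr_scales_as_inverse_sqrt_photons(self, baseline_volume):
        ww = compute_weight_windows(baseline_volume, n_photons=8_000, seed=13)

        def block_std(n, n_blocks=8):
            vals = [
                run_simulation(baseline_volume, n_photons=n, seed=23,
                               photon_offset=k * n,
                               weight_window_map=ww).detected_weight_fraction
                for k in range(n_blocks)
            ]
            return np.std(vals, ddof=1)

        s_small = block_std(4_000)
        s_big = block_std(16_000)
        assert s_big < s_small  # must shrink
        assert s_small / s_big == pytest.approx(2.0, rel=0.75)
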